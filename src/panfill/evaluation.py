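"""Benchmark metrics for imputation and gap-filling.

Prediction metrics are computed only over *masked* positions — reactions not
given as input — so a model is never credited for repeating what it was
told.  Gap-fill metrics count artificially deleted reactions that were
re-added (TP), deleted but not re-added (FN) and added reactions that were
never in the original annotation (FP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from panfill.gapfill import DEFAULT_EPSILON, Medium, check_growth
from panfill.reactome import IncidenceMatrix, MetabolicNetwork, ReactionId

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts, either for predictions or for gap-filling."""

    TP: int
    FP: int
    FN: int
    TN: int
    context: str = "prediction"

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
            self.context,
        )


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    specificity: float
    balanced_accuracy: float


def confusion_from_predictions(
    scores: np.ndarray,
    truth: np.ndarray,
    input_vector: np.ndarray,
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts over masked (non-input) positions only."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    input_vector = np.asarray(input_vector)
    if not (scores.shape == truth.shape == input_vector.shape):
        raise ValueError("scores, truth and input vectors must be aligned")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    masked = input_vector == 0
    pred = scores >= threshold
    pos = truth == 1
    return ConfusionCounts(
        TP=int(np.sum(masked & pos & pred)),
        FN=int(np.sum(masked & pos & ~pred)),
        FP=int(np.sum(masked & ~pos & pred)),
        TN=int(np.sum(masked & ~pos & ~pred)),
        context="prediction",
    )


def confusion_from_gapfill(
    original: set[ReactionId],
    deleted: set[ReactionId],
    added: set[ReactionId],
    candidate_universe: set[ReactionId] | None = None,
) -> ConfusionCounts:
    """Score a gap-fill run against the artificially deleted reactions.

    TNs are candidate database reactions neither in the original annotation
    nor added; pass the prepared database's reaction set as
    ``candidate_universe`` to count them (0 otherwise).
    """
    if not deleted <= original:
        raise ValueError("deleted reactions must be a subset of the original set")
    retained = original - deleted
    if added & retained:
        raise ValueError("added reactions overlap the retained annotation")
    tp = len(added & deleted)
    fn = len(deleted - added)
    fp = len(added - original)
    tn = 0
    if candidate_universe is not None:
        tn = len(candidate_universe - original - added)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, context="gapfill")


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1, specificity and balanced accuracy.

    Zero-denominator cases evaluate to 0 by convention.
    """
    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    precision = _ratio(counts.TP, counts.TP + counts.FP)
    recall = _ratio(counts.TP, counts.TP + counts.FN)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    specificity = _ratio(counts.TN, counts.TN + counts.FP)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        balanced_accuracy=(specificity + recall) / 2.0,
    )


def frequency_binned_metrics(
    per_reaction_counts: Mapping[str, ConfusionCounts],
    occurrences: Mapping[str, int],
    bin_width: int = 50,
) -> pd.DataFrame:
    """Pool per-reaction confusion counts into occurrence bins.

    Reactions are grouped by the number of genomes they occur in, in bins of
    ``bin_width`` genomes; recall and precision are computed from the pooled
    counts per bin.  Empty bins are omitted.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rows = []
    bins: dict[int, list[str]] = {}
    for label, n_occ in occurrences.items():
        if label in per_reaction_counts:
            bins.setdefault(n_occ // bin_width, []).append(label)
    for b in sorted(bins):
        pooled = ConfusionCounts(0, 0, 0, 0)
        for label in bins[b]:
            pooled = pooled + per_reaction_counts[label]
        rep = metrics(pooled)
        rows.append(
            {
                "bin_start": b * bin_width,
                "bin_end": (b + 1) * bin_width,
                "recall": rep.recall,
                "precision": rep.precision,
                "n_reactions": len(bins[b]),
            }
        )
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "recall", "precision", "n_reactions"])


def nearest_neighbor_distance(query: np.ndarray, training: IncidenceMatrix) -> float:
    """Smallest Jaccard distance from a presence vector to any training row.

    Jaccard distance of binary sets A, B: ``1 - |A & B| / |A | B|``.
    """
    q = np.asarray(query).astype(bool)
    if not q.any():
        raise ValueError("query vector has no present reactions")
    rows = training.presence.astype(bool)
    inter = (rows & q).sum(axis=1)
    union = (rows | q).sum(axis=1)
    with np.errstate(invalid="ignore"):
        dist = 1.0 - inter / np.maximum(union, 1)
    return float(dist.min())


def essential_reactions(
    model: MetabolicNetwork,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
) -> set[ReactionId]:
    """Reactions whose single deletion drops max biomass flux below epsilon.

    The model must grow on the medium to begin with.
    """
    base = check_growth(model, medium, epsilon)
    if base < epsilon:
        raise ValueError("model does not grow on the given medium")
    essential: set[ReactionId] = set()
    for rxn in model.reactions:
        if rxn.id.label == model.biomass_reaction_id.label:
            essential.add(rxn.id)  # trivially essential
            continue
        trimmed = MetabolicNetwork(
            [r for r in model.reactions if r.id.label != rxn.id.label],
            model.biomass_reaction_id,
            {k: v for k, v in model.origin.items() if k != rxn.id.label},
            model.model_id,
        )
        if check_growth(trimmed, medium, epsilon) < epsilon:
            essential.add(rxn.id)
    return essential


def carbon_profile(
    model: MetabolicNetwork,
    base_medium: Medium,
    carbon_sources: Sequence[str],
    default_carbon: str | None = None,
    observed: Mapping[str, int] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    uptake_rate: float = 10.0,
) -> tuple[dict[str, int], MetricsReport | None]:
    """Simulated growth (0/1) per single carbon source, optionally scored.

    For each source the medium is the base medium minus the default carbon
    source plus this one.  A model that grows with *no* carbon source at all
    is flagged invalid (ValueError) and should be excluded from profiling; a
    source lacking an exchange reaction is recorded as no-growth with a
    warning.  If an observed binary profile is given, a
    :class:`MetricsReport` (balanced accuracy etc.) against it is returned.
    """
    no_carbon = Medium({
        m: r for m, r in base_medium.uptake.items()
        if m != default_carbon and m not in carbon_sources
    })
    if check_growth(model, no_carbon, epsilon) >= epsilon:
        raise ValueError(
            f"model {model.model_id} grows without any carbon source; "
            "profile would be uninformative"
        )
    exchangeable = {
        next(iter(r.stoichiometry))
        for r in model.reactions
        if r.id.identifier.startswith("EX_") and len(r.stoichiometry) == 1
    }
    profile: dict[str, int] = {}
    for source in carbon_sources:
        if source not in exchangeable:
            logger.warning(
                "%s: no exchange reaction for carbon source %s; recorded as no growth",
                model.model_id, source,
            )
            profile[source] = 0
            continue
        medium = no_carbon.replacing_carbon(None, source, uptake_rate)
        profile[source] = int(check_growth(model, medium, epsilon) >= epsilon)
    report = None
    if observed is not None:
        tp = sum(1 for s in carbon_sources if profile[s] and observed.get(s, 0))
        fp = sum(1 for s in carbon_sources if profile[s] and not observed.get(s, 0))
        fn = sum(1 for s in carbon_sources if not profile[s] and observed.get(s, 0))
        tn = sum(1 for s in carbon_sources if not profile[s] and not observed.get(s, 0))
        report = metrics(ConfusionCounts(tp, fp, fn, tn, context="gapfill"))
    return profile, report
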