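"""Benchmark protocols: corrupt, predict/gap-fill, score.

These functions wire the package's pieces into the standard evaluation
loops: per-genome prediction metrics on corrupted test genomes, per-reaction
confusion pooled into frequency bins, the four-scheme gap-fill recovery
comparison, the nearest-neighbor distance effect, and the deletion-bias
matching experiment.  They are used by the test suite and the reproduction
script alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panfill.corruption import DeletionScheme, corrupt, derive_seed, make_replicates
from panfill.evaluation import (
    ConfusionCounts,
    confusion_from_gapfill,
    confusion_from_predictions,
    frequency_binned_metrics,
    metrics,
    nearest_neighbor_distance,
)
from panfill.gapfill import (
    CostScheme,
    GapfillInfeasibleError,
    halfinterval_gapfill,
    make_costs,
)
from panfill.imputer import ReactionImputer
from panfill.reactome import IncidenceMatrix, PanReactome

logger = logging.getLogger(__name__)

SCHEME_ORDER = ["W1_none", "W2_naive_binary", "W3_frequency", "W4_nn"]


@dataclass
class PredictionBenchmark:
    """Prediction accuracy of an imputer on corrupted test genomes."""

    per_genome: pd.DataFrame
    per_reaction: dict[str, ConfusionCounts]
    mean_f1: float
    mean_recall: float
    mean_precision: float


def prediction_benchmark(
    imputer: ReactionImputer,
    test_matrix: IncidenceMatrix,
    n_replicates: int = 10,
    scheme: DeletionScheme | None = None,
    base_seed: int = 55,
    threshold: float = 0.5,
) -> PredictionBenchmark:
    """Corrupt each test genome ``n_replicates`` times, predict and score.

    Scoring is restricted to masked (non-input) positions.  Also pools
    per-reaction confusion counts for frequency-binned analyses.
    """
    scheme = scheme or DeletionScheme()
    labels = test_matrix.pan_reactome.labels
    rows = []
    per_rxn: dict[str, ConfusionCounts] = {}
    for sample in make_replicates(test_matrix, n_replicates, scheme, base_seed):
        scores = imputer.predict_proba(sample.input_vector.astype(float))
        counts = confusion_from_predictions(
            scores, sample.truth_vector, sample.input_vector, threshold
        )
        rep = metrics(counts)
        rows.append(
            {
                "genome_id": sample.genome_id,
                "replicate": sample.replicate_index,
                "f1": rep.f1,
                "recall": rep.recall,
                "precision": rep.precision,
            }
        )
        masked = sample.input_vector == 0
        pred = scores >= threshold
        for j in np.flatnonzero(masked):
            t = bool(sample.truth_vector[j])
            p = bool(pred[j])
            c = ConfusionCounts(
                int(t and p), int(not t and p), int(t and not p), int(not t and not p)
            )
            lab = labels[j]
            per_rxn[lab] = per_rxn[lab] + c if lab in per_rxn else c
    frame = pd.DataFrame(rows)
    return PredictionBenchmark(
        per_genome=frame,
        per_reaction=per_rxn,
        mean_f1=float(frame["f1"].mean()),
        mean_recall=float(frame["recall"].mean()),
        mean_precision=float(frame["precision"].mean()),
    )


def binned_recall_table(
    bench: PredictionBenchmark,
    matrix: IncidenceMatrix,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Frequency-binned pooled recall/precision; occurrences from ``matrix``."""
    labels = matrix.pan_reactome.labels
    occurrences = dict(zip(labels, matrix.presence.sum(axis=0).tolist()))
    return frequency_binned_metrics(bench.per_reaction, occurrences, bin_width)


def score_gapfill_recovery(
    pan: PanReactome,
    truth_vector: np.ndarray,
    input_vector: np.ndarray,
    added_base_ids,
) -> ConfusionCounts:
    """Confusion of a gap-fill run against the artificially deleted set.

    ``added_base_ids`` are reaction ids with direction tags stripped.
    Additions that merely duplicate retained annotation reactions (the
    opposite half of a split reversible) are ignored.
    """
    truth_set = {r for r, p in zip(pan.reactions, truth_vector) if p}
    input_set = {r for r, p in zip(pan.reactions, input_vector) if p}
    deleted = truth_set - input_set
    added = set(added_base_ids) - input_set
    return confusion_from_gapfill(truth_set, deleted, added)


def gapfill_scheme_benchmark(
    world,
    imputer: ReactionImputer | None,
    train_pan: PanReactome,
    test_matrix: IncidenceMatrix,
    database,
    schemes: list[str] | None = None,
    n_replicates: int = 3,
    base_seed: int = 99,
    deletion: DeletionScheme | None = None,
) -> pd.DataFrame:
    """Delete 30% of each test genome's reactions, gap-fill under each scheme.

    ``world`` supplies the stoichiometric models (``model_for``) and medium;
    ``database`` must be prepared (split, biomass-free).  Returns one row
    per (genome, replicate, scheme) with recovery metrics.
    """
    schemes = schemes or list(SCHEME_ORDER)
    deletion = deletion or DeletionScheme()
    pan = test_matrix.pan_reactome
    rows = []
    for sample in make_replicates(test_matrix, n_replicates, deletion, base_seed):
        model = world.model_for(sample.genome_id, sample.input_vector)
        scores = (
            imputer.predict_proba(sample.input_vector.astype(float))
            if imputer is not None
            else None
        )
        for kind in schemes:
            cost_scheme = CostScheme(kind)
            costs = make_costs(
                cost_scheme,
                train_pan,
                scores if kind.startswith("W4") else None,
                database,
            )
            try:
                result = halfinterval_gapfill(
                    model, database, costs, world.medium
                )
                added = {r.base for r in result.added_reactions}
                counts = score_gapfill_recovery(
                    pan, sample.truth_vector, sample.input_vector, added
                )
                rep = metrics(counts)
                f1, recall, precision = rep.f1, rep.recall, rep.precision
                n_added = len(result.added_reactions)
            except GapfillInfeasibleError:
                logger.warning(
                    "gap-fill infeasible for %s under %s", sample.genome_id, kind
                )
                f1 = recall = precision = 0.0
                n_added = 0
            rows.append(
                {
                    "genome_id": sample.genome_id,
                    "replicate": sample.replicate_index,
                    "scheme": kind,
                    "f1": f1,
                    "recall": recall,
                    "precision": precision,
                    "n_added": n_added,
                }
            )
    return pd.DataFrame(rows)


def distance_effect_benchmark(
    matrix: IncidenceMatrix,
    excluded_genus: str,
    test_matrix: IncidenceMatrix,
    imputer_params: dict | None = None,
    base_seed: int = 3,
) -> pd.DataFrame:
    """Per-genome F1 versus nearest-neighbor Jaccard distance to training.

    Trains an imputer with one genus (clade) excluded, then predicts for the
    held-out clade plus the regular test genomes — a set spanning short and
    long distances to the training collection.
    """
    from panfill.reactome import exclude_partition

    training = exclude_partition(matrix, excluded_genus).recompute_pan()
    params = {"random_state": 7}
    params.update(imputer_params or {})
    imputer = ReactionImputer(**params).fit(training)

    col_full = {l: j for j, l in enumerate(matrix.pan_reactome.labels)}
    idx = [col_full[l] for l in training.pan_reactome.labels]
    genus_of = {g.genome_id: g.genus for g in matrix.genomes}
    eval_ids = [
        g.genome_id for g in matrix.genomes if g.genus == excluded_genus
    ] + [gid for gid in test_matrix.genome_ids if genus_of[gid] != excluded_genus]
    scheme = DeletionScheme()
    rows = []
    for gid in eval_ids:
        truth = matrix.row(gid)[idx]
        sample = corrupt(
            truth, scheme, seed=derive_seed(base_seed, gid, 0), genome_id=gid
        )
        scores = imputer.predict_proba(sample.input_vector.astype(float))
        rep = metrics(
            confusion_from_predictions(scores, sample.truth_vector, sample.input_vector)
        )
        rows.append(
            {
                "genome_id": gid,
                "held_out": genus_of[gid] == excluded_genus,
                "f1": rep.f1,
                "nn_distance": nearest_neighbor_distance(truth, training),
            }
        )
    return pd.DataFrame(rows)


def bias_matching_benchmark(
    uniform_imputer: ReactionImputer,
    biased_imputer: ReactionImputer,
    test_matrix: IncidenceMatrix,
    n_replicates: int = 10,
    base_seed: int = 77,
) -> dict[str, float]:
    """Mean F1 of both imputers on rare-biased corrupted test genomes."""
    rare = DeletionScheme(kind="rare_biased")
    out: dict[str, float] = {}
    for name, imp in (("uniform_trained", uniform_imputer), ("biased_trained", biased_imputer)):
        f1s = [
            metrics(
                confusion_from_predictions(
                    imp.predict_proba(s.input_vector.astype(float)),
                    s.truth_vector,
                    s.input_vector,
                )
            ).f1
            for s in make_replicates(test_matrix, n_replicates, rare, base_seed)
        ]
        out[name] = float(np.mean(f1s))
    return out
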