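"""Weighted half-interval gap-filling of metabolic networks.

A draft model that cannot produce biomass is completed by adding reactions
from a candidate database.  Each candidate carries a cost ``c_r`` — from one
of four weighting schemes (uniform, pan-reactome binary, frequency-based, or
neural-network score based) — and the search looks for a low-cost reaction
set whose addition makes the maximal biomass flux ``f_b`` positive.

The search bisects a scalar trade-off ``alpha``: each step solves the linear
program ``max alpha * f_b - sum_r c_r * f_r`` subject to steady-state mass
balance and flux bounds, and the bisection finds the smallest ``alpha``
whose optimum reaches ``f_b >= epsilon``.  Candidates that carry flux in the
final solution are the gap-fill set; a greedy prune then drops any added
reaction that turned out not to be needed for growth.  All reactions in the
candidate database are irreversible (reversibles are split beforehand) and
biomass-class reactions are removed from it, since biomass is an artificial
construct of the draft model itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from panfill.reactome import (
    DEFAULT_BIOMASS_IDS,
    MetabolicNetwork,
    PanReactome,
    Reaction,
    ReactionDatabase,
    ReactionId,
)

logger = logging.getLogger(__name__)

#: minimum biomass flux that counts as growth (model flux units)
DEFAULT_EPSILON = 1e-6
#: flux magnitude above which a candidate counts as used
FLUX_TOL = 1e-9
#: prefix marking exchange reactions
EXCHANGE_PREFIX = "EX_"


class GapfillInfeasibleError(RuntimeError):
    """No candidate superset reaches the growth threshold."""

    def __init__(self, message: str, blocked_precursors: Sequence[str] = ()) -> None:
        super().__init__(message)
        self.blocked_precursors = list(blocked_precursors)


# ---------------------------------------------------------------------------
# media and cost schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Maximum uptake rate per exchange metabolite (nonnegative numbers)."""

    uptake: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, rate in self.uptake.items():
            if rate < 0:
                raise ValueError(f"negative uptake bound for {met}: {rate}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Medium":
        frame = pd.read_csv(path, sep="\t", comment="#")
        met_col, rate_col = frame.columns[:2]
        return cls({str(r[met_col]): float(r[rate_col]) for _, r in frame.iterrows()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.uptake.items()), columns=["metabolite", "max_uptake"]
        ).to_csv(path, sep="\t", index=False)

    def replacing_carbon(self, remove: str | None, add: str, rate: float = 10.0) -> "Medium":
        """New medium with one carbon source swapped for another."""
        up = {m: r for m, r in self.uptake.items() if m != remove}
        up[add] = rate
        return Medium(up)


@dataclass(frozen=True)
class CostScheme:
    """Gap-filling cost assignment.

    W1_none           every database reaction costs ``default_cost`` (50).
    W2_naive_binary   ``low_cost`` (1) for reactions seen in the training
                      pan-reactome, ``default_cost`` otherwise.
    W3_frequency      ``1 - frac_r`` for pan-reactome reactions.
    W4_nn             ``1 - p_NN`` from the imputer's scores.
    W4_negative       affine map ``1 - 2 * p_NN`` (high-probability reactions
                      get negative cost, actively pulling them in).
    """

    kind: str = "W1_none"
    default_cost: float = 50.0
    low_cost: float = 1.0

    _KINDS = ("W1_none", "W2_naive_binary", "W3_frequency", "W4_nn", "W4_negative")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown cost scheme: {self.kind!r}")
        if not self.default_cost > self.low_cost > 0:
            raise ValueError("require default_cost > low_cost > 0")


@dataclass
class CostVector:
    """Finite per-reaction costs covering every candidate database reaction."""

    costs: dict[str, float]
    scheme: CostScheme

    def __getitem__(self, label: str) -> float:
        return self.costs[label]

    def __contains__(self, label: str) -> bool:
        return label in self.costs


def make_costs(
    scheme: CostScheme,
    pan: PanReactome | None,
    scores: np.ndarray | None,
    database: ReactionDatabase,
) -> CostVector:
    """Assign a cost to every reaction of a (prepared) candidate database.

    Pan-reactome membership and scores are matched on the reaction
    identifier with any direction tag stripped, so both halves of a split
    reversible reaction inherit the cost of their parent.  Reactions outside
    the pan-reactome always get ``default_cost``.
    """
    needs_scores = scheme.kind in ("W4_nn", "W4_negative")
    if needs_scores and scores is None:
        raise ValueError(f"{scheme.kind} requires a score vector")
    if scheme.kind != "W1_none" and pan is None:
        raise ValueError(f"{scheme.kind} requires a pan-reactome")
    by_identifier: dict[str, int] = {}
    if pan is not None:
        by_identifier = {rid.identifier: i for i, rid in enumerate(pan.reactions)}
        if scores is not None and len(scores) != len(pan):
            raise ValueError("score vector length does not match pan-reactome")
    costs: dict[str, float] = {}
    for rxn in database.reactions:
        idx = by_identifier.get(rxn.id.identifier)
        if scheme.kind == "W1_none" or idx is None:
            c = scheme.default_cost
        elif scheme.kind == "W2_naive_binary":
            c = scheme.low_cost
        elif scheme.kind == "W3_frequency":
            c = 1.0 - pan.frequency[pan.reactions[idx]]
        elif scheme.kind == "W4_nn":
            c = 1.0 - float(scores[idx])
        else:  # W4_negative
            c = 1.0 - 2.0 * float(scores[idx])
        costs[rxn.id.label] = c
    return CostVector(costs, scheme)


# ---------------------------------------------------------------------------
# database preparation
# ---------------------------------------------------------------------------

def _is_biomass(rxn: Reaction) -> bool:
    ident = rxn.id.identifier
    return (
        ident in DEFAULT_BIOMASS_IDS
        or ident.lower().startswith("bio")
        and ident[3:4].isdigit()
        or "biomass" in rxn.name.lower()
        or "biomass" in ident.lower()
    )


def prepare_database(db: ReactionDatabase) -> ReactionDatabase:
    """Drop biomass-class reactions and split reversibles into two halves.

    The forward half keeps the original stoichiometry with bounds
    ``[0, upper]``; the backward half negates it with bounds
    ``[0, |lower|]``.  Labels get ``_f``/``_b`` suffixes via direction tags.
    """
    out: list[Reaction] = []
    for rxn in db.reactions:
        if _is_biomass(rxn):
            continue
        if rxn.reversible or rxn.lower_bound < 0:
            fwd = Reaction(
                id=replace(rxn.id, direction_tag="forward"),
                stoichiometry=dict(rxn.stoichiometry),
                reversible=False,
                lower_bound=0.0,
                upper_bound=rxn.upper_bound,
                name=rxn.name,
            )
            out.append(fwd)
            out.append(rxn.reversed())
        else:
            out.append(rxn)
    return ReactionDatabase(out, dict(db.metabolites))


# ---------------------------------------------------------------------------
# flux balance core
# ---------------------------------------------------------------------------

def _apply_medium_bounds(reactions: Sequence[Reaction], medium: Medium) -> list[tuple[float, float]]:
    """Flux bounds with exchange uptake limited by the medium.

    An exchange reaction (id prefixed ``EX_``, single metabolite consumed)
    may run backwards (uptake) only up to the medium's bound for that
    metabolite; secretion stays open.
    """
    bounds = []
    for rxn in reactions:
        lo, hi = rxn.lower_bound, rxn.upper_bound
        if rxn.id.identifier.startswith(EXCHANGE_PREFIX) and len(rxn.stoichiometry) == 1:
            met = next(iter(rxn.stoichiometry))
            lo = -float(medium.uptake.get(met, 0.0))
        bounds.append((lo, hi))
    return bounds


def _stoichiometric_matrix(reactions: Sequence[Reaction]) -> sp.csr_matrix:
    mets: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(reactions):
        for met, coef in rxn.stoichiometry.items():
            i = mets.setdefault(met, len(mets))
            rows.append(i)
            cols.append(j)
            vals.append(coef)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(mets), len(reactions)))


def _solve_lp(
    S: sp.csr_matrix,
    objective: np.ndarray,
    bounds: list[tuple[float, float]],
) -> tuple[np.ndarray | None, str]:
    """Minimise objective . v subject to S v = 0 and bounds."""
    res = linprog(
        objective,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return res.x, "optimal"
    return None, res.message


def check_growth(
    model: MetabolicNetwork,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Maximal biomass flux of a model under a medium (0 if infeasible)."""
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    reactions = model.reactions
    bio_idx = next(
        j for j, r in enumerate(reactions) if r.id.label == model.biomass_reaction_id.label
    )
    S = _stoichiometric_matrix(reactions)
    bounds = _apply_medium_bounds(reactions, medium)
    obj = np.zeros(len(reactions))
    obj[bio_idx] = -1.0  # maximise f_b
    x, status = _solve_lp(S, obj, bounds)
    if x is None:
        logger.debug("growth LP not optimal: %s", status)
        return 0.0
    return float(x[bio_idx])


# ---------------------------------------------------------------------------
# half-interval gap-filling
# ---------------------------------------------------------------------------

@dataclass
class GapfillResult:
    """Outcome of a gap-fill run."""

    added_reactions: set[ReactionId]
    biomass_flux: float
    iterations: int
    objective_value: float
    alpha: float = 0.0

    @property
    def added_labels(self) -> set[str]:
        return {r.label for r in self.added_reactions}


def halfinterval_gapfill(
    model: MetabolicNetwork,
    db: ReactionDatabase,
    costs: CostVector,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
    flux_tol: float = FLUX_TOL,
    max_candidate_flux: float = 100.0,
    alpha_tol: float = 1e-3,
    prune: bool = True,
) -> GapfillResult:
    """Complete a model so it grows, guided by per-reaction costs.

    Bisects the trade-off scalar ``alpha`` of the LP
    ``max alpha * f_b - sum c_r f_r``; returns the candidates carrying flux
    (``|f_r| > flux_tol``) at the smallest growth-sufficient ``alpha``.
    Annotation reactions cost nothing and are never removed; candidate
    fluxes are capped at ``max_candidate_flux`` so negative costs cannot
    make the LP unbounded.  Raises :class:`GapfillInfeasibleError` when even
    the full database cannot reach ``f_b >= epsilon``.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    already = check_growth(model, medium, epsilon)
    if already >= epsilon:
        return GapfillResult(set(), already, 0, 0.0)

    model_labels = {r.id.label for r in model.reactions}
    candidates = [r for r in db.reactions if r.id.label not in model_labels]
    for r in candidates:
        if r.id.label not in costs:
            raise ValueError(f"no cost for candidate reaction {r.id.label}")

    merged = model.reactions + candidates
    n_model = len(model.reactions)
    bio_idx = next(
        j for j, r in enumerate(model.reactions)
        if r.id.label == model.biomass_reaction_id.label
    )
    S = _stoichiometric_matrix(merged)
    bounds = _apply_medium_bounds(model.reactions, medium) + [
        (0.0, min(r.upper_bound, max_candidate_flux)) for r in candidates
    ]
    cost_vec = np.zeros(len(merged))
    for j, r in enumerate(candidates):
        cost_vec[n_model + j] = costs[r.id.label]

    iterations = 0

    def solve(alpha: float) -> tuple[np.ndarray | None, float]:
        nonlocal iterations
        iterations += 1
        obj = cost_vec.copy()
        obj[bio_idx] -= alpha
        x, _ = _solve_lp(S, obj, bounds)
        if x is None:
            return None, 0.0
        return x, float(x[bio_idx])

    # is any completion growth-sufficient at all?
    obj = np.zeros(len(merged))
    obj[bio_idx] = -1.0
    x_max, _ = _solve_lp(S, obj, bounds)
    iterations += 1
    if x_max is None or x_max[bio_idx] < epsilon:
        blocked = _blocked_biomass_precursors(model, merged, S, bounds, epsilon)
        raise GapfillInfeasibleError(
            "no candidate set reaches the biomass flux threshold; blocked "
            f"precursors: {blocked}",
            blocked,
        )

    # smallest alpha whose optimum grows
    x0, fb0 = solve(0.0)
    if x0 is not None and fb0 >= epsilon:
        best_alpha, best_x = 0.0, x0
    else:
        alpha_hi = 1.0
        x_hi, fb_hi = solve(alpha_hi)
        while (x_hi is None or fb_hi < epsilon) and alpha_hi < 1e9:
            alpha_hi *= 4.0
            x_hi, fb_hi = solve(alpha_hi)
        if x_hi is None or fb_hi < epsilon:  # pragma: no cover - guarded above
            raise GapfillInfeasibleError("bisection failed to bracket a growing optimum")
        alpha_lo = 0.0
        best_alpha, best_x = alpha_hi, x_hi
        while alpha_hi - alpha_lo > alpha_tol * max(alpha_hi, 1.0):
            mid = 0.5 * (alpha_lo + alpha_hi)
            x_mid, fb_mid = solve(mid)
            if x_mid is not None and fb_mid >= epsilon:
                alpha_hi, best_alpha, best_x = mid, mid, x_mid
            else:
                alpha_lo = mid
    fluxes = best_x
    added_idx = [
        j for j in range(len(candidates))
        if abs(fluxes[n_model + j]) > flux_tol
    ]
    added = [candidates[j] for j in added_idx]

    if prune and added:
        added = _greedy_prune(model, added, medium, epsilon, costs)
        iterations += 1  # bookkeeping; prune LP count tracked coarsely

    final = model.with_added(added)
    fb = check_growth(final, medium, epsilon)
    kept_labels = {r.id.label for r in added}
    objective_value = float(
        sum(
            costs[candidates[j].id.label] * fluxes[n_model + j]
            for j in added_idx
            if candidates[j].id.label in kept_labels
        )
    )
    logger.info(
        "gap-filled %s: %d reactions added, f_b=%.4g, alpha=%.4g, %d LP solves",
        model.model_id, len(added), fb, best_alpha, iterations,
    )
    return GapfillResult(
        {r.id for r in added}, fb, iterations, objective_value, best_alpha
    )


def _greedy_prune(
    model: MetabolicNetwork,
    added: list[Reaction],
    medium: Medium,
    epsilon: float,
    costs: CostVector,
) -> list[Reaction]:
    """Drop added reactions (costliest first) that growth does not need."""
    kept = list(added)
    for rxn in sorted(added, key=lambda r: -costs[r.id.label]):
        trial = [r for r in kept if r.id.label != rxn.id.label]
        if check_growth(model.with_added(trial), medium, epsilon) >= epsilon:
            kept = trial
    return kept


def _blocked_biomass_precursors(
    model: MetabolicNetwork,
    merged: Sequence[Reaction],
    S: sp.csr_matrix,
    bounds: list[tuple[float, float]],
    epsilon: float,
) -> list[str]:
    """Which biomass substrates cannot be produced even with all candidates."""
    biomass = model.get(model.biomass_reaction_id.label)
    substrates = [m for m, c in biomass.stoichiometry.items() if c < 0]
    mets: dict[str, int] = {}
    for rxn in merged:
        for met in rxn.stoichiometry:
            mets.setdefault(met, len(mets))
    blocked = []
    for met in substrates:
        row = mets.get(met)
        if row is None:
            blocked.append(met)
            continue
        # maximise net production of this metabolite: relax its balance row
        keep = np.ones(S.shape[0], dtype=bool)
        keep[row] = False
        obj = -S.getrow(row).toarray().ravel()
        x, _ = _solve_lp(S[keep], obj, bounds)
        if x is None or -obj @ x < epsilon:
            blocked.append(met)
    return blocked
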