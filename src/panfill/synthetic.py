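"""Synthetic study systems: incidence matrices, stoichiometric worlds, toys.

The generator emulates the structure that makes reaction imputation and
weighted gap-filling non-trivial on real bacterial data:

* a **core** of reactions present in every genome (frequency 1),
* **modules** — blocks of reactions gained and lost together, organised as
  isoenzyme *variant pairs*: two chains with identical stoichiometry that
  different clades use for the same function.  Variants have similar
  overall frequencies but clade-specific co-occurrence, which is exactly
  the signal a frequency-based cost cannot see and a co-occurrence-learning
  network can,
* **rare paralogs** of core steps, present in a small fraction of genomes:
  stoichiometrically interchangeable with a core step, distinguishable only
  by frequency,
* **decoys**, database-only reactions duplicating core steps that no genome
  carries: indistinguishable from the real thing when all costs are equal.

Each genome also gets a stoichiometric interpretation (a toy metabolism)
so gap-filling can be benchmarked end to end: nutrient uptake feeds a core
chain; family chains branch off to module products; a genome's biomass
consumes the end of the core chain plus the products of the modules it
carries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from panfill.gapfill import (
    DEFAULT_EPSILON,
    CostVector,
    Medium,
    check_growth,
)
from panfill.reactome import (
    GenomeRecord,
    IncidenceMatrix,
    MetabolicNetwork,
    PanReactome,
    Reaction,
    ReactionDatabase,
    ReactionId,
)

logger = logging.getLogger(__name__)

_NS = "toy"


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Shape of the synthetic genome collection.

    Defaults give 400 reactions (100 core + 30 module chains of 8 + 60 rare
    paralogs) across 6 clades of 40 genomes — small enough to train the
    imputer in minutes on one CPU while keeping every structural feature.
    ``n_modules`` must be even: modules come in isoenzyme variant pairs.
    """

    n_reactions: int = 400
    n_core: int = 100
    n_modules: int = 30
    module_size: int = 8
    n_clades: int = 6
    genomes_per_clade: int = 40
    module_gain_prob: float = 0.9
    noise_flip_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_modules * self.module_size > self.n_reactions:
            raise ValueError("n_core + n_modules * module_size exceeds n_reactions")
        if self.n_modules % 2 != 0:
            raise ValueError("n_modules must be even (isoenzyme variant pairs)")
        for p in (self.module_gain_prob, self.noise_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_families(self) -> int:
        return self.n_modules // 2

    @property
    def n_background(self) -> int:
        return self.n_reactions - self.n_core - self.n_modules * self.module_size


def _rid(identifier: str) -> ReactionId:
    return ReactionId(_NS, identifier)


def _reaction_labels(config: SyntheticWorldConfig) -> dict[str, list[str]]:
    core = [f"core{i:03d}" for i in range(config.n_core)]
    modules = [
        f"mod{f:02d}{v}s{s}"
        for f in range(config.n_families)
        for v in "AB"
        for s in range(config.module_size)
    ]
    rare = [f"rare{i:03d}" for i in range(config.n_background)]
    return {"core": core, "module": modules, "rare": rare}


def generate_incidence(
    config: SyntheticWorldConfig,
) -> tuple[IncidenceMatrix, dict]:
    """Clade-structured binary incidence matrix plus world annotations.

    Returns the matrix and a dict describing the planted structure: variant
    assignment per (clade, family), module carriage per genome, and the
    reaction-category labels.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels = _reaction_labels(config)
    all_labels = labels["core"] + labels["module"] + labels["rare"]
    col = {lab: j for j, lab in enumerate(all_labels)}
    n_genomes = config.n_clades * config.genomes_per_clade
    presence = np.zeros((n_genomes, len(all_labels)), dtype=np.int8)

    # core present everywhere
    presence[:, : config.n_core] = 1

    # which variant each clade uses, per family (A twice as common as B)
    variant_of = {
        (c, f): ("A" if rng.random() < 2 / 3 else "B")
        for c in range(config.n_clades)
        for f in range(config.n_families)
    }
    # rare paralog carriage probability per column
    rare_prob = rng.uniform(0.03, 0.30, size=config.n_background)

    genomes: list[GenomeRecord] = []
    carried: dict[str, list[int]] = {}
    g = 0
    for c in range(config.n_clades):
        for i in range(config.genomes_per_clade):
            gid = f"G{c:02d}{i:03d}"
            genomes.append(
                GenomeRecord(
                    genome_id=gid,
                    species=f"clade{c:02d}_sp{i // 2:02d}",
                    genus=f"clade{c:02d}",
                    completeness=float(rng.uniform(80, 100)),
                    contamination=float(rng.uniform(0, 4)),
                    coarse_consistency=float(rng.uniform(90, 100)),
                )
            )
            fams = []
            for f in range(config.n_families):
                if rng.random() < config.module_gain_prob:
                    fams.append(f)
                    v = variant_of[(c, f)]
                    for s in range(config.module_size):
                        presence[g, col[f"mod{f:02d}{v}s{s}"]] = 1
            carried[gid] = fams
            presence[g, config.n_core + config.n_modules * config.module_size :] = (
                rng.random(config.n_background) < rare_prob
            ).astype(np.int8)
            g += 1

    # independent flip noise on non-core columns (core stays at frequency 1)
    if config.noise_flip_prob > 0:
        noise_cols = slice(config.n_core, len(all_labels))
        flips = rng.random(presence[:, noise_cols].shape) < config.noise_flip_prob
        presence[:, noise_cols] = np.where(
            flips, 1 - presence[:, noise_cols], presence[:, noise_cols]
        )

    # a pan-reactome column must occur at least once
    empty = np.flatnonzero(presence.sum(axis=0) == 0)
    for j in empty:
        presence[rng.integers(n_genomes), j] = 1

    reactions = [_rid(lab) for lab in all_labels]
    freq = presence.mean(axis=0)
    pan = PanReactome(reactions, dict(zip(reactions, freq)), n_genomes)
    matrix = IncidenceMatrix(genomes, pan, presence)
    world_info = {
        "config": config,
        "labels": labels,
        "variant_of": variant_of,
        "families_carried": carried,
    }
    return matrix, world_info


# ---------------------------------------------------------------------------
# stoichiometric interpretation of the synthetic world
# ---------------------------------------------------------------------------

@dataclass
class MetabolicWorld:
    """Stoichiometric world shared by all synthetic genomes.

    ``database`` holds every pan-reactome reaction plus the decoys (all
    irreversible, no biomass, no exchanges); ``model_for`` assembles one
    genome's network from a presence vector, with biomass requirements read
    from the genome's *true* module content.
    """

    config: SyntheticWorldConfig
    incidence: IncidenceMatrix
    database: ReactionDatabase
    medium: Medium
    required_families: dict[str, list[int]]
    _biomass_cache: dict[str, Reaction] = field(default_factory=dict)

    def model_for(
        self, genome_id: str, presence: np.ndarray | None = None
    ) -> MetabolicNetwork:
        """Build the model of one genome, optionally from a corrupted row."""
        if presence is None:
            presence = self.incidence.row(genome_id)
        pan = self.incidence.pan_reactome
        reactions = [
            self.database.get(rid.label)
            for rid, p in zip(pan.reactions, presence)
            if p and rid.label in self.database
        ]
        biomass = self._biomass(genome_id)
        exchange = Reaction(
            id=_rid("EX_nut_e"),
            stoichiometry={"nut_e": -1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
        )
        return MetabolicNetwork(
            reactions + [exchange, biomass],
            biomass.id,
            model_id=genome_id,
        )

    def _biomass(self, genome_id: str) -> Reaction:
        if genome_id not in self._biomass_cache:
            stoich = {_chain_met(self.config.n_core, self.config): -1.0}
            for f in self.required_families.get(genome_id, []):
                stoich[f"fam{f:02d}p_c"] = -1.0
            self._biomass_cache[genome_id] = Reaction(
                id=_rid("bio1"),
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
                name="biomass",
            )
        return self._biomass_cache[genome_id]


def _chain_met(i: int, config: SyntheticWorldConfig) -> str:
    if i == 0:
        return "nut_e"
    if i == config.n_core:
        return "coreend_c"
    return f"c{i:03d}_c"


def _family_step_stoich(
    f: int, s: int, config: SyntheticWorldConfig
) -> dict[str, float]:
    src = "coreend_c" if s == 0 else f"fam{f:02d}x{s}_c"
    dst = f"fam{f:02d}p_c" if s == config.module_size - 1 else f"fam{f:02d}x{s + 1}_c"
    return {src: -1.0, dst: 1.0}


def generate_metabolic_world(
    incidence: IncidenceMatrix,
    world_info: dict,
    n_decoys: int | None = None,
) -> MetabolicWorld:
    """Attach stoichiometry to a generated incidence matrix.

    Core step ``i`` converts chain metabolite ``i`` into ``i+1`` (step 0
    consumes the external nutrient); rare paralog ``i`` duplicates core step
    ``i``; module variant steps walk family chains off the end of the core
    chain, and the two variants of a family are stoichiometrically
    identical.  The database additionally holds ``n_decoys`` copies of core
    steps (default: one per core step) that no genome carries.
    """
    config: SyntheticWorldConfig = world_info["config"]
    if n_decoys is None:
        n_decoys = config.n_core

    def core_step(i: int) -> dict[str, float]:
        return {_chain_met(i, config): -1.0, _chain_met(i + 1, config): 1.0}

    reactions: list[Reaction] = []
    for i, lab in enumerate(world_info["labels"]["core"]):
        reactions.append(Reaction(_rid(lab), core_step(i)))
    for f in range(config.n_families):
        for v in "AB":
            for s in range(config.module_size):
                reactions.append(
                    Reaction(_rid(f"mod{f:02d}{v}s{s}"), _family_step_stoich(f, s, config))
                )
    for i, lab in enumerate(world_info["labels"]["rare"]):
        reactions.append(Reaction(_rid(lab), core_step(i % config.n_core)))
    for d in range(n_decoys):
        reactions.append(Reaction(_rid(f"dcoy{d:03d}"), core_step(d % config.n_core)))

    database = ReactionDatabase(reactions)
    # biomass requires a family product when the genome truly carries most of
    # either variant chain of that family
    required: dict[str, list[int]] = {}
    pan = incidence.pan_reactome
    col = {rid.label: j for j, rid in enumerate(pan.reactions)}
    half = config.module_size / 2.0
    for genome in incidence.genomes:
        row = incidence.row(genome.genome_id)
        fams = []
        for f in range(config.n_families):
            for v in "AB":
                n_present = sum(
                    row[col[f"mod{f:02d}{v}s{s}"]]
                    for s in range(config.module_size)
                    if f"mod{f:02d}{v}s{s}" in col
                )
                if n_present > half:
                    fams.append(f)
                    break
        required[genome.genome_id] = fams
    return MetabolicWorld(
        config=config,
        incidence=incidence,
        database=database,
        medium=Medium({"nut_e": 10.0}),
        required_families=required,
    )


# ---------------------------------------------------------------------------
# toy stoichiometric networks with known gap-fill ground truth
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """A small model + candidate database with enumerated completions."""

    model: MetabolicNetwork
    database: ReactionDatabase
    medium: Medium
    minimal_sets: list[frozenset[str]]
    example_costs: dict[str, float] = field(default_factory=dict)


def _toy_reaction(ident: str, stoich: dict[str, float]) -> Reaction:
    return Reaction(_rid(ident), stoich)


def minimal_gapfill_sets(
    model: MetabolicNetwork,
    db: ReactionDatabase,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
    max_candidates: int = 16,
) -> list[frozenset[str]]:
    """All inclusion-minimal candidate subsets whose addition yields growth.

    Exhaustive subset enumeration by increasing size; a set is reported only
    if no reported set is a subset of it.  Intended for toys (<= 16
    candidates).
    """
    candidates = [r for r in db.reactions if r.id.label not in model]
    if len(candidates) > max_candidates:
        raise ValueError(f"too many candidates for enumeration: {len(candidates)}")
    minimal: list[frozenset[str]] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            labels = frozenset(r.id.label for r in combo)
            if any(m <= labels for m in minimal):
                continue
            if check_growth(model.with_added(list(combo)), medium, epsilon) >= epsilon:
                minimal.append(labels)
    return minimal


def brute_force_min_cost(
    model: MetabolicNetwork,
    db: ReactionDatabase,
    costs: CostVector | Mapping[str, float],
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
    cost_ceiling: float | None = None,
) -> tuple[float, frozenset[str] | None]:
    """Minimum total cost over all growth-sufficient candidate subsets.

    Subsets are visited in order of increasing total cost; the first
    growth-sufficient one is optimal.  ``cost_ceiling`` restricts the search
    to subsets cheaper than the ceiling (useful for verifying that a found
    solution is within a factor of the optimum without full enumeration).
    Returns ``(cost, labels)``; ``(inf, None)`` if nothing feasible below
    the ceiling.
    """
    candidates = [r for r in db.reactions if r.id.label not in model]
    get = costs.__getitem__
    subsets = sorted(
        (
            (sum(get(r.id.label) for r in combo), combo)
            for size in range(len(candidates) + 1)
            for combo in itertools.combinations(candidates, size)
        ),
        key=lambda t: t[0],
    )
    for total, combo in subsets:
        if cost_ceiling is not None and total >= cost_ceiling:
            return float("inf"), None
        if check_growth(model.with_added(list(combo)), medium, epsilon) >= epsilon:
            return total, frozenset(r.id.label for r in combo)
    return float("inf"), None


def generate_toy_network(template: str, size: int = 4) -> ToyFixture:
    """A named toy with exhaustively verified minimal gap-fill sets.

    ``linear_chain``: an n-step pathway with one interior step moved to the
    database (unique 1-reaction completion).  ``branched_cheap_expensive``:
    biomass reachable via one direct candidate or a two-step detour, with
    example costs ranking them.  ``parallel_paths``: a complete, growing
    model with two redundant routes (no gap-fill needed).
    """
    medium = Medium({"X_e": 10.0})
    ex = _toy_reaction("EX_X_e", {"X_e": -1.0})

    if template == "linear_chain":
        if size < 3:
            raise ValueError("linear_chain needs size >= 3")
        mets = ["X_e"] + [f"m{i}_c" for i in range(1, size)]
        steps = [
            _toy_reaction(f"step{i}", {mets[i]: -1.0, mets[i + 1]: 1.0})
            for i in range(size - 1)
        ]
        biomass = _toy_reaction("bio1", {mets[-1]: -1.0})
        missing = steps[size // 2]
        kept = [s for s in steps if s.id.label != missing.id.label]
        model = MetabolicNetwork(kept + [ex, biomass], biomass.id, model_id="linear_chain")
        distract = _toy_reaction("off1", {"m1_c": -1.0, "off_c": 1.0})
        db = ReactionDatabase([missing, distract])
        fixture = ToyFixture(
            model, db, medium,
            minimal_sets=[frozenset([missing.id.label])],
            example_costs={missing.id.label: 1.0, "off1": 1.0},
        )
    elif template == "branched_cheap_expensive":
        a, b, c = "A_c", "B_c", "C_c"
        upt = _toy_reaction("upt", {"X_e": -1.0, a: 1.0})
        biomass = _toy_reaction("bio1", {b: -1.0})
        model = MetabolicNetwork([ex, upt, biomass], biomass.id, model_id="branched")
        direct = _toy_reaction("direct", {a: -1.0, b: 1.0})
        exp1 = _toy_reaction("exp1", {a: -1.0, c: 1.0})
        exp2 = _toy_reaction("exp2", {c: -1.0, b: 1.0})
        db = ReactionDatabase([direct, exp1, exp2])
        fixture = ToyFixture(
            model, db, medium,
            minimal_sets=[
                frozenset(["direct"]),
                frozenset(["exp1", "exp2"]),
            ],
            example_costs={"direct": 0.1, "exp1": 50.0, "exp2": 50.0},
        )
    elif template == "parallel_paths":
        a, b = "A_c", "B_c"
        upt = _toy_reaction("upt", {"X_e": -1.0, a: 1.0})
        p1 = _toy_reaction("path1", {a: -1.0, b: 1.0})
        p2 = _toy_reaction("path2", {a: -1.0, b: 1.0})
        biomass = _toy_reaction("bio1", {b: -1.0})
        model = MetabolicNetwork([ex, upt, p1, p2, biomass], biomass.id, model_id="parallel")
        db = ReactionDatabase([_toy_reaction("spare", {a: -1.0, "off_c": 1.0})])
        fixture = ToyFixture(model, db, medium, minimal_sets=[frozenset()])
    else:
        raise ValueError(f"unknown toy template: {template!r}")

    verified = minimal_gapfill_sets(fixture.model, fixture.database, fixture.medium)
    if set(verified) != set(fixture.minimal_sets):
        raise AssertionError(
            f"{template}: enumerated minimal sets {verified} disagree with "
            f"fixture {fixture.minimal_sets}"
        )
    return fixture


def generate_random_gapfill_problem(
    seed: int,
    n_chain: int = 4,
    n_extra: int = 8,
) -> tuple[MetabolicNetwork, ReactionDatabase, dict[str, float], Medium]:
    """Random small gap-fill instance with random positive costs.

    A linear uptake-to-biomass chain has a random subset of steps removed
    into the candidate database, which additionally offers random shortcut
    and off-pathway reactions.  The full candidate set always restores
    growth.  Candidate count is ``<= n_chain + n_extra``.
    """
    rng = np.random.default_rng(seed)
    mets = ["X_e"] + [f"m{i}_c" for i in range(1, n_chain + 1)]
    ex = _toy_reaction("EX_X_e", {"X_e": -1.0})
    steps = [
        _toy_reaction(f"step{i}", {mets[i]: -1.0, mets[i + 1]: 1.0})
        for i in range(n_chain)
    ]
    biomass = _toy_reaction("bio1", {mets[-1]: -1.0})
    n_missing = int(rng.integers(1, n_chain))
    missing_idx = sorted(rng.choice(n_chain, size=n_missing, replace=False))
    kept = [s for i, s in enumerate(steps) if i not in missing_idx]
    model = MetabolicNetwork(kept + [ex, biomass], biomass.id, model_id=f"rand{seed}")

    candidates = [steps[i] for i in missing_idx]
    for k in range(n_extra):
        i = int(rng.integers(0, n_chain))
        j = int(rng.integers(i + 1, n_chain + 1))
        kind = rng.random()
        if kind < 0.6:
            stoich = {mets[i]: -1.0, mets[j]: 1.0}  # shortcut
        else:
            stoich = {mets[i]: -1.0, f"off{k}_c": 1.0}  # dead end
        candidates.append(_toy_reaction(f"cand{k}", stoich))
    db = ReactionDatabase(candidates)
    costs = {
        r.id.label: float(np.round(rng.uniform(0.05, 10.0), 3))
        for r in candidates
    }
    return model, db, costs, Medium({"X_e": 10.0})


def generate_phenotypes(
    incidence: IncidenceMatrix,
    source_requirements: Mapping[str, Sequence[str]],
) -> "np.ndarray | object":
    """Observed genome x carbon-source growth table from reaction content.

    A genome grows on a source iff it carries every reaction the mapping
    lists for that source.  With zero noise in the world, the table is fully
    determined by the incidence matrix.
    """
    import pandas as pd

    col = {rid.label: j for j, rid in enumerate(incidence.pan_reactome.reactions)}
    for source, reqs in source_requirements.items():
        missing = [r for r in reqs if r not in col]
        if missing:
            raise ValueError(f"source {source}: unknown reactions {missing}")
    data = {
        source: [
            int(all(incidence.presence[i, col[r]] for r in reqs))
            for i in range(incidence.n_genomes)
        ]
        for source, reqs in source_requirements.items()
    }
    return pd.DataFrame(data, index=incidence.genome_ids)
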