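"""Reaction registries, incidence matrices and metabolic-network containers.

The coordinate system for everything downstream is the *pan-reactome*: the
ordered union of gene-associated reactions observed across a genome
collection.  Presence/absence of those reactions per genome forms the binary
incidence matrix that the imputer trains on; the stoichiometric containers
(`ReactionDatabase`, `MetabolicNetwork`) feed the gap-filler.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: biomass reaction identifiers recognised by default, in lookup order
DEFAULT_BIOMASS_IDS = ("bio1", "Growth")


# ---------------------------------------------------------------------------
# identifiers and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ReactionId:
    """Namespaced reaction identifier.

    ``direction_tag`` is only ever set after reversible splitting, when a
    reversible reaction is replaced by a forward/backward pair.
    """

    namespace: str
    identifier: str
    direction_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("reaction identifier must be non-empty")
        if self.direction_tag not in (None, "forward", "backward"):
            raise ValueError(f"bad direction_tag: {self.direction_tag!r}")

    @property
    def label(self) -> str:
        """Flat string form used as matrix column / cost-vector key."""
        suffix = {"forward": "_f", "backward": "_b"}.get(self.direction_tag, "")
        return f"{self.identifier}{suffix}"

    @property
    def base(self) -> "ReactionId":
        """The identifier with any direction tag stripped."""
        if self.direction_tag is None:
            return self
        return ReactionId(self.namespace, self.identifier)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class GenomeRecord:
    """Quality metadata for one genome; percentages in [0, 100]."""

    genome_id: str
    species: str = ""
    genus: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    coarse_consistency: float = 100.0

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination", "coarse_consistency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] for {self.genome_id}")

    @property
    def quality_score(self) -> float:
        """Sequencing quality: completeness - 5 * contamination."""
        return self.completeness - 5.0 * self.contamination


METADATA_COLUMNS = [
    "genome_id", "species", "genus",
    "completeness", "contamination", "coarse_consistency",
]


# ---------------------------------------------------------------------------
# pan-reactome and incidence matrix
# ---------------------------------------------------------------------------

class PanReactome:
    """Ordered registry of reactions with their frequency across a collection.

    Parameters
    ----------
    reactions
        Ordered reaction identifiers; the order is frozen and defines the
        coordinate system of every presence/score/cost vector downstream.
    frequency
        Fraction of genomes carrying each reaction (``frac_r``), in (0, 1].
    n_genomes
        Number of genomes the frequencies were computed over.
    """

    def __init__(
        self,
        reactions: Sequence[ReactionId],
        frequency: Mapping[ReactionId, float],
        n_genomes: int,
    ) -> None:
        if n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        self.reactions: list[ReactionId] = list(reactions)
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("duplicate reactions in pan-reactome")
        self.frequency: dict[ReactionId, float] = {}
        for rid in self.reactions:
            f = float(frequency[rid])
            if not 0.0 < f <= 1.0:
                raise ValueError(f"frac_r for {rid.label} is {f}, outside (0, 1]")
            self.frequency[rid] = f
        self.n_genomes = int(n_genomes)
        self._index = {rid: i for i, rid in enumerate(self.reactions)}

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, rid: ReactionId) -> bool:
        return rid in self._index

    def index_of(self, rid: ReactionId) -> int:
        return self._index[rid]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.reactions]

    def frequency_vector(self) -> np.ndarray:
        return np.array([self.frequency[r] for r in self.reactions])


class IncidenceMatrix:
    """Binary genomes x reactions presence table with genome metadata.

    Rows follow ``genomes`` order, columns follow ``pan_reactome`` order.
    A matrix built by :func:`build_incidence_matrix` satisfies
    ``column mean == pan_reactome.frequency``; a train/test subset
    deliberately keeps its parent's pan-reactome (same coordinates) and the
    identity then holds only for the parent.
    """

    def __init__(
        self,
        genomes: Sequence[GenomeRecord],
        pan_reactome: PanReactome,
        presence: np.ndarray,
    ) -> None:
        presence = np.asarray(presence)
        if presence.shape != (len(genomes), len(pan_reactome)):
            raise ValueError(
                f"presence shape {presence.shape} != "
                f"({len(genomes)}, {len(pan_reactome)})"
            )
        if presence.size and not np.isin(presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        ids = [g.genome_id for g in genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in incidence matrix")
        self.genomes: list[GenomeRecord] = list(genomes)
        self.pan_reactome = pan_reactome
        self.presence = presence.astype(np.int8)
        self._row = {g.genome_id: i for i, g in enumerate(self.genomes)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def row(self, genome_id: str) -> np.ndarray:
        return self.presence[self._row[genome_id]]

    def reaction_set(self, genome_id: str) -> set[ReactionId]:
        mask = self.row(genome_id).astype(bool)
        return {r for r, m in zip(self.pan_reactome.reactions, mask) if m}

    def column_frequencies(self) -> np.ndarray:
        """Observed per-column frequencies of *this* matrix's rows."""
        return self.presence.mean(axis=0)

    def subset(self, genome_ids: Iterable[str]) -> "IncidenceMatrix":
        """Row subset sharing this matrix's pan-reactome coordinates."""
        ids = list(genome_ids)
        idx = [self._row[g] for g in ids]
        return IncidenceMatrix(
            [self.genomes[i] for i in idx], self.pan_reactome, self.presence[idx]
        )

    def recompute_pan(self) -> "IncidenceMatrix":
        """Rebuild the pan-reactome from this matrix's own rows.

        Columns that are absent from every row are dropped; order of the
        remaining columns is preserved.
        """
        freq = self.column_frequencies()
        keep = np.flatnonzero(freq > 0)
        reactions = [self.pan_reactome.reactions[i] for i in keep]
        pan = PanReactome(
            reactions,
            {r: freq[i] for r, i in zip(reactions, keep)},
            self.n_genomes,
        )
        return IncidenceMatrix(self.genomes, pan, self.presence[:, keep])

    # -- TSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence,
            index=pd.Index(self.genome_ids, name="genome_id"),
            columns=self.pan_reactome.labels,
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": g.genome_id,
                    "species": g.species,
                    "genus": g.genus,
                    "completeness": g.completeness,
                    "contamination": g.contamination,
                    "coarse_consistency": g.coarse_consistency,
                }
                for g in self.genomes
            ],
            columns=METADATA_COLUMNS,
        )

    def to_tsv(self, presence_path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(presence_path, sep="\t")
        if metadata_path is not None:
            self.metadata_frame().to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        presence_path: str | Path,
        metadata_path: str | Path | None = None,
        namespace: str = "modelseed",
    ) -> "IncidenceMatrix":
        frame = pd.read_csv(presence_path, sep="\t", index_col="genome_id")
        meta: dict[str, GenomeRecord] = {}
        if metadata_path is not None:
            mf = pd.read_csv(metadata_path, sep="\t", dtype={"genome_id": str})
            for rec in mf.to_dict("records"):
                meta[str(rec["genome_id"])] = GenomeRecord(
                    genome_id=str(rec["genome_id"]),
                    species=str(rec.get("species", "")),
                    genus=str(rec.get("genus", "")),
                    completeness=float(rec.get("completeness", 100.0)),
                    contamination=float(rec.get("contamination", 0.0)),
                    coarse_consistency=float(rec.get("coarse_consistency", 100.0)),
                )
        genomes = [
            meta.get(str(gid), GenomeRecord(genome_id=str(gid)))
            for gid in frame.index
        ]
        reactions = [ReactionId(namespace, c) for c in frame.columns]
        presence = frame.to_numpy(dtype=np.int8)
        freq = presence.mean(axis=0)
        keep = freq > 0
        if not keep.all():
            # zero columns cannot live in a pan-reactome; drop them on read
            reactions = [r for r, k in zip(reactions, keep) if k]
            presence = presence[:, keep]
            freq = freq[keep]
        pan = PanReactome(
            reactions, dict(zip(reactions, freq)), len(genomes)
        )
        return cls(genomes, pan, presence)


def build_incidence_matrix(
    reaction_sets: Sequence[tuple[GenomeRecord, set[ReactionId]]],
) -> IncidenceMatrix:
    """Assemble a binary incidence matrix from per-genome reaction sets.

    The pan-reactome is the union of all sets (sorted by identifier for a
    stable coordinate order); frequencies are the column means.
    """
    if not reaction_sets:
        raise ValueError("need at least one genome")
    ids = [rec.genome_id for rec, _ in reaction_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in reaction sets")
    for rec, rset in reaction_sets:
        if not rset:
            raise ValueError(f"empty reaction set for genome {rec.genome_id}")
    union: set[ReactionId] = set()
    for _, rset in reaction_sets:
        union |= rset
    reactions = sorted(union)
    col = {r: j for j, r in enumerate(reactions)}
    presence = np.zeros((len(reaction_sets), len(reactions)), dtype=np.int8)
    for i, (_, rset) in enumerate(reaction_sets):
        for r in rset:
            presence[i, col[r]] = 1
    freq = presence.mean(axis=0)
    pan = PanReactome(reactions, dict(zip(reactions, freq)), len(reaction_sets))
    return IncidenceMatrix([rec for rec, _ in reaction_sets], pan, presence)


# ---------------------------------------------------------------------------
# genome selection and splits
# ---------------------------------------------------------------------------

def _best_of(group: list[GenomeRecord]) -> GenomeRecord:
    # quality score, then coarse consistency, then lexicographic id for
    # determinism
    return max(
        group,
        key=lambda g: (g.quality_score, g.coarse_consistency, _NegStr(g.genome_id)),
    )


class _NegStr(str):
    """String whose ordering is reversed, so max() picks the lexicographic min."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def select_best_genomes(
    records: Sequence[GenomeRecord], level: str = "species"
) -> list[GenomeRecord]:
    """Pick the best genome per species (or genus) by sequencing quality.

    The winner maximises ``completeness - 5 * contamination``; ties are broken
    by the highest coarse consistency, remaining ties by lexicographically
    smallest genome id.  Output preserves first-appearance order of labels.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"unknown grouping level: {level}")
    groups: dict[str, list[GenomeRecord]] = {}
    order: list[str] = []
    for rec in records:
        label = getattr(rec, level)
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(rec)
    return [_best_of(groups[label]) for label in order]


def split_train_test(matrix: IncidenceMatrix) -> tuple[IncidenceMatrix, IncidenceMatrix]:
    """Best genome per genus goes to test; every other genome to train.

    Both halves keep the pan-reactome of the full input so that vectors from
    either side live in the same coordinates.  A genus with a single genome
    contributes it to test and nothing to train.
    """
    if any(not g.genus for g in matrix.genomes):
        raise ValueError("genus labels required for train/test split")
    test_records = select_best_genomes(matrix.genomes, level="genus")
    test_ids = {g.genome_id for g in test_records}
    singleton_genera = [
        g.genus
        for g in test_records
        if sum(1 for r in matrix.genomes if r.genus == g.genus) == 1
    ]
    if singleton_genera:
        logger.info(
            "%d genera have a single genome; they contribute to test only",
            len(singleton_genera),
        )
    train_ids = [g for g in matrix.genome_ids if g not in test_ids]
    return matrix.subset(train_ids), matrix.subset(sorted(test_ids))


def exclude_partition(
    matrix: IncidenceMatrix, label: str, level: str = "genus"
) -> IncidenceMatrix:
    """Drop every genome carrying a taxon label; keep column order.

    Frequencies are recomputed over the remaining genomes (columns that
    vanish entirely are dropped, which is what recomputation implies for a
    pan-reactome).  An absent label is a warning no-op.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"unknown grouping level: {level}")
    keep = [g.genome_id for g in matrix.genomes if getattr(g, level) != label]
    if len(keep) == matrix.n_genomes:
        logger.warning("label %r not present at level %s; nothing excluded", label, level)
        return matrix
    if not keep:
        raise ValueError(f"excluding {label!r} would leave no genomes")
    return matrix.subset(keep).recompute_pan()


# ---------------------------------------------------------------------------
# stoichiometric containers
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """One stoichiometric reaction; negative coefficients consume."""

    id: ReactionId
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id.label}: lower bound {self.lower_bound} > upper "
                f"{self.upper_bound}"
            )

    def reversed(self, suffix_tag: str = "backward") -> "Reaction":
        return Reaction(
            id=replace(self.id, direction_tag=suffix_tag),
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            lower_bound=0.0,
            upper_bound=abs(self.lower_bound) if self.lower_bound < 0 else self.upper_bound,
            name=self.name,
        )


class ReactionDatabase:
    """Collection of candidate reactions with declared metabolites."""

    def __init__(
        self,
        reactions: Sequence[Reaction],
        metabolites: Mapping[str, str] | None = None,
    ) -> None:
        self.reactions: list[Reaction] = list(reactions)
        labels = [r.id.label for r in self.reactions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate reaction ids in database")
        if metabolites is None:
            metabolites = {
                m: _compartment_of(m)
                for r in self.reactions
                for m in r.stoichiometry
            }
        self.metabolites: dict[str, str] = dict(metabolites)
        for r in self.reactions:
            missing = set(r.stoichiometry) - set(self.metabolites)
            if missing:
                raise ValueError(
                    f"{r.id.label} references undeclared metabolites: {sorted(missing)}"
                )
        self._by_label = {r.id.label: r for r in self.reactions}

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def get(self, label: str) -> Reaction:
        return self._by_label[label]


def _compartment_of(met_id: str) -> str:
    m = re.search(r"\[(\w+)\]$", met_id)
    if m:
        return m.group(1)
    m = re.search(r"_(\w)$", met_id)
    return m.group(1) if m else "c"


class MetabolicNetwork:
    """A genome's stoichiometric model: reactions, biomass, origin tags.

    ``origin`` marks each reaction as ``"annotation"`` (genetic evidence;
    never removed by gap-filling) or ``"gapfill"`` (added by the search).
    """

    def __init__(
        self,
        reactions: Sequence[Reaction],
        biomass_reaction_id: ReactionId | None = None,
        origin: Mapping[str, str] | None = None,
        model_id: str = "model",
    ) -> None:
        self.reactions: list[Reaction] = list(reactions)
        labels = [r.id.label for r in self.reactions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate reaction ids in model")
        self._by_label = {r.id.label: r for r in self.reactions}
        if biomass_reaction_id is not None and biomass_reaction_id.label not in self._by_label:
            raise ValueError(f"biomass reaction {biomass_reaction_id.label} not in model")
        self.biomass_reaction_id = biomass_reaction_id
        self.origin: dict[str, str] = dict(origin) if origin else {
            lab: "annotation" for lab in labels
        }
        self.model_id = model_id

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def get(self, label: str) -> Reaction:
        return self._by_label[label]

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for m in r.stoichiometry:
                seen.setdefault(m)
        return list(seen)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            self.biomass_reaction_id,
            dict(self.origin),
            self.model_id,
        )

    def with_added(self, added: Sequence[Reaction]) -> "MetabolicNetwork":
        """New network with extra reactions tagged as gap-filled."""
        out = self.copy()
        for r in added:
            if r.id.label in out._by_label:
                continue
            out.reactions.append(r)
            out._by_label[r.id.label] = r
            out.origin[r.id.label] = "gapfill"
        return out

    def annotation_labels(self) -> set[str]:
        return {lab for lab, o in self.origin.items() if o == "annotation"}


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

_EQ_ARROWS = ("<=>", "<--", "-->", "<->", "=>", "<=", "=")


def _parse_side(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^\((?P<coef>[\d.eE+-]+)\)\s+(?P<met>\S+)$", term)
        if m:
            coef = float(m.group("coef"))
            met = m.group("met")
        else:
            parts = term.split()
            if len(parts) == 2:
                coef = float(parts[0])
                met = parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ValueError(f"cannot parse stoichiometric term {term!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``(1) A[c] + (2) B[c] <=> (1) C[c]`` into signed stoichiometry.

    Returns the coefficient mapping (substrates negative) and whether the
    arrow denotes a reversible reaction.
    """
    for arrow in _EQ_ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            reversible = arrow in ("<=>", "<->", "=")
            if arrow in ("<--", "<="):
                left, right = right, left
            lhs = _parse_side(left)
            rhs = _parse_side(right)
            stoich: dict[str, float] = {m: -c for m, c in lhs.items()}
            for m, c in rhs.items():
                stoich[m] = stoich.get(m, 0.0) + c
            return {m: c for m, c in stoich.items() if c != 0.0}, reversible
    raise ValueError(f"no reaction arrow found in equation: {equation!r}")


def load_reaction_database(path: str | Path, dialect: str) -> ReactionDatabase:
    """Read a reaction database in a ModelSEED-style TSV or BiGG-style JSON.

    modelseed_tsv columns: ``id``, ``equation`` (and optionally ``name``,
    ``reversibility`` with ``>``/``<``/``=``, ``lower_bound``,
    ``upper_bound``).  bigg_json: COBRA-style JSON with ``reactions`` entries
    carrying ``metabolites`` coefficient maps and bounds.
    """
    path = Path(path)
    if dialect == "modelseed_tsv":
        return _load_modelseed_tsv(path)
    if dialect == "bigg_json":
        return _load_bigg_json(path)
    raise ValueError(f"unknown reaction database dialect: {dialect!r}")


def _load_modelseed_tsv(path: Path) -> ReactionDatabase:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty reaction database file") from exc
    if frame.empty or "id" not in frame.columns or "equation" not in frame.columns:
        raise ValueError(f"{path}: expected TSV with 'id' and 'equation' columns")
    reactions = []
    for lineno, rec in enumerate(frame.to_dict("records"), start=2):
        try:
            stoich, rev_from_eq = parse_equation(str(rec["equation"]))
            rev_col = rec.get("reversibility")
            if isinstance(rev_col, str) and rev_col.strip():
                reversible = rev_col.strip() == "="
            else:
                reversible = rev_from_eq
            lower = float(rec["lower_bound"]) if _has(rec, "lower_bound") else (
                -1000.0 if reversible else 0.0
            )
            upper = float(rec["upper_bound"]) if _has(rec, "upper_bound") else 1000.0
            reactions.append(
                Reaction(
                    id=ReactionId("modelseed", str(rec["id"])),
                    stoichiometry=stoich,
                    reversible=reversible,
                    lower_bound=lower,
                    upper_bound=upper,
                    name=str(rec.get("name", "") or ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    logger.info("loaded %d reactions from %s", len(reactions), path)
    return ReactionDatabase(reactions)


def _has(rec: Mapping[str, object], key: str) -> bool:
    v = rec.get(key)
    return v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v).strip() != ""


def _load_bigg_json(path: Path) -> ReactionDatabase:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    if "reactions" not in payload:
        raise ValueError(f"{path}: JSON lacks a 'reactions' array")
    metabolites = {
        m["id"]: m.get("compartment", _compartment_of(m["id"]))
        for m in payload.get("metabolites", [])
    } or None
    reactions = []
    for i, rec in enumerate(payload["reactions"]):
        try:
            lower = float(rec.get("lower_bound", 0.0))
            upper = float(rec.get("upper_bound", 1000.0))
            reactions.append(
                Reaction(
                    id=ReactionId("bigg", str(rec["id"])),
                    stoichiometry={str(m): float(c) for m, c in rec["metabolites"].items()},
                    reversible=lower < 0.0,
                    lower_bound=lower,
                    upper_bound=upper,
                    name=str(rec.get("name", "") or ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: reaction entry {i}: {exc}") from exc
    logger.info("loaded %d reactions from %s", len(reactions), path)
    return ReactionDatabase(reactions, metabolites)


def load_model(
    path: str | Path,
    format: str,
    biomass_ids: Sequence[str] = DEFAULT_BIOMASS_IDS,
    namespace: str | None = None,
) -> MetabolicNetwork:
    """Read an SBML or COBRA-JSON model into a :class:`MetabolicNetwork`.

    The biomass reaction is identified by the first matching id from
    ``biomass_ids`` (default ``bio1`` then ``Growth``); if none matches, the
    model is returned without a biomass reaction and a warning is logged.
    """
    import cobra.io

    path = Path(path)
    if format == "sbml":
        model = cobra.io.read_sbml_model(str(path))
        default_ns = "modelseed"
    elif format == "cobra_json":
        model = cobra.io.load_json_model(str(path))
        default_ns = "bigg"
    else:
        raise ValueError(f"unknown model format: {format!r}")
    ns = namespace or default_ns
    if len(model.reactions) == 0:
        raise ValueError(f"{path}: model contains no reactions")
    reactions = [
        Reaction(
            id=ReactionId(ns, rxn.id),
            stoichiometry={met.id: coef for met, coef in rxn.metabolites.items()},
            reversible=rxn.lower_bound < 0.0,
            lower_bound=float(rxn.lower_bound),
            upper_bound=float(rxn.upper_bound),
            name=rxn.name or "",
        )
        for rxn in model.reactions
    ]
    biomass = None
    present = {r.id.identifier for r in reactions}
    for bid in biomass_ids:
        if bid in present:
            biomass = ReactionId(ns, bid)
            break
    if biomass is None:
        logger.warning("%s: no biomass reaction among %s", path, list(biomass_ids))
    return MetabolicNetwork(reactions, biomass, model_id=model.id or path.stem)


def save_model_json(network: MetabolicNetwork, path: str | Path) -> None:
    """Write a network as COBRA-style JSON (readable by cobra and panfill)."""
    mets = network.metabolites
    payload = {
        "id": network.model_id,
        "metabolites": [
            {"id": m, "compartment": _compartment_of(m)} for m in mets
        ],
        "reactions": [
            {
                "id": r.id.label,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "notes": {"origin": network.origin.get(r.id.label, "annotation")},
            }
            for r in network.reactions
        ],
        "genes": [],
        "compartments": {c: c for c in {_compartment_of(m) for m in mets}},
        "version": "1",
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
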