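"""Simulated genome incompleteness: reaction deletion schemes.

Incomplete genomes are emulated by deleting reactions from complete presence
vectors.  Two schemes are supported: *uniform*, which removes an exact
fraction (default 30%) of the present reactions, and *rare_biased*, which
removes each present reaction independently with a logistic probability that
decreases with the reaction's frequency across the collection, mimicking the
binning/annotation biases that preferentially lose accessory genes from
metagenome-assembled genomes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from panfill.reactome import IncidenceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeletionScheme:
    """Parameters of the reaction-deletion process.

    kind
        ``"uniform"``: delete exactly ``round(target_fraction * n_present)``
        reactions, chosen uniformly without replacement.
        ``"rare_biased"``: delete each present reaction independently with a
        logistic probability of its frequency.
    target_fraction
        Fraction deleted under the uniform scheme (default 0.3).
    steepness, midpoint
        Logistic parameters of the rare-biased curve.
    as_printed
        Orientation of the logistic.  The default (False) deletes *rarer*
        reactions more often; True flips the sign of the exponent so the
        probability instead increases with frequency.
    rescale_to_target
        If True, rare-biased probabilities are multiplied by a constant so
        the expected deleted fraction of the genome equals
        ``target_fraction`` (off by default).
    """

    kind: str = "uniform"
    target_fraction: float = 0.3
    steepness: float = 10.0
    midpoint: float = 0.5
    as_printed: bool = False
    rescale_to_target: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "rare_biased"):
            raise ValueError(f"unknown deletion scheme kind: {self.kind!r}")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class CorruptedSample:
    """Paired (input, truth) presence vectors for one genome replicate.

    ``input_vector <= truth_vector`` element-wise: corruption only deletes.
    """

    genome_id: str
    input_vector: np.ndarray
    truth_vector: np.ndarray
    replicate_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_vector.shape != self.truth_vector.shape:
            raise ValueError("input and truth vectors differ in length")
        if np.any(self.input_vector > self.truth_vector):
            raise ValueError("corruption may only delete reactions (I <= T)")

    @property
    def deleted(self) -> np.ndarray:
        """Boolean mask of deleted positions (present in T, absent in I)."""
        return (self.truth_vector == 1) & (self.input_vector == 0)


def deletion_probability(frac: float | np.ndarray, scheme: DeletionScheme) -> float | np.ndarray:
    """Per-reaction deletion probability as a function of frequency.

    Uniform: constant ``target_fraction``.  Rare-biased: logistic
    ``1 - 1/(1 + exp(-k*(frac - m)))``, strictly decreasing in ``frac`` so
    that rare reactions are deleted more often (set ``as_printed=True`` for
    the increasing orientation).
    """
    arr = np.asarray(frac, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("frac must lie in [0, 1]")
    if scheme.kind == "uniform":
        out = np.full_like(arr, scheme.target_fraction)
    else:
        sign = 1.0 if scheme.as_printed else -1.0
        out = 1.0 - 1.0 / (1.0 + np.exp(sign * scheme.steepness * (arr - scheme.midpoint)))
    if arr.ndim == 0:
        return float(out)
    return out


def corrupt(
    truth: np.ndarray,
    scheme: DeletionScheme,
    seed: int,
    frequencies: np.ndarray | None = None,
    genome_id: str = "",
    replicate_index: int = 0,
) -> CorruptedSample:
    """Delete reactions from one presence vector.

    Uniform mode removes exactly ``round(target_fraction * n_present)``
    present reactions; rare-biased mode needs per-reaction ``frequencies``
    and flips independent coins.  A corruption that would delete everything
    is resampled, keeping at least one reaction.
    """
    truth = np.asarray(truth).astype(np.int8)
    present = np.flatnonzero(truth == 1)
    if present.size == 0:
        raise ValueError("truth vector has no present reactions")
    rng = np.random.default_rng(seed)
    inp = truth.copy()
    if scheme.kind == "uniform":
        n_delete = int(round(scheme.target_fraction * present.size))
        n_delete = min(n_delete, present.size - 1)  # always retain >= 1
        if n_delete > 0:
            drop = rng.choice(present, size=n_delete, replace=False)
            inp[drop] = 0
    else:
        if frequencies is None:
            raise ValueError("rare_biased corruption requires reaction frequencies")
        probs = np.asarray(deletion_probability(frequencies, scheme), dtype=float)
        if scheme.rescale_to_target:
            expected = probs[present].mean()
            if expected > 0:
                probs = np.clip(probs * scheme.target_fraction / expected, 0.0, 1.0)
        for _ in range(100):
            coins = rng.random(present.size) < probs[present]
            if not coins.all():
                break
        else:  # pragma: no cover - (1-p)^... practically never exhausts
            coins[rng.integers(coins.size)] = False
            logger.warning("%s: corruption resampling exhausted; forced one retained", genome_id)
        inp[present[coins]] = 0
    return CorruptedSample(
        genome_id=genome_id,
        input_vector=inp,
        truth_vector=truth,
        replicate_index=replicate_index,
        seed=seed,
    )


def derive_seed(base_seed: int, genome_id: str, replicate_index: int) -> int:
    """Deterministic 63-bit per-sample seed from (base seed, genome, replicate)."""
    h = hashlib.blake2b(
        f"{base_seed}:{genome_id}:{replicate_index}".encode(), digest_size=8
    )
    return int.from_bytes(h.digest(), "little") >> 1


def make_replicates(
    matrix: IncidenceMatrix,
    n_replicates: int,
    scheme: DeletionScheme,
    base_seed: int,
) -> Iterator[CorruptedSample]:
    """Stream ``n_genomes * n_replicates`` corrupted samples.

    Each sample's seed is derived deterministically from
    ``(base_seed, genome_id, replicate_index)``, so the stream can be
    regenerated without storing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    freqs = matrix.pan_reactome.frequency_vector()
    for genome in matrix.genomes:
        truth = matrix.row(genome.genome_id)
        for rep in range(n_replicates):
            seed = derive_seed(base_seed, genome.genome_id, rep)
            yield corrupt(
                truth,
                scheme,
                seed,
                frequencies=freqs,
                genome_id=genome.genome_id,
                replicate_index=rep,
            )
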