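"""Residue clustering statistics: inverse-weighted distance with shuffle nulls.

The inverse-weighted distance (IWD) of a set S of residue positions is the
mean over unordered pairs of the reciprocal sequence separation,

    IWD(S) = (1 / N_pairs) * sum_{i<j} 1 / (S_j - S_i),

so tightly grouped residues score high and dispersed ones low.  Because IWD
depends on both sequence length and class count, observed values are
normalised against a null distribution obtained by fully shuffling the
sequence (default 10,000 shuffles) and recomputing IWD on the shuffled class
positions; the Z-score (obs - null mean) / null sd is comparable across
proteins.  A Z above 1.96 is called significant positive clustering, the
normal-approximation analogue of a two-sided p < 0.05; the empirical
two-sided p from the null draws is reported alongside.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .charge_model import ProteinSequence

logger = logging.getLogger("chargescan")

Z_THRESHOLD = 1.96


@dataclass(frozen=True)
class ResidueClassDef:
    """A named residue class, e.g. positive = {R, K}."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"residue class {self.name!r} has no members")


POSITIVE = ResidueClassDef("positive", frozenset("RK"))
NEGATIVE = ResidueClassDef("negative", frozenset("DE"))
AROMATIC = ResidueClassDef("aromatic", frozenset("YFW"))

BUILTIN_CLASSES = {c.name: c for c in (POSITIVE, NEGATIVE, AROMATIC)}


def resolve_class(spec: str) -> ResidueClassDef:
    """Resolve a class name or ``custom:<letters>`` spec to a definition."""
    if spec in BUILTIN_CLASSES:
        return BUILTIN_CLASSES[spec]
    if spec.startswith("custom:"):
        letters = spec.split(":", 1)[1].upper()
        return ResidueClassDef(f"custom:{letters}", frozenset(letters))
    raise ValueError(
        f"unknown residue class {spec!r}; use one of "
        f"{sorted(BUILTIN_CLASSES)} or custom:<letters>"
    )


@dataclass(frozen=True)
class ResiduePositions:
    """Sorted 1-based positions of one residue class within a sequence."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


@dataclass(frozen=True)
class NullDistribution:
    mean: float
    sd: float
    draws: np.ndarray


@dataclass(frozen=True)
class IWDResult:
    seq_id: str
    class_name: str
    n_residues: int
    iwd_obs: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_shuffles: int
    seed: int

    @property
    def significant(self) -> bool:
        """Significant positive clustering: z above the 1.96 threshold."""
        return self.z > Z_THRESHOLD

    @property
    def significant_two_sided(self) -> bool:
        return abs(self.z) > Z_THRESHOLD


def extract_positions(seq: ProteinSequence, cls: ResidueClassDef) -> ResiduePositions:
    """1-based positions of all residues belonging to the class."""
    return ResiduePositions(
        tuple(i for i, aa in enumerate(seq.residues, start=1) if aa in cls.members)
    )


def iwd(pos: ResiduePositions | Iterable[int]) -> float:
    """Mean inverse pairwise sequence separation of a position set."""
    if not isinstance(pos, ResiduePositions):
        pos = ResiduePositions(tuple(sorted(pos)))
    if pos.n < 2:
        raise ValueError(
            f"insufficient residues for IWD: need >= 2 positions, got {pos.n}"
        )
    return _iwd_from_array(np.asarray(pos.positions, dtype=float))


def _iwd_from_array(positions: np.ndarray) -> float:
    # positions sorted ascending; upper-triangle pairwise separations
    diffs = positions[None, :] - positions[:, None]
    iu = np.triu_indices(len(positions), k=1)
    return float(np.mean(1.0 / diffs[iu]))


def _check_null_preconditions(seq: ProteinSequence, cls: ResidueClassDef) -> int:
    n_class = sum(1 for aa in seq.residues if aa in cls.members)
    if n_class < 2:
        raise ValueError(
            f"class {cls.name!r} occupies {n_class} position(s) of {seq.id!r}; "
            "need >= 2 for IWD"
        )
    if n_class >= len(seq):
        raise ValueError(
            f"class {cls.name!r} occupies every position of {seq.id!r}; "
            "the shuffle null is degenerate (sd = 0)"
        )
    return n_class


def null_distribution(
    seq: ProteinSequence,
    cls: ResidueClassDef,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """IWD null from full uniform shuffles of the sequence.

    Each draw permutes the whole residue string (Fisher-Yates via the seeded
    generator) and recomputes IWD over the class positions of the shuffled
    sequence.  The null therefore depends only on sequence length and class
    composition.
    """
    _check_null_preconditions(seq, cls)
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles to estimate a null sd")
    rng = np.random.default_rng(seed)
    mask = np.fromiter((aa in cls.members for aa in seq.residues), dtype=bool)
    # canonical (sorted) arrangement before shuffling: a uniform permutation
    # of any arrangement is uniform, and this makes the null depend only on
    # composition and length, bit-for-bit, under a fixed seed
    mask = np.sort(mask)
    draws = np.empty(n_shuffles, dtype=float)
    for k in range(n_shuffles):
        shuffled = rng.permutation(mask)
        positions = np.flatnonzero(shuffled).astype(float) + 1.0
        draws[k] = _iwd_from_array(positions)
    return NullDistribution(mean=float(draws.mean()), sd=float(draws.std(ddof=1)), draws=draws)


def iwd_zscore(
    seq: ProteinSequence,
    cls: ResidueClassDef,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> IWDResult:
    """Observed IWD normalised against the shuffle null of the same sequence."""
    obs = iwd(extract_positions(seq, cls))
    null = null_distribution(seq, cls, n_shuffles=n_shuffles, seed=seed)
    if null.sd == 0:
        raise ValueError(
            f"degenerate null (sd = 0) for class {cls.name!r} on {seq.id!r}"
        )
    z = (obs - null.mean) / null.sd
    # add-one empirical two-sided p, capped at 1
    hi = int(np.sum(null.draws >= obs))
    lo = int(np.sum(null.draws <= obs))
    p_emp = min(1.0, 2.0 * (min(hi, lo) + 1) / (len(null.draws) + 1))
    return IWDResult(
        seq_id=seq.id,
        class_name=cls.name,
        n_residues=extract_positions(seq, cls).n,
        iwd_obs=obs,
        null_mean=null.mean,
        null_sd=null.sd,
        z=float(z),
        p_empirical=float(p_emp),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def derive_seed(master_seed: int, record_id: str) -> int:
    """Stable per-record seed: SHA-256 of (master seed, record id) mod 2**31.

    Adding or reordering records never perturbs existing per-record nulls.
    """
    digest = hashlib.sha256(f"{master_seed}:{record_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def batch_iwd(
    records: Sequence[ProteinSequence],
    cls: ResidueClassDef,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> list[IWDResult]:
    """One IWDResult per record; degenerate records are skipped with a log line."""
    if not records:
        raise ValueError("batch_iwd requires at least one record")
    results: list[IWDResult] = []
    for rec in records:
        try:
            _check_null_preconditions(rec, cls)
        except ValueError as exc:
            logger.info("skipping %s: %s", rec.id, exc)
            continue
        results.append(
            iwd_zscore(rec, cls, n_shuffles=n_shuffles, seed=derive_seed(seed, rec.id))
        )
    return results


def percentile_rank(target_id: str, results: Sequence[IWDResult]) -> float:
    """Percent of results with z strictly greater than the target's ("top X%")."""
    if len(results) < 2:
        raise ValueError("percentile rank needs at least 2 results")
    by_id = {r.seq_id: r for r in results}
    if target_id not in by_id:
        raise ValueError(f"target {target_id!r} not among the results")
    target_z = by_id[target_id].z
    greater = sum(1 for r in results if r.z > target_z)
    return 100.0 * greater / len(results)
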