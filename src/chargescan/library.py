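"""Rational design of tiled peptide libraries for binding-site mapping.

The core of a library is a 15-mer "mapping" scan shifting by 3 residues
through the parent sequence; regions of interest get finer 1-shift scans,
and candidate binding peptides spawn scrambles (composition-preserving
permutations), truncation ladders, and single-position substitution panels.
All peptides except the one anchored at the parent's N-terminus are flagged
as N-terminally acetylated, mimicking the backbone context of an internal
segment.

A small codon utility computes relative adaptiveness (each codon's usage
frequency scaled to the most-used synonymous codon = 100%), used to pick
rank-matched codons when designing mutants; codon choice itself is left to
the user.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .charge_model import ProteinSequence


@dataclass(frozen=True)
class Peptide:
    """A designed library member with provenance back to its parent."""

    peptide_id: str
    parent_id: str
    sequence: str
    category: str  # mapping | fine_scan | scramble | truncation | substitution
    start: int | None = None  # 1-based inclusive parent coordinates
    end: int | None = None
    acetylated: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.peptide_id!r} has an empty sequence")


def mapping_peptides(
    seq: ProteinSequence,
    length: int = 15,
    shift: int = 3,
    cover_terminus: bool = False,
) -> list[Peptide]:
    """Tiled scan through the parent: starts 1, 1+shift, ... while they fit.

    Only the peptide anchored at position 1 is left unacetylated.  With
    ``cover_terminus``, one extra peptide anchored at the C-terminus is
    appended when the plain grid leaves trailing residues uncovered.
    """
    L = len(seq)
    if length > L:
        raise ValueError(f"peptide length {length} exceeds sequence length {L}")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    starts = list(range(1, L - length + 2, shift))
    if cover_terminus and starts and starts[-1] + length - 1 < L:
        starts.append(L - length + 1)
    peptides = []
    for s in starts:
        e = s + length - 1
        peptides.append(
            Peptide(
                peptide_id=f"{seq.id}_map_{s:05d}",
                parent_id=seq.id,
                sequence=seq.subsequence(s, e),
                category="mapping",
                start=s,
                end=e,
                acetylated=(s != 1),
                provenance=f"map:length={length},shift={shift},start={s}",
            )
        )
    return peptides


def fine_scan(
    seq: ProteinSequence,
    roi_start: int,
    roi_end: int,
    length: int = 15,
    shift: int = 1,
) -> list[Peptide]:
    """1-shift windows covering a region of interest.

    ROIs shorter than ``length`` are extended symmetrically into the parent
    (clamped at the termini) so every library peptide keeps the full length.
    """
    L = len(seq)
    if roi_start > roi_end:
        raise ValueError(f"ROI reversed: start {roi_start} > end {roi_end}")
    if not (1 <= roi_start and roi_end <= L):
        raise ValueError(f"ROI [{roi_start}, {roi_end}] outside sequence of length {L}")
    if roi_end - roi_start + 1 < length:
        deficit = length - (roi_end - roi_start + 1)
        roi_start = max(1, roi_start - (deficit + 1) // 2)
        roi_end = min(L, roi_start + length - 1)
        roi_start = max(1, roi_end - length + 1)
    peptides = []
    for s in range(roi_start, roi_end - length + 2, shift):
        e = s + length - 1
        peptides.append(
            Peptide(
                peptide_id=f"{seq.id}_fine_{s:05d}",
                parent_id=seq.id,
                sequence=seq.subsequence(s, e),
                category="fine_scan",
                start=s,
                end=e,
                acetylated=(s != 1),
                provenance=f"fine:length={length},shift={shift},start={s}",
            )
        )
    return peptides


def scramble_peptides(parent: Peptide, n: int, seed: int) -> list[Peptide]:
    """n seeded, pairwise-distinct permutations of the parent sequence.

    Composition (and hence net charge) is preserved by construction.  Each
    scramble must differ from the parent; rejection sampling is capped at
    1000 attempts per scramble so impossible requests fail loudly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(set(parent.sequence)) < 2:
        raise ValueError(
            f"parent {parent.peptide_id!r} is mono-residue; no distinct scramble exists"
        )
    rng = random.Random(seed)
    seen: set[str] = {parent.sequence}
    out: list[Peptide] = []
    for i in range(1, n + 1):
        for attempt in range(1000):
            letters = list(parent.sequence)
            rng.shuffle(letters)
            cand = "".join(letters)
            if cand not in seen:
                seen.add(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw a new distinct scramble of {parent.peptide_id!r} "
                "within 1000 attempts"
            )
        out.append(
            Peptide(
                peptide_id=f"{parent.peptide_id}_scr{i:02d}",
                parent_id=parent.peptide_id,
                sequence=cand,
                category="scramble",
                acetylated=True,
                provenance=f"scramble:of={parent.peptide_id},seed={seed},index={i}",
            )
        )
    return out


def truncation_series(parent: Peptide, side: str, min_len: int) -> list[Peptide]:
    """Peptides removing 1, 2, ... residues from one end down to ``min_len``."""
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_len > len(parent.sequence):
        raise ValueError(
            f"min_len {min_len} exceeds parent length {len(parent.sequence)}"
        )
    out = []
    for k in range(1, len(parent.sequence) - min_len + 1):
        seq = parent.sequence[k:] if side == "N" else parent.sequence[:-k]
        out.append(
            Peptide(
                peptide_id=f"{parent.peptide_id}_trunc{side}{k:02d}",
                parent_id=parent.peptide_id,
                sequence=seq,
                category="truncation",
                acetylated=parent.acetylated or side == "N",
                provenance=f"truncation:of={parent.peptide_id},side={side},removed={k}",
            )
        )
    return out


def substitution_panel(
    parent: Peptide,
    positions: Iterable[int],
    alphabet: Iterable[str],
) -> list[Peptide]:
    """One peptide per (position, residue != wild-type) combination.

    Positions are 1-based within the parent peptide.  Wild-type cells are
    not emitted (they are the reference), and combinations outside the
    alphabet are simply absent.
    """
    alphabet = sorted(set(alphabet))
    out = []
    for pos in sorted(set(positions)):
        if not 1 <= pos <= len(parent.sequence):
            raise ValueError(
                f"substitution position {pos} outside parent of length "
                f"{len(parent.sequence)}"
            )
        wt = parent.sequence[pos - 1]
        for aa in alphabet:
            if aa == wt:
                continue
            seq = parent.sequence[:pos - 1] + aa + parent.sequence[pos:]
            out.append(
                Peptide(
                    peptide_id=f"{parent.peptide_id}_p{pos:02d}{wt}{aa}",
                    parent_id=parent.peptide_id,
                    sequence=seq,
                    category="substitution",
                    acetylated=parent.acetylated,
                    provenance=(
                        f"substitution:of={parent.peptide_id},pos={pos},wt={wt},mut={aa}"
                    ),
                )
            )
    return out


def relative_adaptiveness(
    codon_freqs: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Per-codon usage scaled to the top synonymous codon (= 100%).

    Input maps amino acid -> {codon: frequency}; output maps codon -> score
    in percent.  Ties at the top all score 100.
    """
    scores: dict[str, float] = {}
    for aa, group in codon_freqs.items():
        if not group:
            raise ValueError(f"amino acid {aa!r} has no codons")
        if any(f < 0 for f in group.values()):
            raise ValueError(f"negative codon frequency in group {aa!r}")
        top = max(group.values())
        if top == 0:
            raise ValueError(f"all-zero codon frequencies for amino acid {aa!r}")
        for codon, f in group.items():
            scores[codon] = 100.0 * f / top
    return scores
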