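"""Residue-level charge assignment at pH 7.0 and windowed sequence profiles.

The charge model is deliberately simple and fixed to pH 7.0: aspartate and
glutamate carry -1, arginine and lysine +1, histidine a fractional +0.091
(its Henderson-Hasselbalch protonated fraction at pH 7.0 with a sidechain
pKa of 6.0), and every other residue is neutral.  Terminal alpha-amino /
alpha-carboxyl charges are never counted: library peptides are N-terminally
acetylated to mimic an internal segment of the parent protein, and the
sidechain-only convention is what reproduces the worked net-charge examples
this package is validated against.

Phosphorylation is modelled as a flat -2 per phosphosite, the net charge of
a phosphate dianion at neutral pH.

Profiles:

* NCPR (net charge per residue): mean sidechain charge over a sliding
  window (default 10 residues), anchored at the window *start* position.
* Kyte-Doolittle hydropathy: mean scale value over an odd, centered window
  (default 5: the residue plus two neighbours on each side).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("chargescan")

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

PHOSPHO_DELTA = -2.0


def histidine_protonated_fraction(ph: float = 7.0, pka: float = 6.0) -> float:
    """Protonated fraction of the histidine sidechain by Henderson-Hasselbalch.

    ``1 / (1 + 10**(ph - pka))``; at pH 7.0 with pKa 6.0 this is 1/11,
    which rounds to the 0.091 charge used throughout the package.
    """
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


@dataclass(frozen=True)
class ChargeRules:
    """Per-residue sidechain charge map at pH 7.0.

    ``histidine_charge`` is configurable (0.091 by default; set 0 to treat
    histidine as neutral) because fractional histidine protonation matters
    for peptide-level net charge but is sometimes omitted from NCPR
    profiles in the literature.
    """

    histidine_charge: float = 0.091
    phospho_delta: float = PHOSPHO_DELTA

    @property
    def charge_map(self) -> dict[str, float]:
        m = {aa: 0.0 for aa in STANDARD_RESIDUES}
        m["D"] = m["E"] = -1.0
        m["R"] = m["K"] = +1.0
        m["H"] = self.histidine_charge
        return m

    def charge(self, residue: str) -> float:
        return residue_charge(residue, self)


DEFAULT_RULES = ChargeRules()


def _validate_residues(residues: str, context: str = "sequence") -> None:
    bad = set(residues) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"non-standard residue code(s) {sorted(bad)} in {context}; "
            "only the 20 standard one-letter codes are accepted"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """An identified residue string with 1-based coordinates.

    ``phosphosites`` is an optional set of 1-based positions carrying a
    phosphate group; sites on non-S/T/Y residues are accepted with a
    warning (published phosphosite lists occasionally contain ambiguous
    assignments) but never silently dropped.
    """

    id: str
    residues: str
    phosphosites: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        _validate_residues(self.residues, context=f"sequence {self.id!r}")
        object.__setattr__(self, "phosphosites", frozenset(self.phosphosites))
        for p in self.phosphosites:
            if not 1 <= p <= len(self.residues):
                raise ValueError(
                    f"phosphosite position {p} outside [1, {len(self.residues)}] "
                    f"for sequence {self.id!r}"
                )
            if self.residues[p - 1] not in "STY":
                logger.warning(
                    "phosphosite at position %d of %s is on %r, not S/T/Y",
                    p, self.id, self.residues[p - 1],
                )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> str:
        """Residues at 1-based inclusive [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"interval [{start}, {end}] outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start - 1:end]


@dataclass(frozen=True)
class NCPRProfile:
    """Windowed net charge per residue, one value per window start (1-based)."""

    seq_id: str
    window: int
    values: tuple[float, ...]
    phospho_applied: bool = False

    @property
    def starts(self) -> range:
        return range(1, len(self.values) + 1)


def residue_charge(residue: str, rules: ChargeRules = DEFAULT_RULES) -> float:
    """Sidechain charge of a single residue at pH 7.0."""
    if len(residue) != 1 or residue not in STANDARD_RESIDUES:
        raise ValueError(
            f"non-standard residue code {residue!r}; "
            "expected one of the 20 standard one-letter codes"
        )
    return rules.charge_map[residue]


def peptide_net_charge(peptide: str, rules: ChargeRules = DEFAULT_RULES) -> float:
    """Net sidechain charge of a peptide (termini not counted)."""
    if not peptide:
        raise ValueError("cannot compute net charge of an empty peptide")
    _validate_residues(peptide, context="peptide")
    cm = rules.charge_map
    return sum(cm[aa] for aa in peptide)


def _per_residue_charges(
    seq: ProteinSequence,
    rules: ChargeRules,
    apply_phospho: bool,
) -> np.ndarray:
    cm = rules.charge_map
    charges = np.array([cm[aa] for aa in seq.residues], dtype=float)
    if apply_phospho and seq.phosphosites:
        idx = np.fromiter((p - 1 for p in seq.phosphosites), dtype=int)
        charges[idx] += rules.phospho_delta
    return charges


def ncpr_profile(
    seq: ProteinSequence,
    window: int = 10,
    apply_phospho: bool = False,
    rules: ChargeRules = DEFAULT_RULES,
) -> NCPRProfile:
    """Sliding-window net charge per residue, anchored at the window start.

    Value at start ``s`` is the mean charge of residues ``s .. s+window-1``;
    phosphosites contribute an additional -2 each when ``apply_phospho``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) < window:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq)}) shorter than window {window}"
        )
    charges = _per_residue_charges(seq, rules, apply_phospho)
    kernel = np.ones(window) / window
    values = np.convolve(charges, kernel, mode="valid")
    return NCPRProfile(
        seq_id=seq.id,
        window=window,
        values=tuple(float(v) for v in values),
        phospho_applied=bool(apply_phospho),
    )


def hydropathy_profile(
    seq: ProteinSequence,
    window: int = 5,
    scale: Mapping[str, float] = KYTE_DOOLITTLE,
) -> dict[int, float]:
    """Centered Kyte-Doolittle hydropathy, keyed by 1-based position.

    The window must be odd; the value at position p averages the scale over
    p and its (window-1)/2 neighbours on each side, so only positions
    [(window+1)/2, L-(window-1)/2] receive a value.
    """
    if window % 2 == 0:
        raise ValueError("hydropathy window must be odd (centered window)")
    if len(seq) < window:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq)}) shorter than window {window}"
        )
    half = window // 2
    values = np.array([scale[aa] for aa in seq.residues], dtype=float)
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    return {pos: float(v) for pos, v in zip(range(half + 1, len(seq) - half + 1), means)}
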