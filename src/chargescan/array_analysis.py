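"""From extracted peptide-array spot intensities to binding statistics.

The pipeline starts where image quantification ends: a table of raw spot
densities (triplicate spots per peptide; undetected spots read 0, manually
excluded spots carry a flag).  Replicates are averaged, means are scaled to
the array maximum, and the top decile of binders is characterised by a
one-proportion z-test on residue (or residue-class) composition,

    z = (p_hat - p0) / sqrt(p0 * (1 - p0) / n),

where p_hat is the unit's proportion among top-decile residues, p0 its
proportion in the full mapping library, and n a residue count whose
convention is configurable ("combined": background + top residues, the
default; "top_only": the standard one-proportion convention).

Charge-binding association is summarised as the Spearman rank correlation
between normalised intensity and peptide net charge, and substitution
panels are reported as log2(mutant / wild-type reference) with a positive
floor so undetected (zero) spots stay finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .charge_model import ChargeRules, DEFAULT_RULES, peptide_net_charge

logger = logging.getLogger("chargescan")

#: Residue classes used for composition enrichment.
RESIDUE_CLASSES: Mapping[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("RK"),
    "polar": frozenset("HCNQS"),
    "aromatic": frozenset("YFW"),
    "nonpolar": frozenset("GAVILMP"),
}


@dataclass(frozen=True)
class SpotRecord:
    peptide_id: str
    replicate: int
    raw_intensity: float
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.raw_intensity < 0:
            raise ValueError(
                f"negative intensity {self.raw_intensity} for spot "
                f"{self.peptide_id}/{self.replicate}"
            )


@dataclass(frozen=True)
class PeptideIntensity:
    peptide_id: str
    n_replicates: int
    mean_raw: float
    normalized: float
    decile: int


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    p_hat: float
    p0: float
    n: int
    z: float
    p_value: float


@dataclass(frozen=True)
class SubstitutionEntry:
    position: int
    wt: str
    mutant: str
    log2_ratio: float
    wt_reference: float


def aggregate(spots: Sequence[SpotRecord]) -> list[PeptideIntensity]:
    """Replicate means, max-normalisation and decile assignment.

    Excluded replicates are dropped; peptides with no usable replicate are
    dropped entirely (logged).  ``normalized`` scales each mean by the
    array's maximum mean, so the strongest binder reads exactly 1.0, and
    deciles run 1 (weakest) to 10 (strongest) on the normalised rank.
    """
    if not spots:
        raise ValueError("no spot records supplied")
    by_pep: dict[str, list[float]] = {}
    order: list[str] = []
    for s in spots:
        if s.peptide_id not in by_pep:
            by_pep[s.peptide_id] = []
            order.append(s.peptide_id)
        if not s.excluded:
            by_pep[s.peptide_id].append(s.raw_intensity)
    means: dict[str, float] = {}
    for pid in order:
        vals = by_pep[pid]
        if not vals:
            logger.info("dropping peptide %s: all replicates excluded", pid)
            continue
        means[pid] = float(np.mean(vals))
    if not means:
        raise ValueError("every peptide had all replicates excluded")
    max_mean = max(means.values())
    if max_mean == 0:
        raise ValueError("all spot intensities are zero; cannot normalise")
    ser = pd.Series(means)
    pct = ser.rank(method="average") / len(ser)
    deciles = np.clip(np.ceil(pct * 10).astype(int), 1, 10)
    return [
        PeptideIntensity(
            peptide_id=pid,
            n_replicates=len(by_pep[pid]),
            mean_raw=means[pid],
            normalized=means[pid] / max_mean,
            decile=int(deciles[pid]),
        )
        for pid in means
    ]


def top_fraction(
    intensities: Sequence[PeptideIntensity],
    fraction: float = 0.10,
) -> list[PeptideIntensity]:
    """The top-binding fraction of peptides, with boundary ties all included.

    The cutoff is the k-th largest normalised value with
    k = floor(fraction * n); every peptide at or above the cutoff is
    returned, so membership never depends on sort stability.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not intensities:
        raise ValueError("no intensities supplied")
    n = len(intensities)
    k = int(fraction * n)
    if k < 1:
        logger.warning(
            "fewer than %d peptides for fraction %.3g; returning the top peptide",
            math.ceil(1 / fraction), fraction,
        )
        k = 1
    cutoff = sorted((p.normalized for p in intensities), reverse=True)[k - 1]
    return [p for p in intensities if p.normalized >= cutoff]


def _unit_members(unit: str) -> frozenset[str]:
    if unit in RESIDUE_CLASSES:
        return RESIDUE_CLASSES[unit]
    if len(unit) == 1:
        return frozenset(unit)
    raise ValueError(f"unknown residue class or code {unit!r}")


def _proportion(sequences: Iterable[str], members: frozenset[str]) -> tuple[float, int]:
    total = hits = 0
    for s in sequences:
        total += len(s)
        hits += sum(1 for aa in s if aa in members)
    if total == 0:
        raise ValueError("no residues in the peptide set")
    return hits / total, total


def composition_ztest(
    top: Sequence[str],
    background: Sequence[str],
    unit: str,
    n_convention: str = "combined",
) -> EnrichmentResult:
    """One-proportion z-test for enrichment of a residue or class in the top set.

    ``top`` and ``background`` are peptide sequences.  ``n_convention``:
    "combined" counts residues across background plus top (the default);
    "top_only" uses only the top-set residue count.
    """
    members = _unit_members(unit)
    p_hat, n_top = _proportion(top, members)
    p0, n_bg = _proportion(background, members)
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError(
            f"background proportion for {unit!r} is {p0}; the z-test variance is zero"
        )
    if n_convention == "combined":
        n = n_bg + n_top
    elif n_convention == "top_only":
        n = n_top
    else:
        raise ValueError(f"unknown n convention {n_convention!r}")
    z = (p_hat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p_value = 2.0 * stats.norm.sf(abs(z))
    return EnrichmentResult(unit=unit, p_hat=p_hat, p0=p0, n=n, z=float(z),
                            p_value=float(p_value))


def enrichment_table(
    top: Sequence[str],
    background: Sequence[str],
    units: Sequence[str] | None = None,
    n_convention: str = "combined",
) -> pd.DataFrame:
    """composition_ztest over several units, sorted by descending z."""
    units = list(units) if units is not None else list(RESIDUE_CLASSES)
    rows = []
    for u in units:
        try:
            r = composition_ztest(top, background, u, n_convention=n_convention)
        except ValueError as exc:
            logger.info("skipping unit %s: %s", u, exc)
            continue
        rows.append(vars(r))
    df = pd.DataFrame(rows)
    return df.sort_values("z", ascending=False).reset_index(drop=True)


def charge_binding_table(
    intensities: Sequence[PeptideIntensity],
    sequences: Mapping[str, str],
    rules: ChargeRules = DEFAULT_RULES,
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Per-peptide rank/intensity/net-charge table plus Spearman rho.

    Returns (table, rho, p_value); rho is None when it is undefined
    (constant charge or a single peptide), never coerced to 0.
    """
    rows = []
    for p in intensities:
        if p.peptide_id not in sequences:
            logger.info("dropping %s from charge table: no sequence", p.peptide_id)
            continue
        rows.append(
            {
                "peptide_id": p.peptide_id,
                "normalized": p.normalized,
                "net_charge": peptide_net_charge(sequences[p.peptide_id], rules),
                "decile": p.decile,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no peptides with sequences available")
    df = df.sort_values("normalized", ascending=False).reset_index(drop=True)
    df.insert(1, "rank", df.index + 1)
    if len(df) < 2 or df["net_charge"].nunique() < 2 or df["normalized"].nunique() < 2:
        return df, None, None
    rho, pval = stats.spearmanr(df["normalized"], df["net_charge"])
    return df, float(rho), float(pval)


def substitution_log2(
    panel_values: Mapping[tuple[int, str, str], float],
    wt_reference_value: float,
) -> list[SubstitutionEntry]:
    """log2(mutant / WT reference) for a substitution panel.

    ``panel_values`` maps (position, wt residue, mutant residue) to the
    mutant peptide's intensity.  Zero intensities (undetected spots) are
    floored at half the smallest positive observed value so the log stays
    finite.
    """
    if wt_reference_value <= 0:
        raise ValueError("WT reference value must be > 0")
    positive = [v for v in panel_values.values() if v > 0]
    floor = 0.5 * min(positive) if positive else 0.5 * wt_reference_value
    out = []
    for (pos, wt, mut), value in sorted(panel_values.items()):
        if value < 0:
            raise ValueError(f"negative panel value at position {pos} ({wt}->{mut})")
        out.append(
            SubstitutionEntry(
                position=pos,
                wt=wt,
                mutant=mut,
                log2_ratio=float(np.log2(max(value, floor) / wt_reference_value)),
                wt_reference=wt_reference_value,
            )
        )
    return out
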