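"""Charge block detection from windowed NCPR profiles.

A charge block is a maximal run of same-sign NCPR windows (10 residues by
default) in which at least one window reaches the signed threshold
(|NCPR| >= 0.5 by default).  Zero-valued windows terminate runs under the
strict reading of "windows sharing a positive NCPR" (the only reading that
keeps positive and negative runs disjoint); a permissive mode that lets
zero windows join same-sign runs is available for sensitivity analysis.

Residue coordinates are reported 1-based inclusive as the union of the
member windows, matching the "a.a. 315-317" convention used for point
mutants; a BED6 export (0-based half-open) is provided for genome-browser
style tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .charge_model import ChargeRules, DEFAULT_RULES, NCPRProfile, ProteinSequence, ncpr_profile


@dataclass(frozen=True)
class ChargeBlock:
    seq_id: str
    sign: str  # "+" or "-"
    window_start_first: int
    window_start_last: int
    residue_start: int
    residue_end: int
    peak_ncpr: float

    @property
    def n_windows(self) -> int:
        return self.window_start_last - self.window_start_first + 1

    def contains(self, start: int, end: int) -> bool:
        return self.residue_start <= start and end <= self.residue_end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(end, self.residue_end) - max(start, self.residue_start) + 1)


def _runs(values: Sequence[float], zero_breaks_run: bool) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs as (sign, first_index, last_index), 0-based.

    With ``zero_breaks_run=False``, zero windows flanked by same-sign runs
    act as joiners (they still contribute no peak).
    """
    signs = [0 if v == 0 else (1 if v > 0 else -1) for v in values]
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < len(signs):
        if signs[i] == 0:
            i += 1
            continue
        s, start = signs[i], i
        j = i
        while j + 1 < len(signs):
            nxt = signs[j + 1]
            if nxt == s:
                j += 1
            elif nxt == 0 and not zero_breaks_run:
                # look past the zero gap: join only if the next nonzero sign matches
                k = j + 1
                while k < len(signs) and signs[k] == 0:
                    k += 1
                if k < len(signs) and signs[k] == s:
                    j = k
                else:
                    break
            else:
                break
        runs.append((s, start, j))
        i = j + 1
    return runs


def detect_blocks(
    seq: ProteinSequence,
    window: int = 10,
    threshold: float = 0.5,
    apply_phospho: bool = False,
    rules: ChargeRules = DEFAULT_RULES,
    zero_breaks_run: bool = True,
) -> list[ChargeBlock]:
    """Detect positive and negative charge blocks from the NCPR profile.

    A run of strictly-positive windows is emitted iff its maximum NCPR
    reaches ``threshold``; a run of strictly-negative windows iff its
    minimum reaches ``-threshold``.  The residue span of a block is the
    union of its member windows.  Output is deterministic and sorted by
    residue start.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    profile = ncpr_profile(seq, window=window, apply_phospho=apply_phospho, rules=rules)
    blocks: list[ChargeBlock] = []
    for sign, i0, i1 in _runs(profile.values, zero_breaks_run):
        member = profile.values[i0:i1 + 1]
        peak = max(member) if sign > 0 else min(member)
        if sign > 0 and peak < threshold:
            continue
        if sign < 0 and peak > -threshold:
            continue
        blocks.append(
            ChargeBlock(
                seq_id=seq.id,
                sign="+" if sign > 0 else "-",
                window_start_first=i0 + 1,
                window_start_last=i1 + 1,
                residue_start=i0 + 1,
                residue_end=i1 + 1 + window - 1,
                peak_ncpr=float(peak),
            )
        )
    blocks.sort(key=lambda b: (b.residue_start, b.sign))
    return blocks


def block_overlap_report(
    blocks: Sequence[ChargeBlock],
    annotations: Iterable[tuple[str, int, int]],
) -> list[dict]:
    """Containment/overlap of annotated intervals against detected blocks.

    For each annotation (name, start, end), report the best-overlapping
    block (if any), whether it fully contains the interval, and the overlap
    length in residues.
    """
    rows = []
    for name, start, end in annotations:
        if start > end:
            raise ValueError(f"malformed interval {name!r}: start {start} > end {end}")
        best, best_ov = None, 0
        for b in blocks:
            ov = b.overlap(start, end)
            if ov > best_ov:
                best, best_ov = b, ov
        rows.append(
            {
                "annotation": name,
                "start": start,
                "end": end,
                "block": None if best is None else
                f"{best.seq_id}:{best.sign}:{best.residue_start}-{best.residue_end}",
                "contained": bool(best is not None and best.contains(start, end)),
                "overlap": best_ov,
            }
        )
    return rows


def blocks_to_bed6(blocks: Sequence[ChargeBlock]) -> str:
    """BED6 text (0-based half-open); score = 1000*|peak NCPR| capped at 1000."""
    lines = []
    for b in blocks:
        score = min(1000, int(round(1000 * abs(b.peak_ncpr))))
        lines.append(
            f"{b.seq_id}\t{b.residue_start - 1}\t{b.residue_end}\t{b.sign}\t{score}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
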