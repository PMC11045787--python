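"""File-format plumbing: FASTA records, phosphosite/spot/library TSVs.

All tabular interfaces are plain TSV with headers; coordinates are 1-based
inclusive throughout, and every join between tables is keyed on
``peptide_id`` or ``seq_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .charge_model import ProteinSequence
from .library import Peptide
from .array_analysis import SpotRecord


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Multi-record FASTA; record id = first whitespace-delimited token."""
    records = [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_phosphosites(
    path: str | Path, timepoint: str | None = None
) -> dict[str, frozenset[int]]:
    """Phosphosite TSV (seq_id, position, optional timepoint) -> sites per id."""
    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "position"}
    if not required <= set(df.columns):
        raise ValueError(f"phosphosite TSV {path} must have columns {sorted(required)}")
    if timepoint is not None:
        if "timepoint" not in df.columns:
            raise ValueError(f"phosphosite TSV {path} has no 'timepoint' column")
        df = df[df["timepoint"] == timepoint]
    return {
        seq_id: frozenset(int(p) for p in grp["position"])
        for seq_id, grp in df.groupby("seq_id")
    }


def write_library_tsv(peptides: Sequence[Peptide], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "peptide_id": p.peptide_id,
                "parent_id": p.parent_id,
                "category": p.category,
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "acetylated": p.acetylated,
                "provenance": p.provenance,
            }
            for p in peptides
        ]
    ).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[Peptide]:
    df = pd.read_csv(path, sep="\t")
    peptides = []
    for row in df.itertuples(index=False):
        peptides.append(
            Peptide(
                peptide_id=str(row.peptide_id),
                parent_id=str(row.parent_id),
                sequence=str(row.sequence),
                category=str(row.category),
                start=None if pd.isna(row.start) else int(row.start),
                end=None if pd.isna(row.end) else int(row.end),
                acetylated=bool(row.acetylated),
                provenance="" if pd.isna(row.provenance) else str(row.provenance),
            )
        )
    return peptides


def write_spots_tsv(spots: Sequence[SpotRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "peptide_id": s.peptide_id,
                "replicate": s.replicate,
                "intensity": s.raw_intensity,
                "excluded": s.excluded,
                "reason": s.reason,
            }
            for s in spots
        ]
    ).to_csv(path, sep="\t", index=False)


def read_spots_tsv(path: str | Path) -> list[SpotRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "replicate", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"spot TSV {path} must have columns {sorted(required)}")
    spots = []
    for row in df.itertuples(index=False):
        excluded = bool(getattr(row, "excluded", False))
        reason = getattr(row, "reason", "")
        spots.append(
            SpotRecord(
                peptide_id=str(row.peptide_id),
                replicate=int(row.replicate),
                raw_intensity=float(row.intensity),
                excluded=excluded,
                reason="" if pd.isna(reason) else str(reason),
            )
        )
    if not spots:
        raise ValueError(f"spot TSV {path} is empty")
    return spots


def read_codon_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Codon TSV (amino_acid, codon, frequency) -> nested dict by amino acid."""
    df = pd.read_csv(path, sep="\t")
    required = {"amino_acid", "codon", "frequency"}
    if not required <= set(df.columns):
        raise ValueError(f"codon TSV {path} must have columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.amino_acid), {})[str(row.codon)] = float(row.frequency)
    return out
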