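"""End-to-end orchestration: charge survey and array pipeline with manifests.

Each run writes its TSV outputs into an output directory together with a
``manifest.json`` recording the configuration, every seed used, and a
SHA-256 hash of every output file, so a run can be replayed and verified
byte-for-byte.  Stochastic stages require explicit seeds; there is no
silent clock seeding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as csio
from .blocks import detect_blocks
from .charge_model import ProteinSequence, ncpr_profile
from .clustering import batch_iwd, percentile_rank, resolve_class
from .array_analysis import (
    aggregate,
    charge_binding_table,
    enrichment_table,
    top_fraction,
)

logger = logging.getLogger("chargescan")


@dataclass
class RunConfig:
    output_dir: Path
    fasta: Path | None = None
    phospho: Path | None = None
    timepoint: str | None = None
    library: Path | None = None
    spots: Path | None = None
    window: int = 10
    block_threshold: float = 0.5
    residue_class: str = "positive"
    n_shuffles: int = 10_000
    seed: int = 0
    top_fraction: float = 0.10
    n_convention: str = "combined"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for attr in ("fasta", "phospho", "library", "spots"):
            p = getattr(self, attr)
            if p is not None:
                p = Path(p)
                setattr(self, attr, p)
                if not p.exists():
                    raise FileNotFoundError(f"{attr} file {p} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: dict, outputs: Sequence[Path]) -> Path:
    manifest = {
        "config": config,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True) + "\n")
    return path


def run_charge_survey(config: RunConfig) -> dict[str, Path]:
    """NCPR profiles, charge blocks, per-record IWD Z-scores, percentile report."""
    if config.fasta is None:
        raise ValueError("charge survey requires a FASTA input")
    records = csio.read_fasta(config.fasta)
    phospho = (
        csio.read_phosphosites(config.phospho, config.timepoint)
        if config.phospho
        else {}
    )
    if phospho:
        records = [
            ProteinSequence(r.id, r.residues, phospho.get(r.id, frozenset()))
            for r in records
        ]
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    apply_phospho = bool(phospho)

    profile_rows, block_rows = [], []
    for rec in records:
        if len(rec) < config.window:
            logger.info("skipping %s: shorter than window %d", rec.id, config.window)
            continue
        prof = ncpr_profile(rec, window=config.window, apply_phospho=apply_phospho)
        for start, v in zip(prof.starts, prof.values):
            profile_rows.append(
                {"seq_id": rec.id, "start": start,
                 "end": start + config.window - 1, "ncpr": v}
            )
        for b in detect_blocks(
            rec, window=config.window, threshold=config.block_threshold,
            apply_phospho=apply_phospho,
        ):
            block_rows.append(
                {"seq_id": b.seq_id, "sign": b.sign,
                 "residue_start": b.residue_start, "residue_end": b.residue_end,
                 "peak_ncpr": b.peak_ncpr, "n_windows": b.n_windows}
            )
    profile_path = outdir / "ncpr_profile.tsv"
    pd.DataFrame(profile_rows).to_csv(profile_path, sep="\t", index=False)
    blocks_path = outdir / "charge_blocks.tsv"
    pd.DataFrame(
        block_rows,
        columns=["seq_id", "sign", "residue_start", "residue_end",
                 "peak_ncpr", "n_windows"],
    ).to_csv(blocks_path, sep="\t", index=False)

    cls = resolve_class(config.residue_class)
    results = batch_iwd(records, cls, n_shuffles=config.n_shuffles, seed=config.seed)
    iwd_path = outdir / "iwd_zscores.tsv"
    pd.DataFrame(
        [
            {"seq_id": r.seq_id, "class": r.class_name, "n_residues": r.n_residues,
             "iwd_obs": r.iwd_obs, "null_mean": r.null_mean, "null_sd": r.null_sd,
             "z": r.z, "p_empirical": r.p_empirical, "significant": r.significant}
            for r in results
        ],
        columns=["seq_id", "class", "n_residues", "iwd_obs", "null_mean",
                 "null_sd", "z", "p_empirical", "significant"],
    ).to_csv(iwd_path, sep="\t", index=False)

    rank_path = outdir / "percentile_rank.tsv"
    rank_rows = []
    if len(results) >= 2:
        for r in results:
            rank_rows.append(
                {"seq_id": r.seq_id, "z": r.z,
                 "percentile": percentile_rank(r.seq_id, results)}
            )
    pd.DataFrame(rank_rows, columns=["seq_id", "z", "percentile"]).to_csv(
        rank_path, sep="\t", index=False
    )

    outputs = [profile_path, blocks_path, iwd_path, rank_path]
    _write_manifest(outdir, vars(config), outputs)
    return {p.stem: p for p in outputs}


def run_array_pipeline(config: RunConfig) -> dict[str, Path]:
    """Aggregation, top-fraction enrichment and charge correlation for one array."""
    if config.library is None or config.spots is None:
        raise ValueError("array pipeline requires library and spot TSVs")
    peptides = csio.read_library_tsv(config.library)
    spots = csio.read_spots_tsv(config.spots)
    lib_ids = {p.peptide_id for p in peptides}
    orphan = sorted({s.peptide_id for s in spots} - lib_ids)
    if orphan:
        logger.warning("spot peptide_ids missing from library: %s", ", ".join(orphan))

    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    intensities = aggregate(spots)
    intens_path = outdir / "intensities.tsv"
    pd.DataFrame([vars(i) for i in intensities]).to_csv(
        intens_path, sep="\t", index=False
    )

    seqs = {p.peptide_id: p.sequence for p in peptides}
    mapping_ids = {p.peptide_id for p in peptides if p.category == "mapping"}
    mapping_intens = [i for i in intensities if i.peptide_id in mapping_ids]
    if not mapping_intens:
        logger.warning("no mapping peptides in library; using all categories")
        mapping_intens = [i for i in intensities if i.peptide_id in seqs]

    top = top_fraction(mapping_intens, fraction=config.top_fraction)
    top_path = outdir / "top_peptides.tsv"
    pd.DataFrame([vars(i) for i in top]).to_csv(top_path, sep="\t", index=False)

    enrich = enrichment_table(
        [seqs[i.peptide_id] for i in top],
        [seqs[i.peptide_id] for i in mapping_intens],
        n_convention=config.n_convention,
    )
    enrich_path = outdir / "enrichment.tsv"
    enrich.to_csv(enrich_path, sep="\t", index=False)

    table, rho, pval = charge_binding_table(mapping_intens, seqs)
    corr_path = outdir / "charge_binding.tsv"
    table.to_csv(corr_path, sep="\t", index=False)
    stats_path = outdir / "charge_binding_stats.tsv"
    pd.DataFrame(
        [{"spearman_rho": rho, "p_value": pval, "n_peptides": len(table)}]
    ).to_csv(stats_path, sep="\t", index=False)

    outputs = [intens_path, top_path, enrich_path, corr_path, stats_path]
    _write_manifest(outdir, vars(config), outputs)
    return {p.stem: p for p in outputs}
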