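# chargescan

Charge-patterning and peptide-microarray analysis for intrinsically
disordered proteins (IDRs), built around the kind of study that maps where a
folded partner binds along a large disordered protein — such as the
*Neurospora crassa* clock protein FRQ and its helicase partner FRH — using
printed synthetic peptide arrays plus sequence-level charge statistics.

It is aimed at protein biochemists and computational biologists who have
(a) protein sequences and want charge profiles, charge-block calls, and
residue-clustering significance, and/or (b) extracted peptide-array spot
intensities and want replicate aggregation, top-binder composition
statistics, charge–binding correlation, and substitution matrices.

## What it computes

**Charge model (pH 7.0, sidechain-only).** D/E = −1, R/K = +1,
H = +0.091 (its Henderson–Hasselbalch protonated fraction with sidechain
pKa 6.0), all other residues 0; each phosphosite adds −2. Net charge per
residue (NCPR) is the mean charge over a 10-residue sliding window;
hydropathy is the Kyte–Doolittle mean over a centered 5-residue window.

**Charge blocks.** Maximal runs of same-sign NCPR windows in which at least
one window reaches |NCPR| ≥ 0.5, reported as 1-based residue intervals.

**Residue clustering.** The inverse-weighted distance of a residue class
with position set *S*,

```
IWD(S) = (1 / N_pairs) * Σ_{i<j} 1 / (S_j − S_i),
```

normalised to a Z-score against a null of 10,000 full shuffles of the same
sequence; Z > 1.96 is called significant positive clustering. Batch mode
surveys whole ortholog sets or proteomes and ranks a target by the percent
of proteins with a strictly greater Z ("top X%").

**Peptide library design.** 15-mer mapping scans shifting by 3 residues
(finer 1-shift scans for regions of interest), composition-preserving
scrambles, truncation ladders, single-position substitution panels, and
N-terminal acetylation metadata (only the parent's N-terminal peptide is
unacetylated). A codon utility computes relative adaptiveness (each codon
scaled to its most-used synonymous codon = 100%) for rank-matched mutant
design.

**Array statistics.** Triplicate spot intensities are averaged (excluded
spots dropped, undetected spots read 0), scaled to the array maximum, and
binned into deciles. Composition enrichment in the top decile is tested with
the one-proportion statistic

```
z = (p̂ − p₀) / sqrt(p₀ (1 − p₀) / n),
```

charge–binding association is the Spearman correlation between normalised
intensity and peptide net charge, and substitution panels are reported as
log2(mutant / wild-type reference) with a positive floor for zero spots.

**Synthetic data.** Seeded generators produce sequences with planted
positive charge blocks, mutated "ortholog" sets, and spot intensities from a
charge-plus-motif binding model, so the entire pipeline is testable with no
external downloads.

## Worked example

```python
import chargescan as cs

# the 15-mer spanning FRQ's KKK charge block next to its kinase-binding motif
cs.peptide_net_charge("MTDKEKKKLVVRRLE")   # -> 3.0

gen = cs.synthetic_frq()                   # 989-residue synthetic FRQ stand-in
blocks = cs.detect_blocks(gen.sequence)    # 10-mer windows, |NCPR| >= 0.5
res = cs.iwd_zscore(gen.sequence, cs.POSITIVE, n_shuffles=10_000, seed=1)
print(f"blocks: {len(blocks)}, z = {res.z:.2f}, significant: {res.significant}")
```

printed with this build:

```
net charge: 3.0
n blocks: 7
  + 289-313 peak +0.50
  + 307-326 peak +0.50
  - 342-363 peak -0.50
  - 359-390 peak -0.50
IWD obs 0.0154 null 0.0131 +/- 0.0005 z 4.98 significant True
```

+3.0 is the peptide's sidechain net charge (3 net positive elementary
charges); the block list gives 1-based residue intervals whose peak window
reaches the ±0.5 NCPR threshold; and z = 4.98 means the positive residues of
this sequence are far more clustered than in 10,000 random shuffles of
itself (z > 1.96 ⇒ significant at p < 0.05). `synthetic_frq` is a labelled
synthetic stand-in — conclusions about the real protein require the real
accession (NCU02265).

The same analyses run from the shell:

```
chargescan profile --fasta seqs.fasta --window 10
chargescan blocks  --fasta seqs.fasta
chargescan iwd     --fasta seqs.fasta --residue-class positive --shuffles 10000 --seed 1
chargescan library map --fasta seqs.fasta --out library.tsv
chargescan simulate array --library library.tsv --seed 3 --out spots.tsv
chargescan array enrich --spots spots.tsv --library library.tsv
chargescan survey  --fasta seqs.fasta --out-dir run1 --seed 1
```

`survey` and `array-pipeline` write TSV outputs plus a `manifest.json` of
SHA-256 hashes so a run can be replayed and verified byte-for-byte.

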