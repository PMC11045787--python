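# Methods

## Charge model

All charge arithmetic uses a fixed pH 7.0 sidechain table: D/E −1, R/K +1,
H +0.091, all other residues 0. The histidine value is the
Henderson–Hasselbalch protonated fraction at pH 7.0 with a sidechain pKa of
6.0 (1/(1+10^(7−6)) = 1/11 ≈ 0.091) and is exposed as a configurable
parameter (`ChargeRules.histidine_charge`), since some NCPR conventions
treat histidine as neutral; one `ChargeRules` table is used everywhere by
default so peptide net charge and NCPR profiles are mutually consistent.
Terminal α-amino/α-carboxyl charges are never counted: array peptides are
N-terminally acetylated to mimic an internal protein segment, and the
sidechain-only convention is the one that reproduces the printed worked
example (MTDKEKKKLVVRRLE → +3). There is no pKa titration across pH and no
isoelectric-point machinery; the fixed table is the contract.

Phosphorylation adds a flat −2 per site (phosphate dianion at neutral pH),
applied at most once per position. Sites on non-S/T/Y residues are accepted
with a logged warning rather than rejected, because published phosphosite
lists occasionally carry ambiguous assignments. Non-standard residue codes
(B, Z, X, U, \*) are rejected outright: coercing them to zero charge would
silently bias NCPR.

NCPR uses a 10-residue window anchored at the window *start* (1-based).
Anchoring rather than centering avoids a half-window convention for an
even window; the block detector consumes window-level values directly, so
no centering is needed anywhere. Hydropathy uses the Kyte–Doolittle scale
over an odd, centered window (default 5), defined only for positions with a
full window.

## Charge blocks

Blocks are maximal runs of strictly same-sign NCPR windows; a positive run
is emitted iff its maximum window NCPR ≥ 0.5, a negative run iff its
minimum ≤ −0.5, and the residue span is the union of member windows
(1-based inclusive). Zero-valued windows terminate runs by default —
"sharing a positive NCPR" is read strictly as NCPR > 0, the only reading
under which positive and negative runs are disjoint — but a permissive
`zero_breaks_run=False` mode lets zero windows join flanking same-sign runs
for sensitivity analysis. Note that two same-sign runs separated by fewer
non-qualifying windows than the window width can overlap in *residue* span
(each span extends window−1 residues past its last anchor) even though
their window anchors never overlap; spans are reported as constructed, not
trimmed. Detection is fully deterministic. A BED6 export (0-based
half-open, score = 1000·|peak NCPR| capped) is provided for browser-style
tooling; the TSV is the canonical 1-based output.

## Clustering statistic and null

IWD(S) = (1/N_pairs) Σ_{i<j} 1/(S_j − S_i) over the 1-based positions of a
residue class (built-ins: positive {R,K}, negative {D,E}, aromatic {Y,F,W};
arbitrary classes via `custom:<letters>`). IWD is undefined for fewer than
two class members. Because the statistic depends on sequence length and
class count, observed values are normalised against a null of 10,000 full
uniform shuffles of the sequence (seeded generator; the membership mask is
put into a canonical sorted arrangement before shuffling, so the null is
bit-for-bit a function of composition, length, shuffle count and seed
only). Z = (obs − null mean)/null sd; Z > 1.96 is flagged as significant
positive clustering, the normal-approximation analogue of two-sided
p < 0.05, and the add-one empirical two-sided p from the draws is reported
alongside so users can prefer either convention. The mathematically
equivalent shortcut — sampling class positions uniformly without
replacement — is used only as an independent test oracle, never in the main
path.

Batch surveys derive a per-record seed as SHA-256(master seed, record id)
mod 2³¹, so adding or reordering records never perturbs existing results;
records whose class is degenerate (fewer than 2 members, or the whole
sequence) are skipped with a log line rather than failing the survey.
Percentile ranking reports 100 · (#results with z strictly greater)/total,
so "top 0%" means no protein scored higher. Kappa and sequence-charge-
decoration style patterning parameters are deliberately out of scope; IWD
and blockiness measure clustering, not the evenness of charge mixing.

## Peptide library design

Mapping scans are 15-mers shifting by 3 residues, starting at position 1
and continuing while a full window fits; `cover_terminus` (default off, so
peptide counts follow the plain shift grid) appends one C-terminally
anchored peptide when trailing residues would otherwise be uncovered. Only
the start-1 peptide is unacetylated. Fine scans shift by 1; regions of
interest shorter than the peptide length are extended symmetrically into
the parent (clamped at termini) so every library member is a full-length
peptide. Scrambles preserve composition (hence net charge) and are drawn by
seeded rejection sampling with a 1000-attempt cap per scramble — a
deterministic failure beats silent duplicates. Every peptide records a
provenance string sufficient to regenerate its sequence bit-for-bit.

Relative adaptiveness scales each codon's usage frequency to the most-used
synonymous codon (= 100%, ties all score 100). It is a standalone ranking
utility: choosing a rank-matched codon for a designed mutation involves
judgment and is left to the user.

## Array statistics

Aggregation takes the mean of non-excluded replicates (triplicate spotting
is the default layout; undetected spots are recorded as 0, not excluded),
drops peptides with no usable replicate, scales means by the array maximum
(so normalisation is idempotent), and assigns deciles 1–10 on the
normalised rank. The top fraction (default 10%) takes the k = ⌊fraction·n⌋
largest normalised values and includes *all* peptides tied at the boundary,
so membership never depends on sort stability; fewer than 1/fraction
peptides yields the single top peptide with a warning.

Composition enrichment uses z = (p̂ − p₀)/√(p₀(1−p₀)/n) with residue
classes acidic {D,E}, basic {R,K}, polar {H,C,N,Q,S}, aromatic {Y,F,W},
nonpolar {G,A,V,I,L,M,P}, and a two-tailed normal p. The default n is the
combined residue count of background plus top sets; the standard
one-proportion convention (n = top-set count) is available via
`n_convention="top_only"`, because the combined convention — while the
package default — is statistically unusual and users should be able to
compare. Units whose background proportion is 0 or 1 are rejected (zero
variance).

Charge–binding association is the Spearman rank correlation between
normalised intensity and sidechain net charge; an undefined correlation
(constant charge, a single peptide) is reported as missing, never coerced
to 0. Substitution panels report log2(value/WT reference); zero intensities
are floored at half the smallest positive observed value so undetected
spots stay finite, and the WT reference is user input (it is an average of
replicate wild-type spots on a given array, not a constant of the method).
Image-domain processing (spot finding, background subtraction,
segmentation) is upstream of this package, which starts at extracted
intensities; binding constants are not estimated.

## Synthetic data generator

Sequences are drawn i.i.d. from a disorder-like background composition
(serine/proline/charge rich, aromatics and cysteine rare; R+K ≈ 12%), with
`n_blocks` non-overlapping planted intervals inside which the R/K
probability is multiplied by `block_enrichment` and renormalised. Defaults
(length 500, 3 blocks of 10, enrichment 5) give sequences whose positive
clustering is detectable but not caricatured; recovery tests that need
near-certain detection raise the enrichment to 25. "Ortholog" sets mutate
each position independently at a given rate, optionally preserving the
charge class of residues inside planted blocks — emulating the empirical
pattern that charge clustering survives sequence divergence in ortholog
families.

Spot intensities follow expected = base + slope·max(0, net charge) +
bonus·[motif present], with defaults base 100, slope 50 density units per
elementary charge, motif bonus 400, lognormal multiplicative noise
(σ = 0.4), 2% dropout to zero, and triplicate replicates. Binding responds
to max(0, charge), not raw charge, because the emulated partner surface is
negatively charged: positive peptides bind more, negative peptides do not
bind "negatively". Lognormal noise reflects positive, right-skewed
chemiluminescent densities. The generator does not emulate image-domain
artifacts (bleed, merged spots), spatial spot layout, saturation, or
sequence-composition effects on synthesis efficiency — so passing
end-to-end tests demonstrates correct statistical machinery under the
stated model, not robustness to real-array artifacts.

`synthetic_frq` is a clearly labelled synthetic stand-in for the 989-residue
clock protein FRQ: background composition, six planted positive blocks of
12 residues (enrichment 8), and the two genuine FRQ peptides printed in the
primary literature spliced in at their true coordinates (a.a. 310–324 and
771–785, carrying the KKK 315–317 and RR 783–784 features). It supports
full-scale demonstrations and tests where downloading the real accession is
impractical; it is not the real protein, and analyses of real FRQ must use
accession NCU02265.

## Numerical and design choices

* Shuffle nulls and all generators use `numpy.random.default_rng` with
  explicit integer seeds; pipelines refuse to run stochastic stages without
  a seed, and run manifests record seeds and SHA-256 hashes of every output
  so reruns can be verified byte-for-byte.
* Test problem sizes are chosen to make Monte-Carlo assertions sharp but
  cheap: null calibration uses 1000 sequences of length 100 with 500
  shuffles each; end-to-end enrichment uses 20 seeds of a 300-residue
  parent; the full-scale clustering demonstration uses the complete
  10,000-shuffle null at length 989.
* The empirical type-I rate of the |z| > 1.96 call sits near 4–5% at 500
  shuffles (slightly below nominal because the IWD null is right-skewed);
  the 1.96 threshold is retained as the field-standard convention rather
  than recalibrated.
* Floating-point policy: IWD is exact to 1e−12 against a brute-force pair
  loop; the enrichment z is exact to 1e−12 against a symbol-by-symbol
  oracle; everything else is asserted at Monte-Carlo-appropriate
  tolerances.

## Known limitations

* The pH 7.0 table cannot represent context-dependent pKa shifts; His
  charge is a global constant, not site-specific.
* Block span construction can let same-sign blocks overlap in residue span
  across short gaps (see above); consumers needing disjoint intervals
  should merge or trim to window anchors.
* The combined-n enrichment convention inflates n relative to the standard
  one-proportion test, making |z| larger for the same proportions; compare
  conventions before interpreting borderline calls.
* The generator's binding model is linear in positive charge with a single
  additive motif term; cooperative, multivalent, or conformation-dependent
  binding is out of scope.
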