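# Methods

This note documents the models, conventions and numerical choices behind
`repeat_regprof`, and what the synthetic fixtures do and do not show.

## Coordinates and input contracts

All internal coordinates are 0-based half-open (`[start, end)`,
BED-native); every reader normalises to this convention on input.
Consensus positions of repeat copies stay 1-based inclusive, exactly as
RepeatMasker reports them.  For the UCSC rmsk dialect, plus-strand rows
take the consensus span from repStart..repEnd; minus-strand rows store
their consensus start in repLeft, so the reader maps consensus_start :=
repLeft, consensus_end := repEnd.  The simplified TSV dialect carries
explicit consensus_start/consensus_end columns and avoids the question.
Records on alternate/patch/unplaced sequences (`*_alt`, `*_random`,
`*_fix`, `chrUn*` under UCSC naming) are excluded before any analysis.

## Interval semantics

The engine pins down three rules that textual descriptions leave
ambiguous, and each is verified exactly against a per-base brute-force
oracle on hundreds of random instances:

* **Fractional overlap** is evaluated against each single target
  interval — a site overlapping two elements 30% each matches neither at
  f = 0.5.  The rule is `overlap_bp >= f * len(query)` (ties count).
* **Windowed joins** extend the anchor by w bp on both sides (clamped at
  0) under half-open arithmetic, so a gap of exactly w does *not* join.
  "Within 500 bp" therefore means gap < 500.
* **Merging** unites maximal chains of *strictly* overlapping intervals
  to their most distal coordinates; bookended intervals stay separate
  (the covered base set is identical either way).  Same-TF merging is
  applied before co-localisation counting so each TF's totals count
  non-redundant sites.

All outputs are sorted (chromosome lexicographic, then start) so CLI
output is byte-stable.

## Meta-profiles

A window of `window_width` (default 20 kb) is centred on the element
midpoint `floor((start+end)/2)` and divided into `profile_bin` (100 bp)
bins.  Elements longer than the window are rejected; windows running off
a chromosome edge are flagged and excluded from averages.  Per element,
bin counts (a site spanning k bins increments k bins) are divided by
their per-window sum, so every included per-element profile sums to
exactly 1 and the average over elements does too.  Normalising by the
bin-count sum rather than the raw site count makes the unit-sum property
hold even when sites straddle bin boundaries; the two denominators agree
whenever no site crosses a bin edge.  Elements with zero sites in the
window are excluded (profiles describe elements containing at least one
site).  Minus-strand windows are reversed so bin 0 is 5'-most; an
unoriented mode is available for genomic-orientation profiles.

Epigenetic profiles use the same grid.  Aligned reads are point-like at
100 bp resolution, so each read increments exactly the bin holding its
midpoint — no double counting, at the cost of ignoring fragment extent.
Counts convert to RPKM = reads × 1e9 / (bin_width × library_size);
replicates are averaged *before* the input control is subtracted
("normalised RPKM", which may legitimately go negative), and group
averages (TF-bound vs unbound elements) are taken last.

## Co-localisation statistics

Proportions are asymmetric by construction (each TF's own site total is
the denominator), mirroring how a low-abundance factor can co-localise
with nearly all of a high-abundance factor's sites but not vice versa.
Element-derived versus rest-of-genome proportions are compared per
ordered TF pair with the pooled two-proportion z statistic

    z = (k1/n1 − k2/n2) / sqrt(phat (1 − phat) (1/n1 + 1/n2)),
    phat = (k1 + k2)/(n1 + n2),

one-tailed for element excess (p = 1 − Φ(z)); the sign of z is kept so
depletion shows as z < 0.  No continuity correction is applied — site
counts are large in intended use, and the omission is documented because
it makes the upper tail slightly anti-conservative at small n (visible
as a per-cell false-positive rate of ~1% at the 6.2e-4 threshold in the
familywise simulations, still far inside the α = 0.05 familywise
budget).  Degenerate pooled proportions (0 or 1) return z = 0, p = 0.5
and are logged.  Bonferroni control uses α/k² — the denominator counts
ordered pairs including the untested self-pairs, matching the published
arithmetic 0.05/9² ≈ 6.2e-4 for nine factors.  Exported significance
stars: `*` below α/k², `**` below 1e-4, `***` below 1e-5.

## Consensus projection

For a site midpoint m inside an element with consensus start c:
position = c + (m − start) on plus-strand copies and
c + (end − 1 − m) on minus-strand copies, clipped at 1 (RepeatMasker
annotations occasionally drift).  The mapping is invertible and the
round-trip is property-tested on both strands.  Motif hits are projected
from oriented element sequences, where offset d from the sequence start
maps directly to c + d.

## TSS classification and the rotation null

Transcript classes use strict fold-change thresholds (up: fc > 2, down:
fc < 0.5; fc exactly at a threshold is unchanged), with an optional
p < 0.05 filter.  The TSS is the strand-aware transcript start (start on
+, end − 1 on −), and TSS-in-element overlap needs only that single base
inside the element (no fraction rule for a point).

The null for TSS-in-element counts is a circular rotation: each
permutation draws one uniform offset per chromosome and shifts every TSS
on that chromosome by it, modulo the chromosome length, with elements
fixed.  This preserves per-chromosome TSS counts and all intra-
chromosomal spacings — the defining property of rotation nulls — while
randomising placement relative to elements.  A single-offset mode
(one offset applied to every chromosome) is available as an option.
The expected probability is the mean rotated overlap count divided by
the TSS total; with uniform TSSs it converges to the element coverage
fraction.  Significance is an exact one-sided binomial tail in the
observed direction: P(X ≥ obs) when enriched, P(X ≤ obs) when depleted,
X ~ Binomial(n_tss, expected_p).  Calibration simulations (200
replicates, 1,000 rotations each — a deliberate scale-down from the
10,000-rotation default to keep the suite fast; the estimate's Monte
Carlo error enters only through expected_p and is negligible at these
sizes) show the fixed-direction p-values approximately uniform with
type-I error at 0.05 inside its binomial interval.

Novel transcripts are associated with known ones when any exon pair
overlaps by ≥ 1 bp on the same chromosome *and strand* — the strand
match is the conservative codification of an otherwise visual
comparison.

## Motif scanning

JASPAR count matrices become probabilities via
(count + pseudocount) / (column total + 4·pseudocount) with pseudocount
0.1 per cell (JASPAR matrices contain zeros), log2-odds against a
uniform background by default.  Scores are discretised at 1e-3 bits and
the exact null distribution of a background word's score is built by
convolving per-position score distributions; the discretisation bounds
the p-value error by width × 1e-3 bits, and the distribution matches
brute-force enumeration over all 4^w words for small widths to within
floating round-off.  Zero-probability letters get a finite log-odds
floor of −30 bits, which affects only tails below ~2⁻³⁰ per position.
The scan cutoff is the smallest discretised score whose tail is ≤ the
requested p (default 1e-4); scanning is on the provided strand only
(sequences are extracted strand-aware, so each element reads 5'→3'), and
windows containing N are skipped.  Logo count matrices (4 × width base
counts per populated histogram bin) are exported for external rendering.

## Synthetic fixtures

The generator emulates the statistical structure the analysis assumes,
not sequence realism: elements are placed uniformly without overlap on a
3 × 1 Mb toy genome (60 copies × 6 kb, 12% coverage; ~30% of copies are
5'-truncated with consensus_start > 1); TF sites follow a homogeneous
Poisson process per chromosome (100 sites/Mb/TF) — the simplest model
under which the null tests are analytic — with a ×2 density in each
element's 900 bp 5' subregion, matching a promoter-dense 5' UTR whose
binding frequency roughly doubles relative to flanks; pairwise coupling
plants, for each in-element site of one TF, a partner-TF site within
100 bp with probability 0.8; 40% of up-regulated TSSs are placed inside
elements (≈3.3× the coverage fraction — the planted excess must dominate
coverage for the recovery tests to be meaningful, and the genome-scale
excess this emulates is larger still); coverage reads pile onto bound
elements' 5' subregions over a uniform background, with input controls
carrying background only; sequences are i.i.d. uniform bases with a
strongly conserved 12-mer planted at 5'-offset 300 in 80% of elements.

The per-TF site density and coupling strength are deliberately higher
than genome-wide averages: at 3 Mb they reproduce the *counting regime*
(tens of in-element sites per TF) in which the genome-scale statistics
operate, which is what gives the z-test its power in recovery tests.
Every planted quantity is recorded in `truth.json` so closed-loop tests
can assert recovery.  What passing these tests does **not** show:
robustness to non-uniform background site density, mappability artefacts,
repeat-family cross-contamination, clustered (non-Poisson) binding, or
read-level noise — none of which the generator models.

## Determinism and output conventions

All randomness flows from explicit seeds through `numpy`'s Generator;
identical seeds give byte-identical fixture bundles and statistical
outputs.  Numeric TSV/JSON outputs are written at 6 significant digits.
Each CLI run writes a `manifest.json` with the config snapshot, SHA-256
digests of file inputs, the seed and the package version.

## Known limitations

The rotation null's single-offset mode draws one offset from the longest
chromosome and reduces it modulo each length, which is marginally
non-uniform when lengths differ; the per-chromosome mode (default) has
no such caveat.  The epigenome module ignores fragment length and
read strand.  The z-test's normal approximation is slightly
anti-conservative for element-site counts below ~20; the binomial and
motif machinery are exact.
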