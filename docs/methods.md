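# Methods

## 3C quantification model

The measured quantity for an anchor–test restriction-fragment pair is a PCR
band intensity from the 3C ligation library and one from a control-template
library (equimolar BAC/fosmid digest–ligation containing every possible
junction). The association frequency is the plain ratio `I_3C / I_ctrl`,
which cancels primer-pair amplification efficiency; no further rescaling is
applied by default (an optional per-profile max normalization exists for
cross-panel comparison). Template loading amounts are metadata only — the
ratio is between measured intensities. Replicate aggregation uses the
arithmetic mean and the *sample* SD (n−1 denominator), which at n = 2
assays per line is the conventional "mean ± SD of the two replicates".

Pooling control lines ("controls mean") averages over all constituent assay
values, not line means: with per-line sufficient statistics (mean, sd, n)
the pooled mean and sample SD are recovered exactly via
`SS = Σ[(nᵢ−1)sᵢ² + nᵢ(mᵢ−m̄)²]`, identical to pooling the raw replicates.

Degenerate inputs: a zero control band makes the ratio undefined; the
record is flagged and excluded (never treated as frequency 0). Fragments
with no usable measurement propagate as explicit gaps, never imputed —
3C primer coverage of a region is intrinsically partial.

Control-template uniformity is checked by the coefficient of variation of
control bands across primer pairs (sample SD / mean); the default failure
threshold of 0.5 is deliberately permissive, flagging only grossly uneven
templates.

## In-silico digestion

The shipped enzyme table is BglII = AGATCT (cut offset 1) and BamHI =
GGATCC (cut offset 1). Scanning is top-strand only (both motifs are
palindromic, so this is lossless) and greedy left-to-right for
non-overlapping occurrences — deterministic, and these hexamers cannot
self-overlap in practice. Fragments tile the region exactly; coordinates
are 0-based half-open (BED convention) internally and in BED I/O. A 3C
primer must fall entirely inside one fragment; a primer spanning a cut site
is rejected, and two primers sharing a fragment collapse to one axis entry
with a warning.

## Differential calling

Profiles are compared with a two-way fixed-effects ANOVA, factors group
(control vs case) × fragment, fitted on individual assay values (default;
a `units="lines"` option first averages replicate pairs per line — the
choice of error unit for a 2-line × 2-replicate control group is genuinely
open, and assays-as-observations matches the common Prism workflow). The
per-fragment post-test is the group-contrast t statistic using the pooled
residual mean square of the full model, two-sided, Bonferroni-multiplied by
the number of fragments on the anchor's axis (the family is the per-anchor
panel) and clipped at 1. A design with zero residual variance everywhere is
reported with an explicit flag (p = 0 where means differ, 1 where they do
not) rather than NaNs.

ROI categories: `unchanged` iff adjusted p > 0.05; otherwise `novel` when
the control mean is below ε·max and the case mean at or above it, `lost`
for the mirror image, else `increased`/`decreased` by the sign of
case − control. ε defaults to 5 % of the anchor profile's maximum mean —
a relative floor mimicking gel-band detectability, since "novel"/"lost" are
qualitative band-presence judgements; the boundary is inclusive on the
present side. Star codes follow the ladder 0.05/0.01/0.001/0.0001.
Fragment-to-element annotation uses the enclosing element, else the nearest
by midpoint with ties broken upstream; fragments outside the annotation
span are labeled `unannotated`, not dropped.

## Allele phasing and methylation

Qualitative calls mirror Sanger traces: a minor peak counts as present when
it reaches 20 % of the major peak; a single visible allele at every tested
SNP gives a monoallelic call with the haplotype string (alleles in genomic
order), any SNP with both alleles present gives biallelic, and a sample
homozygous at a tested SNP is uninformative. The quantitative path uses the
allele-A signal fraction with a monoallelic threshold θ = 0.8 — no exact
cutoff separating "predominantly monoallelic" from biallelic exists in
practice, so θ is configuration; 80/20 is a common mass-spectrometry
genotyping heuristic. Parental-origin labels are never computed — origin is
not identifiable from ligation products alone and may only be supplied as
user annotation.

Methylation classification partitions [0, 100] % per ICR with inclusive
normal-range bounds (ICR1 40–52 %, ICR2 39–50 %). Subtype inference maps
the four canonical defect patterns; any other combination (e.g. ICR2
hypermethylation) is `unclassified` rather than force-fitted.

## FISH geometry and statistics

Distances are 3D Euclidean on centroid coordinates already in µm — no
pixel/voxel scaling happens in the pipeline; spot detection is upstream.
Nuclei must have exactly 2 spots per channel; others are excluded and
counted in a QC report (no salvage). Green–red pairing selects the cheaper
of the two perfect matchings by summed distance, with exact ties keeping
index order; the choice is invariant under rigid motions of the nucleus.
Cis colocalization uses ≤ 0.35 µm and trans association ≤ 1 µm, both
boundary-inclusive. The doublet reference point for the trans distance is
the midpoint of its two spots (configurable to either spot channel — the
measurement convention between "the doublets" is otherwise ambiguous).

Cohort pooling has two modes because the two published conventions differ:
`pooled_counts` sums integer nucleus counts and recomputes percentages
(used for category percentages), while `mean_of_lines` averages per-line
rates unweighted (used for the control-mean allele colocalization rate).
Between-line statistics: unpaired two-sided t-test on allele-level cis
distances (the distance-level test; testing per-line percentages with a
t-test at k = 2 lines is not meaningful), Fisher's exact test per nucleus
category and on trans counts. A degenerate 2×2 table with a zero margin
reports p = 1 with a warning.

## Synthetic-data generator

The FISH generator emulates the data's *decision structure*, not nuclear
physics: allele midpoints sit in a 3 µm-radius sphere (plausible
lymphoblastoid scale); the second allele is placed within the 1 µm trans
cutoff with probability p_trans, else at 1.2–3.2 µm; each allele is
colocalized with probability p_cis, drawing its green–red separation from
|N(0, 0.15 µm)| capped at 0.35 µm, else uniform in 0.5–2.0 µm. Capping at
the cutoff makes p_cis identifiable as the expected colocalization rate.
What it does not emulate: chromatic shift, detection noise, missing/extra
spots, z-anisotropy, or chromatin polymer behaviour — so passing recovery
tests shows the classification logic is correct, not that real microscopy
bias is handled. One realism *does* carry over: minimum-distance pairing
can cross alleles when doublets interleave, giving a small (~1 pp)
downward bias of the recovered colocalization rate; the recovery tolerance
(3 binomial SEs) accommodates it.

Presets: `CTRL-like` (p_cis 0.44, p_trans 0.05, 300 nuclei) and
`BWS-ICR2-like` (p_cis 0.29, p_trans 0.03, 300 nuclei) are calibrated to
the measured cohort rates of control vs ICR2-hypomethylated lymphoblastoid
lines. The 3C band generator draws control intensities log-normal around a
base level and multiplies truth × control × unit-mean log-normal noise
(CV parameterized), so zero noise recovers the truth profile exactly. SNP
draws use true major fractions 0.95 (monoallelic) / 0.5 (biallelic) with
10 % multiplicative noise. All generators derive per-nucleus/per-fragment
substreams from a single root seed by counter keys, so any subset is
reproducible independently of iteration order and equal seeds give
byte-identical tables.

## Problem sizes and numerical choices

Tests run the generators at 300 nuclei per line (matching the ~300-nucleus
cohorts), 50 seeds for rate recovery, 100 seed pairs for preset
separability, and 1,000 draws for the SNP caller and pairing oracles; the
acceptance script uses 20 seeds / 50 pairs for the same measures. ANOVA
zero-variance detection uses a relative floor of 1e-12 × (data scale)².
ECDF tables use a 0.05 µm grid extended through the cis cutoff so the
colocalization rate is always readable off the table.

## Known limitations

- The 3C stage consumes quantified band intensities; densitometry, PCR
  efficiency correction and primer design are out of scope.
- The ANOVA assumes homoscedastic cells; with 2 observations per cell the
  pooled-error post-test is the only well-powered option, and normality is
  taken on faith as in the standard workflow.
- Trans-association significance is count-based here; a distance-level
  trans test would need per-nucleus inter-doublet distances from both
  cohorts, which the category counts alone do not determine.
- Haplotype phasing across separate ligation products assumes the products
  derive from the same allele only when SNPs are co-ligated; trio-based
  phasing is out of scope.
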