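# Methods

This note documents the statistical procedures implemented in `fpscan`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Gene diversity and the IBD scan

Within one foundation-parent (FP) group, allele frequencies at a biallelic
SNP are estimated from all non-missing calls, a heterozygote contributing
one copy of each allele. Gene diversity is Nei's expected heterozygosity
`GD = 1 − p² − q²`. Markers with fewer than `min_calls` (default 4)
non-missing lines get a missing GD: without this guard, high-missingness
markers produce spurious zero-diversity calls. `GD = 0` if and only if a
single allele is observed; such markers are *tag loci*.

Each tag locus anchors a candidate window `[pos − hw, pos + hw]` with
`hw = 25 000` bp, clipped to the chromosome's marker extent. The window
is accepted iff its mean GD (over markers with non-missing GD, the tag
included) is **strictly** below the chromosome threshold
`mean(GD) − 0.5 · SD(GD)`, where mean and SD are taken over the
chromosome's per-marker GD values for that group and SD is the sample
standard deviation (n−1). Strict inequalities are used both at the tag
definition (GD exactly 0) and the threshold comparison. Accepted windows
that overlap or bookend merge into one IBD segment whose summary GD is
the marker-count-weighted mean of its member windows. Segment extent is
the union of accepted windows, not the tag-to-tag span: the ±25 kb window
is the method's only stated geometry, so a segment's boundary resolution
is ±hw by construction.

Coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open.

### Venn partition

Segment sets from several groups are overlaid per chromosome. Union
intervals are maximal runs of covered bases (bookend-merged). Each union
interval is labeled with the set of groups having at least one segment
overlapping it (`any_overlap`, ≥1 bp, the default) or satisfying a
reciprocal-overlap fraction (`reciprocal`, configurable `f`). Counting
classes over union intervals makes the arithmetic internally consistent:
for every group, specific + shared contributions = the group's total.
"Common-to-S" counts are superset-inclusive (an interval shared by all
four groups counts toward every pair and triple), which yields the
monotone cascade pairwise ≥ triple ≥ quadruple.

## Population structure

IBS similarity per locus is the mean over the four ordered allele pairs
of the identity indicator (hom vs same hom 1, hom vs opposite hom 0,
anything involving a het 0.5), averaged over loci non-missing in both
lines; the distance is `D = 1 − IBS`. `D` is a semimetric: symmetry and
`D(i,i) = 0` hold, the triangle inequality is not asserted. The diagonal
of the distance matrix is 0 by definition even for lines carrying
heterozygous calls (whose self-similarity under the allele-pair rule is
below 1); the IBS kinship matrix keeps that self-similarity on its
diagonal, so kinship equals `1 − D` off-diagonal only.

UPGMA is implemented directly (arithmetic-mean cluster distance, node
height = half the joining distance) because the tie rule is part of the
contract: ties break toward the pair whose lexicographically smallest
member id is smallest, making the tree deterministic. scipy's average
linkage serves as an independent cross-check in the tests, never as the
implementation.

PCA is plain covariance PCA of the dosage matrix after per-marker mean
imputation and column centering — no allele-variance scaling. Component
signs are fixed by making each score vector's largest-magnitude entry
positive.

The diversity-covering sub-panel is chosen by greedy backward
elimination: repeatedly drop the line whose removal leaves the highest
subset mean per-marker GD (ties: drop the lexicographically smallest
id). Coverage is defined as mean per-marker GD of the subset divided by
that of the full panel — GD is the package's own diversity measure, and
no more specific statistic is standard for this purpose.

## Phenotypes and BLUP

Composite traits are record-wise maps per (line, environment,
replicate): `ASI = DTS − DTP`, `EH/PH`, `KD = KWE / KV` (g/mL),
`10KL/10KW`. Missing operands and division by zero yield missing values.

Per-line BLUPs come from the all-random two-way model
`y_ijk = μ + g_i + e_j + (ge)_ij + ε_ijk` with variance components by
REML (Nelder-Mead on log-variances of a dense-V restricted likelihood;
desk-scale data keeps V small). Replicate effects are folded into the
residual: with one observation per replicate cell a separate replicate
variance is not identifiable on the synthetic designs used here. A
method-of-moments estimator from the balanced ANOVA expected mean
squares is provided as an alternative (`method="anova"`) and agrees with
REML on balanced fixtures. The reported value is `μ + BLUP(g_i)`
(genotype deviation plus grand mean, no environment effects), and as
`σ²_g → 0` all values shrink to `μ`.

Group comparisons are one-way ANOVA on line BLUPs with Tukey HSD at
α = 0.05 and an insert-and-absorb compact letter display. Degenerate
zero-within-variance groups are separated exactly by distinct means.

## GWAS

The association model is `y = μ + Qγ + x_s β_s + u + ε` with
`u ~ N(0, σ²_g K)`. Variance components are estimated once per trait
under the null (P3D): after eigendecomposition `K = U S Uᵀ`, the REML
profile in `δ = σ²_e/σ²_g` is minimized over `ln δ ∈ [−10, 10]`; the
estimate is reused for every marker. Each marker is then tested by
weighted least squares in the rotated basis with a Wald z p-value; the
residual-variance denominator `n − p` makes the `K = I`, no-covariate
case numerically identical to OLS (coefficient and SE to 1e-8; the
normal rather than t reference costs ~0.15 percentage points of size at
n = 180 and is documented as the package's test convention). Markers
monomorphic in the matched lines are skipped; markers collinear with
the covariates are skipped with a flag. Kinship options: VanRaden
(`MMᵀ / 2Σp(1−p)` on 2p-centered, mean-imputed dosages) and IBS
similarity. Default structure covariates are the first 3 PCA scores; a
membership table can be supplied instead. QTNs are markers with
`p < α/m` (strict), `m` defaulting to the number of tested markers.

## Co-localization and candidate genes

A QTN supports a segment when its position lies inside the closed
segment interval; a QTL supports it at ≥1 bp intersection. Segments
supported by both are the important candidate regions. A cluster is
≥ `min_loci` (default 3) QTN/QTL features inside one segment, reported
with the trait categories spanned (PT/FT/KRT/ET). Candidate genes are
gene models whose minimum distance from some tag SNP of the segment is
≤ 25 kb (0 when the tag falls inside the gene), the radius motivated by
the panel's average linkage-disequilibrium extent of ~30 kb; the radius
is configurable (e.g. 50 kb to mimic peak-SNP-anchored screens).

## Expression

FPKM values are normalized as `log2(FPKM + 1)`: a pseudocount is
required because log2 of zero FPKM is undefined, and 1 maps zero
expression to zero. Differential expression between two FP groups is a
per-gene one-way ANOVA (equivalent to a t-test for two groups) on the
log2 scale; the fold change is the **difference of group means of log2
values**, not the log2 of the ratio of mean FPKM — the two differ and
the former matches the stated normalization. No multiple-testing
correction is applied by default (raw per-gene significance is
reported); Benjamini–Hochberg is available via `fdr=True`. Co-expression
edges are Pearson correlations across organ samples with `|r| ≥ 0.8`
by default — no standard threshold exists for this kind of edge list,
so the value is a package choice and configurable. Constant genes are
excluded (undefined r).

## The synthetic-data generator

The generator emulates a four-group FP breeding panel. Per group a
founder haplotype is drawn against panel-level allele frequencies
`f ~ U(0.1, 0.9)`; each descendant copies the founder and, outside
planted segments, each marker is independently resampled from the panel
distribution with probability ρ = 0.4, producing background within-group
gene diversity with closed-form expectation
`E[GD] = 1.28 · E[f(1−f)] · (1 − 1/(2n)) ≈ 0.24` at n = 15 lines (the
`background_gd_target` default). Inside a planted segment listed for the
group the founder allele is copied exactly, so GD is 0 there by
construction. 1% of calls are set missing panel-wide; 0.5% are made
heterozygous **outside** a line's own-group planted segments — a single
het inside a planted block would destroy the exact-conservation truth
the recovery tests assert, and chip heterozygosity in truly IBD regions
is a genotyping artifact the scan is not meant to model.

Default dimensions mirror the real panel (4 groups of 99/95/61/49
lines); the desk-scale configuration (`SimConfig.ci_scale()`: 4 × 15
lines, 8 000 markers, two 10 Mb chromosomes) is used throughout the
tests and the reproduction script. Physical coordinates are compressed
relative to the real 2.1 Gb maize genome so that a ±25 kb window
contains ~20 markers: at real marker density a window would usually hold
only its tag, the window-mean filter would be vacuous, and no desk-scale
test could exercise it. Planted blocks (default 12 group-specific per
group of 80–200 kb, plus one shared block per pair, per triple, and one
common to all) are placed on a 300 kb slot grid so distinct blocks stay
separated by more than twice the half-window; blocks planted closer than
the method's boundary resolution would merge through legitimate window
overhang and make the truth itself ambiguous.

Phenotypes: per trait, planted QTN effects `β_k` are scaled so marker k
explains its configured fraction of a unit reference variance; a
polygenic line effect (default variance 0.5), group mean shifts,
environment main effects (0.25), G×E (0.1) and per-replicate residuals
(0.3) are added, emitted in long format over environments × replicates.
Expression: per-gene baseline `log2 ~ N(5, 1)`, planted group shifts of
±2 log2 units, sample noise SD 0.5, 9 lines per group (kernel mode) or
27 organs with one 5-gene block sharing a latent factor at generative
r = 0.95 (organ mode). FPKM is `2^v − 1` floored at 0.

What the generator does **not** emulate: linkage disequilibrium and
recombination-block structure (markers are resampled independently —
the diversity scan is window-mean based and insensitive to LD realism),
allele-frequency spectra from real ascertainment, genotyping batch
effects, shared pedigree between groups, and selection. Passing
recovery tests therefore demonstrate correctness of the statistics and
the scan geometry, not performance on real chip data with LD-induced
correlation between neighboring windows.

### Recovery metrics

Scan sensitivity is the fraction of planted blocks intersected by ≥1
called segment. False-called length is the called length outside the
planted truth *dilated by the half-window*, as a fraction of total
called length: boundary markers of a planted block are genuine tag loci
and the method reports ±25 kb windows around them, so up to hw of
overhang per block edge is part of the stated geometry, not error. Venn
assignment accuracy is the fraction of planted group-specific length
lying in union intervals labeled with exactly the right group.

## Numerical conventions

* Genotypes are int8 alt-allele dosages {0, 1, 2, −1 = missing};
  heterozygotes are legal (inbred panels still show residual hets).
* Missing-rate and MAF thresholds are strict inequalities; rates are
  computed as integer quotients to avoid float-boundary artifacts.
* Merging of intervals treats bookended intervals ([a,b], [b+1,c]) as
  contiguous.
* Harmonization flips a later panel's calls into the first panel's
  allele frame when allele sets are Watson–Crick complements (dosage
  complemented when ref/alt roles swap); A/T and C/G markers are kept
  but flagged strand-ambiguous; duplicate lines keep the first panel's
  calls with the discordance count reported.
* All simulator randomness flows from one integer seed through
  `numpy.random.SeedSequence` children; identical configs give
  byte-identical output files.

## Problem sizes

The test suite and reproduction script run the scan on the 60-line ×
8 000-marker panel, MLM calibration on 5 × 1 000 null markers at
n = 180, QTN power over 50 replicates at m = 2 000, and DE recovery on
200–1 000 genes — sizes chosen so the whole verification completes in
minutes on a single CPU while keeping every statistical check at usable
resolution.

## Known limitations

* The scan's boundary resolution is ±25 kb; reported segment lengths
  are systematically larger than the underlying conserved blocks.
* REML for the BLUP model builds the dense n×n covariance; it is meant
  for trial sizes up to a few thousand observations, not for
  national-scale MET data.
* The Wald z convention in the MLM is mildly anticonservative at small
  n relative to an exact F test; at n ≥ 100 the difference is
  negligible.
* `group_trait_anova` letters use Tukey HSD; with strongly unbalanced
  or heteroscedastic groups a Games–Howell-type procedure would be more
  appropriate and is not implemented.
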