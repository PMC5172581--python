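# fpscan

Identity-by-descent (IBD) segment discovery in maize foundation-parent
breeding panels.

A handful of elite inbred lines — foundation parents (FPs) such as B73,
Mo17, PH207 and Huangzaosi — sit at the root of most modern maize
breeding programs. Chromosome segments that descendants inherited intact
from their FP show up as stretches of *suppressed within-group diversity*
in SNP data. `fpscan` is a library for breeders and population
geneticists that finds those segments, asks which are specific to one FP
group versus shared among several, and connects them to phenotypes: GWAS
QTNs, literature QTLs, physically linked candidate genes, and
group-differential expression.

## The method

For each FP group and SNP the package computes Nei's gene diversity from
the group's allele frequencies,

    GD = 1 − p² − q²,

the probability that two alleles drawn at random from the group differ.
SNPs with GD exactly 0 are **tag loci**. Around every tag locus a window
of ±25 kb is evaluated, and the window is accepted when its mean GD falls
strictly below the chromosome-specific threshold

    T_c = mean(GD_c) − 0.5 · SD(GD_c),

computed over that chromosome's markers in that group. Accepted windows
merge into **IBD segments**; the segment sets of all groups are overlaid
on one coordinate frame and partitioned into group-combination classes
(specific, pairwise … common-to-all) over union intervals.

Around this core the package provides the standard pipeline stages:

* `genotype_io` — HapMap/CSV panels, complementary-allele harmonization
  across chips, MAF/missingness filtering (strict `MAF > 0.05`,
  `missing < 0.2`).
* `popstructure` — IBS distance `D = 1 − IBS`, UPGMA cladogram (newick),
  covariance PCA, greedy diversity-covering sub-panel selection.
* `phenotypes` — composite traits (`ASI = DTS − DTP`, `EH/PH`,
  `KD = KWE/KV`, `10KL/10KW`), per-line BLUPs from the all-random model
  `y = μ + g + e + ge + ε` (REML), Tukey-HSD group letters.
* `gwas` — P3D mixed linear model `y = μ + Qγ + x·β + u + ε`,
  `u ~ N(0, σ²_g K)`, with VanRaden or IBS kinship; QTNs at the
  Bonferroni cutoff `0.05/m`.
* `colocalize` — QTN/QTL projection onto segments, QTN/QTL clusters,
  candidate genes within 25 kb of tag SNPs (GFF3 annotation).
* `expression` — log2(FPKM+1) group ANOVA with fold changes, Pearson
  co-expression edge lists across organs.
* `synthetic_data` — a founder–descendant panel simulator with planted
  conserved segments, QTNs and DE genes, so every stage has a
  parameter-recovery test with known truth.

## Worked example

```python
from fpscan import SimConfig, simulate_panel, scan_group, venn_partition

cfg = SimConfig.ci_scale(seed=7)          # 4 groups x 15 lines, 8,000 SNPs
g, truth = simulate_panel(cfg)
segment_sets = {grp: scan_group(g, grp) for grp in g.groups}
vp = venn_partition(segment_sets)
for grp in g.groups:
    print(grp, vp.group_total(grp), vp.specific_count(grp))
print("common to all:", vp.count_at_least(g.groups))
```

prints

```
207 20 12
B73 22 12
HZS 21 12
Mo17 21 12
common to all: 1
```

— each group's 12 planted group-specific blocks are recovered as
specific union intervals, the single planted common-to-all block appears
as exactly one quadruple-shared interval, and the remaining totals are
the planted pairwise/triple shared blocks. For one group the scan
reports, e.g. (`examples/02_ibd_scan.py`):

```
group HZS: 2052 tag loci (GD = 0) of 8000 SNPs
  chr1: acceptance threshold = 0.1284
called 21 IBD segments
recovery vs planted truth: sensitivity 1.00, false-called length fraction 0.030
```

The `examples/` directory holds one short script per capability
(simulation, scan, venn algebra, GWAS, co-localization, expression); each
prints the numbers it computes and a line on what they mean. A thin CLI
mirrors the pipeline for shell use:

```bash
fps sim --seed 7 --out demo/
fps ibd scan --genotypes demo/genotypes.csv --groups demo/groups.csv --out segs.bed
fps ibd venn --genotypes demo/genotypes.csv --groups demo/groups.csv --out venn.tsv
```

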