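"""Founder-descendant panel simulator with planted, machine-readable truth.

The generator emulates the structure of a maize foundation-parent (FP)
breeding panel: four groups of near-homozygous inbred lines, each group
descending from a single founder haplotype. Outside planted conserved
segments every descendant call is independently resampled from the
panel-level allele distribution with probability ``rho`` (creating
background within-group diversity); inside a planted segment listed for
the line's group the founder allele is copied exactly, so within-group
gene diversity there is 0 by construction. Planted segments may be
group-specific or shared by 2-4 groups; QTNs with configured variance
fractions are planted inside segments, and differentially expressed genes
are planted per group. Every simulated dataset is paired with a
:class:`TruthSet` so each pipeline stage has a parameter-recovery test.

Physical coordinates are compressed relative to the real maize genome
(10 x 10 Mb chromosomes at full scale) so that the +/-25 kb window scan
sees a realistic number of markers per window at desk-scale marker counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import child_seeds
from .genotype_io import GenotypeMatrix, MISSING, write_genotypes
from .expression import ExpressionMatrix, write_expression

DEFAULT_GROUPS = ("B73", "207", "HZS", "Mo17")
# Results-section group sizes (sum to the 304-line panel)
DEFAULT_LINES_PER_GROUP = (99, 95, 61, 49)


@dataclass(frozen=True)
class PlantedSegment:
    chrom: str
    start_bp: int
    end_bp: int
    groups: tuple[str, ...]  # groups in which the segment is conserved


@dataclass(frozen=True)
class QtnPlan:
    segment_index: int   # index into planted segments; marker picked inside
    trait: str
    h2: float            # variance fraction of the reference variance (1.0)


@dataclass(frozen=True)
class DePlan:
    gene: str
    group: str
    log2_shift: float


@dataclass
class SimConfig:
    """Study conditions for the simulator; same config => bit-identical output."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    lines_per_group: tuple[int, ...] = DEFAULT_LINES_PER_GROUP
    n_markers: int = 43_252
    chrom_lengths_bp: dict = field(
        default_factory=lambda: {str(c): 10_000_000 for c in range(1, 11)})
    planted_segments: list[PlantedSegment] | None = None  # None -> default plan
    n_specific_per_group: int = 12
    block_length_range_bp: tuple[int, int] = (80_000, 200_000)
    rho: float = 0.4                  # background resampling probability
    background_gd_target: float = 0.24
    freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.01
    het_rate: float = 0.005
    qtn_plan: list[QtnPlan] | None = None     # None -> default plan
    traits: tuple[str, ...] = ("EH", "PH", "DTP", "DTS", "DTT", "KD", "ED")
    n_envs: int = 15
    n_reps: int = 2
    sigma2_polygenic: float = 0.5
    sigma2_env: float = 0.25
    sigma2_gxe: float = 0.1
    sigma2_resid: float = 0.3
    group_shifts: dict = field(default_factory=dict)  # trait -> {group: shift}
    n_genes: int = 200
    de_plan: list[DePlan] | None = None       # None -> default plan
    expr_lines_per_group: int = 9
    expr_baseline_mean: float = 5.0
    expr_baseline_sd: float = 1.0
    expr_sigma: float = 0.5
    n_organs: int = 27
    coexpr_block_size: int = 5
    coexpr_block_r: float = 0.95
    seed: int = 7

    @classmethod
    def ci_scale(cls, seed: int = 7, **overrides) -> "SimConfig":
        """Desk/CI-scale conditions: 4 x 15 lines, 8,000 markers, 2 x 10 Mb."""
        base = dict(
            lines_per_group=(15, 15, 15, 15),
            n_markers=8_000,
            chrom_lengths_bp={"1": 10_000_000, "2": 10_000_000},
            n_envs=4,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthSet:
    """Planted ground truth written alongside every simulated dataset."""

    segments: pd.DataFrame   # chrom, start_bp, end_bp, groups (comma-joined)
    qtns: pd.DataFrame       # marker_id, chrom, pos_bp, trait, h2, segment_index
    de_genes: pd.DataFrame   # gene, group, log2_shift

    def segment_tuples(self):
        return [PlantedSegment(r["chrom"], int(r["start_bp"]), int(r["end_bp"]),
                               tuple(r["groups"].split(",")))
                for _, r in self.segments.iterrows()]

    def to_json(self, path) -> None:
        payload = {
            "segments": self.segments.to_dict(orient="records"),
            "qtns": self.qtns.to_dict(orient="records"),
            "de_genes": self.de_genes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["segments"]),
                   pd.DataFrame(payload["qtns"]),
                   pd.DataFrame(payload["de_genes"]))


# ---------------------------------------------------------------------------
# planted-segment and qtn plans

def default_segment_plan(cfg: SimConfig, rng: np.random.Generator) -> list[PlantedSegment]:
    """Place non-overlapping blocks on a 250 kb slot grid.

    Per group ``n_specific_per_group`` group-specific blocks, plus shared
    blocks: one per group pair, one per group triple and one common to all
    groups, each with a random length in ``block_length_range_bp``. The
    slot pitch keeps distinct blocks separated by more than twice the scan
    half-window, so two planted blocks can never merge into one called
    region purely through window overhang.
    """
    slot = 300_000
    slots = [(c, s) for c, L in cfg.chrom_lengths_bp.items()
             for s in range(0, L - slot + 1, slot)]
    order = rng.permutation(len(slots))
    from itertools import combinations
    wanted: list[tuple[str, ...]] = []
    for g in cfg.groups:
        wanted += [(g,)] * cfg.n_specific_per_group
    for k in (2, 3):
        wanted += list(combinations(cfg.groups, k))
    wanted.append(tuple(cfg.groups))
    if len(wanted) > len(slots):
        raise ValueError("genome too small for the requested planted blocks")
    lo, hi = cfg.block_length_range_bp
    plan = []
    for i, grps in enumerate(wanted):
        c, s = slots[order[i]]
        length = int(rng.integers(lo, hi + 1))
        plan.append(PlantedSegment(str(c), s + 1, s + length, tuple(grps)))
    plan.sort(key=lambda p: (p.chrom, p.start_bp))
    return plan


def default_qtn_plan(cfg: SimConfig, segments: list[PlantedSegment]) -> list[QtnPlan]:
    """One QTN per group's first specific segment, on rotating traits."""
    traits = ["EH", "DTT", "KD", "ED"]
    h2s = [0.25, 0.25, 0.2, 0.2]
    plan = []
    for gi, g in enumerate(cfg.groups):
        for si, seg in enumerate(segments):
            if seg.groups == (g,):
                plan.append(QtnPlan(si, traits[gi % len(traits)], h2s[gi % len(h2s)]))
                break
    return plan


def default_de_plan(cfg: SimConfig) -> list[DePlan]:
    """Two planted DE genes per group, shifts +2 and -2 log2 units."""
    plan = []
    gi = 0
    for g in cfg.groups:
        plan.append(DePlan(f"GENE{gi + 1:04d}", g, 2.0))
        plan.append(DePlan(f"GENE{gi + 2:04d}", g, -2.0))
        gi += 2
    return plan


# ---------------------------------------------------------------------------
# panel

def _unique_sorted_positions(rng, length_bp, n):
    pos = set()
    while len(pos) < n:
        draw = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos.update(int(x) for x in draw)
    return np.array(sorted(pos))


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate the genotype panel and its truth set (deterministic in cfg)."""
    seeds = child_seeds(cfg.seed, 4)
    rng = np.random.default_rng(seeds[0])
    chroms = list(cfg.chrom_lengths_bp)
    total_len = sum(cfg.chrom_lengths_bp.values())
    n_per = {c: int(round(cfg.n_markers * cfg.chrom_lengths_bp[c] / total_len))
             for c in chroms}
    n_per[chroms[-1]] += cfg.n_markers - sum(n_per.values())
    pos_list, chrom_list = [], []
    for c in chroms:
        p = _unique_sorted_positions(rng, cfg.chrom_lengths_bp[c], n_per[c])
        pos_list.append(p)
        chrom_list += [c] * len(p)
    pos = np.concatenate(pos_list)
    chrom = np.array(chrom_list)
    m = len(pos)

    segments = (cfg.planted_segments if cfg.planted_segments is not None
                else default_segment_plan(cfg, rng))
    for seg in segments:
        in_seg = (chrom == seg.chrom) & (pos >= seg.start_bp) & (pos <= seg.end_bp)
        if not in_seg.any():
            raise ValueError(f"planted segment {seg} contains zero markers")

    lo, hi = cfg.freq_range
    f = rng.uniform(lo, hi, m)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, m)
    alt_idx = (ref_idx + rng.integers(1, 4, m)) % 4
    markers = pd.DataFrame({
        "marker_id": [f"SNP{i + 1:06d}" for i in range(m)],
        "chrom": chrom, "pos_bp": pos,
        "ref": bases[ref_idx], "alt": bases[alt_idx],
    })

    planted_mask = {g: np.zeros(m, dtype=bool) for g in cfg.groups}
    for seg in segments:
        in_seg = (chrom == seg.chrom) & (pos >= seg.start_bp) & (pos <= seg.end_bp)
        for g in seg.groups:
            planted_mask[g] |= in_seg

    line_rows, call_rows = [], []
    for gi, g in enumerate(cfg.groups):
        n_lines = cfg.lines_per_group[gi]
        founder = (rng.random(m) < f).astype(np.int8) * 2
        keep_founder = planted_mask[g]
        calls = np.repeat(founder[None, :], n_lines, axis=0)
        resample = (rng.random((n_lines, m)) < cfg.rho) & ~keep_founder
        fresh = (rng.random((n_lines, m)) < f).astype(np.int8) * 2
        calls = np.where(resample, fresh, calls)
        het = (rng.random((n_lines, m)) < cfg.het_rate) & ~keep_founder
        calls[het] = 1
        miss = rng.random((n_lines, m)) < cfg.missing_rate
        calls[miss] = MISSING
        membership = rng.uniform(0.6, 1.0, n_lines).round(3)
        for j in range(n_lines):
            line_rows.append({"line_id": f"{g}_{j + 1:03d}", "group": g,
                              "membership": membership[j]})
        call_rows.append(calls)

    lines = pd.DataFrame(line_rows)
    calls = np.vstack(call_rows).astype(np.int8)
    g_matrix = GenotypeMatrix(lines, markers, calls)

    seg_df = pd.DataFrame([{
        "chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
        "groups": ",".join(s.groups),
    } for s in segments])

    qtn_plan = (cfg.qtn_plan if cfg.qtn_plan is not None
                else default_qtn_plan(cfg, segments))
    qtn_rows = []
    for qp in qtn_plan:
        seg = segments[qp.segment_index]
        in_seg = np.where((chrom == seg.chrom) & (pos >= seg.start_bp)
                          & (pos <= seg.end_bp))[0]
        mid = in_seg[len(in_seg) // 2]
        qtn_rows.append({"marker_id": markers["marker_id"].iat[mid],
                         "chrom": seg.chrom, "pos_bp": int(pos[mid]),
                         "trait": qp.trait, "h2": qp.h2,
                         "segment_index": qp.segment_index})
    qtn_df = pd.DataFrame(qtn_rows, columns=["marker_id", "chrom", "pos_bp",
                                             "trait", "h2", "segment_index"])

    de_plan = cfg.de_plan if cfg.de_plan is not None else default_de_plan(cfg)
    de_df = pd.DataFrame([{"gene": d.gene, "group": d.group,
                           "log2_shift": d.log2_shift} for d in de_plan],
                         columns=["gene", "group", "log2_shift"])
    return g_matrix, TruthSet(seg_df, qtn_df, de_df)


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(g: GenotypeMatrix, truth: TruthSet,
                        cfg: SimConfig) -> pd.DataFrame:
    """Multi-environment long-format phenotypes with planted QTN effects.

    Per line and trait the genetic value is sum(beta_k * dosage_k) with
    beta scaled so QTN k explains its configured fraction of the reference
    phenotypic variance (1.0), plus a polygenic line effect, group mean
    shifts, environment main effects, G x E noise and per-replicate
    residuals.
    """
    rng = np.random.default_rng(child_seeds(cfg.seed, 4)[1])
    d = g.dosage()
    n = g.n_lines
    records = []
    envs = [f"E{j + 1:02d}" for j in range(cfg.n_envs)]
    group_of = g.lines["group"].to_numpy()
    for trait in cfg.traits:
        tq = truth.qtns.loc[truth.qtns["trait"] == trait]
        if tq["h2"].sum() >= 1.0:
            raise ValueError(f"trait {trait}: QTN variance fractions sum >= 1")
        genetic = np.zeros(n)
        for _, q in tq.iterrows():
            jcol = g.markers.index[g.markers["marker_id"] == q["marker_id"]][0]
            x = d[:, jcol]
            x = np.where(np.isnan(x), np.nanmean(x), x)
            vx = x.var()
            if vx == 0:
                continue
            beta = np.sqrt(q["h2"] / vx)
            genetic = genetic + beta * (x - x.mean())
        if cfg.sigma2_polygenic > 0:
            genetic = genetic + rng.normal(0, np.sqrt(cfg.sigma2_polygenic), n)
        shifts = cfg.group_shifts.get(trait, {})
        genetic = genetic + np.array([shifts.get(grp, 0.0) for grp in group_of])
        env_eff = (rng.normal(0, np.sqrt(cfg.sigma2_env), cfg.n_envs)
                   if cfg.sigma2_env > 0 else np.zeros(cfg.n_envs))
        gxe = (rng.normal(0, np.sqrt(cfg.sigma2_gxe), (n, cfg.n_envs))
               if cfg.sigma2_gxe > 0 else np.zeros((n, cfg.n_envs)))
        for ej, env in enumerate(envs):
            for rep in range(1, cfg.n_reps + 1):
                resid = (rng.normal(0, np.sqrt(cfg.sigma2_resid), n)
                         if cfg.sigma2_resid > 0 else np.zeros(n))
                vals = genetic + env_eff[ej] + gxe[:, ej] + resid
                for i, lid in enumerate(g.line_ids):
                    records.append((lid, env, rep, trait, vals[i]))
    return pd.DataFrame(records, columns=["line_id", "env", "rep", "trait", "value"])


# ---------------------------------------------------------------------------
# expression

def simulate_expression(truth: TruthSet, cfg: SimConfig) -> ExpressionMatrix:
    """Kernel FPKM matrix: N lines per FP group, planted group shifts.

    Baseline log2 expression is Normal(expr_baseline_mean, expr_baseline_sd)
    per gene; planted shifts add to the gene's mean in the listed group;
    per-sample noise is Normal(0, expr_sigma). FPKM = 2^value - 1, floored
    at 0.
    """
    rng = np.random.default_rng(child_seeds(cfg.seed, 4)[2])
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    base = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)
    sample_ids, groups = [], []
    for g in cfg.groups:
        for j in range(cfg.expr_lines_per_group):
            sample_ids.append(f"{g}_K{j + 1:02d}")
            groups.append(g)
    vals = np.empty((cfg.n_genes, len(sample_ids)))
    shift_map = {(r["gene"], r["group"]): r["log2_shift"]
                 for _, r in truth.de_genes.iterrows()}
    for si, (sid, grp) in enumerate(zip(sample_ids, groups)):
        mu = base + np.array([shift_map.get((gene, grp), 0.0) for gene in genes])
        vals[:, si] = mu + rng.normal(0, cfg.expr_sigma, cfg.n_genes)
    fpkm = np.maximum(2.0 ** vals - 1.0, 0.0)
    values = pd.DataFrame(fpkm, index=genes, columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return ExpressionMatrix(values, samples)


def simulate_organ_expression(truth: TruthSet, cfg: SimConfig) -> ExpressionMatrix:
    """Organ-mode matrix with one correlated gene block for network tests.

    The first ``coexpr_block_size`` genes share a latent organ factor with
    generative pairwise correlation ``coexpr_block_r``; remaining genes are
    independent across organs.
    """
    rng = np.random.default_rng(child_seeds(cfg.seed, 4)[3])
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    organs = [f"organ_{j + 1:02d}" for j in range(cfg.n_organs)]
    base = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)
    vals = np.empty((cfg.n_genes, cfg.n_organs))
    latent = rng.normal(0, 1, cfg.n_organs)
    r = cfg.coexpr_block_r
    for i in range(cfg.n_genes):
        if i < cfg.coexpr_block_size:
            noise = rng.normal(0, 1, cfg.n_organs)
            vals[i] = base[i] + np.sqrt(r) * latent + np.sqrt(1 - r) * noise
        else:
            vals[i] = base[i] + rng.normal(0, 1, cfg.n_organs)
    fpkm = np.maximum(2.0 ** vals - 1.0, 0.0)
    values = pd.DataFrame(fpkm, index=genes, columns=organs)
    samples = pd.DataFrame({"sample_id": organs, "organ": organs})
    return ExpressionMatrix(values, samples)


# ---------------------------------------------------------------------------
# annotation + QTL files

def write_annotation(truth: TruthSet, cfg: SimConfig, gff_path, qtl_path) -> None:
    """GFF3 gene models at controlled distances from planted segments,
    plus a QTL TSV overlapping the QTN-bearing segments.

    For every planted segment three 2 kb gene models are written: one
    spanning the segment midpoint (distance 0 to a tag), one 10 kb past the
    segment end (inside the 25 kb linkage radius) and one 30 kb past the
    end (outside it).
    """
    gene_rows = []
    offsets = {"d0": None, "d10k": 10_000, "d30k": 30_000}
    for si, seg in enumerate(truth.segments.itertuples()):
        mid = (seg.start_bp + seg.end_bp) // 2
        for tag_name, off in offsets.items():
            if off is None:
                start = mid - 1_000
            else:
                start = seg.end_bp + off
            gene_rows.append({
                "gene_id": f"GENE_S{si:03d}_{tag_name}",
                "chrom": seg.chrom, "start_bp": start, "end_bp": start + 2_000,
                "strand": "+" if si % 2 == 0 else "-",
            })
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, L in cfg.chrom_lengths_bp.items():
            fh.write(f"##sequence-region {c} 1 {L}\n")
        for r in gene_rows:
            fh.write(f"{r['chrom']}\tfpscan_sim\tgene\t{r['start_bp']}\t{r['end_bp']}"
                     f"\t.\t{r['strand']}\t.\tID={r['gene_id']}\n")

    qtl_rows = []
    for qi, q in enumerate(truth.qtns.itertuples()):
        qtl_rows.append({
            "name": f"q{q.trait.replace('/', '')}{qi + 1}", "trait": q.trait,
            "chrom": q.chrom, "start_bp": max(1, q.pos_bp - 50_000),
            "end_bp": q.pos_bp + 50_000, "source": "synthetic",
        })
    pd.DataFrame(qtl_rows, columns=["name", "trait", "chrom", "start_bp",
                                    "end_bp", "source"]).to_csv(
        qtl_path, sep="\t", index=False)


def write_all(cfg: SimConfig, outdir) -> dict:
    """Simulate every pipeline input and write it under ``outdir``.

    Emits genotypes.csv, groups.csv, phenotypes.csv, annotation.gff3,
    qtls.tsv, expression_kernel.tsv, expression_organs.tsv and truth.json;
    returns the paths. Byte-identical across runs with the same config.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("genotypes", "genotypes.csv"), ("groups", "groups.csv"),
        ("phenotypes", "phenotypes.csv"), ("annotation", "annotation.gff3"),
        ("qtls", "qtls.tsv"), ("expression_kernel", "expression_kernel.tsv"),
        ("expression_organs", "expression_organs.tsv"), ("truth", "truth.json"),
    ]}
    g, truth = simulate_panel(cfg)
    write_genotypes(g, paths["genotypes"], dialect="csv")
    g.lines.to_csv(paths["groups"], index=False)
    pheno = simulate_phenotypes(g, truth, cfg)
    pheno.to_csv(paths["phenotypes"], index=False, float_format="%.6g")
    write_annotation(truth, cfg, paths["annotation"], paths["qtls"])
    write_expression(simulate_expression(truth, cfg), paths["expression_kernel"])
    write_expression(simulate_organ_expression(truth, cfg), paths["expression_organs"])
    truth.to_json(paths["truth"])
    return paths
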