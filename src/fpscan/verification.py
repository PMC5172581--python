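"""End-to-end recovery measurements on simulated panels.

These helpers run whole pipeline stages against a :class:`TruthSet` and
report the summary statistics used to verify the method: scan sensitivity
and false-called length, venn assignment accuracy, GWAS power and null
calibration, and differential-expression recovery. They are part of the
public API so the same measurements back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import child_seeds, interval_overlap, merge_intervals
from .genotype_io import GenotypeMatrix
from .gwas import call_qtns, kinship_matrix, mlm_associate
from .ibd_scan import DEFAULT_HALF_WINDOW_BP, scan_group, venn_partition
from .phenotypes import TraitBlup
from .synthetic_data import SimConfig, TruthSet, simulate_panel


def truth_blocks(truth: TruthSet, group: str, specific_only: bool = False):
    """Planted intervals conserved in ``group`` as {chrom: [[s, e], ...]}."""
    out: dict[str, list] = {}
    for _, seg in truth.segments.iterrows():
        grps = seg["groups"].split(",")
        if group not in grps:
            continue
        if specific_only and len(grps) > 1:
            continue
        out.setdefault(str(seg["chrom"]), []).append(
            [int(seg["start_bp"]), int(seg["end_bp"])])
    return {c: merge_intervals(iv) for c, iv in out.items()}


def scan_recovery(g: GenotypeMatrix, truth: TruthSet, group: str,
                  half_window_bp: int = DEFAULT_HALF_WINDOW_BP) -> dict:
    """Sensitivity and false-called length of the scan for one group.

    Sensitivity is the fraction of planted blocks intersected by a called
    segment. False-called length is the called length falling outside the
    planted truth dilated by the half-window (the scan reports +/-hw
    windows around tag loci, so block-edge overhang up to hw is part of
    the method's stated geometry, not error), as a fraction of total
    called length.
    """
    segs = scan_group(g, group, half_window_bp=half_window_bp)
    blocks = truth_blocks(truth, group)
    dilated = {c: merge_intervals([[max(1, s - half_window_bp), e + half_window_bp]
                                   for s, e in iv])
               for c, iv in blocks.items()}
    total_called = false_len = 0
    n_blocks = n_hit = 0
    for seg in segs:
        length = seg.length_bp
        total_called += length
        cov = sum(interval_overlap(seg.start_bp, seg.end_bp, s, e)
                  for s, e in dilated.get(str(seg.chrom), []))
        false_len += length - cov
    for chrom, iv in blocks.items():
        for s, e in iv:
            n_blocks += 1
            if any(str(seg.chrom) == chrom
                   and interval_overlap(seg.start_bp, seg.end_bp, s, e) > 0
                   for seg in segs):
                n_hit += 1
    return {
        "n_segments": len(segs),
        "n_planted_blocks": n_blocks,
        "sensitivity": n_hit / n_blocks if n_blocks else np.nan,
        "false_length_fraction": false_len / total_called if total_called else np.nan,
        "segments": segs,
    }


def venn_specific_accuracy(g: GenotypeMatrix, truth: TruthSet,
                           half_window_bp: int = DEFAULT_HALF_WINDOW_BP) -> dict:
    """Fraction of planted group-specific length assigned to the right group.

    Runs the scan for every group, partitions the segment sets, and
    measures how much planted single-group length lands in union intervals
    labeled with exactly that group.
    """
    seg_sets = {grp: scan_group(g, grp, half_window_bp=half_window_bp)
                for grp in g.groups}
    vp = venn_partition(seg_sets)
    correct = total = 0
    for grp in g.groups:
        spec = truth_blocks(truth, grp, specific_only=True)
        only = vp.intervals.loc[vp.intervals["label"] == frozenset([grp])]
        for chrom, iv in spec.items():
            for s, e in iv:
                total += e - s + 1
                sub = only.loc[only["chrom"].astype(str) == chrom]
                correct += sum(interval_overlap(s, e, us, ue)
                               for us, ue in zip(sub["start_bp"], sub["end_bp"]))
    return {"venn": vp, "specific_length_accuracy": correct / total if total else np.nan}


# ---------------------------------------------------------------------------
# GWAS verification

def _structured_panel(n_per_group: int, n_markers: int, seed: int) -> GenotypeMatrix:
    cfg = SimConfig.ci_scale(
        seed=seed, lines_per_group=(n_per_group,) * 4, n_markers=n_markers,
        planted_segments=[], qtn_plan=[], de_plan=[])
    g, _ = simulate_panel(cfg)
    return g


def mlm_null_calibration(n_lines: int = 180, n_markers: int = 1000,
                         seeds=(1, 2, 3, 4, 5), alpha: float = 0.05) -> dict:
    """Fraction of null p-values below ``alpha`` pooled over seeds.

    The generative null is y ~ N(0, 0.5 K + 0.5 I) with K the VanRaden
    kinship of the simulated structured panel; a calibrated test keeps the
    fraction near alpha.
    """
    fractions = []
    n_per = n_lines // 4
    for seed in seeds:
        g = _structured_panel(n_per, n_markers, seed)
        k = kinship_matrix(g, method="vanraden")
        rng = np.random.default_rng(child_seeds(seed, 3)[2])
        v = 0.5 * k.k + 0.5 * np.eye(g.n_lines)
        y = np.linalg.cholesky(v + 1e-10 * np.eye(g.n_lines)) @ \
            rng.normal(0, 1, g.n_lines)
        blups = [TraitBlup(lid, "null", float(val), 1)
                 for lid, val in zip(g.line_ids, y)]
        res = mlm_associate(blups, g, k, trait="null")
        p = res.loc[~res["skipped"], "p_value"].to_numpy()
        fractions.append(float(np.mean(p < alpha)))
    pooled = float(np.mean(fractions))
    n_total = len(seeds) * n_markers
    ci = 1.96 * np.sqrt(alpha * (1 - alpha) / n_total)
    return {"fraction_below_alpha": pooled, "per_seed": fractions,
            "alpha": alpha, "ci_halfwidth": ci}


def qtn_power(n_lines: int = 180, n_markers: int = 2000, h2: float = 0.25,
              n_reps: int = 50, alpha: float = 0.05, seed: int = 1) -> dict:
    """Detection rate of one planted QTN at the Bonferroni cutoff.

    Per replicate a structured panel is simulated, a marker is planted to
    explain ``h2`` of the phenotypic variance, and the MLM scan is run with
    the cutoff alpha / m.
    """
    detected = 0
    rep_seeds = child_seeds(seed, n_reps)
    for rs in rep_seeds:
        g = _structured_panel(n_lines // 4, n_markers, rs)
        rng = np.random.default_rng(child_seeds(rs, 2)[1])
        d = g.dosage()
        # pick a reasonably polymorphic marker as the causal site
        p = np.nanmean(d, axis=0) / 2
        cand = np.where((p > 0.2) & (p < 0.8))[0]
        j = int(cand[rng.integers(len(cand))])
        x = np.where(np.isnan(d[:, j]), np.nanmean(d[:, j]), d[:, j])
        beta = np.sqrt(h2 / x.var())
        y = beta * (x - x.mean()) + rng.normal(0, np.sqrt(1 - h2), g.n_lines)
        k = kinship_matrix(g, method="vanraden")
        blups = [TraitBlup(lid, "T", float(v), 1) for lid, v in zip(g.line_ids, y)]
        res = mlm_associate(blups, g, k, trait="T")
        qtns = call_qtns(res, alpha=alpha)
        hits = set(qtns.loc[qtns["passes"], "marker_id"])
        detected += g.markers["marker_id"].iat[j] in hits
    return {"power": detected / n_reps, "n_reps": n_reps,
            "cutoff": alpha / n_markers}


def de_recovery(cfg: SimConfig) -> dict:
    """Planted DE detection rate and null false-positive rate."""
    from .expression import group_de, normalize_log2
    from .synthetic_data import simulate_expression

    _, truth = simulate_panel(cfg)
    e = normalize_log2(simulate_expression(truth, cfg))
    detected = 0
    for _, row in truth.de_genes.iterrows():
        grp = row["group"]
        other = next(x for x in cfg.groups if x != grp)
        de = group_de(e, (grp, other), alpha=0.05)
        detected += row["gene"] in set(de["gene"])
    n_planted = len(truth.de_genes)
    null_cfg = SimConfig.ci_scale(seed=cfg.seed + 1, de_plan=[], n_genes=1000)
    _, null_truth = simulate_panel(null_cfg)
    e0 = normalize_log2(simulate_expression(null_truth, null_cfg))
    de0 = group_de(e0, (cfg.groups[0], cfg.groups[2]), alpha=0.05)
    return {"de_detection_rate": detected / n_planted if n_planted else np.nan,
            "null_fpr": len(de0) / null_cfg.n_genes}
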