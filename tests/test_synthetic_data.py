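import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fpscan.colocalize import candidate_genes, project, read_gene_annotation, read_qtl_table
from fpscan.ibd_scan import find_tag_loci, gene_diversity
from fpscan.phenotypes import derive_traits
from fpscan.synthetic_data import (
    DePlan, PlantedSegment, QtnPlan, SimConfig, simulate_expression,
    simulate_organ_expression, simulate_panel, simulate_phenotypes,
    write_all, write_annotation,
)
from fpscan.expression import coexpression_network, group_de, normalize_log2
from fpscan.ibd_scan import IbdSegment


def _planted_masks(g, truth):
    masks = {}
    chrom = g.markers["chrom"].to_numpy()
    pos = g.markers["pos_bp"].to_numpy()
    for _, seg in truth.segments.iterrows():
        in_seg = (chrom == seg["chrom"]) & (pos >= seg["start_bp"]) & (pos <= seg["end_bp"])
        for grp in seg["groups"].split(","):
            masks[grp] = masks.get(grp, np.zeros(len(pos), bool)) | in_seg
    return masks


class TestPanel:
    def test_planted_segment_zero_diversity_without_noise(self):
        cfg = SimConfig.ci_scale(seed=11, missing_rate=0.0, het_rate=0.0,
                                 n_markers=3000)
        g, truth = simulate_panel(cfg)
        masks = _planted_masks(g, truth)
        for grp in cfg.groups:
            dp = gene_diversity(g, g.group_line_ids(grp), group=grp)
            assert np.all(dp.gd[masks[grp]] == 0.0)

    def test_planted_markers_remain_tags_after_missingness(self, ci_panel):
        cfg, g, truth = ci_panel
        masks = _planted_masks(g, truth)
        for grp in cfg.groups:
            dp = gene_diversity(g, g.group_line_ids(grp), group=grp)
            tags = {(t.chrom, t.pos_bp) for t in find_tag_loci(dp)}
            planted = list(zip(g.markers["chrom"][masks[grp]],
                               g.markers["pos_bp"][masks[grp]]))
            frac = np.mean([p in tags for p in planted])
            assert frac >= 0.99

    def test_rho_zero_degenerate_all_tags(self):
        cfg = SimConfig.ci_scale(seed=12, rho=0.0, missing_rate=0.0,
                                 het_rate=0.0, n_markers=1000,
                                 planted_segments=[], qtn_plan=[])
        g, _ = simulate_panel(cfg)
        for grp in cfg.groups:
            dp = gene_diversity(g, g.group_line_ids(grp), group=grp)
            assert np.all(dp.gd == 0.0)

    def test_background_gd_near_target(self, ci_panel):
        cfg, g, truth = ci_panel
        masks = _planted_masks(g, truth)
        for grp in cfg.groups:
            dp = gene_diversity(g, g.group_line_ids(grp), group=grp)
            bg = dp.gd[~masks[grp]]
            assert abs(np.nanmean(bg) - cfg.background_gd_target) < 0.05

    def test_empty_planted_segment_rejected(self):
        cfg = SimConfig.ci_scale(
            seed=13, n_markers=50,
            planted_segments=[PlantedSegment("1", 1, 5, ("B73",))])
        with pytest.raises(ValueError, match="zero markers"):
            simulate_panel(cfg)


class TestPhenotypes:
    def test_zero_plan_zero_noise_gives_group_means(self):
        cfg = SimConfig.ci_scale(
            seed=14, n_markers=500, planted_segments=[], qtn_plan=[], traits=("EH",),
            sigma2_polygenic=0.0, sigma2_env=0.0, sigma2_gxe=0.0,
            sigma2_resid=0.0, group_shifts={"EH": {"B73": 3.0, "HZS": -1.0}},
            n_envs=2)
        g, truth = simulate_panel(cfg)
        p = simulate_phenotypes(g, truth, cfg)
        merged = p.merge(g.lines, on="line_id")
        for grp, expect in [("B73", 3.0), ("HZS", -1.0), ("207", 0.0)]:
            vals = merged.loc[merged["group"] == grp, "value"]
            np.testing.assert_allclose(vals, expect, atol=1e-12)

    def test_qtn_explains_configured_variance_fraction(self):
        cfg = SimConfig.ci_scale(
            seed=15, n_markers=600, lines_per_group=(45, 45, 45, 45),
            traits=("EH",), n_envs=2,
            planted_segments=[PlantedSegment("1", 1_000_001, 1_200_000, ("B73",))],
            qtn_plan=[QtnPlan(0, "EH", 0.25)])
        g, truth = simulate_panel(cfg)
        qtn = truth.qtns.loc[truth.qtns["trait"] == "EH"].iloc[0]
        p = simulate_phenotypes(g, truth, cfg)
        line_means = p.loc[p["trait"] == "EH"].groupby("line_id")["value"].mean()
        j = g.markers.index[g.markers["marker_id"] == qtn["marker_id"]][0]
        x = g.dosage()[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        order = [g.line_ids.index(l) for l in line_means.index]
        r2 = np.corrcoef(x[order], line_means.to_numpy())[0, 1] ** 2
        assert 0.15 < r2 < 0.35

    def test_asi_pipeline_identity(self):
        cfg = SimConfig.ci_scale(seed=16, n_markers=400, planted_segments=[],
                                 qtn_plan=[], traits=("DTS", "DTP"), n_envs=2)
        g, truth = simulate_panel(cfg)
        p = simulate_phenotypes(g, truth, cfg)
        out = derive_traits(p)
        wide = out.pivot_table(index=["line_id", "env", "rep"], columns="trait",
                               values="value")
        np.testing.assert_allclose(wide["ASI"], wide["DTS"] - wide["DTP"],
                                   atol=1e-12)

    def test_oversubscribed_variance_rejected(self):
        cfg = SimConfig.ci_scale(seed=17, n_markers=400, planted_segments=[],
                                 qtn_plan=[], traits=("EH",), n_envs=2)
        g, truth = simulate_panel(cfg)
        truth.qtns = pd.DataFrame([
            {"marker_id": g.markers["marker_id"].iat[5], "chrom": "1",
             "pos_bp": 1, "trait": "EH", "h2": 0.6, "segment_index": 0},
            {"marker_id": g.markers["marker_id"].iat[6], "chrom": "1",
             "pos_bp": 2, "trait": "EH", "h2": 0.5, "segment_index": 0},
        ])
        with pytest.raises(ValueError, match="sum >= 1"):
            simulate_phenotypes(g, truth, cfg)


class TestExpression:
    def test_planted_shift_recovered(self, ci_panel):
        cfg, _, truth = ci_panel
        e = normalize_log2(simulate_expression(truth, cfg), pseudocount=1.0)
        first = True
        for _, row in truth.de_genes.iterrows():
            grp, gene, shift = row["group"], row["gene"], row["log2_shift"]
            other = next(x for x in cfg.groups if x != grp)
            de = group_de(e, (grp, other), alpha=1.0)
            est = de.set_index("gene").at[gene, "log2_fold_change"]
            # sd of the mean difference is 0.5*sqrt(2/9) ~ 0.24; the first
            # gene gets the tight 2-sigma check, the full set a 3-sigma one
            assert abs(est - shift) < (0.5 if first else 0.75)
            first = False

    def test_null_fpr_without_plan(self):
        cfg = SimConfig.ci_scale(seed=18, de_plan=[], n_genes=800,
                                 planted_segments=[], qtn_plan=[])
        _, truth = simulate_panel(cfg)
        e = normalize_log2(simulate_expression(truth, cfg))
        de = group_de(e, ("B73", "HZS"), alpha=0.05)
        rate = len(de) / cfg.n_genes
        ci = 1.96 * np.sqrt(0.05 * 0.95 / cfg.n_genes)
        assert abs(rate - 0.05) < ci + 1e-9

    def test_organ_block_edges_recovered(self, ci_panel):
        cfg, _, truth = ci_panel
        e = normalize_log2(simulate_organ_expression(truth, cfg))
        block = [f"GENE{i + 1:04d}" for i in range(cfg.coexpr_block_size)]
        edges = coexpression_network(e, gene_set=block, r_min=0.8)
        assert len(edges) >= 9  # of the 10 within-block pairs


class TestAnnotation:
    def test_gene_distances_drive_candidate_calls(self, ci_panel, tmp_path):
        cfg, g, truth = ci_panel
        gff = tmp_path / "ann.gff3"
        qtl = tmp_path / "qtl.tsv"
        write_annotation(truth, cfg, gff, qtl)
        ann = read_gene_annotation(gff)
        # treat each planted segment as a called segment with tags at its markers
        seg0 = truth.segments.iloc[0]
        chrom = g.markers["chrom"].to_numpy()
        pos = g.markers["pos_bp"].to_numpy()
        in_seg = (chrom == seg0["chrom"]) & (pos >= seg0["start_bp"]) & \
                 (pos <= seg0["end_bp"])
        from fpscan.ibd_scan import TagLocus
        tags = [TagLocus("x", seg0["chrom"], int(p), f"t{p}", 30)
                for p in pos[in_seg]]
        seg = IbdSegment("x", seg0["chrom"], int(seg0["start_bp"]),
                         int(seg0["end_bp"]), tags, 0.0, len(tags))
        out = candidate_genes([seg], ann, radius_bp=25_000)
        ids = set(out["gene_id"])
        assert "GENE_S000_d0" in ids
        assert "GENE_S000_d10k" in ids
        assert "GENE_S000_d30k" not in ids

    def test_qtl_overlaps_qtn_segment_for_both_class(self, ci_panel, tmp_path):
        cfg, g, truth = ci_panel
        gff = tmp_path / "ann.gff3"
        qtl_path = tmp_path / "qtl.tsv"
        write_annotation(truth, cfg, gff, qtl_path)
        qtls = read_qtl_table(qtl_path)
        qtn = truth.qtns.iloc[0]
        seg_row = truth.segments.iloc[int(qtn["segment_index"])]
        seg = IbdSegment("x", seg_row["chrom"], int(seg_row["start_bp"]),
                         int(seg_row["end_bp"]), [], 0.0, 0)
        qtns = truth.qtns.rename(columns={"marker_id": "marker_id"})
        supported = project([seg], qtns, qtls)
        assert supported and supported[0].support_class == "both"


class TestDeterminism:
    def test_write_all_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig.ci_scale(
            seed=19, n_markers=1500, n_genes=40, n_envs=2,
            traits=("EH", "DTS", "DTP"),
            planted_segments=[PlantedSegment("1", 100_001, 300_000, ("B73",)),
                              PlantedSegment("2", 100_001, 260_000, ("HZS", "207"))],
            qtn_plan=[QtnPlan(0, "EH", 0.2)])
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        p1 = write_all(cfg, d1)
        p2 = write_all(cfg, d2)
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        cfg_a = SimConfig.ci_scale(seed=20, n_markers=800,
                                   planted_segments=[], qtn_plan=[])
        cfg_b = SimConfig.ci_scale(seed=21, n_markers=800,
                                   planted_segments=[], qtn_plan=[])
        ga, _ = simulate_panel(cfg_a)
        gb, _ = simulate_panel(cfg_b)
        assert not np.array_equal(ga.calls, gb.calls)

    def test_truth_json_round_trip(self, tmp_path):
        cfg = SimConfig.ci_scale(seed=22)
        _, truth = simulate_panel(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        from fpscan.synthetic_data import TruthSet
        back = TruthSet.from_json(path)
        pd.testing.assert_frame_equal(
            back.segments[truth.segments.columns], truth.segments)
        pd.testing.assert_frame_equal(back.qtns[truth.qtns.columns], truth.qtns)
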