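import numpy as np
import pandas as pd
import pytest

from fpscan.genotype_io import MISSING
from fpscan.ibd_scan import (
    DiversityProfile, IbdSegment, call_segments, chromosome_threshold,
    find_tag_loci, gene_diversity, scan_group, venn_partition, window_mean_gd,
)

from conftest import make_matrix


def _profile(gd, pos=None, chrom=None, group="G"):
    gd = np.asarray(gd, dtype=float)
    m = len(gd)
    markers = pd.DataFrame({
        "marker_id": [f"M{j:03d}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": "A", "alt": "G",
    })
    return DiversityProfile(group, markers, gd, np.full(m, 30), 4)


class TestGeneDiversity:
    def test_monomorphic_marker_zero(self):
        g = make_matrix(np.zeros((6, 1), dtype=np.int8))
        dp = gene_diversity(g, g.line_ids)
        assert dp.gd[0] == 0.0

    def test_half_frequency_gives_half(self):
        calls = np.array([[0], [0], [2], [2]], dtype=np.int8)
        dp = gene_diversity(make_matrix(calls), [f"L{i:02d}" for i in range(4)])
        assert dp.gd[0] == pytest.approx(0.5)

    def test_hand_enumerated_with_missing(self):
        # alleles A x6, G x2 among 4 non-missing lines (1 missing):
        # GD = 1 - 0.75^2 - 0.25^2 = 0.375
        calls = np.array([[0], [0], [1], [1], [MISSING]], dtype=np.int8)
        dp = gene_diversity(make_matrix(calls), [f"L{i:02d}" for i in range(5)])
        assert dp.gd[0] == pytest.approx(0.375)

    def test_matches_bruteforce_allele_tally(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([0, 1, 2, MISSING], size=(10, 60),
                           p=[0.45, 0.05, 0.4, 0.1]).astype(np.int8)
        g = make_matrix(calls)
        dp = gene_diversity(g, g.line_ids, min_calls=1)
        for j in range(60):
            counts = {"r": 0, "a": 0}
            for c in calls[:, j]:
                if c != MISSING:
                    counts["a"] += int(c)
                    counts["r"] += 2 - int(c)
            tot = counts["r"] + counts["a"]
            expect = 1 - (counts["r"] / tot) ** 2 - (counts["a"] / tot) ** 2
            assert dp.gd[j] == pytest.approx(expect, abs=1e-12)

    def test_invariance_to_allele_swap_and_line_order(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        g = make_matrix(calls)
        gd1 = gene_diversity(g, g.line_ids).gd
        swapped = (2 - calls).astype(np.int8)
        gd2 = gene_diversity(make_matrix(swapped), g.line_ids).gd
        perm = rng.permutation(8)
        gd3 = gene_diversity(make_matrix(calls[perm]), g.line_ids).gd
        np.testing.assert_allclose(gd1, gd2, atol=1e-12)
        np.testing.assert_allclose(gd1, gd3, atol=1e-12)

    def test_empty_group_error(self):
        g = make_matrix(np.zeros((3, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="empty"):
            gene_diversity(g, [])


class TestTagLoci:
    def test_min_calls_guard(self):
        calls = np.full((5, 1), MISSING, dtype=np.int8)
        calls[0, 0] = 0  # GD 0 but one call only
        dp = gene_diversity(make_matrix(calls), [f"L{i:02d}" for i in range(5)],
                            min_calls=4)
        assert find_tag_loci(dp) == []

    def test_counts_monomorphic_columns(self):
        rng = np.random.default_rng(14)
        calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        mono_cols = rng.choice(50, 7, replace=False)
        calls[:, mono_cols] = 0
        # ensure the other columns are polymorphic
        for j in range(50):
            if j not in mono_cols and len(set(calls[:, j])) == 1:
                calls[0, j] = (calls[0, j] + 1) % 3
        g = make_matrix(calls)
        tags = find_tag_loci(gene_diversity(g, g.line_ids))
        assert len(tags) == 7
        assert {t.marker_id for t in tags} == {f"M{j:03d}" for j in sorted(mono_cols)}


class TestWindowsAndThreshold:
    def test_window_only_tag(self):
        dp = _profile([0.0, 0.5], pos=[1000, 200_000])
        tag = find_tag_loci(dp)[0]
        assert window_mean_gd(dp, tag) == 0.0

    def test_window_arithmetic_mean(self):
        dp = _profile([0.0, 0.1, 0.2], pos=[1000, 2000, 3000])
        tag = find_tag_loci(dp)[0]
        assert window_mean_gd(dp, tag) == pytest.approx(0.1)

    def test_window_equals_naive_rescan(self):
        rng = np.random.default_rng(15)
        m = 300
        pos = np.sort(rng.choice(2_000_000, m, replace=False)) + 1
        gd = rng.random(m).round(3)
        gd[rng.choice(m, 20, replace=False)] = 0.0
        dp = _profile(gd, pos=pos)
        for tag in find_tag_loci(dp):
            naive = np.mean([g for p, g in zip(pos, gd) if abs(p - tag.pos_bp) <= 25_000])
            assert window_mean_gd(dp, tag) == pytest.approx(naive, abs=1e-12)

    def test_threshold_fixture(self):
        dp = _profile([0.0, 0.1, 0.2, 0.3, 0.4])
        assert chromosome_threshold(dp, "1") == pytest.approx(0.12094, abs=1e-5)

    def test_constant_gd_threshold_is_constant(self):
        dp = _profile([0.25] * 5)
        assert chromosome_threshold(dp, "1") == pytest.approx(0.25)

    def test_threshold_matches_two_pass_computation(self):
        rng = np.random.default_rng(16)
        gd = rng.random(500)
        dp = _profile(gd)
        mean = sum(gd) / len(gd)
        sd = np.sqrt(sum((x - mean) ** 2 for x in gd) / (len(gd) - 1))
        assert chromosome_threshold(dp, "1") == pytest.approx(mean - 0.5 * sd, abs=1e-12)

    def test_too_few_markers_error(self):
        dp = _profile([0.2])
        with pytest.raises(ValueError, match="fewer than 2"):
            chromosome_threshold(dp, "1")


def _segment_profile():
    """Background GD 0.5, two low-GD pockets around tags; 1 kb marker grid."""
    m = 400
    pos = (np.arange(m) + 1) * 1000
    gd = np.full(m, 0.5)
    for center in (100, 300):  # marker indices
        gd[center - 26:center + 26] = 0.0
    return _profile(gd, pos=pos)


class TestCallSegments:
    def test_nearby_accepted_tags_merge(self):
        dp = _profile(np.r_[np.zeros(61), np.full(200, 0.5)],
                      pos=np.r_[(np.arange(61) + 1) * 500,
                                100_000 + (np.arange(200) + 1) * 2000])
        segs = call_segments(dp)
        assert len(segs) == 1
        assert segs[0].start_bp == 500  # clipped at marker extent

    def test_distant_tags_stay_separate(self):
        dp = _segment_profile()
        segs = call_segments(dp)
        assert len(segs) == 2
        # windows are +/-25 kb around the outermost tags of each pocket
        assert segs[0].end_bp < segs[1].start_bp

    def test_merge_is_order_independent(self):
        dp = _segment_profile()
        tags = find_tag_loci(dp)
        rng = np.random.default_rng(17)
        shuffled = [tags[i] for i in rng.permutation(len(tags))]
        a = call_segments(dp, tags)
        b = call_segments(dp, shuffled)
        assert [(s.start_bp, s.end_bp) for s in a] == [(s.start_bp, s.end_bp) for s in b]

    def test_segments_validate_post_hoc(self, ci_panel):
        """Every called segment holds >=1 tag and sits below its threshold."""
        _, g, _ = ci_panel
        grp = g.groups[0]
        dp = gene_diversity(g, g.group_line_ids(grp), group=grp)
        segs = call_segments(dp)
        assert segs
        for s in segs:
            assert len(s.tag_loci) >= 1
            thr = chromosome_threshold(dp, s.chrom)
            assert s.mean_window_gd < thr
            for t in s.tag_loci:
                assert s.start_bp <= t.pos_bp <= s.end_bp


def _mk_seg(group, chrom, start, end):
    return IbdSegment(group, chrom, start, end, [], 0.0, 0)


def _venn_oracle(segment_sets, max_bp=20_000):
    """Basepair-resolution coloring oracle over small coordinates."""
    cover = {}
    for grp, segs in segment_sets.items():
        for s in segs:
            arr = cover.setdefault(s.chrom, np.zeros((len(segment_sets), max_bp), bool))
            gi = list(segment_sets).index(grp)
            arr[gi, s.start_bp - 1:s.end_bp] = True
    labels = []
    groups = list(segment_sets)
    for chrom, arr in cover.items():
        covered = arr.any(axis=0)
        j = 0
        while j < max_bp:
            if covered[j]:
                k = j
                while k < max_bp and covered[k]:
                    k += 1
                members = frozenset(groups[gi] for gi in range(len(groups))
                                    if arr[gi, j:k].any())
                labels.append(members)
                j = k
            else:
                j += 1
    return labels


class TestVennPartition:
    def test_overlapping_pair_is_common(self):
        vp = venn_partition({"A": [_mk_seg("A", "1", 100, 200)],
                             "B": [_mk_seg("B", "1", 150, 250)]})
        assert len(vp.intervals) == 1
        assert vp.intervals["label"].iloc[0] == frozenset({"A", "B"})
        assert vp.specific_count("A") == 0

    def test_disjoint_pair_is_specific(self):
        vp = venn_partition({"A": [_mk_seg("A", "1", 100, 200)],
                             "B": [_mk_seg("B", "1", 300, 400)]})
        assert vp.specific_count("A") == 1
        assert vp.specific_count("B") == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_basepair_coloring_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = ["A", "B", "C", "D"]
        segment_sets = {}
        for g in groups:
            segs = []
            for _ in range(rng.integers(3, 9)):
                chrom = str(rng.integers(1, 3))
                start = int(rng.integers(1, 19_000))
                segs.append(_mk_seg(g, chrom, start, start + int(rng.integers(50, 2000))))
            segment_sets[g] = segs
        vp = venn_partition(segment_sets)
        mine = sorted(map(sorted, vp.intervals["label"]))
        oracle = sorted(map(sorted, _venn_oracle(segment_sets)))
        assert mine == oracle

    def test_monotone_cascade_and_sum_rule(self, ci_panel):
        _, g, _ = ci_panel
        seg_sets = {grp: scan_group(g, grp) for grp in g.groups}
        vp = venn_partition(seg_sets)
        from itertools import combinations
        all4 = vp.count_at_least(g.groups)
        for trip in combinations(g.groups, 3):
            c3 = vp.count_at_least(trip)
            assert all4 <= c3
            for pair in combinations(trip, 2):
                assert c3 <= vp.count_at_least(pair)
        for grp in g.groups:
            with_grp = [lab for lab in vp.intervals["label"] if grp in lab]
            assert vp.group_total(grp) == len(with_grp)
            assert vp.specific_count(grp) + sum(1 for lab in with_grp if len(lab) > 1) \
                == vp.group_total(grp)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            venn_partition({"A": [_mk_seg("X", "1", 1, 10)],
                            "B": [_mk_seg("B", "1", 1, 10)]})
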