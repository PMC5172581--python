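"""Identity-by-descent segment detection by within-group diversity suppression.

For each foundation-parent (FP) group the scan computes Nei's gene diversity
GD = 1 - sum(p^2) at every SNP from the group's lines, anchors candidate
windows of +/- ``half_window_bp`` (default 25 kb) on *tag loci* (SNPs with
GD exactly 0), and accepts a window when its mean GD falls strictly below
the chromosome-specific threshold

    mean(GD over the chromosome) - 0.5 * SD(GD over the chromosome),

both statistics taken over that group's per-marker GD values. Accepted
windows on a chromosome are merged (overlap or bookend) into IBD segments.
Segment sets from several groups are partitioned into group-combination
classes (group-specific, shared pairwise/triple, common to all) over the
union interval set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, interval_overlap, merge_intervals
from .genotype_io import GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_HALF_WINDOW_BP = 25_000
DEFAULT_MIN_CALLS = 4


@dataclass
class DiversityProfile:
    """Per-marker gene diversity for one FP group, plus chromosome stats."""

    group: str
    markers: pd.DataFrame          # marker map (shares order with gd)
    gd: np.ndarray                 # per-marker GD, NaN where < min_calls
    n_nonmissing: np.ndarray
    min_calls: int
    chrom_stats: pd.DataFrame = field(default=None)  # chrom, mean_gd, sd_gd, n

    def __post_init__(self):
        if self.chrom_stats is None:
            rows = []
            for chrom in self.markers["chrom"].unique():
                mask = (self.markers["chrom"] == chrom).to_numpy()
                vals = self.gd[mask]
                vals = vals[~np.isnan(vals)]
                rows.append({
                    "chrom": chrom,
                    "mean_gd": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd_gd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                })
            self.chrom_stats = pd.DataFrame(rows)


@dataclass(frozen=True)
class TagLocus:
    group: str
    chrom: str
    pos_bp: int
    marker_id: str
    n_nonmissing: int


@dataclass
class IbdSegment:
    """A maximal run of accepted low-diversity windows for one group."""

    group: str
    chrom: str
    start_bp: int
    end_bp: int
    tag_loci: list[TagLocus]
    mean_window_gd: float
    n_markers: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class VennPartition:
    """Union intervals across groups labeled with the groups supporting them."""

    groups: list[str]
    intervals: pd.DataFrame  # chrom, start_bp, end_bp, label (frozenset of groups)

    @property
    def counts_exact(self) -> dict[frozenset, int]:
        out: dict[frozenset, int] = {}
        for lab in self.intervals["label"]:
            out[lab] = out.get(lab, 0) + 1
        return out

    def count_at_least(self, subset) -> int:
        """Union intervals supported by every group in ``subset`` (and maybe more)."""
        s = frozenset(subset)
        return int(sum(1 for lab in self.intervals["label"] if s <= lab))

    def specific_count(self, group: str) -> int:
        return int(sum(1 for lab in self.intervals["label"] if lab == frozenset([group])))

    def group_total(self, group: str) -> int:
        return self.count_at_least([group])

    def class_counts(self) -> pd.DataFrame:
        """Per-class table: specific per group, then common-to-k for all subsets."""
        rows = [{"class": f"specific:{g}", "count": self.specific_count(g)}
                for g in self.groups]
        for k in range(2, len(self.groups) + 1):
            for sub in combinations(self.groups, k):
                rows.append({"class": "common:" + "+".join(sub),
                             "count": self.count_at_least(sub)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene diversity

def gene_diversity(g: GenotypeMatrix, group_lines,
                   min_calls: int = DEFAULT_MIN_CALLS,
                   group: str = "") -> DiversityProfile:
    """Nei gene diversity per marker over the given group's lines.

    Allele frequencies are computed from non-missing alleles, a heterozygote
    contributing one of each allele; GD = 1 - p^2 - q^2, the probability
    that two alleles drawn at random (with replacement) from the group
    differ. Markers with fewer than ``min_calls`` non-missing lines get
    missing GD.
    """
    group_lines = list(group_lines)
    if not group_lines:
        raise ValueError("empty group")
    sub = g.subset_lines(group_lines)
    d = sub.dosage()
    n_nonmiss = np.sum(~np.isnan(d), axis=0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_nonmiss)
        gd = 1.0 - p**2 - (1.0 - p) ** 2
    gd[n_nonmiss < min_calls] = np.nan
    # exact zero for monomorphic markers despite float arithmetic
    gd[np.abs(gd) < 1e-15] = 0.0
    return DiversityProfile(group or "+".join(map(str, group_lines[:1])),
                            g.markers, gd, n_nonmiss, min_calls)


def find_tag_loci(dp: DiversityProfile, min_calls: int | None = None) -> list[TagLocus]:
    """Markers with GD exactly zero and enough non-missing calls, in map order."""
    mc = dp.min_calls if min_calls is None else min_calls
    out = []
    idx = np.where((dp.gd == 0.0) & (dp.n_nonmissing >= mc))[0]
    for i in idx:
        m = dp.markers.iloc[i]
        out.append(TagLocus(dp.group, str(m["chrom"]), int(m["pos_bp"]),
                            str(m["marker_id"]), int(dp.n_nonmissing[i])))
    return out


def window_mean_gd(dp: DiversityProfile, tag: TagLocus,
                   half_window_bp: int = DEFAULT_HALF_WINDOW_BP) -> float:
    """Mean GD over markers within ``half_window_bp`` of the tag (tag included)."""
    chrom_mask = (dp.markers["chrom"] == tag.chrom).to_numpy()
    pos = dp.markers["pos_bp"].to_numpy()
    in_win = chrom_mask & (np.abs(pos - tag.pos_bp) <= half_window_bp)
    vals = dp.gd[in_win]
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals))


def chromosome_threshold(dp: DiversityProfile, chrom) -> float:
    """Acceptance threshold mean_gd(chrom) - 0.5 * sd_gd(chrom) (sample SD)."""
    row = dp.chrom_stats.loc[dp.chrom_stats["chrom"] == chrom]
    if row.empty or row["n"].iat[0] < 2:
        raise ValueError(f"chromosome {chrom}: fewer than 2 usable markers")
    thr = float(row["mean_gd"].iat[0] - 0.5 * row["sd_gd"].iat[0])
    if thr <= 0:
        log.warning("chromosome %s: threshold %.4f <= 0, no window can pass", chrom, thr)
    return thr


def call_segments(dp: DiversityProfile, tags: list[TagLocus] | None = None,
                  half_window_bp: int = DEFAULT_HALF_WINDOW_BP) -> list[IbdSegment]:
    """Accept tag windows below the chromosome threshold and merge them.

    Each tag anchors a candidate interval [pos - hw, pos + hw], clipped to
    the chromosome's marker extent. The candidate is accepted iff the mean
    GD of markers in the window is strictly below the chromosome threshold.
    Overlapping or bookended accepted intervals merge into one segment whose
    ``mean_window_gd`` is the marker-count-weighted mean of its windows.
    """
    if tags is None:
        tags = find_tag_loci(dp)
    segments: list[IbdSegment] = []
    chroms = sorted({t.chrom for t in tags}, key=chrom_sort_key)
    pos_all = dp.markers["pos_bp"].to_numpy()
    chrom_all = dp.markers["chrom"].to_numpy()
    for chrom in chroms:
        cmask = chrom_all == chrom
        cpos = pos_all[cmask]
        cgd = dp.gd[cmask]
        thr = chromosome_threshold(dp, chrom)
        lo_ext, hi_ext = int(cpos[0]), int(cpos[-1])
        ctags = sorted((t for t in tags if t.chrom == chrom), key=lambda t: t.pos_bp)
        accepted = []  # (start, end, mean_gd, n_markers, tag)
        for t in ctags:
            i0 = np.searchsorted(cpos, t.pos_bp - half_window_bp, side="left")
            i1 = np.searchsorted(cpos, t.pos_bp + half_window_bp, side="right")
            vals = cgd[i0:i1]
            vals = vals[~np.isnan(vals)]
            mean_gd = float(np.mean(vals))
            if mean_gd < thr:
                accepted.append((max(t.pos_bp - half_window_bp, lo_ext),
                                 min(t.pos_bp + half_window_bp, hi_ext),
                                 mean_gd, len(vals), t))
        if not accepted:
            continue
        cur = None
        for start, end, mgd, nm, t in accepted:
            if cur is not None and start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], end)
                cur["gd_sum"] += mgd * nm
                cur["n"] += nm
                cur["tags"].append(t)
            else:
                if cur is not None:
                    segments.append(_finish_segment(dp.group, chrom, cur))
                cur = {"start": start, "end": end, "gd_sum": mgd * nm, "n": nm, "tags": [t]}
        segments.append(_finish_segment(dp.group, chrom, cur))
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start_bp))
    return segments


def _finish_segment(group, chrom, cur) -> IbdSegment:
    return IbdSegment(group, chrom, int(cur["start"]), int(cur["end"]),
                      cur["tags"], cur["gd_sum"] / cur["n"], int(cur["n"]))


def scan_group(g: GenotypeMatrix, group: str,
               half_window_bp: int = DEFAULT_HALF_WINDOW_BP,
               min_calls: int = DEFAULT_MIN_CALLS) -> list[IbdSegment]:
    """Convenience: gene diversity -> tag loci -> segments for one group."""
    ids = g.group_line_ids(group)
    dp = gene_diversity(g, ids, min_calls=min_calls, group=group)
    return call_segments(dp, find_tag_loci(dp), half_window_bp)


# ---------------------------------------------------------------------------
# venn partition over union intervals

def venn_partition(segment_sets: dict[str, list[IbdSegment]],
                   overlap_rule: str = "any_overlap",
                   reciprocal_f: float = 0.5) -> VennPartition:
    """Partition group segment sets into group-combination classes.

    The union interval set is built across all groups (maximal runs of
    covered bases, bookend-merged); each union interval is labeled with the
    subset of groups having at least one segment satisfying the overlap
    rule with it. ``any_overlap`` requires >= 1 shared base;
    ``reciprocal`` requires the shared bases to be >= ``reciprocal_f`` of
    both the segment and the union interval.
    """
    if len(segment_sets) < 2:
        raise ValueError("need at least two groups")
    if overlap_rule not in ("any_overlap", "reciprocal"):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    groups = list(segment_sets)
    by_chrom: dict[str, list] = {}
    for grp, segs in segment_sets.items():
        for s in segs:
            if s.group not in segment_sets:
                raise ValueError(f"segment group {s.group!r} not among declared groups")
            by_chrom.setdefault(s.chrom, []).append((s.start_bp, s.end_bp, grp))
    rows = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        entries = by_chrom[chrom]
        union = merge_intervals([(s, e) for s, e, _ in entries], bookend=True)
        for us, ue in union:
            label = set()
            for s, e, grp in entries:
                ov = interval_overlap(s, e, us, ue)
                if ov == 0:
                    continue
                if overlap_rule == "any_overlap":
                    label.add(grp)
                else:
                    if ov >= reciprocal_f * (e - s + 1) and ov >= reciprocal_f * (ue - us + 1):
                        label.add(grp)
            rows.append({"chrom": chrom, "start_bp": us, "end_bp": ue,
                         "label": frozenset(label)})
    return VennPartition(groups, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# export

def segments_to_frame(segments: list[IbdSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "chrom": s.chrom, "start_bp": s.start_bp,
        "end_bp": s.end_bp, "mean_gd": s.mean_window_gd,
        "n_markers": s.n_markers, "n_tags": len(s.tag_loci),
    } for s in segments])


def write_segments_bed(segments: list[IbdSegment], path) -> None:
    """BED-like TSV export (0-based half-open coordinates in the file)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgroup\tmean_gd\tn_tags\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.group}"
                     f"\t{s.mean_window_gd:.6f}\t{len(s.tag_loci)}\n")


def frame_diagram_table(profiles: dict[str, DiversityProfile],
                        segments: dict[str, list[IbdSegment]]) -> pd.DataFrame:
    """Per-chromosome data behind the genetic frame diagram: one row per
    segment with group, coordinates and mean GD (plot-ready)."""
    rows = []
    for grp, segs in segments.items():
        for s in segs:
            rows.append({"group": grp, "chrom": s.chrom, "start_bp": s.start_bp,
                         "end_bp": s.end_bp, "mean_gd": s.mean_window_gd})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "start_bp"], key=lambda c: (
            c.map(chrom_sort_key) if c.name == "chrom" else c)).reset_index(drop=True)
    return df
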