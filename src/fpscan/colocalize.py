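"""Co-localization of IBD segments with QTNs, literature QTLs and genes.

All features live in one physical coordinate frame (1-based inclusive bp
on a single reference build). A QTN supports a segment when its position
lies inside the segment; a QTL supports it when the intervals share at
least one base. Segments supported by both are the important candidate
regions. Genes whose body lies within ``radius_bp`` (default 25 kb,
motivated by the panel's average linkage disequilibrium extent) of a
segment's tag SNP are tightly linked candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, interval_overlap
from .ibd_scan import IbdSegment
from .phenotypes import TRAIT_CATEGORIES

QTL_COLUMNS = ["name", "trait", "chrom", "start_bp", "end_bp", "source"]


@dataclass
class SupportedSegment:
    segment: IbdSegment
    qtns: pd.DataFrame
    qtls: pd.DataFrame
    support_class: str  # qtn_only | qtl_only | both

    @property
    def n_features(self) -> int:
        return len(self.qtns) + len(self.qtls)


@dataclass
class GeneCluster:
    segment: IbdSegment
    features: pd.DataFrame       # kind, name, trait, position columns
    trait_categories: list[str] = field(default_factory=list)


def read_qtl_table(path) -> pd.DataFrame:
    """BED-like TSV of literature QTLs: name, trait, chrom, start_bp, end_bp, source."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(QTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    return df[QTL_COLUMNS]


def _check_chroms(known: set, frames: list[pd.DataFrame]):
    unknown = set()
    for df in frames:
        if df is not None and len(df):
            unknown |= set(df["chrom"].astype(str)) - known
    if unknown:
        raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")


def project(segments: list[IbdSegment], qtns: pd.DataFrame,
            qtls: pd.DataFrame, chromosomes=None) -> list[SupportedSegment]:
    """Project QTNs and QTLs onto IBD segments; emit supported segments only.

    ``chromosomes`` optionally declares the coordinate frame; QTN/QTL
    chromosome labels outside it raise an error.
    """
    if chromosomes is not None:
        _check_chroms(set(map(str, chromosomes)), [qtns, qtls])
    out = []
    for seg in segments:
        if qtns is not None and len(qtns):
            qmask = (qtns["chrom"].astype(str) == str(seg.chrom)) & \
                    (qtns["pos_bp"] >= seg.start_bp) & (qtns["pos_bp"] <= seg.end_bp)
            seg_qtns = qtns.loc[qmask].reset_index(drop=True)
        else:
            seg_qtns = pd.DataFrame(columns=["marker_id", "trait", "chrom", "pos_bp"])
        if qtls is not None and len(qtls):
            lmask = (qtls["chrom"].astype(str) == str(seg.chrom)) & \
                    (qtls["start_bp"] <= seg.end_bp) & (qtls["end_bp"] >= seg.start_bp)
            seg_qtls = qtls.loc[lmask].reset_index(drop=True)
        else:
            seg_qtls = pd.DataFrame(columns=QTL_COLUMNS)
        if len(seg_qtns) and len(seg_qtls):
            cls = "both"
        elif len(seg_qtns):
            cls = "qtn_only"
        elif len(seg_qtls):
            cls = "qtl_only"
        else:
            continue
        out.append(SupportedSegment(seg, seg_qtns, seg_qtls, cls))
    return out


def find_clusters(supported: list[SupportedSegment],
                  min_loci: int = 3) -> list[GeneCluster]:
    """Segments carrying >= ``min_loci`` QTN/QTL features (counted together)."""
    clusters = []
    for ss in supported:
        if ss.n_features < min_loci:
            continue
        feats = []
        for _, q in ss.qtns.iterrows():
            feats.append({"kind": "qtn", "name": q.get("marker_id", ""),
                          "trait": q.get("trait", ""), "start_bp": q["pos_bp"],
                          "end_bp": q["pos_bp"]})
        for _, q in ss.qtls.iterrows():
            feats.append({"kind": "qtl", "name": q["name"], "trait": q["trait"],
                          "start_bp": q["start_bp"], "end_bp": q["end_bp"]})
        fdf = pd.DataFrame(feats).sort_values("start_bp").reset_index(drop=True)
        cats = sorted({TRAIT_CATEGORIES.get(t, "other") for t in fdf["trait"] if t})
        clusters.append(GeneCluster(ss.segment, fdf, cats))
    return clusters


# ---------------------------------------------------------------------------
# candidate genes

def read_gene_annotation(path) -> pd.DataFrame:
    """Gene features from a GFF3 file (gene_id, chrom, start_bp, end_bp, strand)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"gene_id": gid, "chrom": str(feat.seqid),
                     "start_bp": feat.start, "end_bp": feat.end,
                     "strand": feat.strand})
    if not rows:
        raise ValueError("annotation contains no gene features")
    return pd.DataFrame(rows)


def _gene_tag_distance(gene_start, gene_end, tag_pos) -> int:
    if gene_start <= tag_pos <= gene_end:
        return 0
    return int(min(abs(gene_start - tag_pos), abs(gene_end - tag_pos)))


def candidate_genes(segments: list[IbdSegment], annotation: pd.DataFrame,
                    radius_bp: int = 25_000,
                    qtns: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genes within ``radius_bp`` of a segment's tag SNPs.

    A gene qualifies when the minimum distance from some tag SNP of the
    segment to the gene interval is <= ``radius_bp`` (0 when the tag lies
    inside the gene). Each gene is reported once per segment with its
    nearest anchoring tag; when ``qtns`` is given, the nearest QTN inside
    the same segment is attached.
    """
    if annotation is None or not len(annotation):
        raise ValueError("empty gene annotation")
    if radius_bp <= 0:
        raise ValueError("radius_bp must be positive")
    rows = []
    for seg in segments:
        genes = annotation.loc[annotation["chrom"].astype(str) == str(seg.chrom)]
        if not len(genes) or not seg.tag_loci:
            continue
        tag_pos = np.array([t.pos_bp for t in seg.tag_loci])
        seg_qtns = None
        if qtns is not None and len(qtns):
            qmask = (qtns["chrom"].astype(str) == str(seg.chrom)) & \
                    (qtns["pos_bp"] >= seg.start_bp) & (qtns["pos_bp"] <= seg.end_bp)
            seg_qtns = qtns.loc[qmask]
        for _, gene in genes.iterrows():
            dists = [_gene_tag_distance(gene["start_bp"], gene["end_bp"], tp)
                     for tp in tag_pos]
            best = int(np.argmin(dists))
            if dists[best] > radius_bp:
                continue
            rec = {"gene_id": gene["gene_id"], "chrom": seg.chrom,
                   "start_bp": int(gene["start_bp"]), "end_bp": int(gene["end_bp"]),
                   "strand": gene.get("strand", "."), "group": seg.group,
                   "anchor_tag": seg.tag_loci[best].marker_id,
                   "anchor_pos_bp": int(tag_pos[best]),
                   "distance_bp": int(dists[best]),
                   "segment_start_bp": seg.start_bp, "segment_end_bp": seg.end_bp,
                   "linked_qtn": None, "linked_qtn_trait": None}
            if seg_qtns is not None and len(seg_qtns):
                mid = (gene["start_bp"] + gene["end_bp"]) / 2
                qi = (seg_qtns["pos_bp"] - mid).abs().idxmin()
                rec["linked_qtn"] = seg_qtns.at[qi, "marker_id"]
                rec["linked_qtn_trait"] = seg_qtns.at[qi, "trait"] if "trait" in seg_qtns else None
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start_bp", "gene_id"], key=lambda c: (
            c.map(chrom_sort_key) if c.name == "chrom" else c)).reset_index(drop=True)
    return df


def supported_to_frame(supported: list[SupportedSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.segment.group, "chrom": s.segment.chrom,
        "start_bp": s.segment.start_bp, "end_bp": s.segment.end_bp,
        "n_qtns": len(s.qtns), "n_qtls": len(s.qtls),
        "support_class": s.support_class,
    } for s in supported])
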