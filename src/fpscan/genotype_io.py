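"""SNP panel data model and I/O.

Inbred-line panels are held as a :class:`GenotypeMatrix`: a lines x markers
array of alt-allele dosages (0/1/2, -1 for missing) plus marker map
(chromosome, 1-based physical position, ref/alt alleles) and line metadata
(foundation-parent group label, co-ancestry membership).

Two on-disk dialects are supported:

* **hapmap** — tab-separated, the classic 11 metadata columns
  (``rs#, alleles, chrom, pos, strand, assembly#, center, protLSID,
  assayLSID, panelLSID, QCcode``) followed by one column per line, cells
  as nucleotide pairs (``AA``, ``AG``, ``NN``).
* **csv** — header ``marker_id,chrom,pos,ref,alt,<line ids...>`` with calls
  in {0,1,2,NA}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chrom_sort_key

log = logging.getLogger(__name__)

MISSING = np.int8(-1)

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic SNP calls.

    Attributes
    ----------
    lines : pandas.DataFrame
        Columns ``line_id``, ``group``, ``membership``; one row per line,
        in call-matrix row order.
    markers : pandas.DataFrame
        Columns ``marker_id``, ``chrom``, ``pos_bp``, ``ref``, ``alt``
        (optionally ``ambiguous``); sorted by (chrom, pos_bp), in
        call-matrix column order.
    calls : numpy.ndarray
        ``int8`` array of shape (n_lines, n_markers); alt-allele dosage
        0/1/2 or -1 for missing.
    meta : dict
        Free-form provenance (e.g. harmonization conflict counts).
    """

    lines: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"(n_lines={len(self.lines)}, n_markers={len(self.markers)})"
            )
        self.calls = np.asarray(self.calls, dtype=np.int8)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def line_ids(self) -> list[str]:
        return self.lines["line_id"].tolist()

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def line_indices(self, line_ids) -> np.ndarray:
        idx = pd.Index(self.lines["line_id"])
        loc = idx.get_indexer(list(line_ids))
        if (loc < 0).any():
            missing = [l for l, i in zip(line_ids, loc) if i < 0]
            raise KeyError(f"unknown line ids: {missing[:5]}")
        return loc

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        loc = self.line_indices(line_ids)
        return GenotypeMatrix(
            self.lines.iloc[loc].reset_index(drop=True),
            self.markers.copy(),
            self.calls[loc],
            dict(self.meta),
        )

    def subset_markers(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.lines.copy(),
            self.markers.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
            dict(self.meta),
        )

    def group_line_ids(self, group: str) -> list[str]:
        return self.lines.loc[self.lines["group"] == group, "line_id"].tolist()

    @property
    def groups(self) -> list[str]:
        gs = [g for g in self.lines["group"].unique() if g != "unassigned"]
        return sorted(gs)


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray):
    order = sorted(
        range(len(markers)),
        key=lambda i: (chrom_sort_key(markers["chrom"].iat[i]), markers["pos_bp"].iat[i]),
    )
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


def _check_duplicates(markers: pd.DataFrame):
    dup = markers.duplicated(subset=["chrom", "pos_bp"], keep=False)
    if dup.any():
        first = markers.loc[dup, ["chrom", "pos_bp"]].iloc[0]
        raise ValueError(
            f"duplicated marker position: chrom={first['chrom']} pos={first['pos_bp']}"
        )


def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a SNP panel from ``path`` in the given dialect.

    Markers are returned sorted by (chrom, pos_bp). Unknown nucleotide codes
    become missing; non-biallelic markers are dropped with a warning;
    duplicated (chrom, pos) is a hard error.
    """
    if dialect == "hapmap":
        return _read_hapmap(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df.columns) < 12:
        raise ValueError("hapmap file needs 11 metadata columns + >=1 line column")
    line_cols = list(df.columns[11:])
    n_dropped = 0
    marker_rows, call_rows = [], []
    for _, row in df.iterrows():
        alleles = [a for a in str(row.iloc[1]).split("/") if a in _COMPLEMENT]
        cells = [str(row[c]).upper() for c in line_cols]
        observed = {b for cell in cells if len(cell) == 2 for b in cell if b in _COMPLEMENT}
        allele_set = set(alleles) | observed
        if len(allele_set) > 2 or len(alleles) > 2:
            n_dropped += 1
            log.warning("dropping non-biallelic marker %s (alleles %s)", row.iloc[0], allele_set)
            continue
        if len(alleles) == 2:
            ref, alt = alleles
        elif len(allele_set) == 2:
            ref, alt = sorted(allele_set)
        else:
            # monomorphic-with-unknown-alt: keep with a placeholder alt
            ref = next(iter(allele_set)) if allele_set else "A"
            alt = next(b for b in "ACGT" if b != ref)
        calls = np.full(len(cells), MISSING, dtype=np.int8)
        for j, cell in enumerate(cells):
            if len(cell) != 2 or any(b not in (ref, alt) for b in cell):
                continue
            calls[j] = (cell[0] == alt) + (cell[1] == alt)
        marker_rows.append((str(row.iloc[0]), str(row.iloc[2]), int(row.iloc[3]), ref, alt))
        call_rows.append(calls)
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chrom", "pos_bp", "ref", "alt"])
    calls = np.array(call_rows, dtype=np.int8).T if call_rows else np.empty((len(line_cols), 0), np.int8)
    _check_duplicates(markers)
    markers, calls = _sort_markers(markers, calls)
    lines = pd.DataFrame({"line_id": line_cols, "group": "unassigned", "membership": np.nan})
    g = GenotypeMatrix(lines, markers, calls)
    g.meta["n_dropped_non_biallelic"] = n_dropped
    return g


def _read_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"chrom": str})
    fixed = ["marker_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != fixed:
        raise ValueError(f"csv dialect requires leading columns {fixed}")
    line_cols = list(df.columns[5:])
    bad = ~df["ref"].isin(list("ACGT")) | ~df["alt"].isin(list("ACGT")) | (df["ref"] == df["alt"])
    if bad.any():
        log.warning("dropping %d non-biallelic markers", int(bad.sum()))
    df = df.loc[~bad].reset_index(drop=True)
    markers = pd.DataFrame({
        "marker_id": df["marker_id"].astype(str),
        "chrom": df["chrom"].astype(str),
        "pos_bp": df["pos"].astype(int),
        "ref": df["ref"],
        "alt": df["alt"],
    })
    calls_f = df[line_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    calls = np.where(np.isnan(calls_f) | ~np.isin(calls_f, (0, 1, 2)), MISSING, calls_f).astype(np.int8)
    _check_duplicates(markers)
    markers, calls = _sort_markers(markers, calls)
    lines = pd.DataFrame({"line_id": line_cols, "group": "unassigned", "membership": np.nan})
    return GenotypeMatrix(lines, markers, calls)


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "csv") -> None:
    """Write a panel; round-trips calls, marker order and missing mask exactly."""
    if dialect == "csv":
        cols = {
            "marker_id": g.markers["marker_id"],
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos_bp"],
            "ref": g.markers["ref"],
            "alt": g.markers["alt"],
        }
        df = pd.DataFrame(cols)
        calls = g.calls.astype(object)
        for j, lid in enumerate(g.line_ids):
            col = calls[j].copy()
            col[g.calls[j] == MISSING] = "NA"
            df[lid] = col
        df.to_csv(path, index=False)
    elif dialect == "hapmap":
        rows = []
        for i in range(g.n_markers):
            m = g.markers.iloc[i]
            meta = [m["marker_id"], f"{m['ref']}/{m['alt']}", m["chrom"], str(m["pos_bp"]),
                    "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            cells = []
            for j in range(g.n_lines):
                c = g.calls[j, i]
                if c == MISSING:
                    cells.append("NN")
                else:
                    cells.append({0: m["ref"] * 2, 1: m["ref"] + m["alt"], 2: m["alt"] * 2}[int(c)])
            rows.append(meta + cells)
        header = _HAPMAP_META + g.line_ids
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_groups(path) -> pd.DataFrame:
    """Read a line->group membership table (CSV: line_id,group,membership)."""
    df = pd.read_csv(path, dtype={"line_id": str, "group": str})
    if "membership" not in df.columns:
        df["membership"] = np.nan
    return df[["line_id", "group", "membership"]]


def assign_groups(g: GenotypeMatrix, groups: pd.DataFrame,
                  min_membership: float = 0.5) -> GenotypeMatrix:
    """Attach group labels to a panel; lines below ``min_membership`` stay unassigned."""
    gmap = groups.set_index("line_id")
    lines = g.lines.copy()
    for i, lid in enumerate(lines["line_id"]):
        if lid in gmap.index:
            mem = gmap.at[lid, "membership"]
            if pd.isna(mem) or mem > min_membership:
                lines.at[i, "group"] = gmap.at[lid, "group"]
                lines.at[i, "membership"] = mem
    return GenotypeMatrix(lines, g.markers.copy(), g.calls.copy(), dict(g.meta))


def _is_ambiguous(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def harmonize_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge >=2 panels over their shared markers into one allele frame.

    Markers are matched on identical (chrom, pos_bp) and marker name. Where a
    later panel's alleles are the Watson-Crick complement of the first
    panel's, its calls are flipped into the first panel's frame (dosage
    complemented when ref/alt roles swap). Strand-ambiguous A/T and C/G
    markers are kept but flagged. A line occurring in several panels keeps
    the first panel's calls; discordant duplicate calls are counted in
    ``meta['duplicate_line_conflicts']``.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to harmonize")
    key = lambda p: set(zip(p.markers["chrom"], p.markers["pos_bp"], p.markers["marker_id"]))
    shared = set.intersection(*(key(p) for p in panels))
    if not shared:
        raise ValueError("panels share no markers (empty intersection)")

    base = panels[0]
    base_keys = list(zip(base.markers["chrom"], base.markers["pos_bp"], base.markers["marker_id"]))
    keep_idx = [i for i, k in enumerate(base_keys) if k in shared]
    markers = base.markers.iloc[keep_idx].reset_index(drop=True)
    n_dropped = 0
    conflicts = 0

    # per-panel column aligned to the merged marker order, with allele-frame fix
    aligned_calls = []
    aligned_lines = []
    drop_marker = np.zeros(len(markers), dtype=bool)
    for pi, p in enumerate(panels):
        pkeys = {k: i for i, k in enumerate(zip(p.markers["chrom"], p.markers["pos_bp"],
                                                p.markers["marker_id"]))}
        cols = np.array([pkeys[(c, pos, mid)] for c, pos, mid
                         in zip(markers["chrom"], markers["pos_bp"], markers["marker_id"])])
        calls = p.calls[:, cols].copy()
        if pi > 0:
            for j in range(len(markers)):
                ra, aa = markers["ref"].iat[j], markers["alt"].iat[j]
                rb = p.markers["ref"].iat[cols[j]]
                ab = p.markers["alt"].iat[cols[j]]
                if (rb, ab) == (ra, aa):
                    continue
                if (rb, ab) == (aa, ra):
                    calls[:, j] = np.where(calls[:, j] == MISSING, MISSING, 2 - calls[:, j])
                elif (_COMPLEMENT[rb], _COMPLEMENT[ab]) == (ra, aa):
                    continue  # complement, same orientation: dosage unchanged
                elif (_COMPLEMENT[rb], _COMPLEMENT[ab]) == (aa, ra):
                    calls[:, j] = np.where(calls[:, j] == MISSING, MISSING, 2 - calls[:, j])
                else:
                    drop_marker[j] = True
                    n_dropped += 1
                    log.warning("marker %s: allele sets neither equal nor complementary",
                                markers["marker_id"].iat[j])
        aligned_calls.append(calls)
        aligned_lines.append(p.lines)

    seen: dict[str, int] = {}
    out_lines = []
    out_calls = []
    for calls, lines_df in zip(aligned_calls, aligned_lines):
        for j, lid in enumerate(lines_df["line_id"]):
            if lid in seen:
                prev = out_calls[seen[lid]]
                both = (prev != MISSING) & (calls[j] != MISSING)
                conflicts += int(np.sum(prev[both] != calls[j][both]))
                continue
            seen[lid] = len(out_calls)
            out_calls.append(calls[j])
            out_lines.append(lines_df.iloc[j])

    lines = pd.DataFrame(out_lines).reset_index(drop=True)
    calls = np.array(out_calls, dtype=np.int8)
    markers = markers.copy()
    markers["ambiguous"] = [
        _is_ambiguous(r, a) for r, a in zip(markers["ref"], markers["alt"])
    ]
    keep = ~drop_marker
    merged = GenotypeMatrix(lines, markers.loc[keep].reset_index(drop=True), calls[:, keep])
    merged.markers, merged.calls = _sort_markers(merged.markers, merged.calls)
    merged.meta["duplicate_line_conflicts"] = conflicts
    merged.meta["n_dropped_incompatible"] = n_dropped
    return merged


def allele_frequencies(g: GenotypeMatrix):
    """Alt-allele frequency and missing rate per marker (het = one of each allele)."""
    d = g.dosage()
    n_nonmiss = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(d, axis=0) / (2 * n_nonmiss)
    miss_rate = (g.n_lines - n_nonmiss) / g.n_lines
    return p_alt, miss_rate


def filter_snps(g: GenotypeMatrix, maf_min: float = 0.05,
                miss_max: float = 0.2) -> GenotypeMatrix:
    """Keep markers with MAF strictly above ``maf_min`` and missing rate
    strictly below ``miss_max``."""
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < miss_max <= 1):
        raise ValueError("miss_max must be in (0, 1]")
    p_alt, miss_rate = allele_frequencies(g)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p_alt, 1 - p_alt)
    keep = (maf > maf_min) & (miss_rate < miss_max) & ~np.isnan(maf)
    if not keep.any():
        raise ValueError("all markers removed; review maf_min/miss_max thresholds")
    return g.subset_markers(keep)
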