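"""Group-differential expression and co-expression networks on FPKM data.

Expression values are normalized as log2(FPKM + pseudocount); differential
expression between two foundation-parent groups is a per-gene one-way
ANOVA on the normalized values (equivalent to a t-test for two groups),
with the fold change reported as the difference of group means on the
log2 scale. Co-expression edges across organ samples are Pearson
correlations exceeding a magnitude threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM (or log2) values with sample metadata.

    ``values``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame with ``sample_id`` plus ``group`` and/or
    ``organ`` columns, one row per value column, same order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample metadata must match value columns in order")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")

    def group_columns(self, group: str) -> list[str]:
        return self.samples.loc[self.samples["group"] == group, "sample_id"].tolist()


def normalize_log2(e: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value <- log2(FPKM + pseudocount); FPKM must be non-negative."""
    if (e.values.to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    return ExpressionMatrix(np.log2(e.values + pseudocount), e.samples.copy())


def delog2(e: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`normalize_log2`."""
    return ExpressionMatrix(2.0 ** e.values - pseudocount, e.samples.copy())


def group_de(e_log: ExpressionMatrix, pair: tuple[str, str],
             alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Differential expression between two FP groups on log2 values.

    Returns significant genes (p < alpha, or BH-adjusted p with
    ``fdr=True``) with log2 fold change mean(A) - mean(B) and direction.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    a_name, b_name = pair
    acols = e_log.group_columns(a_name)
    bcols = e_log.group_columns(b_name)
    if len(acols) < 2 or len(bcols) < 2:
        raise ValueError("need >=2 samples per group")
    a = e_log.values[acols].to_numpy()
    b = e_log.values[bcols].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.empty(len(lfc))
    for i in range(len(lfc)):
        va, vb = a[i].var(ddof=1), b[i].var(ddof=1)
        if va == 0 and vb == 0:
            pvals[i] = 1.0 if lfc[i] == 0 else 0.0
        else:
            pvals[i] = stats.f_oneway(a[i], b[i]).pvalue
    out = pd.DataFrame({
        "gene": e_log.values.index,
        "pair": f"{a_name}/{b_name}",
        "log2_fold_change": lfc,
        "p_value": pvals,
    })
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
        sig = out["p_adj"] < alpha
    else:
        sig = out["p_value"] < alpha
    out = out.loc[sig].reset_index(drop=True)
    out["direction"] = np.where(out["log2_fold_change"] > 0, "up", "down")
    return out


def coexpression_network(e_log: ExpressionMatrix, gene_set=None,
                         r_min: float = 0.8) -> pd.DataFrame:
    """Pearson co-expression edges among ``gene_set`` across samples.

    Edges with |r| >= ``r_min`` are kept, reported once per unordered pair
    with gene_a < gene_b; constant genes are excluded with a warning.
    Requires >= 3 samples.
    """
    if e_log.values.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    genes = list(gene_set) if gene_set is not None else list(e_log.values.index)
    vals = e_log.values.loc[genes]
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("excluding %d constant genes (undefined r)", int(constant.sum()))
        vals = vals.loc[~constant]
    genes = list(vals.index)
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "n_samples"])
    r = np.corrcoef(vals.to_numpy())
    n = vals.shape[1]
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if abs(r[i, j]) >= r_min:
                ga, gb = sorted((genes[i], genes[j]))
                rows.append({"gene_a": ga, "gene_b": gb,
                             "r": float(r[i, j]), "n_samples": n})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n_samples"])


def edge_degrees(edges: pd.DataFrame) -> pd.Series:
    """Number of co-expression partners per gene."""
    if not len(edges):
        return pd.Series(dtype=int)
    return pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts().sort_index()


def read_expression(path, n_meta_rows: int = 1) -> ExpressionMatrix:
    """Read a genes x samples TSV whose first row(s) carry sample metadata.

    Layout: first column ``gene``; header = sample ids; the first
    ``n_meta_rows`` data rows are metadata keyed by the gene column
    (e.g. ``__group__`` / ``__organ__``), remaining rows FPKM values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_rows = df.index[:n_meta_rows]
    samples = pd.DataFrame({"sample_id": df.columns})
    for mr in meta_rows:
        samples[str(mr).strip("_")] = df.loc[mr].to_numpy()
    values = df.drop(index=meta_rows).astype(float)
    return ExpressionMatrix(values, samples)


def write_expression(e: ExpressionMatrix, path) -> None:
    meta_cols = [c for c in e.samples.columns if c != "sample_id"]
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(e.values.columns) + "\n")
        for mc in meta_cols:
            fh.write(f"__{mc}__\t" + "\t".join(map(str, e.samples[mc])) + "\n")
        for gene, row in e.values.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
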