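"""Mixed-linear-model GWAS with kinship and structure covariates.

The association model for marker s is

    y = mu + Q gamma + x_s beta_s + u + eps,   u ~ N(0, sigma2_g K)

with y the per-line trait BLUPs, Q optional structure covariates (PCA
scores or membership fractions) and K a kinship matrix. Variance
components are estimated once per trait under the null by REML over the
ratio delta = sigma2_e / sigma2_g (P3D), using the eigendecomposition of K;
each marker is then tested by generalized least squares with a Wald
p-value. QTNs are SNPs passing the Bonferroni cutoff alpha / m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .phenotypes import TraitBlup
from .popstructure import ibs_similarity

log = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    ids: list[str]
    k: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.k, self.k.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class MlmFit:
    """Null-model variance components reused for every marker (P3D)."""

    delta: float        # sigma2_e / sigma2_g
    sigma2_g: float
    reml_loglik: float


def kinship_matrix(g: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """Pairwise relatedness: ``ibs`` similarity or VanRaden's genomic matrix.

    ``vanraden``: K = M M' / (2 sum p(1-p)) with M the per-marker
    mean-imputed, 2p-centered dosage matrix.
    """
    if g.n_lines < 2:
        raise ValueError("need at least two lines")
    if method == "ibs":
        return KinshipMatrix(g.line_ids, ibs_similarity(g))
    if method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    d = g.dosage()
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    d = d[:, poly]
    p = p[poly]
    idx = np.where(np.isnan(d))
    d[idx] = 2.0 * p[idx[1]]
    m = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return KinshipMatrix(g.line_ids, (m @ m.T) / denom)


def _reml_delta_nll(log_delta, s, yt, xt):
    """-2 REML log-likelihood profile in delta on the eigenbasis of K."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    n, p = xt.shape
    xtw = xt * w[:, None]
    xtwx = xt.T @ xtw
    try:
        beta = np.linalg.solve(xtwx, xtw.T @ yt)
    except np.linalg.LinAlgError:
        return 1e12
    r = yt - xt @ beta
    rss = float(np.sum(w * r * r))
    sigma2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return 1e12
    return ((n - p) * np.log(sigma2) - np.sum(np.log(w)) + logdet_xx + (n - p))


def fit_null_mlm(y: np.ndarray, x0: np.ndarray, k: np.ndarray) -> tuple[MlmFit, dict]:
    """Estimate delta by 1-D REML on log delta in [-10, 10] (natural log)."""
    s, u = np.linalg.eigh((k + k.T) / 2.0)
    s = np.clip(s, 0.0, None)
    yt = u.T @ y
    xt = u.T @ x0
    obj = lambda ld: _reml_delta_nll(ld, s, yt, xt)
    res = optimize.minimize_scalar(obj, bounds=(-10.0, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    n, p = xt.shape
    w = 1.0 / (s + delta)
    xtw = xt * w[:, None]
    beta = np.linalg.solve(xt.T @ xtw, xtw.T @ yt)
    r = yt - xt @ beta
    sigma2_g = float(np.sum(w * r * r) / (n - p))
    fit = MlmFit(delta, sigma2_g, -0.5 * float(res.fun))
    return fit, {"s": s, "u": u, "yt": yt, "xt": xt}


def mlm_associate(blups: list[TraitBlup], g: GenotypeMatrix, k: KinshipMatrix,
                  q_covariates: np.ndarray | None = None,
                  trait: str | None = None) -> pd.DataFrame:
    """Per-marker MLM association scan (P3D / EMMAX-style).

    ``q_covariates`` rows must align with ``k.ids``. Markers monomorphic in
    the matched lines are skipped; markers collinear with the covariates
    are skipped with a flag. Returns a DataFrame (trait, marker_id, chrom,
    pos_bp, effect, se, p_value, skipped).
    """
    trait = trait or (blups[0].trait if blups else "trait")
    bmap = {b.line_id: b.blup for b in blups if b.trait == trait}
    ids = [i for i in k.ids if i in bmap and i in set(g.line_ids)]
    if len(ids) < 10:
        raise ValueError("fewer than 10 lines after matching blups/genotypes/kinship")
    kidx = [k.ids.index(i) for i in ids]
    kk = k.k[np.ix_(kidx, kidx)]
    y = np.array([bmap[i] for i in ids])
    sub = g.subset_lines(ids)
    x0 = np.ones((len(ids), 1))
    if q_covariates is not None:
        q = np.asarray(q_covariates)[kidx]
        x0 = np.hstack([x0, q])
    fit, basis = fit_null_mlm(y, x0, kk)
    s, u, yt, xt = basis["s"], basis["u"], basis["yt"], basis["xt"]
    w = 1.0 / (s + fit.delta)
    d = sub.dosage()
    col_mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    n, p0 = xt.shape
    rows = []
    sw = np.sqrt(w)
    yt_w = yt * sw
    xt_w = xt * sw[:, None]
    mono = np.nanstd(d, axis=0) == 0
    dt = u.T @ d
    for j in range(sub.n_markers):
        m = sub.markers.iloc[j]
        rec = {"trait": trait, "marker_id": m["marker_id"], "chrom": m["chrom"],
               "pos_bp": m["pos_bp"], "effect": np.nan, "se": np.nan,
               "p_value": np.nan, "skipped": False}
        if mono[j]:
            rec["skipped"] = True
            rows.append(rec)
            continue
        xs = dt[:, j] * sw
        xfull = np.hstack([xt_w, xs[:, None]])
        q_, r_ = np.linalg.qr(xfull)
        if abs(r_[-1, -1]) < 1e-8 * max(1.0, abs(r_[0, 0])):
            rec["skipped"] = True  # collinear with covariates
            rows.append(rec)
            continue
        beta = np.linalg.solve(r_, q_.T @ yt_w)
        resid = yt_w - xfull @ beta
        dof = n - (p0 + 1)
        sigma2 = float(resid @ resid) / dof
        # [(R'R)^-1]_{last,last} = ||R^-T e_last||^2 = 1/R_pp^2 (R upper triangular)
        var_beta = sigma2 / float(r_[-1, -1]) ** 2
        se = np.sqrt(var_beta)
        z = beta[-1] / se
        rec.update(effect=float(beta[-1]), se=float(se),
                   p_value=float(2.0 * stats.norm.sf(abs(z))))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["mlm_fit"] = fit
    return out


def call_qtns(result: pd.DataFrame, alpha: float = 0.05,
              m: int | None = None) -> pd.DataFrame:
    """Flag markers with p strictly below the Bonferroni cutoff alpha / m.

    ``m`` defaults to the number of tested (non-skipped) markers. Returns
    all tested markers sorted by ascending p with a ``passes`` column.
    """
    tested = result.loc[~result["skipped"] & result["p_value"].notna()].copy()
    if m is None:
        m = len(tested)
    if m < 1:
        raise ValueError("m must be >= 1")
    cutoff = alpha / m
    tested["passes"] = tested["p_value"] < cutoff
    tested["cutoff"] = cutoff
    return tested.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def multi_trait_summary(qtn_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Markers significantly associated with >= 2 traits, with trait counts."""
    if len(qtn_tables) < 2:
        raise ValueError("need >=2 traits analyzed")
    recs = []
    for trait, tab in qtn_tables.items():
        hits = tab.loc[tab["passes"], "marker_id"]
        recs += [(mk, trait) for mk in hits]
    if not recs:
        return pd.DataFrame(columns=["marker_id", "n_traits", "traits"])
    df = pd.DataFrame(recs, columns=["marker_id", "trait"]).drop_duplicates()
    agg = df.groupby("marker_id")["trait"].agg(["nunique", lambda s: ",".join(sorted(s))])
    agg.columns = ["n_traits", "traits"]
    agg = agg.loc[agg["n_traits"] >= 2].reset_index()
    return agg.sort_values(["n_traits", "marker_id"],
                           ascending=[False, True]).reset_index(drop=True)
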