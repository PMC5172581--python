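"""Trait derivation, per-line BLUPs across environments, group comparisons.

Phenotypes travel in long format: one record per
(line_id, env, rep, trait, value). Composite traits follow the field's
standard definitions: ASI = DTS - DTP (anthesis-silking interval),
EH/PH (ear-to-plant height ratio), KD = KWE / KV (kernel density, g/mL),
10KL/10KW (kernel shape). BLUPs come from the all-random two-way model

    y_ijk = mu + g_i + e_j + (ge)_ij + eps_ijk

with variance components by REML (an ANOVA method-of-moments estimator is
available for balanced data); the reported value is mu + BLUP(g_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

PHENO_COLUMNS = ["line_id", "env", "rep", "trait", "value"]

#: composite trait -> (operator, operand traits)
DERIVED_TRAITS = {
    "ASI": ("sub", ("DTS", "DTP")),
    "EH/PH": ("div", ("EH", "PH")),
    "KD": ("div", ("KWE", "KV")),
    "10KL/10KW": ("div", ("10KL", "10KW")),
}

#: trait -> category (plant architecture / flowering time / kernel / ear)
TRAIT_CATEGORIES = {
    "EH": "PT", "PH": "PT", "EH/PH": "PT",
    "DTP": "FT", "DTS": "FT", "DTT": "FT", "ASI": "FT",
    "10KL": "KRT", "10KW": "KRT", "10KL/10KW": "KRT", "KD": "KRT",
    "KV": "KRT", "KWE": "KRT", "KNPR": "KRT",
    "ED": "ET", "EL": "ET", "ER": "ET",
}


@dataclass
class TraitBlup:
    line_id: str
    trait: str
    blup: float   # grand mean + genotype BLUP, trait units
    n_obs: int


def derive_traits(p: pd.DataFrame) -> pd.DataFrame:
    """Append composite-trait records computed per (line, env, rep) context.

    Records whose operand is missing yield a missing value; division by
    zero yields missing with a warning count.
    """
    p = p[PHENO_COLUMNS].copy()
    wide = p.pivot_table(index=["line_id", "env", "rep"], columns="trait",
                         values="value", aggfunc="first")
    n_div_zero = 0
    new_rows = []
    for name, (op, (ta, tb)) in DERIVED_TRAITS.items():
        if ta not in wide.columns or tb not in wide.columns:
            continue
        a, b = wide[ta], wide[tb]
        if op == "sub":
            val = a - b
        else:
            zero = b == 0
            n_div_zero += int((zero & a.notna()).sum())
            val = a / b.where(~zero)
        for (lid, env, rep), v in val.items():
            new_rows.append({"line_id": lid, "env": env, "rep": rep,
                             "trait": name, "value": v})
    if n_div_zero:
        log.warning("derive_traits: %d division-by-zero records set missing", n_div_zero)
    return pd.concat([p, pd.DataFrame(new_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# variance components & BLUP

def _design(df: pd.DataFrame):
    lines = sorted(df["line_id"].unique())
    envs = sorted(df["env"].unique())
    li = df["line_id"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    ei = df["env"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    n = len(df)
    zg = np.zeros((n, len(lines)))
    zg[np.arange(n), li] = 1.0
    ze = np.zeros((n, len(envs)))
    ze[np.arange(n), ei] = 1.0
    ge_idx = li * len(envs) + ei
    used_ge = np.unique(ge_idx)
    zge = np.zeros((n, len(used_ge)))
    zge[np.arange(n), np.searchsorted(used_ge, ge_idx)] = 1.0
    return lines, envs, zg, ze, zge


def _reml_nll(log_vars, y, zs):
    """-2 x REML log-likelihood of the all-random model (X = intercept)."""
    n = len(y)
    sig = np.exp(log_vars)
    v = sig[-1] * np.eye(n)
    for s, z in zip(sig[:-1], zs):
        v += s * (z @ z.T)
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    vi_x = np.linalg.solve(v, ones)
    xtvix = float(ones @ vi_x)
    vi_y = np.linalg.solve(v, y)
    beta = float(ones @ vi_y) / xtvix
    r = y - beta
    vi_r = np.linalg.solve(v, r)
    return float(logdet_v + np.log(xtvix) + r @ vi_r)


def variance_components_reml(df: pd.DataFrame):
    """REML variance components (sigma2_g, sigma2_e, sigma2_ge, sigma2_eps)."""
    y = df["value"].to_numpy(dtype=float)
    _, _, zg, ze, zge = _design(df)
    zs = [zg, ze, zge]
    var0 = max(np.var(y), 1e-6)
    x0 = np.log(np.full(4, var0 / 4))
    res = optimize.minimize(_reml_nll, x0, args=(y, zs), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    return tuple(np.exp(res.x))


def variance_components_anova(df: pd.DataFrame):
    """Method-of-moments components from the balanced two-way ANOVA table.

    Expected mean squares with l lines, a environments, r replicates:
    E[MS_G] = s2 + r*s2_ge + a*r*s2_g; E[MS_E] = s2 + r*s2_ge + l*r*s2_e;
    E[MS_GE] = s2 + r*s2_ge; E[MSE] = s2. Negative estimates clip to 0.
    """
    wide = df.pivot_table(index="line_id", columns="env", values="value",
                          aggfunc=["mean", "count"])
    counts = wide["count"].to_numpy()
    if np.isnan(counts).any() or len(np.unique(counts)) != 1:
        raise ValueError("ANOVA method-of-moments requires balanced data")
    r = int(counts.flat[0])
    cell = wide["mean"].to_numpy()
    l, a = cell.shape
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    gm = cell.mean(axis=1)
    em = cell.mean(axis=0)
    ss_g = a * r * np.sum((gm - grand) ** 2)
    ss_e = l * r * np.sum((em - grand) ** 2)
    ss_ge = r * np.sum((cell - gm[:, None] - em[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_g - ss_e - ss_ge
    ms_g = ss_g / (l - 1)
    ms_e = ss_e / (a - 1)
    ms_ge = ss_ge / ((l - 1) * (a - 1))
    mse = ss_err / (l * a * (r - 1)) if r > 1 else 0.0
    s2 = mse
    s2_ge = max((ms_ge - s2) / r, 0.0)
    s2_g = max((ms_g - ms_ge) / (a * r), 0.0)
    s2_e = max((ms_e - ms_ge) / (l * r), 0.0)
    return s2_g, s2_e, s2_ge, s2


def blup_per_line(p: pd.DataFrame, trait: str,
                  method: str = "reml") -> list[TraitBlup]:
    """Per-line BLUPs (grand mean + genotype effect) for one trait.

    ``method`` selects the variance-component estimator: ``reml`` (default)
    or ``anova`` (balanced data only). As the genotypic variance tends to
    zero every BLUP shrinks to the grand mean.
    """
    df = p.loc[(p["trait"] == trait) & p["value"].notna(),
               ["line_id", "env", "rep", "value"]].copy()
    if df.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    if df["env"].nunique() < 2 or df["line_id"].nunique() < 2:
        raise ValueError("need >=2 environments and >=2 lines with observations")
    all_lines = sorted(p.loc[p["trait"] == trait, "line_id"].unique())
    dropped = set(all_lines) - set(df["line_id"].unique())
    if dropped:
        log.warning("%d lines with no observations omitted", len(dropped))

    comps = (variance_components_anova(df) if method == "anova"
             else variance_components_reml(df))
    s2_g, s2_e, s2_ge, s2 = comps
    y = df["value"].to_numpy(dtype=float)
    lines, envs, zg, ze, zge = _design(df)
    n = len(y)
    v = s2 * np.eye(n) + s2_g * (zg @ zg.T) + s2_e * (ze @ ze.T) + s2_ge * (zge @ zge.T)
    ones = np.ones(n)
    vi_x = np.linalg.solve(v, ones)
    beta = float(ones @ np.linalg.solve(v, y)) / float(ones @ vi_x)
    r = y - beta
    g_blup = s2_g * (zg.T @ np.linalg.solve(v, r))
    n_obs = zg.sum(axis=0).astype(int)
    return [TraitBlup(lid, trait, beta + float(g_blup[i]), int(n_obs[i]))
            for i, lid in enumerate(lines)]


def blups_to_frame(blups: list[TraitBlup]) -> pd.DataFrame:
    return pd.DataFrame([{"line_id": b.line_id, "trait": b.trait,
                          "blup": b.blup, "n_obs": b.n_obs} for b in blups])


# ---------------------------------------------------------------------------
# group comparison with compact letter display

def _compact_letters(groups, different: set[tuple]) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise decisions."""
    letter_sets: list[set] = []
    for grp in groups:
        placed = False
        for s in letter_sets:
            if all((min(grp, o), max(grp, o)) not in different for o in s):
                s.add(grp)
                placed = True
        if not placed:
            letter_sets.append({grp})
    # absorb subsets
    keep = []
    for i, s in enumerate(letter_sets):
        if not any(i != j and s < t for j, t in enumerate(letter_sets)):
            keep.append(s)
    letters = {g: "" for g in groups}
    for k, s in enumerate(keep):
        for g in s:
            letters[g] += chr(ord("a") + k)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def group_trait_anova(blups: list[TraitBlup], groups: dict[str, str],
                      alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of line BLUPs across FP groups with Tukey HSD letters.

    Returns one row per (trait, group) with the group mean, n, ANOVA
    p-value and compact-letter-display letter; groups sharing no letter
    differ at ``alpha``.
    """
    df = blups_to_frame(blups)
    df["group"] = df["line_id"].map(groups)
    df = df.dropna(subset=["group"])
    out = []
    for trait, sub in df.groupby("trait"):
        samples = {g: s["blup"].to_numpy() for g, s in sub.groupby("group")}
        names = sorted(samples, key=lambda g: -np.mean(samples[g]))
        if len(names) < 2:
            p_anova, different = 1.0, set()
            letters = {names[0]: "a"} if names else {}
        else:
            within_var = np.array([np.var(v, ddof=1) if len(v) > 1 else 0.0
                                   for v in samples.values()])
            if np.all(within_var == 0):
                # degenerate: exact separation by distinct means
                p_anova = 0.0 if len({np.mean(v) for v in samples.values()}) > 1 else 1.0
                different = {(min(a, b), max(a, b))
                             for a, b in combinations(names, 2)
                             if np.mean(samples[a]) != np.mean(samples[b])}
            else:
                p_anova = float(stats.f_oneway(*samples.values()).pvalue)
                different = _tukey_pairs(samples, alpha)
            letters = _compact_letters(names, different)
        for g in names:
            out.append({"trait": trait, "group": g,
                        "mean": float(np.mean(samples[g])), "n": len(samples[g]),
                        "anova_p": p_anova, "letters": letters.get(g, "a")})
    return pd.DataFrame(out)


def _tukey_pairs(samples: dict, alpha: float) -> set[tuple]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    vals = np.concatenate(list(samples.values()))
    labs = np.concatenate([[g] * len(v) for g, v in samples.items()])
    res = pairwise_tukeyhsd(vals, labs, alpha=alpha)
    different = set()
    for (a, b), rej in zip(combinations(res.groupsunique, 2), res.reject):
        if rej:
            different.add((min(a, b), max(a, b)))
    return different


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "env": str})
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    return df[PHENO_COLUMNS]
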