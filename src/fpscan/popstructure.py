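"""Population structure: IBS distance, UPGMA cladogram, PCA, diverse subsets.

The distance between two inbred lines is the modified Euclidean distance
D = 1 - IBS, where IBS is the probability that alleles drawn at random, one
from each line at the same locus, are identical, averaged over loci
non-missing in both lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, entries in [0,1]; NaN where no shared loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class PcaResult:
    ids: list[str]
    coordinates: np.ndarray        # lines x k
    explained_fraction: np.ndarray  # k fractions, non-increasing


@dataclass
class SubsetSelection:
    selected_ids: list[str]
    coverage: float  # mean per-marker gene diversity of subset / full panel


def ibs_similarity(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS similarity matrix.

    Per locus the similarity is the mean over the four ordered allele pairs
    of the identity indicator: hom vs identical hom -> 1, hom vs opposite
    hom -> 0, hom vs het -> 0.5, het vs het -> 0.5.
    """
    d = g.dosage()
    n = g.n_lines
    s = np.empty((n, n))
    het = d == 1
    for i in range(n):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice mean
            per_locus = 1.0 - np.abs(d[i] - d) / 2.0
            per_locus[het[i][None, :].repeat(n, 0) & het] = 0.5
            s[i] = np.nanmean(per_locus, axis=1)
    return s


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """D = 1 - IBS over loci non-missing in both lines of each pair."""
    if g.n_lines < 2:
        raise ValueError("need at least two lines")
    s = ibs_similarity(g)
    if np.isnan(s).any():
        log.warning("some line pairs share no non-missing loci; distance set missing")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(g.line_ids, d)


# ---------------------------------------------------------------------------
# UPGMA

class _Cluster:
    __slots__ = ("members", "height", "newick", "min_id")

    def __init__(self, members, height, newick, min_id):
        self.members = members
        self.height = height
        self.newick = newick
        self.min_id = min_id


def upgma_tree(dm: DistanceMatrix) -> str:
    """UPGMA agglomeration to a rooted ultrametric tree in newick text.

    Cluster-to-cluster distance is the arithmetic mean of member pairwise
    distances; a join at distance d places the parent node at height d/2.
    Ties are broken toward the pair whose lexicographically smallest member
    id is smallest (then the second member's id).
    """
    d = np.array(dm.d, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix has missing entries; drop offending lines first")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two lines")
    clusters = {i: _Cluster([i], 0.0, dm.ids[i], dm.ids[i]) for i in range(n)}
    # dist[(a,b)] = mean pairwise distance between clusters a and b
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for (a, b), v in dist.items():
            ka = (v, *sorted((clusters[a].min_id, clusters[b].min_id)))
            if best is None or ka < best[0]:
                best = (ka, a, b)
        _, a, b = best
        h = dist[(a, b)] / 2.0
        ca, cb = clusters.pop(a), clusters.pop(b)
        first, second = sorted((ca, cb), key=lambda c: c.min_id)
        nwk = (f"({first.newick}:{h - first.height:.10g},"
               f"{second.newick}:{h - second.height:.10g})")
        new = _Cluster(ca.members + cb.members, h, nwk, min(ca.min_id, cb.min_id))
        na, nb = sizes.pop(a), sizes.pop(b)
        # arithmetic-mean update
        new_dist = {}
        for c in clusters:
            da = dist.pop(tuple(sorted((a, c))))
            db = dist.pop(tuple(sorted((b, c))))
            new_dist[(c, next_id)] = (na * da + nb * db) / (na + nb)
        dist.pop((a, b), None)
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        dist.update(new_dist)
        clusters[next_id] = new
        sizes[next_id] = na + nb
        next_id += 1
    root = next(iter(clusters.values()))
    return root.newick + ";"


# ---------------------------------------------------------------------------
# PCA

def pca(g: GenotypeMatrix, k: int = 3) -> PcaResult:
    """Covariance PCA of the dosage matrix.

    Missing dosages are mean-imputed per marker, columns centered, no
    variance scaling. Each component's sign is fixed so its
    largest-magnitude score is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = g.dosage()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    d -= d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    total = np.sum(s**2)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if k > rank:
        log.warning("k=%d exceeds rank %d; truncating", k, rank)
        k = max(rank, 1)
    scores = u[:, :k] * s[:k]
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(g.line_ids, scores, frac)


# ---------------------------------------------------------------------------
# Diversity-covering subset

def _mean_gd_from_counts(alt, nonmiss):
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = 2.0 * nonmiss
        p = alt / tot
        gd = 1.0 - p**2 - (1.0 - p) ** 2
    gd[nonmiss == 0] = np.nan
    return float(np.nanmean(gd))


def select_diverse_subset(g: GenotypeMatrix, target_n: int) -> SubsetSelection:
    """Greedy backward elimination maximizing retained gene diversity.

    Coverage is the ratio of the subset's mean per-marker gene diversity
    (Nei's expected heterozygosity) to the full panel's. At each step the
    line whose removal leaves the highest subset diversity is dropped
    (ties: drop the lexicographically smallest line id) until ``target_n``
    lines remain.
    """
    if not (2 <= target_n <= g.n_lines):
        raise ValueError("target_n must be in [2, n_lines]")
    d = g.dosage()
    alt_per_line = np.where(np.isnan(d), 0.0, d)          # alt alleles contributed
    nonmiss_per_line = (~np.isnan(d)).astype(float)
    alt = alt_per_line.sum(axis=0)
    nonmiss = nonmiss_per_line.sum(axis=0)
    full_gd = _mean_gd_from_counts(alt, nonmiss)
    ids = list(g.line_ids)
    active = list(range(g.n_lines))
    while len(active) > target_n:
        best = None
        for i in active:
            gd_i = _mean_gd_from_counts(alt - alt_per_line[i], nonmiss - nonmiss_per_line[i])
            key = (-gd_i, ids[i])
            if best is None or key < best[0]:
                best = (key, i)
        _, drop = best
        active.remove(drop)
        alt = alt - alt_per_line[drop]
        nonmiss = nonmiss - nonmiss_per_line[drop]
    coverage = _mean_gd_from_counts(alt, nonmiss) / full_gd if full_gd > 0 else 1.0
    return SubsetSelection([ids[i] for i in active], float(coverage))
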