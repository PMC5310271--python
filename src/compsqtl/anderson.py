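"""Hellinger-distance Anderson (PERMANOVA) test: the slow per-pair oracle.

For one gene-variant pair, samples are points on the simplex of splicing
ratios, compared through the Hellinger distance (Euclidean distance of
sqrt-ratio vectors).  Total, within-group and between-group sums of
squared distances give the pseudo F-ratio

    F = [SS_B / (L-1)] / [SS_W / (N - L)],   SS_B = SS_T - SS_W,

whose significance is assessed by label permutation.  The sums of
squares use the pairwise-distance identity SS = (1/N) sum_{a<b} d^2(a,b),
which for the Hellinger embedding equals the centroid route with the
centroid taken as the element-wise mean of the sqrt-ratio vectors.

This module exists to cross-validate the fast matrix path; it is O(N^2)
per pair and is meant for top hits only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats


@dataclass
class DistanceDecomposition:
    ss_total: float
    ss_within: float
    ss_between: float
    group_sizes: dict[float, int]
    L: int


def hellinger_distance(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """d_H(a, b) = sqrt( sum_i (sqrt(p_ia) - sqrt(p_ib))^2 ); <= sqrt(2)."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("ratio vectors have different lengths")
    return float(np.linalg.norm(np.sqrt(p_a) - np.sqrt(p_b)))


def _sq_distance_matrix(ratios: np.ndarray) -> np.ndarray:
    """Squared Hellinger distances between all sample columns of (n x N)."""
    q = np.sqrt(np.asarray(ratios, dtype=float)).T  # samples x isoforms
    return squareform(pdist(q, metric="sqeuclidean"))


def ss_decomposition(ratios: np.ndarray, groups: np.ndarray) -> DistanceDecomposition:
    """SS_T, SS_W, SS_B of the Hellinger distances, via the pairwise identity.

    ``ratios`` is (n_isoforms x N); ``groups`` labels each sample column
    (NaN labels are not allowed here — mask upstream).
    """
    groups = np.asarray(groups, dtype=float)
    if np.isnan(groups).any():
        raise ValueError("group labels contain NaN; mask samples first")
    d2 = _sq_distance_matrix(ratios)
    N = d2.shape[0]
    ss_t = d2.sum() / (2.0 * N)  # sum over a<b once
    ss_w = 0.0
    sizes: dict[float, int] = {}
    for c in np.unique(groups):
        idx = np.flatnonzero(groups == c)
        sizes[float(c)] = idx.size
        if idx.size > 1:
            ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return DistanceDecomposition(
        ss_total=float(ss_t),
        ss_within=float(ss_w),
        ss_between=float(ss_t - ss_w),
        group_sizes=sizes,
        L=len(sizes),
    )


def ss_decomposition_centroid(ratios: np.ndarray, groups: np.ndarray) -> DistanceDecomposition:
    """Centroid route to the same decomposition (cross-check path).

    Centroids are element-wise means of sqrt-ratio vectors (the embedding
    mean, not renormalized); agrees with the pairwise identity to
    rounding error.
    """
    groups = np.asarray(groups, dtype=float)
    q = np.sqrt(np.asarray(ratios, dtype=float))
    c_all = q.mean(axis=1, keepdims=True)
    ss_t = ((q - c_all) ** 2).sum()
    ss_w = 0.0
    sizes: dict[float, int] = {}
    for c in np.unique(groups):
        idx = groups == c
        sizes[float(c)] = int(idx.sum())
        qg = q[:, idx]
        ss_w += ((qg - qg.mean(axis=1, keepdims=True)) ** 2).sum()
    return DistanceDecomposition(
        ss_total=float(ss_t),
        ss_within=float(ss_w),
        ss_between=float(ss_t - ss_w),
        group_sizes=sizes,
        L=len(sizes),
    )


def pseudo_f(ratios: np.ndarray, groups: np.ndarray) -> float:
    """Anderson pseudo F-ratio for one gene-variant pair."""
    dec = ss_decomposition(ratios, groups)
    N = sum(dec.group_sizes.values())
    if dec.L < 2 or any(n < 2 for n in dec.group_sizes.values()):
        raise ValueError("need >=2 groups with >=2 samples each")
    if dec.ss_within <= 0:
        return np.inf if dec.ss_between > 0 else 0.0
    return float((dec.ss_between / (dec.L - 1)) / (dec.ss_within / (N - dec.L)))


def bartlett_homogeneity_p(ratios: np.ndarray, groups: np.ndarray) -> float:
    """Bartlett test p-value on per-sample distances to the group centroid.

    A small p warns that group dispersions differ, a situation in which
    the pseudo-F test can lose calibration.
    """
    groups = np.asarray(groups, dtype=float)
    q = np.sqrt(np.asarray(ratios, dtype=float))
    per_group = []
    for c in np.unique(groups):
        qg = q[:, groups == c]
        if qg.shape[1] < 2:
            continue
        cg = qg.mean(axis=1, keepdims=True)
        per_group.append(np.sqrt(((qg - cg) ** 2).sum(axis=0)))
    if len(per_group) < 2:
        return np.nan
    return float(stats.bartlett(*per_group).pvalue)


def permutation_p(
    ratios: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value of the pseudo F-ratio.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); the distance matrix is
    computed once and reused across permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = np.asarray(groups, dtype=float)
    d2 = _sq_distance_matrix(ratios)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def f_of(labels: np.ndarray) -> float:
        N = d2.shape[0]
        ss_t = d2.sum() / (2.0 * N)
        ss_w = 0.0
        L = 0
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            L += 1
            if idx.size > 1:
                ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        if ss_w <= 0:
            return np.inf
        return ((ss_t - ss_w) / (L - 1)) / (ss_w / (N - L))

    f_obs = f_of(groups)
    count = 0
    labels = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        if f_of(labels) >= f_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)
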