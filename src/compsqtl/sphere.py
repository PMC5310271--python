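"""Spherical-coordinate transform of splicing-ratio vectors.

A gene with n isoforms has ratio vectors on the simplex (sum p_i = 1, n-1
degrees of freedom).  Taking q_i = sqrt(p_i) places each sample on the
unit n-sphere (sum q_i^2 = 1, radius 1), and the n-1 polar angles

    phi_k = arccos( q_k / sqrt(q_k^2 + ... + q_n^2) ),  k = 1..n-1

are unconstrained coordinates in [0, pi/2] — the "converted splicing
components" the fast association test operates on.  Isoforms are ordered
once per gene, largest mean sqrt-ratio first, before the transform.
"""

from __future__ import annotations

import numpy as np

from .model import ComponentMatrix, SplicingRatioSet

_SUM_TOL = 1e-6


def _angles(q: np.ndarray) -> np.ndarray:
    """Polar angles of columns of a (n x l) sqrt-ratio matrix -> (n-1 x l).

    A zero trailing tail (q_k..q_n all zero) yields phi_k = 0 by
    convention; the arccos argument is clamped to [-1, 1] against
    floating-point drift.
    """
    tail = np.sqrt(np.cumsum(q[::-1] ** 2, axis=0)[::-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tail[:-1] > 0, q[:-1] / np.where(tail[:-1] > 0, tail[:-1], 1.0), 1.0)
    return np.arccos(np.clip(ratio, -1.0, 1.0))


def to_sphere(p: np.ndarray, order: np.ndarray | None = None) -> np.ndarray:
    """Transform one ratio vector (length n, summing to 1) to n-1 angles.

    ``order`` is the isoform permutation applied before the transform;
    identity when omitted.
    """
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"ratios sum to {p.sum()!r}, not 1")
    if (p < 0).any():
        raise ValueError("ratios must be non-negative")
    if order is not None:
        p = p[np.asarray(order, dtype=int)]
    return _angles(np.sqrt(p)[:, None])[:, 0]


def from_sphere(phi: np.ndarray) -> np.ndarray:
    """Inverse transform: n-1 angles in [0, pi/2] -> ratio vector of length n."""
    phi = np.asarray(phi, dtype=float)
    if ((phi < 0) | (phi > np.pi / 2 + 1e-12)).any():
        raise ValueError("angles must lie in [0, pi/2]")
    n = phi.size + 1
    q = np.empty(n)
    sin_prod = 1.0
    for k in range(n - 1):
        q[k] = sin_prod * np.cos(phi[k])
        sin_prod *= np.sin(phi[k])
    q[n - 1] = sin_prod
    return q**2


def isoform_order(ratios: np.ndarray, isoform_ids: list[str]) -> np.ndarray:
    """Permutation sorting isoforms by mean sqrt-ratio, descending.

    Ties on the mean are broken by isoform id (lexicographic) so the
    ordering is deterministic.
    """
    mean_q = np.sqrt(np.asarray(ratios, dtype=float)).mean(axis=1)
    keyed = sorted(range(len(isoform_ids)), key=lambda i: (-mean_q[i], isoform_ids[i]))
    return np.asarray(keyed, dtype=int)


def build_component_matrix(ratios: SplicingRatioSet) -> ComponentMatrix:
    """Stack all genes' converted splicing components into one t x l matrix.

    t = sum over genes of (n_isoforms - 1).  Columns follow the global
    aligned sample list; a gene's non-retained samples are NaN in its
    rows.  Genes are emitted in sorted id order, components in rank order
    1..n-1.
    """
    n_samples = len(ratios.sample_ids)
    rows: list[np.ndarray] = []
    row_index: list[tuple[str, int]] = []
    gene_df: dict[str, int] = {}
    for gene_id in sorted(ratios.genes):
        g = ratios.genes[gene_id]
        order = isoform_order(g.ratios, g.isoform_ids)
        q = np.sqrt(g.ratios[order, :])
        phi = _angles(q)  # (n-1) x l_g
        gene_df[gene_id] = phi.shape[0]
        block = np.full((phi.shape[0], n_samples), np.nan)
        block[:, g.sample_mask] = phi
        rows.append(block)
        row_index.extend((gene_id, k + 1) for k in range(phi.shape[0]))
    values = np.vstack(rows) if rows else np.empty((0, n_samples))
    return ComponentMatrix(
        values=values,
        row_index=row_index,
        gene_df=gene_df,
        sample_ids=list(ratios.sample_ids),
    )
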