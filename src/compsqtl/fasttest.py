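"""Batched association tests of splicing components against variants.

The engine follows the Matrix-eQTL strategy: rows (components, genotype
codes) are standardized to mean 0 and unit sum of squares over their
shared non-missing samples, so every component-variant Pearson
correlation is a plain inner product and a whole block of tests is one
matrix multiplication.  Two models are available:

* ``linear`` — genotype as 0/1/2 dose; statistic t = r sqrt((N-2)/(1-r^2)),
  two-sided p from Student's t with N-2 df.
* ``anova`` (default) — genotype as categorical; the one-way ANOVA F is
  recovered from the same inner products via the categorical-regression
  identity F = (R^2/(L-1)) / ((1-R^2)/(N-L)), with R^2 the squared
  projection of the standardized component onto an orthonormalized
  group-indicator basis.

Missing data are handled by grouping rows into missingness patterns and
computing each pattern-pair block over its shared sample mask, which
keeps the batched results identical to per-pair scalar computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ComponentMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_SHARED = 6


@dataclass
class StandardizedMatrix:
    """Rows centered and scaled to unit sum of squares over their mask."""

    values: np.ndarray
    mask: np.ndarray  # boolean availability, same shape as values
    valid: np.ndarray  # per row: False when the row was constant over its mask


@dataclass
class ComponentTestResult:
    """Per component-variant pair: the model statistic and its p-value."""

    component_row: int
    variant: int
    statistic: float
    df: tuple[int, ...]
    p_value: float


@dataclass
class ComponentTestStats:
    """Dense per-pair results: arrays of shape (n_components, n_variants).

    ``p_value`` is NaN for pairs that could not be tested (too few shared
    samples, a single genotype group, or a constant component).
    """

    statistic: np.ndarray
    p_value: np.ndarray
    n_samples: np.ndarray
    n_groups: np.ndarray
    model: str


def standardize(rows: np.ndarray, mask: np.ndarray | None = None) -> StandardizedMatrix:
    """Center each row to mean 0 and scale to sum of squares 1 over its mask.

    Masked-out entries are set to 0 so that inner products over the full
    column range equal inner products over the mask.  Constant rows are
    flagged invalid (their values stay 0) rather than raising.
    """
    rows = np.asarray(rows, dtype=float)
    if mask is None:
        mask = ~np.isnan(rows)
    mask = np.asarray(mask, dtype=bool)
    filled = np.where(mask, rows, 0.0)
    n = mask.sum(axis=1)
    valid = n >= 3
    safe_n = np.maximum(n, 1)
    mean = filled.sum(axis=1) / safe_n
    centered = np.where(mask, filled - mean[:, None], 0.0)
    ss = (centered**2).sum(axis=1)
    valid &= ss > 0
    out = np.where(valid[:, None], centered / np.sqrt(np.where(ss > 0, ss, 1.0))[:, None], 0.0)
    return StandardizedMatrix(values=out, mask=mask, valid=valid)


def correlation_block(phi_std: StandardizedMatrix, v_std: StandardizedMatrix) -> np.ndarray:
    """Pearson correlations of every component row with every variant row.

    Both inputs must be standardized over the *same* column mask (the
    pattern-pair machinery in :func:`test_components` guarantees this);
    the correlation is then the inner product of the two rows.  Pairs
    involving an invalid row are NaN.
    """
    r = phi_std.values @ v_std.values.T
    r = np.clip(r, -1.0, 1.0)
    bad = ~phi_std.valid[:, None] | ~v_std.valid[None, :]
    r[bad] = np.nan
    return r


def _anova_from_values(y: np.ndarray, g: np.ndarray) -> tuple[float, int, int, int]:
    """Direct group-mean one-way ANOVA: (F, L, N, df2). L<2 -> F is nan."""
    codes = np.unique(g)
    n = y.size
    grand = y.mean()
    ssb = 0.0
    ssw = 0.0
    for c in codes:
        yc = y[g == c]
        ssb += yc.size * (yc.mean() - grand) ** 2
        ssw += ((yc - yc.mean()) ** 2).sum()
    L = codes.size
    if L < 2 or n - L < 1:
        return np.nan, L, n, 0
    if ssw <= 0:
        return (np.nan if ssb <= 0 else np.inf), L, n, n - L
    return (ssb / (L - 1)) / (ssw / (n - L)), L, n, n - L


def anova_test(phi_row: np.ndarray, groups: np.ndarray) -> ComponentTestResult:
    """One-way ANOVA of a single component against genotype groups.

    NaNs in either input drop the sample.  F has df (L-1, N-L) where L is
    the number of genotype groups actually present.
    """
    phi_row = np.asarray(phi_row, dtype=float)
    groups = np.asarray(groups, dtype=float)
    ok = ~np.isnan(phi_row) & ~np.isnan(groups)
    F, L, n, df2 = _anova_from_values(phi_row[ok], groups[ok])
    if not np.isfinite(F):
        p = 0.0 if F == np.inf else np.nan
    else:
        p = float(stats.f.sf(F, L - 1, df2))
    return ComponentTestResult(
        component_row=-1, variant=-1, statistic=float(F), df=(L - 1, df2), p_value=p
    )


def linear_test(phi_row: np.ndarray, v_row: np.ndarray) -> ComponentTestResult:
    """Simple-regression t-test of a component on genotype dose."""
    phi_row = np.asarray(phi_row, dtype=float)
    v_row = np.asarray(v_row, dtype=float)
    ok = ~np.isnan(phi_row) & ~np.isnan(v_row)
    y, v = phi_row[ok], v_row[ok]
    n = y.size
    if n < 3 or np.ptp(v) == 0 or np.ptp(y) == 0:
        return ComponentTestResult(-1, -1, np.nan, (max(n - 2, 0),), np.nan)
    r = float(np.corrcoef(y, v)[0, 1])
    d = n - 2
    if abs(r) >= 1.0:
        return ComponentTestResult(-1, -1, np.inf, (d,), 0.0)
    t = r * np.sqrt(d / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), d))
    return ComponentTestResult(-1, -1, float(t), (d,), p)


def _group_basis(g: np.ndarray) -> np.ndarray | None:
    """Orthonormal basis of the centered group-indicator space, (N, L-1).

    Returns None when fewer than two groups are present.  The span of the
    centered indicators is what one-way ANOVA regresses on, so squared
    projections onto this basis give the per-pair R^2.
    """
    codes = np.unique(g)
    if codes.size < 2:
        return None
    ind = (g[:, None] == codes[None, :]).astype(float)
    ind -= ind.mean(axis=0, keepdims=True)
    qmat, rmat = np.linalg.qr(ind)
    keep = np.abs(np.diag(rmat)) > 1e-12
    basis = qmat[:, keep]
    return basis if basis.shape[1] == codes.size - 1 else basis


def test_components(
    components: ComponentMatrix | np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    model: str = "anova",
    min_shared_samples: int = DEFAULT_MIN_SHARED,
) -> ComponentTestStats:
    """Test every component row against every variant row.

    Rows are grouped by missingness pattern; each (component-pattern,
    variant-pattern) block is standardized over its shared sample mask
    and evaluated through matrix products, so results match per-pair
    scalar computation exactly.
    """
    if model not in ("anova", "linear"):
        raise ValueError(f"unknown model {model!r}")
    Phi = components.values if isinstance(components, ComponentMatrix) else np.asarray(components, float)
    V = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    if Phi.shape[1] != V.shape[1]:
        raise ValueError("component and genotype matrices have mismatched samples")
    t, k = Phi.shape[0], V.shape[0]
    stat = np.full((t, k), np.nan)
    pval = np.full((t, k), np.nan)
    n_shared = np.zeros((t, k), dtype=int)
    n_groups = np.zeros((t, k), dtype=int)

    phi_mask = ~np.isnan(Phi)
    v_mask = ~np.isnan(V)
    p_pat, p_inv = np.unique(phi_mask, axis=0, return_inverse=True)
    v_pat, v_inv = np.unique(v_mask, axis=0, return_inverse=True)

    for pi in range(p_pat.shape[0]):
        phi_rows = np.flatnonzero(p_inv == pi)
        for vi in range(v_pat.shape[0]):
            v_rows = np.flatnonzero(v_inv == vi)
            cols = p_pat[pi] & v_pat[vi]
            N = int(cols.sum())
            if N < min_shared_samples:
                continue
            n_shared[np.ix_(phi_rows, v_rows)] = N
            sub_phi = standardize(Phi[np.ix_(phi_rows, cols)])
            if model == "linear":
                _linear_block(
                    sub_phi, V[np.ix_(v_rows, cols)], N, phi_rows, v_rows, stat, pval, n_groups
                )
            else:
                _anova_block(
                    sub_phi, V[np.ix_(v_rows, cols)], N, phi_rows, v_rows, stat, pval, n_groups
                )
    return ComponentTestStats(
        statistic=stat, p_value=pval, n_samples=n_shared, n_groups=n_groups, model=model
    )


test_components.__test__ = False  # noqa: E305 -- name clashes with pytest collection


def _linear_block(sub_phi, v_block, N, phi_rows, v_rows, stat, pval, n_groups):
    sub_v = standardize(v_block)
    r = correlation_block(sub_phi, sub_v)
    d = N - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(d / np.maximum(1.0 - r**2, 0.0))
    tstat[np.abs(r) >= 1.0] = np.inf * np.sign(r[np.abs(r) >= 1.0])
    p = 2.0 * stats.t.sf(np.abs(tstat), d)
    p[~np.isfinite(tstat)] = 0.0
    p[np.isnan(r)] = np.nan
    tstat[np.isnan(r)] = np.nan
    stat[np.ix_(phi_rows, v_rows)] = tstat
    pval[np.ix_(phi_rows, v_rows)] = p
    n_groups[np.ix_(phi_rows, v_rows)] = 2


def _anova_block(sub_phi, v_block, N, phi_rows, v_rows, stat, pval, n_groups):
    for j, vrow in enumerate(v_rows):
        g = v_block[j]
        basis = _group_basis(g)
        if basis is None:
            continue
        L = basis.shape[1] + 1
        if N - L < 1:
            continue
        proj = sub_phi.values @ basis  # (t_block, L-1)
        r2 = np.clip((proj**2).sum(axis=1), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (r2 / (L - 1)) / np.maximum((1.0 - r2) / (N - L), 0.0)
        F[r2 >= 1.0] = np.inf
        p = stats.f.sf(F, L - 1, N - L)
        p[~np.isfinite(F)] = 0.0
        F[~sub_phi.valid] = np.nan
        p[~sub_phi.valid] = np.nan
        stat[phi_rows, vrow] = F
        pval[phi_rows, vrow] = p
        n_groups[phi_rows, vrow] = L
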