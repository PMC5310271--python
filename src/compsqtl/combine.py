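"""Combine per-component statistics into per-gene chi-square tests, plus FDR.

Each component test yields a p-value p_i; the one-sided map
z_i = Phi^{-1}(1 - p_i) makes z_i standard normal whenever p_i is
uniform, so under the null the composite statistic s = sum z_i^2 over a
gene's n-1 components follows chi-square with n-1 degrees of freedom.
Gene-level p-values across the run are converted to q-values (Storey
FDR with a smoother pi0 estimate; pi0 = 1, i.e. Benjamini-Hochberg,
when the fit is degenerate).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .fasttest import ComponentTestResult, ComponentTestStats
from .model import AssociationResult

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def stat_to_z(component_result: "ComponentTestResult | float") -> float:
    """Map a component test to z = Phi^{-1}(1 - p); p floored at 1e-300.

    Accepts either a :class:`ComponentTestResult` or a bare p-value.
    """
    p = (
        component_result.p_value
        if isinstance(component_result, ComponentTestResult)
        else float(component_result)
    )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < P_FLOOR:
        logger.warning("component p-value %g clipped to %g", p, P_FLOOR)
        p = P_FLOOR
    return float(stats.norm.isf(p))


def combine_gene(z_values: np.ndarray, gene_id: str = "", variant_id: str = "",
                 expected_df: int | None = None) -> AssociationResult:
    """s = sum z_i^2 ~ chi-square with df = number of components combined.

    NaN entries (components skipped for zero variance) reduce the df and
    set the ``reduced_df`` flag; raises if no component survives.
    """
    z = np.asarray(z_values, dtype=float)
    ok = np.isfinite(z)
    df = int(ok.sum())
    if df == 0:
        raise ValueError("no testable components for this pair")
    s = float((z[ok] ** 2).sum())
    return AssociationResult(
        gene_id=gene_id,
        variant_id=variant_id,
        statistic_s=s,
        df=df,
        p_value=float(stats.chi2.sf(s, df)),
        reduced_df=expected_df is not None and df < expected_df,
    )


def combine_pairs(
    stats_: ComponentTestStats,
    row_index: list[tuple[str, int]],
    variant_ids: list[str],
) -> pd.DataFrame:
    """Aggregate dense component-level results into gene-level rows.

    Returns a DataFrame with columns gene_id, variant_id, df, statistic,
    p_value (fdr left NaN; apply :func:`compute_fdr` after pooling all
    chunks), sorted by (gene_id, variant_id).  Pairs with no testable
    component are dropped.
    """
    p = stats_.p_value
    z = stats.norm.isf(np.clip(p, P_FLOOR, 1.0))
    z[np.isnan(p)] = np.nan
    genes = np.asarray([g for g, _ in row_index])
    records: list[dict] = []
    for gene_id in pd.unique(genes):
        rows = np.flatnonzero(genes == gene_id)
        zg = z[rows, :]  # (n-1) x k
        ok = np.isfinite(zg)
        df_per_variant = ok.sum(axis=0)
        s = np.nansum(zg**2, axis=0)
        for j, variant_id in enumerate(variant_ids):
            dfj = int(df_per_variant[j])
            if dfj == 0:
                continue
            records.append(
                {
                    "gene_id": gene_id,
                    "variant_id": variant_id,
                    "df": dfj,
                    "statistic": float(s[j]),
                    "p_value": float(stats.chi2.sf(s[j], dfj)),
                    "fdr": np.nan,
                }
            )
    df = pd.DataFrame(
        records, columns=["gene_id", "variant_id", "df", "statistic", "p_value", "fdr"]
    )
    return df.sort_values(["gene_id", "variant_id"], kind="mergesort").reset_index(drop=True)


def estimate_pi0(p_values: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid
    lambda = 0.05..0.95 and smoothed with a cubic spline; the estimate is
    the smoothed value at the largest lambda, clipped to (0, 1].  Falls
    back to 1 for small m or a degenerate fit.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    except Exception:  # degenerate fit
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def compute_fdr(p_values: np.ndarray) -> np.ndarray:
    """Storey q-values: q_(i) = min over j>=i of pi0 * m * p_(j) / j.

    With pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    Output is monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
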