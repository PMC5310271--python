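import numpy as np
import pytest
from scipy import stats

from compsqtl.fasttest import (
    anova_test,
    correlation_block,
    linear_test,
    standardize,
    test_components,
)


class TestStandardize:
    def test_closed_form_row(self):
        out = standardize(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(
            out.values[0], [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-12
        )
        assert out.valid[0]

    def test_constant_row_flagged(self):
        out = standardize(np.array([[2.0, 2.0, 2.0]]))
        assert not out.valid[0]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(4, 12))
        once = standardize(rows)
        twice = standardize(once.values)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_moments_over_mask(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(5, 20))
        mask = rng.uniform(size=rows.shape) > 0.2
        out = standardize(rows, mask)
        for i in range(5):
            if out.valid[i]:
                assert abs(out.values[i][mask[i]].sum()) < 1e-9
                assert abs((out.values[i][mask[i]] ** 2).sum() - 1.0) < 1e-9


class TestCorrelationBlock:
    def test_self_correlation_is_one(self):
        row = np.array([[0.0, 1.0, 2.0, 1.0, 0.0, 2.0]])
        r = correlation_block(standardize(row), standardize(row))
        assert r[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_give_zero(self):
        a = standardize(np.array([[1.0, -1.0, 1.0, -1.0]]))
        b = standardize(np.array([[1.0, 1.0, -1.0, -1.0]]))
        assert correlation_block(a, b)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_pearson(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(5, 8)), rng.normal(size=(4, 8))
        r = correlation_block(standardize(A), standardize(B))
        for i in range(5):
            for j in range(4):
                expected = stats.pearsonr(A[i], B[j]).statistic
                assert r[i, j] == pytest.approx(expected, abs=1e-10)


class TestScalarAnova:
    def test_equal_group_means_give_zero_f(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        res = anova_test(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        g = rng.choice([0.0, 1.0, 2.0], size=60)
        res = anova_test(y, g)
        ref = stats.f_oneway(*(y[g == c] for c in np.unique(g)))
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_separated_groups_drive_p_to_zero(self):
        y = np.r_[np.zeros(10), np.ones(10), np.full(10, 2.0)]
        y += np.random.default_rng(5).normal(0, 1e-6, 30)
        g = np.r_[np.zeros(10), np.ones(10), np.full(10, 2.0)]
        assert anova_test(y, g).p_value < 1e-30


class TestScalarLinear:
    def test_zero_correlation(self):
        y = np.array([1.0, -1.0] * 5)
        v = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 0.0, 0.0, 1.0, 1.0])
        res = linear_test(y, v)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(6)
        v = rng.choice([0.0, 1.0, 2.0], size=40)
        y = 0.3 * v + rng.normal(size=40)
        res = linear_test(y, v)
        ref = stats.linregress(v, y)
        assert res.statistic == pytest.approx(ref.rvalue * np.sqrt(38 / (1 - ref.rvalue**2)), rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_perfect_correlation_sentinel(self):
        v = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        res = linear_test(v.copy(), v)
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0


def _random_instance(seed, with_na=True):
    rng = np.random.default_rng(seed)
    t, k, l = rng.integers(2, 8), rng.integers(2, 8), int(rng.integers(20, 50))
    phi = rng.uniform(0, np.pi / 2, size=(t, l))
    codes = rng.choice([0.0, 1.0, 2.0], size=(k, l), p=[0.4, 0.4, 0.2])
    if with_na:
        phi[rng.uniform(size=phi.shape) < 0.1] = np.nan
        codes[rng.uniform(size=codes.shape) < 0.1] = np.nan
    return phi, codes


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("model", ["anova", "linear"])
def test_batched_equals_scalar_path(seed, model):
    """Core Matrix-eQTL property: the batched engine reproduces per-pair
    scalar statistics exactly, with and without missing data."""
    phi, codes = _random_instance(seed)
    res = test_components(phi, codes, model=model, min_shared_samples=6)
    for i in range(phi.shape[0]):
        for j in range(codes.shape[0]):
            ok = ~np.isnan(phi[i]) & ~np.isnan(codes[j])
            if ok.sum() < 6 or np.isnan(res.p_value[i, j]):
                continue
            if model == "anova":
                ref = anova_test(phi[i], codes[j])
            else:
                ref = linear_test(phi[i], codes[j])
            assert res.statistic[i, j] == pytest.approx(ref.statistic, abs=1e-9, rel=1e-9)
            assert res.p_value[i, j] == pytest.approx(ref.p_value, abs=1e-12, rel=1e-9)


def test_single_genotype_group_pair_skipped():
    phi = np.random.default_rng(0).uniform(size=(2, 20))
    codes = np.zeros((1, 20))
    res = test_components(phi, codes)
    assert np.isnan(res.p_value).all()


def test_null_component_pvalues_calibrated():
    """Components independent of genotype: rejection rate ~ alpha."""
    rng = np.random.default_rng(123)
    phi = rng.uniform(0, np.pi / 2, size=(200, 150))
    codes = rng.choice([0.0, 1.0, 2.0], size=(50, 150), p=[0.49, 0.42, 0.09])
    res = test_components(phi, codes, model="anova")
    p = res.p_value[np.isfinite(res.p_value)]
    for alpha in (0.01, 0.05):
        se = np.sqrt(alpha * (1 - alpha) / p.size)
        assert abs((p < alpha).mean() - alpha) < 3 * se
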