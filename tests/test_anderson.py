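import numpy as np
import pytest
from scipy import stats

from compsqtl import hellinger_distance, permutation_p, pseudo_f, ss_decomposition
from compsqtl.anderson import bartlett_homogeneity_p, ss_decomposition_centroid
from compsqtl.fasttest import anova_test
from compsqtl.sphere import to_sphere


class TestHellingerDistance:
    def test_identical_vectors(self):
        assert hellinger_distance([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_maximal_distance_is_sqrt2(self):
        assert hellinger_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.sqrt(2))

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        a, b = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        expected = np.sqrt(sum((np.sqrt(x) - np.sqrt(y)) ** 2 for x, y in zip(a, b)))
        assert hellinger_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hellinger_distance([0.5, 0.5], [1.0, 0.0, 0.0])


def _random_case(seed, n_iso=3, n=40):
    rng = np.random.default_rng(seed)
    ratios = rng.dirichlet(np.ones(n_iso) * 2, size=n).T
    groups = rng.choice([0.0, 1.0, 2.0], size=n)
    return ratios, groups


class TestSSDecomposition:
    @pytest.mark.parametrize("seed", range(10))
    def test_total_equals_within_plus_between(self, seed):
        ratios, groups = _random_case(seed)
        dec = ss_decomposition(ratios, groups)
        assert dec.ss_total == pytest.approx(dec.ss_within + dec.ss_between, abs=1e-9)
        assert dec.ss_between >= -1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_pairwise_route_equals_centroid_route(self, seed):
        ratios, groups = _random_case(seed, n_iso=4)
        a = ss_decomposition(ratios, groups)
        b = ss_decomposition_centroid(ratios, groups)
        assert a.ss_total == pytest.approx(b.ss_total, abs=1e-9)
        assert a.ss_within == pytest.approx(b.ss_within, abs=1e-9)

    def test_nan_groups_rejected(self):
        ratios, groups = _random_case(0)
        groups[0] = np.nan
        with pytest.raises(ValueError):
            ss_decomposition(ratios, groups)


class TestPseudoF:
    def test_identical_group_distributions_give_zero(self):
        # both groups contain the same two points: group centroids coincide
        block = np.array([[0.7, 0.1], [0.2, 0.3], [0.1, 0.6]])
        ratios = np.hstack([block, block])
        groups = np.array([0.0, 0.0, 1.0, 1.0])
        assert pseudo_f(ratios, groups) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_reordering_within_groups(self):
        ratios, groups = _random_case(3)
        f1 = pseudo_f(ratios, groups)
        order = np.argsort(groups, kind="mergesort")
        f2 = pseudo_f(ratios[:, order], groups[order])
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        ratios, _ = _random_case(4, n=5)
        groups = np.array([0.0, 0.0, 0.0, 0.0, 1.0])  # one group of size 1
        with pytest.raises(ValueError):
            pseudo_f(ratios, groups)

    def test_two_isoform_ranking_agrees_with_fast_anova(self):
        """For n=2 genes the Hellinger F and the component ANOVA F rank
        gene-variant pairs near-identically."""
        rng = np.random.default_rng(7)
        f_ref, f_fast = [], []
        for rep in range(30):
            shift = rng.uniform(0, 3.0)
            n = 60
            g = rng.choice([0.0, 1.0, 2.0], size=n)
            alpha0 = np.array([2.0, 2.0])
            ratios = np.empty((2, n))
            for code in (0.0, 1.0, 2.0):
                idx = g == code
                alpha = alpha0 + np.array([shift * code / 2.0, 0.0])
                ratios[:, idx] = rng.dirichlet(alpha, size=int(idx.sum())).T
            f_ref.append(pseudo_f(ratios, g))
            phi = np.array([to_sphere(ratios[:, j]) [0] for j in range(n)])
            f_fast.append(anova_test(phi, g).statistic)
        rho = stats.spearmanr(f_ref, f_fast).statistic
        assert rho > 0.9


class TestPermutationP:
    def test_lower_bound_when_f_dominates(self):
        rng = np.random.default_rng(8)
        n = 30
        g = np.r_[np.zeros(15), np.ones(15)]
        ratios = np.empty((3, n))
        ratios[:, :15] = rng.dirichlet([20, 1, 1], size=15).T
        ratios[:, 15:] = rng.dirichlet([1, 1, 20], size=15).T
        p = permutation_p(ratios, g, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_same_seed_same_p(self):
        ratios, groups = _random_case(9)
        p1 = permutation_p(ratios, groups, n_perm=150, seed=5)
        p2 = permutation_p(ratios, groups, n_perm=150, seed=5)
        assert p1 == p2

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(40):
            ratios, groups = _random_case(100 + rep, n=30)
            ps.append(permutation_p(ratios, groups, n_perm=150, seed=rep))
        assert 0.2 < np.mean(ps) < 0.8

    def test_too_few_permutations_rejected(self):
        ratios, groups = _random_case(11)
        with pytest.raises(ValueError):
            permutation_p(ratios, groups, n_perm=50)


def test_bartlett_warning_detects_unequal_dispersion():
    rng = np.random.default_rng(12)
    n = 60
    g = np.r_[np.zeros(30), np.ones(30)]
    ratios = np.empty((3, n))
    ratios[:, :30] = rng.dirichlet([100, 100, 100], size=30).T  # tight
    ratios[:, 30:] = rng.dirichlet([1, 1, 1], size=30).T  # diffuse
    assert bartlett_homogeneity_p(ratios, g) < 0.01
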