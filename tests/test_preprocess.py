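import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compsqtl import (
    FilterConfig,
    GeneRatios,
    GenotypeMatrix,
    SplicingRatioSet,
    filter_isoforms_and_genes,
    filter_samples_per_gene,
    filter_variants,
    splicing_ratios,
    splicing_variability,
)
from compsqtl.preprocess import preprocess
from compsqtl.io import align_samples


class TestSplicingRatios:
    @pytest.mark.parametrize(
        "col, pseudo, expected",
        [
            ([2.0, 2.0, 0.0], 0.0, [0.5, 0.5, 0.0]),
            ([0.0, 0.0], 0.5, [0.5, 0.5]),
            ([3.0, 1.0], 1.0, [4 / 6, 2 / 6]),
        ],
    )
    def test_known_columns(self, col, pseudo, expected):
        out = splicing_ratios(np.array(col)[:, None], pseudo)
        np.testing.assert_allclose(out[:, 0], expected)

    @given(
        st.integers(2, 6),
        st.integers(1, 8),
        st.floats(1e-4, 1.0),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_one(self, n, l, pseudo, seed):
        x = np.random.default_rng(seed).gamma(1.0, 5.0, size=(n, l))
        out = splicing_ratios(x, pseudo)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-9)
        assert (out >= 0).all()


def _ratio_set(mat, sample_ids=None, gene_id="g1"):
    mat = np.asarray(mat, float)
    sample_ids = sample_ids or [f"s{i}" for i in range(mat.shape[1])]
    rs = SplicingRatioSet(sample_ids=sample_ids)
    rs.genes[gene_id] = GeneRatios(
        gene_id=gene_id,
        isoform_ids=[f"i{k}" for k in range(mat.shape[0])],
        ratios=mat,
        sample_mask=np.ones(mat.shape[1], dtype=bool),
    )
    return rs


class TestActivityFilter:
    def test_trace_isoform_dropped_and_renormalized(self):
        rs = _ratio_set(np.tile([[0.6], [0.39], [0.01]], (1, 3)))
        out = filter_isoforms_and_genes(rs, FilterConfig(active_ratio_threshold=0.05))
        g = out.genes["g1"]
        assert g.isoform_ids == ["i0", "i1"]
        np.testing.assert_allclose(g.ratios.sum(axis=0), 1.0)
        np.testing.assert_allclose(g.ratios[:, 0], [0.6 / 0.99, 0.39 / 0.99])

    def test_gene_with_one_dominant_isoform_removed(self):
        rs = _ratio_set(np.tile([[0.97], [0.02], [0.01]], (1, 3)))
        out = filter_isoforms_and_genes(rs, FilterConfig(active_ratio_threshold=0.05))
        assert not out.genes

    def test_zero_threshold_is_identity(self):
        mat = np.array([[0.7, 0.5], [0.2, 0.3], [0.1, 0.2]])
        rs = _ratio_set(mat)
        out = filter_isoforms_and_genes(rs, FilterConfig(active_ratio_threshold=0.0))
        np.testing.assert_allclose(out.genes["g1"].ratios, mat)


class TestSplicingVariability:
    def test_identical_columns_give_zero(self):
        mat = np.tile([[0.5], [0.3], [0.2]], (1, 6))
        assert splicing_variability(mat) == pytest.approx(0.0, abs=1e-12)

    def test_two_opposite_vertices_match_centroid_oracle(self):
        # brute-force oracle: centroid = renormalized mean of sqrt-ratio vectors
        mat = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = np.sqrt(mat)
        c = q.mean(axis=1)
        c = c / np.linalg.norm(c)
        expected = np.mean([np.sum((q[:, j] - c) ** 2) for j in range(2)])
        assert splicing_variability(mat) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2 - np.sqrt(2), abs=1e-12)

    def test_invariance_under_permutation_and_replication(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet([2, 1, 1], size=9).T
        v = splicing_variability(mat)
        perm = rng.permutation(9)
        assert splicing_variability(mat[:, perm]) == pytest.approx(v, rel=1e-12)
        assert splicing_variability(np.hstack([mat, mat])) == pytest.approx(v, rel=1e-12)


class TestSampleFilter:
    @pytest.mark.parametrize(
        "sums, threshold, expected",
        [
            ([0.2, 0.005, 0.011], 0.01, [True, False, True]),
            ([0.0, 0.0], 0.01, [False, False]),
            ([0.5, 0.1], 0.0, [True, True]),
        ],
    )
    def test_strict_threshold_on_column_sums(self, sums, threshold, expected):
        expr = np.asarray(sums)[None, :]  # single isoform carries the sums
        cfg = FilterConfig(min_gene_expression=threshold)
        assert filter_samples_per_gene(expr, cfg).tolist() == expected


class TestVariantFilter:
    def _geno(self, sizes):
        codes = np.concatenate(
            [np.full(n, code) for code, n in sizes.items()]
        ).astype(float)
        return GenotypeMatrix(
            variant_ids=["v"],
            sample_ids=[f"s{i}" for i in range(codes.size)],
            codes=codes[None, :],
        )

    def test_small_group_masked_variant_kept(self):
        out = filter_variants(self._geno({0: 50, 1: 30, 2: 3}), FilterConfig())
        assert out.n_variants == 1
        row = out.codes[0]
        assert np.isnan(row[(np.arange(83) >= 80)]).all()
        assert (row[:80] == np.r_[np.zeros(50), np.ones(30)]).all()

    def test_single_surviving_group_drops_variant(self):
        out = filter_variants(self._geno({0: 90, 1: 4, 2: 2}), FilterConfig())
        assert out.n_variants == 0

    def test_boundary_groups_unchanged(self):
        out = filter_variants(self._geno({0: 5, 1: 5, 2: 5}), FilterConfig())
        assert out.n_variants == 1
        assert not np.isnan(out.codes).any()

    def test_never_increases_non_na_entries(self):
        rng = np.random.default_rng(11)
        codes = rng.choice([0.0, 1.0, 2.0, np.nan], size=(30, 40), p=[0.5, 0.3, 0.1, 0.1])
        geno = GenotypeMatrix(
            variant_ids=[f"v{i}" for i in range(30)],
            sample_ids=[f"s{j}" for j in range(40)],
            codes=codes,
        )
        out = filter_variants(geno, FilterConfig())
        assert (~np.isnan(out.codes)).sum() <= (~np.isnan(codes)).sum()


def test_full_preprocess_counts_on_simulated_data(sim_data):
    expr, geno = sim_data
    expr, geno = align_samples(expr, geno)
    ratio_set, geno_f, counts = preprocess(expr, geno, FilterConfig())
    ratio_set.validate()
    assert counts["input_genes"] == 10
    assert counts["genes_after_sample_filter"] == len(ratio_set.genes) > 0
    assert geno_f.n_variants == counts["variants_after_group_filter"] > 0
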