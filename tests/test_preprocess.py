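import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ssges import preprocess
from ssges.preprocess import FilterParams


def mat(rows, genes=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestLog2Transform:
    def test_plain_log2(self):
        out = preprocess.log2_transform(mat([[8.0]]), floor=1.0)
        assert out.iloc[0, 0] == 3.0

    def test_floor_clamp(self):
        out = preprocess.log2_transform(mat([[0.1]]), floor=1.0)
        assert out.iloc[0, 0] == 0.0

    def test_missing_passthrough(self):
        out = preprocess.log2_transform(mat([[np.nan, 4.0]]), floor=1.0)
        assert np.isnan(out.iloc[0, 0]) and out.iloc[0, 1] == 2.0

    def test_nonpositive_floor(self):
        with pytest.raises(ValueError):
            preprocess.log2_transform(mat([[1.0]]), floor=0.0)


class TestQuantileNormalize:
    def test_rank_means_two_columns(self):
        out = preprocess.quantile_normalize(mat([[2, 4], [6, 8]]))
        np.testing.assert_allclose(out.to_numpy(), [[3, 3], [7, 7]])

    def test_already_identical_is_fixed_point(self):
        m = mat([[1, 1], [5, 5], [9, 9]])
        out = preprocess.quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_ties_share_mean_of_rank_means(self):
        # column A tied at 5: both entries get the mean (3+4)/2 = 3.5
        out = preprocess.quantile_normalize(mat([[5, 1], [5, 3]]))
        np.testing.assert_allclose(out.to_numpy(), [[3.5, 3.0], [3.5, 4.0]])

    def test_single_sample_warns_and_returns_copy(self):
        m = mat([[1], [2]])
        with pytest.warns(UserWarning):
            out = preprocess.quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_missing_values_stay_missing(self):
        m = mat([[1, 2], [np.nan, 4], [5, 6]])
        out = preprocess.quantile_normalize(m)
        assert np.isnan(out.iloc[1, 0])
        assert out.notna().sum().sum() == 5

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        arrays(
            np.float64,
            (12, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_sorted_columns_identical_and_idempotent(self, X):
        X = X + np.arange(48).reshape(12, 4) * 1e-6  # break exact ties
        out = preprocess.quantile_normalize(mat(X))
        V = out.to_numpy()
        sorted_cols = np.sort(V, axis=0)
        for j in range(1, V.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)
        again = preprocess.quantile_normalize(out)
        np.testing.assert_allclose(again.to_numpy(), V, atol=1e-9)


class TestVariationFilter:
    def test_constant_gene_excluded(self):
        out = preprocess.variation_filter(mat([np.full(10, 5.0)]))
        assert len(out) == 0

    def test_exactly_ten_percent_retained(self):
        # one of ten values deviates by 1 >= log2(1.5): fraction exactly 10%
        gene = [5, 5, 5, 5, 5, 5, 5, 5, 5, 6]
        out = preprocess.variation_filter(mat([gene]))
        assert len(out) == 1

    def test_missingness_rule(self):
        gene = [1, 10] + [np.nan] * 8  # 80% missing > 60%
        out = preprocess.variation_filter(mat([gene]))
        assert len(out) == 0

    def test_all_missing_gene_excluded_not_error(self):
        out = preprocess.variation_filter(mat([[np.nan] * 5, [0, 0, 9, 9, 9]]))
        assert list(out.index) == ["g1"]

    def test_preserves_gene_order(self):
        m = mat([[0, 9, 0, 9], [1, 1, 1, 1], [0, 8, 0, 8]])
        out = preprocess.variation_filter(m)
        assert list(out.index) == ["g0", "g2"]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        arrays(np.float64, (15, 10), elements=st.floats(0, 16, allow_nan=False)),
        st.floats(0.05, 0.5),
        st.floats(1.2, 3.0),
    )
    def test_monotone_in_thresholds(self, X, min_frac, fc):
        m = mat(X)
        loose = preprocess.variation_filter(m, FilterParams(fold_change=1.5, min_fraction=0.10))
        tight = preprocess.variation_filter(
            m,
            FilterParams(
                fold_change=max(fc, 1.5), min_fraction=max(min_frac, 0.10)
            ),
        )
        assert set(tight.index) <= set(loose.index)


class TestAverageReplicates:
    def test_mean_of_replicates(self):
        m = mat([[1, 3], [3, 5]], genes=["p1", "p2"])
        out = preprocess.average_replicates(m, {"p1": "G", "p2": "G"})
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [2, 4])

    def test_singleton_identity(self):
        m = mat([[1, 2]], genes=["p1"])
        out = preprocess.average_replicates(m, {"p1": "G"})
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [1, 2])

    def test_missing_ignored_in_mean(self):
        m = mat([[2, 1], [np.nan, 3]], genes=["p1", "p2"])
        out = preprocess.average_replicates(m, {"p1": "G", "p2": "G"})
        np.testing.assert_allclose(out.loc["G"].to_numpy(), [2, 2])

    def test_empty_map_identity(self, small_matrix):
        out = preprocess.average_replicates(small_matrix, {})
        pd.testing.assert_frame_equal(out, small_matrix)


class TestCollapseProbes:
    def test_max_mean_probe_kept(self):
        m = mat([[5, 5], [7, 7]], genes=["p1", "p2"])
        out = preprocess.collapse_probes(m, {"p1": "X", "p2": "X"})
        assert list(out.index) == ["X"]
        np.testing.assert_allclose(out.loc["X"].to_numpy(), [7, 7])

    def test_tie_keeps_earlier_probe(self):
        m = mat([[3, 5], [5, 3]], genes=["p1", "p2"])
        out = preprocess.collapse_probes(m, {"p1": "X", "p2": "X"})
        np.testing.assert_allclose(out.loc["X"].to_numpy(), [3, 5])

    def test_unmapped_probe_error(self):
        m = mat([[1, 2]], genes=["p9"])
        with pytest.raises(KeyError, match="p9"):
            preprocess.collapse_probes(m, {"p1": "X"})

    def test_one_row_per_gene_and_shrinks(self, rng):
        m = mat(rng.normal(size=(10, 3)), genes=[f"p{i}" for i in range(10)])
        pmap = {f"p{i}": f"G{i % 4}" for i in range(10)}
        out = preprocess.collapse_probes(m, pmap)
        assert len(out) == 4 and len(out) <= len(m)
        assert not out.index.has_duplicates


class TestCenterScale:
    def test_unit_sd_row(self):
        out = preprocess.center_scale_genes(mat([[1, 2, 3]]))
        np.testing.assert_allclose(out.to_numpy(), [[-1, 0, 1]])

    def test_postcondition_mean0_sd1(self, rng):
        m = mat(rng.normal(5, 3, size=(6, 9)))
        out = preprocess.center_scale_genes(m)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_error(self):
        with pytest.raises(ValueError, match="g0"):
            preprocess.center_scale_genes(mat([[2, 2, 2]]))


class TestClusterSamples:
    def test_identical_samples_merge_first(self, rng):
        base = rng.normal(size=20)
        X = np.column_stack([base, base, rng.normal(size=20)])
        d = preprocess.cluster_samples(mat(X))
        # first merge joins leaves 0 and 1 at height 0
        assert set(d.linkage[0, :2].astype(int)) == {0, 1}
        assert d.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_sample_distance_two(self, rng):
        base = rng.normal(size=20)
        X = np.column_stack([base, -base])
        d = preprocess.cluster_samples(mat(X))
        assert d.linkage[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_planted_pairs_separate_in_leaf_order(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        X = np.column_stack(
            [a + 0.01 * rng.normal(size=30), a + 0.01 * rng.normal(size=30),
             b + 0.01 * rng.normal(size=30), b + 0.01 * rng.normal(size=30)]
        )
        d = preprocess.cluster_samples(mat(X, samples=["a1", "a2", "b1", "b2"]))
        order = d.leaf_order
        assert {order[0], order[1]} in ({"a1", "a2"}, {"b1", "b2"})
        assert {order[2], order[3]} in ({"a1", "a2"}, {"b1", "b2"})

    def test_too_few_shared_genes_error(self):
        X = np.array([[1.0, np.nan], [np.nan, 2.0], [3.0, 4.0], [5.0, 6.0]])
        with pytest.raises(ValueError, match="fewer than 3"):
            preprocess.cluster_samples(mat(X))

    def test_newick_contains_all_leaves(self, rng):
        X = rng.normal(size=(25, 5))
        d = preprocess.cluster_samples(mat(X))
        nwk = d.to_newick()
        assert nwk.endswith(";")
        for s in d.sample_ids:
            assert s in nwk
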