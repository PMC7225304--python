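import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssges import diffexp


def mat(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])])


AB = ["a"] * 4 + ["b"] * 4


class TestTTest:
    def test_identical_groups_t0_p1(self):
        r = diffexp.ttest_per_gene(mat([[1, 2, 3, 1, 2, 3]]), ["a"] * 3 + ["b"] * 3)
        assert r.table["t"].iloc[0] == 0.0
        assert r.table["p"].iloc[0] == 1.0

    def test_pooled_t_closed_form(self):
        r = diffexp.ttest_per_gene(mat([[1, 2, 3, 4, 3, 4, 5, 6]]), AB)
        assert r.table["t"].iloc[0] == pytest.approx(-2.1909, abs=1e-4)
        # matches scipy's pooled-variance t-test
        ref = stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6])
        assert r.table["t"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)
        assert r.table["p"].iloc[0] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_flagged_unevaluable(self):
        r = diffexp.ttest_per_gene(mat([[0, 0, 1, 1]]), ["a", "a", "b", "b"])
        assert not r.table["evaluable"].iloc[0]
        assert len(r.table) == 1  # flagged, not dropped

    def test_group_entirely_missing_flagged(self):
        r = diffexp.ttest_per_gene(
            mat([[np.nan, np.nan, 1, 2, 3, 4]]), ["a", "a", "a", "b", "b", "b"]
        )
        assert not r.table["evaluable"].iloc[0]

    def test_direction_matches_sign(self, rng):
        m = mat(rng.normal(size=(50, 10)))
        r = diffexp.ttest_per_gene(m, ["a"] * 5 + ["b"] * 5)
        ok = r.table["evaluable"]
        up = r.table.loc[ok & (r.table["direction"] == "up"), "t"]
        assert (up >= 0).all()

    def test_welch_flag(self):
        r = diffexp.ttest_per_gene(mat([[1, 2, 3, 4, 3, 4, 5, 6]]), AB, welch=True)
        ref = stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=False)
        assert r.table["t"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)


class TestSelectSignificant:
    def _result(self, pvals):
        t = pd.DataFrame(
            {
                "t": 1.0,
                "p": pvals,
                "direction": "up",
                "n1": 3,
                "n2": 3,
                "evaluable": True,
            },
            index=[f"g{i}" for i in range(len(pvals))],
        )
        return diffexp.ClassComparisonResult(table=t, group_levels=["a", "b"])

    def test_strict_threshold(self):
        r = self._result([1e-8, 1e-3])
        assert diffexp.select_significant(r, 1e-7) == ["g0"]

    def test_alpha_one_keeps_all_evaluable(self):
        r = self._result([0.2, 0.999])
        assert diffexp.select_significant(r, 1.0) == ["g0", "g1"]

    def test_boundary_p_excluded(self):
        r = self._result([0.01])
        assert diffexp.select_significant(r, 0.01) == []

    def test_monotone_shrinkage(self):
        r = self._result([1e-9, 1e-6, 1e-4, 1e-2])
        prev = None
        for alpha in (1e-1, 1e-3, 1e-5, 1e-8):
            cur = set(diffexp.select_significant(r, alpha))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestSamStatistic:
    def test_identical_groups_d0(self):
        d = diffexp.sam_statistic(mat([[1, 2, 3, 1, 2, 3]]), ["a"] * 3 + ["b"] * 3)
        assert d.iloc[0] == 0.0

    def test_s0_zero_equals_pooled_t_random(self, two_group_matrix):
        m, labels = two_group_matrix
        d = diffexp.sam_statistic(m, labels, s0=0.0)
        t = diffexp.ttest_per_gene(m, labels).table["t"]
        np.testing.assert_allclose(d.to_numpy(), t.to_numpy(), atol=1e-9)

    def test_hand_value_with_fudge(self):
        d = diffexp.sam_statistic(mat([[1, 2, 3, 4, 3, 4, 5, 6]]), AB, s0=0.5)
        assert d.iloc[0] == pytest.approx(-1.4156, abs=1e-4)

    def test_degenerate_gene_nan(self):
        d = diffexp.sam_statistic(mat([[2, 2, 2, 2]]), ["a", "a", "b", "b"], s0=0.0)
        assert np.isnan(d.iloc[0])


class TestChooseS0:
    def test_all_s_equal_gives_zero(self):
        # equal spread in every gene -> identical s(i) -> s0 = 0
        base = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        m = mat([base + k for k in range(12)])
        assert diffexp.choose_s0(m, ["a"] * 3 + ["b"] * 3) == 0.0

    def test_two_scale_data_selects_positive_s0(self, rng):
        lo = rng.normal(0, 0.05, size=(300, 12))
        hi = rng.normal(0, 0.5, size=(300, 12))
        m = mat(np.vstack([lo, hi]))
        s0 = diffexp.choose_s0(m, ["a"] * 6 + ["b"] * 6)
        assert s0 > 0

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError):
            diffexp.choose_s0(mat([[1, 2, 3, 4]]), ["a", "a", "b", "b"])


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, two_group_matrix):
        m, labels = two_group_matrix
        n1, dbar1 = diffexp.sam_permutation_null(m, labels, n_perm=20, seed=7)
        n2, dbar2 = diffexp.sam_permutation_null(m, labels, n_perm=20, seed=7)
        np.testing.assert_array_equal(n1, n2)
        np.testing.assert_array_equal(dbar1, dbar2)

    def test_small_groups_enumerate_all_assignments(self):
        m = mat(np.arange(40, dtype=float).reshape(10, 4))
        null, _ = diffexp.sam_permutation_null(
            m, ["a", "a", "b", "b"], n_perm=1000, seed=0
        )
        assert null.shape[0] == math.comb(4, 2)

    def test_null_dbar_centred_near_zero(self, rng):
        m = mat(rng.normal(size=(500, 16)))
        _, dbar = diffexp.sam_permutation_null(
            m, ["a"] * 8 + ["b"] * 8, n_perm=60, seed=3
        )
        se = dbar.std() / np.sqrt(len(dbar))
        assert abs(dbar.mean()) < 3 * max(se, 0.01)

    def test_label_swap_negates_d(self, two_group_matrix):
        m, labels = two_group_matrix
        d_ab = diffexp.sam_statistic(m, labels, s0=0.1, levels=["A", "B"])
        d_ba = diffexp.sam_statistic(m, labels, s0=0.1, levels=["B", "A"])
        np.testing.assert_allclose(d_ab.to_numpy(), -d_ba.to_numpy(), atol=1e-12)


class TestSamCallAndDelta:
    @pytest.fixture
    def fitted_null(self, two_group_matrix):
        m, labels = two_group_matrix
        d = diffexp.sam_statistic(m, labels, s0=0.0)
        null, dbar = diffexp.sam_permutation_null(m, labels, n_perm=50, seed=1)
        return d, dbar, null

    def test_infinite_delta_calls_nothing_fdr_zero(self, fitted_null):
        d, dbar, null = fitted_null
        res = diffexp.sam_call(d, dbar, null, delta=1e9)
        assert res.table["called"].sum() == 0
        assert res.fdr_estimate == 0.0

    def test_delta_zero_is_maximal_call_set(self, fitted_null):
        d, dbar, null = fitted_null
        res0 = diffexp.sam_call(d, dbar, null, delta=0.0)
        res1 = diffexp.sam_call(d, dbar, null, delta=0.5)
        assert res0.table["called"].sum() >= res1.table["called"].sum()

    def test_target_fdr_one_gives_delta_zero(self, fitted_null):
        d, dbar, null = fitted_null
        assert diffexp.sam_select_delta(d, dbar, null, target_fdr=1.0) == 0.0

    def test_strong_signal_recovered(self, rng):
        X = rng.normal(0, 1, size=(500, 20))
        planted = np.arange(50)
        X[np.ix_(planted, np.arange(10))] += 5.0  # 5 SD shift in group a
        m = mat(X)
        labels = ["a"] * 10 + ["b"] * 10
        s0 = diffexp.choose_s0(m, labels)
        d = diffexp.sam_statistic(m, labels, s0=s0)
        null, dbar = diffexp.sam_permutation_null(m, labels, n_perm=100, seed=2, s0=s0)
        delta = diffexp.sam_select_delta(d, dbar, null, target_fdr=0.01)
        res = diffexp.sam_call(d, dbar, null, delta)
        called = set(res.called_genes)
        hits = called & {f"g{i}" for i in planted}
        assert len(hits) >= 45  # >= 90% of planted genes
        assert res.fdr_estimate <= 0.01


class TestSAMEstimator:
    def test_fit_attributes_and_support(self, rng):
        X = rng.normal(size=(20, 100))
        X[:10, :10] += 4.0
        y = np.array(["a"] * 10 + ["b"] * 10)
        est = diffexp.SAM(target_fdr=0.05, n_permutations=50, random_state=0)
        est.fit(X, y)
        assert est.d_.shape == (100,)
        assert est.s0_ >= 0
        assert est.get_support().dtype == bool
        assert est.get_support()[:10].sum() >= 9

    def test_sklearn_param_interface(self):
        est = diffexp.SAM(target_fdr=0.2)
        assert est.get_params()["target_fdr"] == 0.2
        est.set_params(n_permutations=10)
        assert est.n_permutations == 10
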