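import numpy as np
import pytest
from scipy import stats

from nemtie.baselines import (
    auc_score,
    classification_metrics,
    compare_methods_resampled,
    laplacian_score_select,
    mrmr_select,
    pearson_pfdr,
    storey_qvalues,
)
from nemtie.data import split_cohort

from conftest import make_table
from oracles import pair_counting_auc


class TestAucScore:
    def test_perfect_and_inverted_ranking(self):
        y = [0, 0, 1, 1]
        assert auc_score([1, 2, 3, 4], y) == 1.0
        assert auc_score([4, 3, 2, 1], y) == 0.0

    def test_half_concordant_pairs(self):
        # scores [0.9, 0.8, 0.3], labels [1, 0, 1]: 1 of 2 pairs concordant
        assert auc_score([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_ties_get_half_credit(self):
        assert auc_score([1.0, 1.0], [0, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 51))
        scores = np.round(rng.standard_normal(m), 1)  # rounding forces ties
        labels = rng.integers(0, 2, m)
        if labels.sum() in (0, m):
            labels[0] = 1 - labels[0]
        assert auc_score(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        assert auc_score(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([1, 2], [1, 1])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = np.array([0] * 10 + [1] * 10)
        scores = np.where(y == 1, 2.0, -2.0)
        m = classification_metrics(scores, y, n_boot=100, seed=0)
        assert m.auc == m.sensitivity == m.specificity == 1.0

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 25)
        scores = rng.standard_normal(50) + y
        m = classification_metrics(scores, y, n_boot=500, seed=2)
        for name, value in [("AUC", m.auc), ("Sensitivity", m.sensitivity),
                            ("Specificity", m.specificity)]:
            lo, hi = m.ci[name]
            assert lo <= value <= hi

    def test_bootstrap_stability_under_more_reps(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 40)
        scores = rng.standard_normal(80) + 1.2 * y
        a = classification_metrics(scores, y, n_boot=500, seed=4)
        b = classification_metrics(scores, y, n_boot=5000, seed=5)
        for metric in ("AUC", "Sensitivity", "Specificity"):
            assert abs(a.ci[metric][0] - b.ci[metric][0]) < 0.05
            assert abs(a.ci[metric][1] - b.ci[metric][1]) < 0.05

    def test_youden_operating_point(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([-3.0, -2.0, 5.0, 4.0, 6.0, 7.0])
        fixed = classification_metrics(scores, y, n_boot=10, seed=0)
        youden = classification_metrics(scores, y, operating="youden", n_boot=10, seed=0)
        assert youden.sensitivity + youden.specificity >= fixed.sensitivity + fixed.specificity


class TestMrmrSelect:
    def test_label_identical_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 30)
        X = np.column_stack([rng.standard_normal(60), y.astype(float),
                             rng.standard_normal(60)])
        assert mrmr_select(make_table(X, y), n_select=1)[0] == 1

    def test_duplicate_penalized_by_redundancy(self):
        # f0 == f1 (both informative), f2 independent and mildly informative:
        # after picking f0, mRMR must prefer f2 over the exact duplicate f1
        rng = np.random.default_rng(1)
        y = np.tile([0, 1], 40)
        strong = y + 0.1 * rng.standard_normal(80)
        mild = 0.8 * y + rng.standard_normal(80)
        table = make_table(np.column_stack([strong, strong, mild]), y)
        order = mrmr_select(table, n_select=3)
        assert order[0] == 0
        assert order[1] == 2
        assert order[2] == 1

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.standard_normal((50, 8)), [0, 1] * 25)
        assert mrmr_select(table, n_select=5) == mrmr_select(table, n_select=5)

    def test_invalid_n_select(self):
        table = make_table(np.zeros((4, 2)), [0, 1, 0, 1])
        with pytest.raises(ValueError):
            mrmr_select(table, n_select=0)
        with pytest.raises(ValueError):
            mrmr_select(table, n_select=5)


class TestLaplacianScoreSelect:
    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal((30, 3)), np.full(30, 2.0)])
        table = make_table(X, [0, 1] * 15)
        order = laplacian_score_select(table, n_select=4)
        assert order[-1] == 3

    def test_cluster_separating_feature_beats_noise(self):
        # two tight sample clusters along f0; f1 is white noise
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cluster = np.repeat([0.0, 8.0], 20)
            X = np.column_stack(
                [cluster + 0.2 * rng.standard_normal(40), rng.standard_normal(40)]
            )
            table = make_table(X, [0, 1] * 20)
            if laplacian_score_select(table, n_select=2)[0] == 0:
                wins += 1
        assert wins >= 8

    def test_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 5))
        table = make_table(X, [0, 1] * 12 + [0])
        perm = [3, 1, 4, 0, 2]
        table_p = make_table(X[:, perm], [0, 1] * 12 + [0])
        a = laplacian_score_select(table, n_select=5)
        b = laplacian_score_select(table_p, n_select=5)
        assert [perm[j] for j in b] == a

    def test_knn_must_be_smaller_than_m(self):
        table = make_table(np.zeros((4, 2)), [0, 1, 0, 1])
        with pytest.raises(ValueError):
            laplacian_score_select(table, n_select=1, knn=4)


class TestPearsonPfdr:
    def test_label_identical_feature(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 20)
        X = np.column_stack([y.astype(float), rng.standard_normal(40)])
        rep = pearson_pfdr(make_table(X, y))
        assert rep.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert rep.loc[0, "p_value"] < 1e-10

    def test_zero_variance_feature_flagged(self):
        y = np.array([0, 1] * 5)
        X = np.column_stack([np.ones(10), y.astype(float)])
        rep = pearson_pfdr(make_table(X, y))
        assert rep.loc[0, "zero_variance"]
        assert rep.loc[0, "pearson_r"] == 0.0 and rep.loc[0, "p_value"] == 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        X = rng.standard_normal((100, 1000))
        rep = pearson_pfdr(make_table(X, y))
        ks = stats.kstest(rep["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_qvalues_preserve_p_ordering(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_matches_bh_when_pi0_is_one(self):
        # with pi0 = 1 the q-values reduce to Benjamini-Hochberg adjusted p
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)  # < 100 tests forces the pi0 = 1 fallback
        q = storey_qvalues(p)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)


class TestCompareMethodsResampled:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * 40)
        X = rng.standard_normal((80, 5))
        X[:, 0] += y
        return make_table(X, y)

    def test_identical_methods_give_t0_p1(self):
        table = self._table()

        def method(table, split, seed):
            return 0.75

        aucs, comp = compare_methods_resampled(
            table, {"a": method, "b": method}, n_resamples=5
        )
        assert comp.loc[0, "t"] == 0.0 and comp.loc[0, "p_value"] == 1.0

    def test_constant_shift_detected(self):
        table = self._table(1)
        rng = np.random.default_rng(2)

        def base(table, split, seed):
            return 0.6 + 0.02 * rng.standard_normal()

        history = {}

        def shifted(table, split, seed):
            return history[seed]

        # paired: shifted = base + 0.1 on the same resample
        def make_pair():
            def a(table, split, seed):
                v = base(table, split, seed)
                history[seed] = v + 0.1
                return v

            return a

        aucs, comp = compare_methods_resampled(
            table, {"base": make_pair(), "shifted": shifted}, n_resamples=10
        )
        assert comp.loc[0, "p_value"] < 0.01
        assert comp.loc[0, "t"] < 0

    def test_one_sided_p_is_half_two_sided_for_positive_t(self):
        table = self._table(3)
        rng = np.random.default_rng(4)
        vals = {}

        def better(table, split, seed):
            v = 0.8 + 0.05 * rng.standard_normal()
            vals[seed] = v - 0.07
            return v

        def worse(table, split, seed):
            return vals[seed]

        methods = {"better": better, "worse": worse}
        _, two = compare_methods_resampled(table, dict(methods), n_resamples=8, sides="two")
        rng = np.random.default_rng(4)
        vals.clear()
        _, one = compare_methods_resampled(table, dict(methods), n_resamples=8, sides="one")
        assert one.loc[0, "t"] > 0
        assert one.loc[0, "p_value"] == pytest.approx(two.loc[0, "p_value"] / 2, rel=1e-9)

    def test_failing_method_dropped_pairwise(self):
        table = self._table(5)

        def good(table, split, seed):
            return 0.7

        calls = {"n": 0}

        def flaky(table, split, seed):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return 0.6

        aucs, comp = compare_methods_resampled(
            table, {"good": good, "flaky": flaky}, n_resamples=4
        )
        assert aucs["flaky"].isna().sum() == 1
        assert comp.loc[0, "n"] == 3
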