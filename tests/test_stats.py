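"""Metrics, AUC comparisons, and normality-gated univariate tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazescreen import compute_metrics, compare_stages, correlate, group_compare
from gazescreen.screening import StagePredictions
from gazescreen.stats import rank_auc

from oracles import auc_bruteforce, confusion_bruteforce


def make_preds(labels, proba, stage="s"):
    labels = np.asarray(labels)
    return StagePredictions(stage, np.arange(labels.size), np.asarray(proba, float),
                            labels, np.zeros(labels.size, int))


class TestMetrics:
    def test_perfect_probabilities(self):
        y = np.array([1, 1, 1, 0, 0])
        m = compute_metrics(make_preds(y, y.astype(float)))
        assert (m.accuracy, m.recall, m.precision, m.f1, m.auc) == (1, 1, 1, 1, 1)

    def test_all_half_ties_auc(self):
        y = np.array([1, 0, 1, 0])
        m = compute_metrics(make_preds(y, np.full(4, 0.5)))
        assert m.auc == 0.5

    def test_twenty_subject_oracle(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 8 + [0] * 12)
        p = rng.uniform(size=20)
        m = compute_metrics(make_preds(y, p))
        tp, fp, fn, tn = confusion_bruteforce(y, p)
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert m.accuracy == pytest.approx((tp + tn) / 20)
        assert m.f1 == pytest.approx(2 * m.precision * m.recall
                                     / (m.precision + m.recall))
        assert m.auc == pytest.approx(auc_bruteforce(y, p))

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_bruteforce_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        p = np.round(rng.uniform(size=n), 2)   # induce ties
        assert rank_auc(y, p) == pytest.approx(auc_bruteforce(y, p))

    def test_auc_invariant_to_monotone_transform_metrics_not(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 10 + [0] * 10)
        p = rng.uniform(0.2, 0.8, 20)
        a = compute_metrics(make_preds(y, p))
        b = compute_metrics(make_preds(y, p ** 3))   # strictly monotone
        assert a.auc == pytest.approx(b.auc)
        assert (a.tp, a.fp) != (b.tp, b.fp)   # thresholded counts move

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError):
            compute_metrics(make_preds(np.ones(5, int), np.full(5, 0.7)))


class TestCompareStages:
    def test_identical_vectors_rank_sum(self):
        y = np.array([1] * 36 + [0] * 37)
        p = np.random.default_rng(1).uniform(size=73)
        res = compare_stages(make_preds(y, p, "a"), make_preds(y, p, "b"))
        assert res.statistic == pytest.approx(73 * 73 / 2)
        assert res.p_value > 0.9

    def test_stochastic_dominance_small_p(self):
        y = np.array([1] * 30 + [0] * 30)
        rng = np.random.default_rng(2)
        pa = rng.uniform(0.5, 1.0, 60)
        pb = rng.uniform(0.0, 0.5, 60)
        res = compare_stages(make_preds(y, pa, "a"), make_preds(y, pb, "b"))
        assert res.p_value < 1e-6

    def test_delong_identical_is_null(self):
        y = np.array([1] * 20 + [0] * 25)
        p = np.random.default_rng(3).uniform(size=45)
        res = compare_stages(make_preds(y, p, "a"), make_preds(y, p, "b"),
                             method="delong")
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_delong_detects_better_model(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 60 + [0] * 60)
        good = np.clip(y + rng.normal(0, 0.35, 120), 0, 1)
        bad = rng.uniform(size=120)
        res = compare_stages(make_preds(y, good, "a"), make_preds(y, bad, "b"),
                             method="delong")
        assert res.auc_a > res.auc_b and res.p_value < 0.01

    def test_subject_mismatch_rejected(self):
        y = np.array([1, 0, 1, 0])
        a = make_preds(y, np.full(4, 0.5), "a")
        b = StagePredictions("b", np.arange(10, 14), np.full(4, 0.5), y,
                             np.zeros(4, int))
        with pytest.raises(ValueError):
            compare_stages(a, b)

    def test_null_type_one_error_controlled(self):
        """Identical generating distributions: rejections at ~alpha."""
        alpha = 0.05
        rng = np.random.default_rng(5)
        y = np.array([1] * 36 + [0] * 37)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            pa = rng.uniform(size=73)
            pb = rng.uniform(size=73)
            res = compare_stages(make_preds(y, pa, "a"), make_preds(y, pb, "b"))
            rejections += res.p_value < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 2 * se


class TestGroupCompare:
    def test_gaussian_data_takes_t_test(self):
        rng = np.random.default_rng(6)
        res = group_compare(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert res.test == "t" and res.normal

    def test_lognormal_data_takes_mann_whitney(self):
        rng = np.random.default_rng(7)
        res = group_compare(rng.lognormal(0, 1.2, 150), rng.lognormal(0, 1.2, 150))
        assert res.test == "mann_whitney" and not res.normal

    def test_constant_sample_forces_mann_whitney(self):
        res = group_compare(np.full(10, 3.0), np.random.default_rng(8).normal(size=10))
        assert res.test == "mann_whitney" and res.normal is False

    def test_published_sex_table_chi_square(self):
        res = group_compare([45, 11], [33, 46], variable="sex", kind="categorical")
        assert res.test == "chi_square"
        assert res.p_value < 0.001

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_null_p_values_uniform(self):
        """Under equal-mean Gaussians the gated test's p-values are uniform."""
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(400):
            res = group_compare(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
            pvals.append(res.p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCorrelate:
    def test_self_correlation_is_one(self):
        x = pd.DataFrame({"a": np.random.default_rng(10).normal(size=50)})
        r, p, n = correlate(x, x)
        assert r.loc["a", "a"] == pytest.approx(1.0)

    def test_linear_relation_r_near_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        r, p, n = correlate(pd.DataFrame({"x": x}),
                            pd.DataFrame({"y": 2 * x + rng.normal(0, 1e-3, 200)}))
        assert r.loc["x", "y"] > 0.999

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(12)
        feats = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        scores = pd.DataFrame(rng.normal(size=(2000, 2)), columns=list("xy"))
        r, p, n = correlate(feats, scores)
        assert np.abs(r.to_numpy(float)).mean() < 0.05

    def test_missing_pairs_dropped_and_counted(self):
        x = pd.DataFrame({"a": [1, 2, 3, 4, np.nan, 6.0]})
        y = pd.DataFrame({"b": [2, 4, 6, 8, 10, np.nan]})
        r, p, n = correlate(x, y)
        assert n.loc["a", "b"] == 4
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        x = pd.DataFrame({"a": np.ones(10)})
        y = pd.DataFrame({"b": np.arange(10.0)})
        r, p, n = correlate(x, y)
        assert np.isnan(r.loc["a", "b"])
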