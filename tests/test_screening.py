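"""Dummy baseline, candidate screening, soft voting, and the model API."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from gazescreen import (ScreeningModel, dummy_accuracy, fit_soft_voting,
                        screen_candidates, tune)
from gazescreen.screening import default_members
from gazescreen.synth import CohortSpec, sample_feature_table


class FixedProba(BaseEstimator, ClassifierMixin):
    """Stub classifier emitting a constant P(ADHD) for every subject."""

    def __init__(self, p=0.5):
        self.p = p

    def fit(self, X, y):
        self.classes_ = np.array(sorted(set(y)))
        return self

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p),
                                np.full(len(X), self.p)])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def cohort_labels(n_adhd=56, n_tdc=79):
    return np.repeat([1, 0], [n_adhd, n_tdc])


class TestDummy:
    def test_published_cohort_split(self):
        y = cohort_labels()
        acc = dummy_accuracy(y, seed=0)
        # whole-sample majority rate is 79/135 ~ 0.585; stratified folding
        # lands within a percent of it
        assert acc == pytest.approx(79 / 135, abs=0.01)

    def test_balanced_half(self):
        assert dummy_accuracy(cohort_labels(50, 50), seed=1) == pytest.approx(0.5, abs=0.01)

    def test_single_class_perfect(self):
        assert dummy_accuracy(np.zeros(40, dtype=int), seed=2) == 1.0


class TestScreening:
    def test_planted_signal_flags_tree_ensembles(self):
        rng = np.random.default_rng(0)
        y = cohort_labels(40, 40)
        X = rng.standard_normal((80, 6))
        X[y == 1, :2] += 2.5
        res = screen_candidates(X, y, seed=0)
        assert res.superior["random_forest"] and res.superior["extra_trees"]

    def test_dummy_candidate_never_superior(self):
        from sklearn.dummy import DummyClassifier

        y = cohort_labels(30, 40)
        X = np.random.default_rng(1).standard_normal((70, 4))
        res = screen_candidates(X, y, {"dummy": DummyClassifier(strategy="most_frequent"),
                                       "other": FixedProba(0.2)}, seed=1)
        assert not res.superior["dummy"]

    def test_pure_noise_rarely_flagged(self):
        flags = 0
        trials = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = cohort_labels(28, 40)
            X = rng.standard_normal((68, 10))
            res = screen_candidates(
                X, y, {"rf": default_members(60, 5)["random_forest"],
                       "et": default_members(60, 5)["extra_trees"]}, seed=seed)
            flags += sum(res.superior.values())
            trials += 2
        assert flags / trials <= 0.10

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            screen_candidates(np.zeros((10, 2)), cohort_labels(5, 5),
                              {"only": FixedProba()})


class TestTune:
    def test_singleton_grid(self):
        from sklearn.ensemble import RandomForestClassifier

        X = np.random.default_rng(2).standard_normal((40, 3))
        y = cohort_labels(20, 20)
        best, acc = tune(RandomForestClassifier(n_estimators=20), X, y,
                         {"max_depth": [3]}, seed=2)
        assert best == {"max_depth": 3} and 0 <= acc <= 1

    def test_planted_optimum_wins(self):
        """A depth-1 stump suffices for a single-threshold rule, and deeper
        trees overfit the added noise: the grid prefers the shallow one."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(3)
        n = 200
        y = cohort_labels(n // 2, n // 2)
        X = rng.standard_normal((n, 8))
        X[:, 0] = y * 2.0 + rng.standard_normal(n) * 0.1
        best, _ = tune(DecisionTreeClassifier(), X, y,
                       {"max_depth": [1, None]}, seed=3)
        assert best == {"max_depth": 1}


class TestSoftVoting:
    def test_probability_averaging(self):
        y = cohort_labels(20, 20)
        X = pd.DataFrame(np.zeros((40, 2)))
        preds = fit_soft_voting(X, y, members={"a": FixedProba(0.8),
                                               "b": FixedProba(0.6)}, seed=0)
        np.testing.assert_allclose(preds.proba, 0.7)

    def test_identical_members_idempotent(self):
        y = cohort_labels(20, 20)
        X = pd.DataFrame(np.zeros((40, 2)))
        a = fit_soft_voting(X, y, members={"m1": FixedProba(0.3),
                                           "m2": FixedProba(0.3)}, seed=0)
        np.testing.assert_allclose(a.proba, 0.3)

    def test_member_permutation_invariance_and_bounds(self):
        spec = CohortSpec(seed=5, n_per_group={"ADHD": 20, "TDC": 25})
        wide = sample_feature_table(spec).wide()
        y = np.array([1] * 20 + [0] * 25)
        m = default_members(60, 3)
        a = fit_soft_voting(wide, y, members=m, seed=4)
        b = fit_soft_voting(wide, y, members=dict(reversed(list(m.items()))), seed=4)
        np.testing.assert_allclose(a.proba, b.proba)
        lo = np.minimum(a.member_proba["random_forest"], a.member_proba["extra_trees"])
        hi = np.maximum(a.member_proba["random_forest"], a.member_proba["extra_trees"])
        assert ((a.proba >= lo - 1e-12) & (a.proba <= hi + 1e-12)).all()

    def test_every_subject_predicted_once(self):
        y = cohort_labels(15, 20)
        X = pd.DataFrame(np.random.default_rng(6).standard_normal((35, 3)))
        preds = fit_soft_voting(X, y, members={"m": FixedProba(0.4)}, seed=6)
        assert np.isfinite(preds.proba).all()
        assert set(preds.fold) == set(range(5))


class TestModelAPI:
    def test_fit_summary_and_auc_above_chance(self):
        spec = CohortSpec(seed=7, n_per_group={"ADHD": 30, "TDC": 40})
        table = sample_feature_table(spec)
        model = ScreeningModel.from_feature_table("stage1", table,
                                                  members=default_members(150, 5))
        res = model.fit(seed=1)
        assert res.metrics.auc > 0.5
        text = res.summary()
        assert "AUC" in text and "Dummy" in text
        roc = res.roc_curve()
        assert {"fpr", "tpr", "threshold"} <= set(roc.columns)

    def test_plot_roc_smoke(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")

        spec = CohortSpec(seed=8, n_per_group={"ADHD": 15, "TDC": 15})
        table = sample_feature_table(spec)
        res = ScreeningModel.from_feature_table(
            "stage1", table, members={"m": FixedProba(0.6)}).fit(seed=0)
        ax = res.plot_roc()
        ax.figure.savefig(tmp_path / "roc.png")
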