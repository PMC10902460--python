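"""Dummy-referenced classifier screening and the soft-voting ensemble.

The central objects follow the statsmodels convention: a
:class:`ScreeningModel` is built from a feature matrix and labels (or from
a :class:`~gazescreen.features.FeatureTable` via ``from_feature_table``);
``fit`` produces a :class:`ScreeningResults` carrying the out-of-fold
probabilities, threshold metrics, ROC curve and a ``summary()`` table, with
stage comparison and plotting hanging off the results object.

Candidate screening follows the published rule: a classifier is "superior"
when its mean stratified 5-fold CV accuracy exceeds the dummy baseline (a
model that labels every participant as typically developing) by at least
0.10.  The two tree ensembles that pass on the real data — random forest
and extremely randomised trees — are the default soft-voting members; the
ensemble's probability is the unweighted mean of the members' out-of-fold
probabilities, every member being fitted inside its training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (ExtraTreesClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable, assemble_stage

__all__ = ["ScreeningModel", "ScreeningResults", "StagePredictions", "ScreenResult",
           "dummy_accuracy", "screen_candidates", "tune", "fit_soft_voting",
           "default_candidates", "default_members"]

SUPERIORITY_MARGIN = 0.10

#: Default hyperparameter grid for the ensemble members; the depth cap is
#: the anti-overfitting control on n ~ 135 cohorts.
DEFAULT_GRID = {"n_estimators": [500, 1000, 2000], "max_depth": [3, 5, 8, None]}


def default_members(n_estimators: int = 1000, max_depth: int | None = 5):
    """The soft-voting members: random forest + extremely randomised trees,
    with a depth cap to curb overfitting on small cohorts."""
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth, n_jobs=1),
        "extra_trees": ExtraTreesClassifier(
            n_estimators=n_estimators, max_depth=max_depth, n_jobs=1),
    }


def default_candidates(n_estimators: int = 500):
    """A fixed screening roster spanning the standard classifier families."""
    return {
        "random_forest": RandomForestClassifier(n_estimators=n_estimators,
                                                max_depth=5, n_jobs=1),
        "extra_trees": ExtraTreesClassifier(n_estimators=n_estimators,
                                            max_depth=5, n_jobs=1),
        "logistic": make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000)),
        "svm_rbf": make_pipeline(StandardScaler(), SVC(probability=True)),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "gradient_boosting": GradientBoostingClassifier(),
        "naive_bayes": GaussianNB(),
    }


def _folds(y: np.ndarray, n_splits: int, seed: int):
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _seeded(est, seed: int):
    est = clone(est)
    params = est.get_params()
    for name in params:
        if name == "random_state" or name.endswith("__random_state"):
            est.set_params(**{name: seed})
    return est


def _cv_accuracy(est, X: np.ndarray, y: np.ndarray, folds, seed: int) -> float:
    accs = []
    for f, (tr, te) in enumerate(folds):
        m = _seeded(est, seed + f)
        m.fit(X[tr], y[tr])
        accs.append(m.score(X[te], y[te]))
    return float(np.mean(accs))


def dummy_accuracy(y, folds: int = 5, seed: int = 0) -> float:
    """Mean stratified-CV accuracy of the all-TDC (majority-class) dummy."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("labels are empty")
    fold_idx = _folds(y, folds, seed)
    dummy = DummyClassifier(strategy="most_frequent")
    return _cv_accuracy(dummy, np.zeros((y.size, 1)), y, fold_idx, seed)


@dataclass
class ScreenResult:
    accuracies: dict[str, float]
    dummy: float

    @property
    def superior(self) -> dict[str, bool]:
        return {k: v >= self.dummy + SUPERIORITY_MARGIN
                for k, v in self.accuracies.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cv_accuracy": self.accuracies,
                             "dummy_accuracy": self.dummy,
                             "superior": self.superior})


def screen_candidates(X, y, candidates: dict | None = None, folds: int = 5,
                      seed: int = 0) -> ScreenResult:
    """Score each candidate against the dummy under shared CV folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    candidates = candidates if candidates is not None else default_candidates()
    if len(candidates) < 2:
        raise ValueError("screening expects at least two candidates")
    fold_idx = _folds(y, folds, seed)
    dummy = _cv_accuracy(DummyClassifier(strategy="most_frequent"),
                         np.zeros((y.size, 1)), y, fold_idx, seed)
    accs = {name: _cv_accuracy(est, X, y, fold_idx, seed)
            for name, est in candidates.items()}
    return ScreenResult(accs, dummy)


def tune(estimator, X, y, grid: dict[str, list], folds: int = 5, seed: int = 0):
    """Exhaustive grid search maximising mean CV accuracy.

    Ties resolve to the earliest configuration in documented grid order.
    Returns ``(best_params, best_accuracy)``.
    """
    from itertools import product

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold_idx = _folds(y, folds, seed)
    names = list(grid)
    best, best_acc = None, -np.inf
    for combo in product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        est = clone(estimator).set_params(**params)
        acc = _cv_accuracy(est, X, y, fold_idx, seed)
        if acc > best_acc:
            best, best_acc = params, acc
    return best, float(best_acc)


@dataclass
class StagePredictions:
    """Out-of-fold ensemble probabilities for one stage."""

    stage: str
    subject_ids: np.ndarray
    proba: np.ndarray              # P(ADHD) per subject, out of fold
    labels: np.ndarray             # 1 = ADHD, 0 = TDC
    fold: np.ndarray
    member_proba: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not ((self.proba >= 0) & (self.proba <= 1)).all():
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "fold": self.fold,
                           "probability": self.proba, "label": self.labels})
        for name, p in self.member_proba.items():
            df[f"p_{name}"] = p
        return df


def fit_soft_voting(X, y, members: dict | None = None, folds: int = 5,
                    seed: int = 0, stage: str = "stage1",
                    subject_ids=None) -> StagePredictions:
    """Out-of-fold soft-voting probabilities.

    Each member is fitted on the training side of every fold; a subject's
    ensemble probability is the unweighted mean of the member probabilities
    from the single fold in which the subject was held out.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if subject_ids is None:
        subject_ids = (np.asarray(X.index) if isinstance(X, pd.DataFrame)
                       else np.arange(y.size))
    members = members if members is not None else default_members()
    fold_idx = _folds(y, folds, seed)
    proba = np.full(y.size, np.nan)
    fold_of = np.full(y.size, -1)
    member_p = {name: np.full(y.size, np.nan) for name in members}
    for f, (tr, te) in enumerate(fold_idx):
        ps = []
        for name, est in members.items():
            m = _seeded(est, seed + f)
            m.fit(Xa[tr], y[tr])
            idx1 = list(m.classes_).index(1)
            p = m.predict_proba(Xa[te])[:, idx1]
            member_p[name][te] = p
            ps.append(p)
        proba[te] = np.mean(ps, axis=0)
        fold_of[te] = f
    assert not np.isnan(proba).any(), "every subject must be predicted exactly once"
    return StagePredictions(stage, np.asarray(subject_ids), proba, y,
                            fold_of, member_p)


# ---------------------------------------------------------------------------
# model / results objects

class ScreeningModel:
    """ADHD-vs-TDC screening model for one feature stage.

    Parameters
    ----------
    X : DataFrame (subjects x features)
    y : array-like of {0, 1} or {"TDC", "ADHD"}
    members : dict of soft-voting member estimators (default RF + extra trees)
    folds, seed : cross-validation layout
    """

    def __init__(self, X: pd.DataFrame, y, members: dict | None = None,
                 folds: int = 5, stage: str = "stage1"):
        self.X = pd.DataFrame(X)
        y = pd.Series(y, index=self.X.index)
        if y.dtype == object:
            y = y.map({"ADHD": 1, "TDC": 0})
        self.y = y.astype(int)
        if set(self.y.unique()) - {0, 1}:
            raise ValueError("labels must be binary ADHD/TDC")
        self.members = members
        self.folds = folds
        self.stage = stage

    @classmethod
    def from_feature_table(cls, stage, eye_table: FeatureTable | None,
                           subject_records=None, **kwargs) -> "ScreeningModel":
        X, y = assemble_stage(stage, eye_table, subject_records)
        return cls(X, y, stage=str(stage), **kwargs)

    def fit(self, seed: int = 0) -> "ScreeningResults":
        preds = fit_soft_voting(self.X, self.y.to_numpy(), members=self.members,
                                folds=self.folds, seed=seed, stage=self.stage,
                                subject_ids=self.X.index.to_numpy())
        dummy = dummy_accuracy(self.y.to_numpy(), folds=self.folds, seed=seed)
        return ScreeningResults(self, preds, dummy, seed)

    def screen(self, candidates: dict | None = None, seed: int = 0) -> ScreenResult:
        return screen_candidates(self.X, self.y.to_numpy(), candidates,
                                 folds=self.folds, seed=seed)


class ScreeningResults:
    """Fitted-stage results: out-of-fold predictions, metrics, comparisons."""

    def __init__(self, model: ScreeningModel, predictions: StagePredictions,
                 dummy_acc: float, seed: int):
        from .stats import compute_metrics

        self.model = model
        self.predictions = predictions
        self.dummy_accuracy = dummy_acc
        self.seed = seed
        self.metrics = compute_metrics(predictions)

    def compare(self, other: "ScreeningResults | StagePredictions",
                method: str = "rank_sum_probs"):
        from .stats import compare_stages

        other_preds = other.predictions if isinstance(other, ScreeningResults) else other
        return compare_stages(self.predictions, other_preds, method=method)

    def roc_curve(self) -> pd.DataFrame:
        from sklearn.metrics import roc_curve

        fpr, tpr, thr = roc_curve(self.predictions.labels, self.predictions.proba)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    def plot_roc(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        roc = self.roc_curve()
        name = label or self.predictions.stage
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC = {self.metrics.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate (recall)")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        m = self.metrics
        n = self.predictions.labels.size
        n_pos = int(self.predictions.labels.sum())
        lines = [
            "ADHD screening ensemble (soft voting: random forest + extra trees)",
            "=" * 66,
            f"Stage: {self.predictions.stage}    subjects: {n} "
            f"(ADHD {n_pos} / TDC {n - n_pos})    folds: {self.model.folds}    "
            f"seed: {self.seed}",
            "-" * 66,
            f"{'Accuracy':<12}{m.accuracy:>8.3f}    {'Recall':<12}{m.recall:>8.3f}",
            f"{'Precision':<12}{m.precision:>8.3f}    {'F1-score':<12}{m.f1:>8.3f}",
            f"{'AUC':<12}{m.auc:>8.3f}    {'Dummy acc.':<12}{self.dummy_accuracy:>8.3f}",
            "-" * 66,
            f"Confusion (threshold 0.5): TP={m.tp} FP={m.fp} FN={m.fn} TN={m.tn}",
        ]
        return "\n".join(lines)
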