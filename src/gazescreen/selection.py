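"""Random-forest importance-driven backward feature elimination.

Per task, features are iteratively removed in order of lowest mean
impurity-decrease importance (averaged over the five stratified
cross-validation folds' fitted forests), recording the mean CV accuracy of
every surviving set; the best set is the one with the highest mean
accuracy, with ties broken toward the smaller set.  Folds are fixed per
seed across elimination steps so accuracy differences reflect feature
sets, not fold noise.

Note on design: the selection and its accuracy estimate share the same
cross-validation (there is no outer loop), which carries an optimistic
bias; this mirrors the published procedure and is deliberately not
corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import TASK_IDS
from .tables import STAGE1_SCHEMA, STAGE1_TASK_COUNTS

__all__ = ["SelectionTrace", "rank_importances", "backward_eliminate",
           "select_all_tasks", "packaged_schema"]


@dataclass
class SelectionTrace:
    """Bookkeeping for one backward-elimination run."""

    steps: list[dict] = field(default_factory=list)   # feature_names, accuracy, importances
    best_features: tuple[str, ...] = ()
    best_accuracy: float = float("nan")

    def sizes(self) -> list[int]:
        return [len(s["feature_names"]) for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            rows.append({"step": i, "n_features": len(s["feature_names"]),
                         "cv_accuracy": s["accuracy"],
                         "features": "|".join(s["feature_names"])})
        return pd.DataFrame(rows)


def _folds(y: np.ndarray, n_splits: int, seed: int):
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _cv_fit(X: np.ndarray, y: np.ndarray, folds, n_trees: int, seed: int):
    """Mean CV accuracy and fold-averaged impurity importances."""
    accs, imps = [], []
    for f, (tr, te) in enumerate(folds):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + f,
                                     n_jobs=1)
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
        imps.append(clf.feature_importances_)
    return float(np.mean(accs)), np.mean(imps, axis=0)


def rank_importances(X, y, n_trees: int = 2000, folds: int = 5, seed: int = 0
                     ) -> pd.Series:
    """Per-feature importance, averaged over the CV folds' forests.

    Deterministic given ``seed``; raises on single-class labels.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("importances require at least two classes")
    fold_idx = _folds(y, folds, seed)
    _, imp = _cv_fit(X.to_numpy(), y, fold_idx, n_trees, seed)
    return pd.Series(imp, index=X.columns).sort_values(ascending=False)


def backward_eliminate(X, y, step: int = 1, n_trees: int = 2000, folds: int = 5,
                       seed: int = 0) -> SelectionTrace:
    """Iteratively drop the lowest-importance feature(s); keep the set with
    the best mean CV accuracy (ties -> smaller set; equal importances ->
    drop the lexicographically last name)."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("backward elimination requires at least two features")
    if np.unique(y).size < 2:
        raise ValueError("backward elimination requires two classes")
    fold_idx = _folds(y, folds, seed)
    trace = SelectionTrace()
    current = list(X.columns)
    while current:
        acc, imp = _cv_fit(X[current].to_numpy(), y, fold_idx, n_trees, seed)
        imp_s = pd.Series(imp, index=current)
        trace.steps.append({"feature_names": tuple(current), "accuracy": acc,
                            "importances": imp_s})
        if len(current) == 1:
            break
        # stable ranking: ties broken toward dropping the later name
        order = sorted(current, key=lambda f: (imp_s[f], tuple(-ord(c) for c in f)))
        drop = set(order[:step])
        current = [f for f in current if f not in drop]
    best = max(trace.steps,
               key=lambda s: (s["accuracy"], -len(s["feature_names"])))
    trace.best_features = tuple(best["feature_names"])
    trace.best_accuracy = best["accuracy"]
    return trace


def packaged_schema() -> dict[str, tuple[str, ...]]:
    """The published per-task selected features (7+11+8+4+3 = 33)."""
    out: dict[str, list[str]] = {t: [] for t in TASK_IDS}
    for col in STAGE1_SCHEMA:
        task, feat = col.split("__", 1)
        out[task].append(col)
    assert {t: len(v) for t, v in out.items()} == dict(STAGE1_TASK_COUNTS)
    return {t: tuple(v) for t, v in out.items()}


def select_all_tasks(wide_table: pd.DataFrame | None, y=None, *,
                     replicate: bool = False, step: int = 1,
                     n_trees: int = 2000, folds: int = 5, seed: int = 0):
    """Run backward elimination per task and concatenate the best sets into
    a stage-1 schema.

    ``replicate=True`` returns the packaged published schema (the 33
    features with per-task counts 7/11/8/4/3) instead of re-selecting.
    Returns ``(schema, traces)`` where traces is empty in replicate mode.
    """
    if replicate:
        per_task = packaged_schema()
        schema = tuple(c for t in TASK_IDS for c in per_task[t])
        return schema, {}
    if wide_table is None or y is None:
        raise ValueError("fresh selection requires a wide feature table and labels")
    traces: dict[str, SelectionTrace] = {}
    schema: list[str] = []
    for task in TASK_IDS:
        cols = [c for c in wide_table.columns if c.startswith(f"{task}__")]
        if not cols:
            continue
        tr = backward_eliminate(wide_table[cols], y, step=step, n_trees=n_trees,
                                folds=folds, seed=seed)
        traces[task] = tr
        schema.extend(tr.best_features)
    return tuple(schema), traces
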