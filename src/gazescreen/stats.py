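"""Classification metrics, ROC/AUC comparison, and univariate group tests.

Group comparisons follow a normality gate: a variable is compared with the
independent-samples t-test only when both the Lilliefors (Kolmogorov-
Smirnov with estimated parameters) and Shapiro-Wilk tests are
non-significant (p > 0.05) in both groups; otherwise the Mann-Whitney U
test is used.  Categorical variables use the chi-square test (no
continuity correction by default).

Model AUCs are compared two ways: ``rank_sum_probs`` — a two-sample
Wilcoxon rank-sum test on the two models' out-of-fold probability vectors,
which reproduces the scale of the published U statistics but whose
inferential target is loose — and ``delong``, the paired DeLong test for
correlated AUC differences, recommended for actual inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .screening import StagePredictions

__all__ = ["MetricReport", "ComparisonResult", "GroupTestResult",
           "compute_metrics", "compare_stages", "group_compare", "correlate",
           "rank_auc"]


@dataclass
class MetricReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "recall", "precision", "f1", "auc", "tp", "fp", "fn", "tn")}


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties get mid-ranks)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(preds: StagePredictions | tuple, threshold: float = 0.5
                    ) -> MetricReport:
    """Threshold-based confusion metrics (ADHD positive) plus rank AUC."""
    if isinstance(preds, StagePredictions):
        y, p = preds.labels, preds.proba
    else:
        y, p = preds
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    acc = (tp + tn) / y.size
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return MetricReport(acc, recall, precision, f1, rank_auc(y, p),
                        tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# AUC comparison

@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float          # U for rank_sum_probs, z for delong
    p_value: float
    method: str
    auc_a: float
    auc_b: float


def _delong_variance(labels: np.ndarray, scores: np.ndarray):
    """DeLong placement values and AUC for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # mid-rank placements
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return v10, v01, v10.mean()


def compare_stages(preds_a: StagePredictions, preds_b: StagePredictions,
                   method: str = "rank_sum_probs") -> ComparisonResult:
    """Compare two stages' out-of-fold predictions on the same subjects."""
    ids_a = np.asarray(preds_a.subject_ids)
    ids_b = np.asarray(preds_b.subject_ids)
    if ids_a.size != ids_b.size or set(ids_a.tolist()) != set(ids_b.tolist()):
        raise ValueError("stage predictions cover different subjects")
    order = {s: i for i, s in enumerate(ids_b.tolist())}
    perm = np.array([order[s] for s in ids_a.tolist()])
    pb = preds_b.proba[perm]
    yb = preds_b.labels[perm]
    if not np.array_equal(preds_a.labels, yb):
        raise ValueError("subject labels disagree between prediction sets")
    auc_a = rank_auc(preds_a.labels, preds_a.proba)
    auc_b = rank_auc(yb, pb)
    pair = (preds_a.stage, preds_b.stage)

    if method == "rank_sum_probs":
        res = sps.mannwhitneyu(preds_a.proba, pb, alternative="two-sided",
                               method="asymptotic")
        return ComparisonResult(pair, float(res.statistic), float(res.pvalue),
                                method, auc_a, auc_b)
    if method == "delong":
        y = preds_a.labels
        v10a, v01a, _ = _delong_variance(y, preds_a.proba)
        v10b, v01b, _ = _delong_variance(y, pb)
        m, n = v10a.size, v01a.size
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        diff = auc_a - auc_b
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = diff / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
        return ComparisonResult(pair, float(z), p, method, auc_a, auc_b)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# univariate group statistics

@dataclass
class GroupTestResult:
    variable: str
    test: str                    # "t", "mann_whitney", "chi_square"
    statistic: float
    p_value: float
    normal: bool | None = None   # normality-gate outcome (None for categorical)


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return False
    _, p_ks = lilliefors(x, dist="norm")
    _, p_sw = sps.shapiro(x)
    return p_ks > 0.05 and p_sw > 0.05


def group_compare(a, b, variable: str = "", kind: str = "continuous"
                  ) -> GroupTestResult:
    """Two-group comparison with the normality-gated test choice.

    ``kind="continuous"``: t-test when both samples pass both normality
    tests, Mann-Whitney otherwise (constant samples force Mann-Whitney).
    ``kind="categorical"``: ``a``/``b`` are count vectors forming the
    contingency-table rows; chi-square without continuity correction.
    """
    if kind == "categorical":
        table = np.asarray([a, b])
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return GroupTestResult(variable, "chi_square", float(stat), float(p))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    normal = (not degenerate) and _is_normal(a) and _is_normal(b)
    if normal:
        stat, p = sps.ttest_ind(a, b)
        return GroupTestResult(variable, "t", float(stat), float(p), True)
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult(variable, "mann_whitney", float(stat), float(p), False)


def correlate(features: pd.DataFrame, scores: pd.DataFrame,
              adjust: str | None = None):
    """Pairwise Pearson correlations between feature and score columns.

    Missing pairs are dropped casewise; per-cell n is reported.  Zero-
    variance columns yield NaN and are flagged.  ``adjust="fdr_bh"``
    applies a Benjamini-Hochberg correction across all cells (off by
    default, matching the uncorrected published analysis).

    Returns ``(r, p, n)`` DataFrames indexed by feature, columned by score.
    """
    r = pd.DataFrame(index=features.columns, columns=scores.columns, dtype=float)
    p = r.copy()
    n = r.copy()
    for f in features.columns:
        for s in scores.columns:
            x = features[f]
            y = scores[s]
            ok = x.notna() & y.notna()
            n.loc[f, s] = int(ok.sum())
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                r.loc[f, s] = np.nan
                p.loc[f, s] = np.nan
                continue
            rr, pp = sps.pearsonr(x[ok], y[ok])
            r.loc[f, s] = rr
            p.loc[f, s] = pp
    if adjust == "fdr_bh":
        flat = p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = flat.copy()
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return r, p, n
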