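"""Independent brute-force oracles used to validate the implementations."""

import math

import numpy as np


def fixations_bruteforce(t, x, y, valid, dispersion_px, min_fixation_ms=70.0):
    """Exhaustive maximal-run fixation scan.

    Walks every candidate start index inside each valid run, extends the
    window one sample at a time recomputing the bounding box from scratch,
    and emits the maximal qualifying run greedily (earliest start first).
    Returns (start_ms, end_ms, cx, cy) tuples.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.asarray(valid, bool)
    n = t.size
    out = []
    seg_start = 0
    while seg_start < n:
        if not valid[seg_start]:
            seg_start += 1
            continue
        seg_end = seg_start
        while seg_end + 1 < n and valid[seg_end + 1]:
            seg_end += 1
        i = seg_start
        while i <= seg_end:
            j = i
            best = i
            while j <= seg_end:
                xs = x[i:j + 1]
                ys = y[i:j + 1]
                diag = math.hypot(xs.max() - xs.min(), ys.max() - ys.min())
                if diag > dispersion_px:
                    break
                best = j
                j += 1
            if t[best] - t[i] >= min_fixation_ms:
                out.append((t[i], t[best],
                            float(x[i:best + 1].mean()), float(y[i:best + 1].mean())))
                i = best + 1
            else:
                i += 1
        seg_start = seg_end + 1
    return out


def auc_bruteforce(labels, scores):
    """Pairwise concordance AUC with half-credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def confusion_bruteforce(labels, proba, threshold=0.5):
    """Explicit per-subject confusion counting."""
    tp = fp = fn = tn = 0
    for y, p in zip(labels, proba):
        pred = 1 if p >= threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
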