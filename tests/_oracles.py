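"""Independent brute-force oracles shared by the metric and acceptance tests.

These are deliberately coded without reference to aprnet.metrics: the AUC as
an explicit pairwise-ordering probability, average precision as an explicit
threshold sweep, Youden's J by exhaustive midpoint search, and the segment
overlap score over explicit index sets.
"""

import math

import numpy as np


def pairwise_auc(scores, truth):
    """AUC as the probability a positive outranks a negative (ties = 0.5)."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_sweep_ap(scores, truth):
    """Average precision by explicit descending-threshold summation."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    t = np.asarray(truth)[order]
    n_pos = t.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        mask = s >= thr
        tp = t[mask].sum()
        prec = tp / mask.sum()
        rec = tp / n_pos
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


def exhaustive_youden(scores, truth):
    """Best J over all midpoint thresholds (plus sentinels), by brute force."""
    uniq = sorted(set(scores))
    candidates = [uniq[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    candidates += [uniq[-1], uniq[-1] + 1.0]
    candidates += uniq
    best = -2.0
    for thr in candidates:
        pred = [1 if s >= thr else 0 for s in scores]
        tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        best = max(best, j)
    return best


def sov_oracle(pred, truth, target):
    """Refined segment-overlap score, coded independently over index sets."""
    def runs(labels):
        out, i = [], 0
        while i < len(labels):
            if labels[i] == target:
                j = i
                while j < len(labels) and labels[j] == target:
                    j += 1
                out.append(set(range(i, j)))
                i = j
            else:
                i += 1
        return out

    true_runs, pred_runs = runs(truth), runs(pred)
    num, den = 0.0, 0
    for s1 in true_runs:
        pairs = [s2 for s2 in pred_runs if s1 & s2]
        if not pairs:
            den += len(s1)
            continue
        for s2 in pairs:
            minov = len(s1 & s2)
            maxov = max(s1 | s2) - min(s1 | s2) + 1
            delta = min(maxov - minov, minov, len(s1) // 2, len(s2) // 2)
            num += len(s1) * (minov + delta) / maxov
            den += len(s1)
    return math.nan if den == 0 else 100.0 * num / den


def random_scored_instance(rng, n_max=50, discretize=False):
    """A random binary-truth / real-score instance with both classes present."""
    n = int(rng.integers(4, n_max + 1))
    truth = rng.integers(0, 2, size=n)
    while truth.min() == truth.max():
        truth = rng.integers(0, 2, size=n)
    scores = rng.random(n)
    if discretize:  # force ties
        scores = np.round(scores, 1)
    return scores, truth
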