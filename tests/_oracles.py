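"""Independent brute-force metric oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def auroc_bruteforce(labels: np.ndarray, scores: np.ndarray) -> float:
    """All-pairs Mann-Whitney AUROC: ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += float(np.sum(p > neg)) + 0.5 * float(np.sum(p == neg))
    return wins / (len(pos) * len(neg))


def aupr_bruteforce(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive threshold sweep with step interpolation.

    Thresholds are the distinct scores in descending order; at each, the
    (recall, precision) point is taken and the area accumulated as
    sum (R_k - R_{k-1}) * P_k with R_0 = 0 -- no linear interpolation.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        predicted = scores >= t
        tp = int((labels[predicted] == 1).sum())
        precision = tp / int(predicted.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
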