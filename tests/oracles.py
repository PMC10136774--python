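"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in plain Python loops (or direct
pairwise enumeration) so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def bf_axis_starts(length: int, edge: int, stride: int) -> list[int]:
    """Window start offsets along one axis, re-derived step by step."""
    if length < edge:
        return []
    starts = []
    s = 0
    while s + edge <= length:
        starts.append(s)
        s += stride
    if starts[-1] + edge < length:
        starts.append(length - edge)
    return starts


def bf_windows(shape: tuple[int, int], edge: int, p_omega: float) -> list[tuple[int, int]]:
    """All (y0, x0) window origins for a given overlap."""
    stride = max(1, round(edge * (1.0 - p_omega)))
    return [
        (y, x)
        for y in bf_axis_starts(shape[0], edge, stride)
        for x in bf_axis_starts(shape[1], edge, stride)
    ]


def bf_counts(mask: np.ndarray, y0: int, x0: int, edge: int, target: int) -> tuple[int, int, int]:
    """(N, M, T) counted pixel by pixel."""
    N = M = T = 0
    for y in range(y0, y0 + edge):
        for x in range(x0, x0 + edge):
            N += 1
            v = int(mask[y, x])
            if v >= 2:
                M += 1
            if v == target:
                T += 1
    return N, M, T


def bf_accept(
    N: int, M: int, T: int, p_alpha: float, p_beta: float, denominator: str
) -> bool:
    coverage = M / N
    if denominator == "all":
        purity = T / N
    else:
        purity = T / M if M else 0.0
    return coverage >= p_alpha and purity >= p_beta


def bf_auc(y_true, y_score) -> float | None:
    """Pairwise-ranking AUC: wins + half ties over all pos/neg pairs."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bf_metrics(y_true, y_pred) -> dict:
    """Contingency-table metric suite with explicit None for 0/0."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)

    def ratio(a, b):
        return a / b if b else None

    # F1 = 2TP / (2TP + FP + FN) equals the harmonic mean whenever defined
    f1 = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else None
    return {
        "accuracy": ratio(tp + tn, len(y_true)),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "f1": f1,
    }
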