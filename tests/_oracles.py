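"""Independent brute-force re-implementations used as test oracles.

Deliberately written with plain Python loops and Counter-based frequency
estimates so they share no code path with the package implementation.
"""

from collections import Counter
from math import log, sqrt

import numpy as np


def mi_oracle(x, y) -> float:
    """Mutual information in nats from empirical cell frequencies."""
    x = list(x)
    y = list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (xv, yv), c in joint.items():
        pxy = c / n
        total += pxy * log(pxy / ((px[xv] / n) * (py[yv] / n)))
    return total


def mrmr_oracle(states: np.ndarray, labels: np.ndarray, n_select: int):
    """Greedy max-relevance min-redundancy, re-evaluated from scratch
    each round: round 1 maximizes MI(f, c); round h maximizes
    MI(f, c) - mean over selected g of MI(f, g). Ties -> lowest index.

    Ties (mathematically equal criteria; floating-point summation order
    may differ from the implementation's by ~1e-16) break toward the
    lowest column index, the declared deterministic rule.

    Returns (selected column indices, criterion value per round).
    """
    n, p = states.shape
    tie_eps = 1e-12
    relevance = [mi_oracle(states[:, j], labels) for j in range(p)]
    selected: list[int] = []
    criteria: list[float] = []
    while len(selected) < n_select:
        best_j, best_val = None, None
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = sum(mi_oracle(states[:, j], states[:, g]) for g in selected)
                val = relevance[j] - red / len(selected)
            else:
                val = relevance[j]
            if best_val is None or val > best_val + tie_eps:
                best_j, best_val = j, val
        selected.append(best_j)
        criteria.append(best_val)
    return selected, criteria


def jackknife_mcc_oracle(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cosine-distance nearest neighbor, one sample at a time."""
    n = X.shape[0]
    tp = tn = fp = fn = 0
    for i in range(n):
        best_j, best_d = None, None
        for j in range(n):
            if j == i:
                continue
            d = 1.0 - float(np.dot(X[i], X[j])) / (
                float(np.linalg.norm(X[i])) * float(np.linalg.norm(X[j]))
            )
            if best_d is None or d < best_d:
                best_j, best_d = j, d
        pred = y[best_j]
        if pred == 1 and y[i] == 1:
            tp += 1
        elif pred == 0 and y[i] == 0:
            tn += 1
        elif pred == 1 and y[i] == 0:
            fp += 1
        else:
            fn += 1
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)
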