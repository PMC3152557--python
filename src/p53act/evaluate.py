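"""Nearest-neighbor classification, jackknife cross-validation and MCC.

The classifier assigns a query the label of the training sample with the
smallest cosine-style distance

    D(v1, v2) = 1 - <v1, v2> / (||v1|| * ||v2||),

which lies in [0, 2]; smaller means more similar. The jackknife
(leave-one-out) test predicts every sample from the remaining ones, which
yields a unique result for a given table. Performance is summarized by the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

appropriate for the severe active/inactive imbalance of the p53 datasets;
if any factor of the denominator is zero, MCC is defined as 0. Distance
ties break toward the lowest sample index. No feature standardization is
applied before the distance (exposed as an off-by-default flag upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .encoding import FeatureTable
from .exceptions import DegenerateVectorError, EmptyInputError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with 'positive' = transcriptionally active."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if counts.total == 0:
        raise EmptyInputError("MCC of zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def nn_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 2], 0 for parallel vectors."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateVectorError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - float(v1 @ v2) / (n1 * n2))


def nn_predict(query: np.ndarray, training: FeatureTable) -> tuple[int, str]:
    """Label and id of the nearest training sample (lowest index on ties)."""
    if training.n_samples == 0:
        raise EmptyInputError("empty training table")
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != training.n_features:
        raise ValueError(
            f"query has {query.shape[0]} features, table {training.n_features}"
        )
    distances = np.array([nn_distance(query, row) for row in training.X])
    j = int(np.argmin(distances))
    return int(training.y[j]), training.ids[j]


@dataclass
class JackknifeResult:
    """Per-sample leave-one-out predictions plus aggregate counts and MCC."""

    predictions: np.ndarray  # (n,) predicted 0/1 labels
    neighbor_ids: list[str]  # id of each sample's nearest neighbor
    counts: ConfusionCounts
    mcc: float


def jackknife(table: FeatureTable, feature_subset: list[str] | None = None) -> JackknifeResult:
    """Leave-one-out nearest-neighbor evaluation on a feature subset."""
    if table.n_samples < 2:
        raise EmptyInputError("jackknife needs at least 2 samples")
    if len(np.unique(table.y)) < 2:
        raise ValueError("jackknife needs both classes present")
    if feature_subset is None:
        X = table.X
    else:
        X = table.X[:, table.column_indices(list(feature_subset))]
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        bad = table.ids[int(np.argmax(norms == 0.0))]
        raise DegenerateVectorError(f"zero-norm sample under this feature subset: {bad}")
    Xn = X / norms[:, None]
    D = 1.0 - Xn @ Xn.T
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)  # first min = lowest sample index on ties
    predictions = table.y[nn]
    y = table.y
    counts = ConfusionCounts(
        tp=int(((predictions == 1) & (y == 1)).sum()),
        tn=int(((predictions == 0) & (y == 0)).sum()),
        fp=int(((predictions == 1) & (y == 0)).sum()),
        fn=int(((predictions == 0) & (y == 1)).sum()),
    )
    return JackknifeResult(
        predictions=predictions,
        neighbor_ids=[table.ids[j] for j in nn],
        counts=counts,
        mcc=mcc(counts),
    )
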