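"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Features are ranked greedily. Round 1 picks the feature with maximal mutual
information (MI) with the class label (relevance). Each later round picks,
among the not-yet-selected features, the maximiser of

    MI(f, label)  -  (1/m) * sum over selected g of MI(f, g)

i.e. relevance minus mean redundancy against the m already-selected
features (the difference form of the criterion). A better feature is
selected earlier and carries a smaller rank index h.

MI is computed on discretized data: continuous features are binned into
three states split at mean +/- alpha * std (alpha = 0.5 by default,
population std), the common default of Peng's mRMR program. MI uses
empirical cell frequencies and natural logarithms (nats); the log base only
rescales MI and cannot change a ranking. Ties break toward the lowest
original column index so reruns are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import FeatureTable
from .exceptions import EmptyInputError

DEFAULT_ALPHA = 0.5


# ---------------------------------------------------------------------------
# discretization


def discretize(values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, tuple[float, float]]:
    """Bin a real vector into 3 states split at mean +/- alpha*std.

    Returns the integer state vector and the (low, high) thresholds. A
    constant vector maps to the single state 0 with equal thresholds.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyInputError("cannot discretize an empty vector")
    if not np.isfinite(values).all():
        raise ValueError("cannot discretize non-finite values")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mean = values.mean()
    std = values.std()  # population std
    lo, hi = mean - alpha * std, mean + alpha * std
    states = (values > lo).astype(np.int8) + (values > hi).astype(np.int8)
    return states, (float(lo), float(hi))


@dataclass
class DiscretizedTable:
    """Integer state matrix + binning metadata, so MI is reproducible."""

    states: np.ndarray  # (n, p) small ints
    thresholds: np.ndarray  # (p, 2) low/high split points
    label_states: np.ndarray  # (n,) ints
    feature_names: list[str]
    alpha: float

    @property
    def n_features(self) -> int:
        return self.states.shape[1]


def discretize_table(table: FeatureTable, alpha: float = DEFAULT_ALPHA) -> DiscretizedTable:
    """Vectorized 3-state binning of every feature column."""
    if table.n_samples == 0:
        raise EmptyInputError("cannot discretize an empty table")
    X = table.X
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    lo = mean - alpha * std
    hi = mean + alpha * std
    states = (X > lo).astype(np.int8) + (X > hi).astype(np.int8)
    return DiscretizedTable(
        states=states,
        thresholds=np.column_stack([lo, hi]),
        label_states=table.y.astype(np.int8),
        feature_names=list(table.feature_names),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in nats between two discrete vectors (empirical frequencies)."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise EmptyInputError("mutual information of empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(px, py)
    return float((joint[mask] * np.log(joint[mask] / outer[mask])).sum())


def _mi_columns(states: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI (nats) of every column of ``states`` against the vector ``y``."""
    n, p = states.shape
    y = np.asarray(y).ravel()
    mi = np.zeros(p)
    n_states = int(states.max()) + 1 if n else 1
    px = np.stack([(states == s).sum(axis=0) for s in range(n_states)]) / n
    for yv in np.unique(y):
        mask = y == yv
        py = mask.sum() / n
        sub = states[mask]
        for s in range(n_states):
            pxy = (sub == s).sum(axis=0) / n
            nz = pxy > 0
            mi[nz] += pxy[nz] * np.log(pxy[nz] / (px[s, nz] * py))
    return mi


# ---------------------------------------------------------------------------
# greedy ranking


@dataclass
class RankedFeatureList:
    """mRMR output: names in selection order with per-round scores.

    ``names[i]`` was selected in round h = i + 1; ``criterion[i]`` is its
    relevance minus mean redundancy at selection time.
    """

    names: list[str]
    relevance: np.ndarray
    redundancy: np.ndarray
    criterion: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def top(self, k: int) -> list[str]:
        return self.names[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": np.arange(1, len(self.names) + 1),
                "name": self.names,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
                "criterion": self.criterion,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "RankedFeatureList":
        frame = pd.read_csv(path)
        return cls(
            names=[str(n) for n in frame["name"]],
            relevance=frame["relevance"].to_numpy(dtype=float),
            redundancy=frame["redundancy"].to_numpy(dtype=float),
            criterion=frame["criterion"].to_numpy(dtype=float),
        )


def mrmr_rank(disc: DiscretizedTable, n_select: int | None = None) -> RankedFeatureList:
    """Greedy mRMR ranking of ``n_select`` features (all by default)."""
    N = disc.n_features
    if N == 0:
        raise EmptyInputError("no features to rank")
    if n_select is None:
        n_select = N
    if not 1 <= n_select <= N:
        raise ValueError(f"n_select must be in 1..{N}, got {n_select}")
    states = disc.states
    relevance = _mi_columns(states, disc.label_states)
    remaining = np.ones(N, dtype=bool)
    red_sum = np.zeros(N)
    names, rel_out, red_out, crit_out = [], [], [], []
    for h in range(1, n_select + 1):
        m = h - 1
        redundancy = red_sum / m if m else np.zeros(N)
        criterion = relevance - redundancy
        masked = np.where(remaining, criterion, -np.inf)
        # mathematically tied criteria can differ by ~1e-16 from summation
        # order; snap near-ties so the lowest column index wins reproducibly
        j = int(np.argmax(masked >= masked.max() - 1e-12))
        names.append(disc.feature_names[j])
        rel_out.append(relevance[j])
        red_out.append(redundancy[j])
        crit_out.append(criterion[j])
        remaining[j] = False
        if h < n_select:
            red_sum += _mi_columns(states, states[:, j])
    return RankedFeatureList(
        names=names,
        relevance=np.asarray(rel_out),
        redundancy=np.asarray(red_out),
        criterion=np.asarray(crit_out),
    )
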