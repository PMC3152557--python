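"""Incremental feature selection (IFS) over an mRMR ranking.

Nested feature sets S_k = {top k ranked features} are evaluated by the
jackknifed nearest-neighbor MCC for k on a grid (step, 2*step, ...,
k_max). The curve (k, MCC) is returned with the optimal set: the smallest
k attaining the maximal MCC (parsimony tie rule).

:func:`summarize_families` breaks a feature subset down by family (SNP,
pro-pro, AAFactor, PSSM, disorder, GRANTHAM, distance, 2D/3D structure)
and, for multi-site mutants, by mutation site (AP1, AP2, ...), mirroring
how optimal sets are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import FAMILIES, FeatureTable, parse_feature_name
from .evaluate import jackknife
from .exceptions import EmptyInputError
from .mrmr import RankedFeatureList


@dataclass
class IFSCurve:
    """The (k, MCC) table over nested feature prefixes."""

    ks: np.ndarray
    mccs: np.ndarray
    optimal_k: int
    optimal_features: list[str]

    @property
    def optimal_mcc(self) -> float:
        return float(self.mccs[np.where(self.ks == self.optimal_k)[0][0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.ks, "mcc": self.mccs})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def ifs_run(
    table: FeatureTable,
    ranking: RankedFeatureList,
    k_max: int | None = None,
    step: int = 1,
) -> IFSCurve:
    """Evaluate jackknife MCC over nested top-k prefixes of the ranking."""
    if len(ranking) == 0:
        raise EmptyInputError("empty ranking")
    if step < 1:
        raise ValueError("step must be >= 1")
    if k_max is None:
        k_max = len(ranking)
    if k_max > len(ranking):
        raise ValueError(f"k_max {k_max} exceeds ranking length {len(ranking)}")
    ks = np.arange(step, k_max + 1, step)
    mccs = np.array([jackknife(table, ranking.top(int(k))).mcc for k in ks])
    best = int(np.argmax(mccs))  # first max = smallest k on ties
    optimal_k = int(ks[best])
    return IFSCurve(
        ks=ks,
        mccs=mccs,
        optimal_k=optimal_k,
        optimal_features=ranking.top(optimal_k),
    )


@dataclass
class FamilySummary:
    """Per-family and per-mutation-site composition of a feature subset."""

    families: dict[str, int]
    sites: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.families.values())


def summarize_families(feature_names: list[str]) -> FamilySummary:
    """Count features per family and per AP-site; rejects unknown names."""
    families = {f: 0 for f in FAMILIES}
    sites: dict[str, int] = {}
    for name in feature_names:
        parsed = parse_feature_name(name)
        families[parsed.family] += 1
        if parsed.site is not None:
            key = f"AP{parsed.site}"
            sites[key] = sites.get(key, 0) + 1
    return FamilySummary(families=families, sites=sites)
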