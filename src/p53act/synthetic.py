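"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* :func:`generate_table` draws a labeled feature table at the exact
  dimension of the k-site feature space, with class-conditional Gaussian
  features: a chosen number of *informative* features whose active-class
  mean is shifted by ``effect_size`` standard deviations, optional
  *redundant* noisy copies of each informative feature, and independent
  standard-normal noise everywhere else. Feature names follow the encoding
  scheme so family summaries work unchanged.

* :func:`generate_mutant_inputs` writes a self-consistent bundle of input
  files (mutant list, FASTA, PSSM, disorder, structure matrix) in the
  dialects the encoding readers expect, sufficient to exercise the full
  encode -> rank -> IFS pipeline without the external mutant database.

Presets mirror the four study datasets and their severe class imbalance:
62 one-site (7 active), 16372 two-site (57 active), 111 three-site (63
active) and 31 four-site (7 active) mutants; :func:`preset_config` can
scale them down proportionally while keeping at least a handful of active
samples so leave-one-out evaluation has same-class neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .encoding import (
    N_STRUCTURE,
    DisorderProfile,
    FeatureTable,
    MutantSpec,
    PSSMMatrix,
    StructureFeatureRecord,
    feature_dimension,
    feature_names,
)
from .exceptions import CapacityError
from .tables import AMINO_ACIDS, PSSM_COLUMNS
from . import io

P53_LENGTH = 393

#: (k_sites, n_active, n_inactive) of the four study datasets.
PRESETS: dict[str, tuple[int, int, int]] = {
    "one-site": (1, 7, 55),
    "two-site": (2, 57, 16315),
    "three-site": (3, 63, 48),
    "four-site": (4, 7, 24),
}

MIN_ACTIVE = 5  # floor under scaling: leave-one-out needs same-class neighbors


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults describe a moderate-signal study."""

    k_sites: int = 1
    n_active: int = 7
    n_inactive: int = 55
    n_informative: int = 5
    effect_size: float = 2.0  # active-class mean shift, in feature-std units
    n_redundant: int = 0  # noisy copies per informative feature
    redundancy_noise: float = 0.3  # std of the copy noise
    seed: int = 0

    def __post_init__(self):
        feature_dimension(self.k_sites)  # arity check
        if min(self.n_active, self.n_inactive, self.n_informative, self.n_redundant) < 0:
            raise ValueError("counts must be non-negative")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")

    @property
    def n_samples(self) -> int:
        return self.n_active + self.n_inactive


def preset_config(
    name: str,
    *,
    scale: float = 1.0,
    n_max: int | None = None,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """A :class:`SyntheticConfig` for one of the four study presets.

    ``scale`` multiplies both class counts; ``n_max`` caps the total sample
    count (tightening ``scale`` if needed). Scaled-down configurations keep
    at least ``MIN_ACTIVE`` active samples.
    """
    k, n_active, n_inactive = PRESETS[name]
    total = n_active + n_inactive
    if n_max is not None and total * scale > n_max:
        scale = n_max / total
    if scale != 1.0:
        n_active = max(MIN_ACTIVE, round(n_active * scale))
        n_inactive = max(MIN_ACTIVE, round(n_inactive * scale))
        if n_max is not None and n_active + n_inactive > n_max:
            n_inactive = n_max - n_active
    return SyntheticConfig(
        k_sites=k, n_active=n_active, n_inactive=n_inactive, seed=seed, **overrides
    )


def generate_table(config: SyntheticConfig) -> tuple[FeatureTable, list[str]]:
    """Draw a labeled table at the exact k-site dimension.

    Returns the table and the names of the planted informative features
    (ground truth for feature-selection benchmarks).
    """
    names = feature_names(config.k_sites)
    p = len(names)
    n_planted = config.n_informative * (1 + config.n_redundant)
    if n_planted > p:
        raise CapacityError(f"{n_planted} planted features exceed dimension {p}")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    X = rng.standard_normal((n, p))
    y = np.concatenate([np.ones(config.n_active, int), np.zeros(config.n_inactive, int)])
    chosen = rng.choice(p, size=n_planted, replace=False)
    informative = chosen[: config.n_informative]
    X[np.ix_(y == 1, informative)] += config.effect_size
    copy_slots = chosen[config.n_informative :]
    for c, slot in enumerate(copy_slots):
        source = informative[c % config.n_informative]
        X[:, slot] = X[:, source] + rng.normal(0.0, config.redundancy_noise, n)
    ids = [f"M{i + 1:05d}" for i in range(n)]
    table = FeatureTable(ids=ids, feature_names=names, X=X, y=y)
    return table, [names[i] for i in informative]


@dataclass(frozen=True)
class InputBundle:
    """Paths of a generated self-consistent encoding-input file set."""

    mutants: Path
    fasta: Path
    pssm: Path
    disorder: Path
    structure: Path
    sequence: str
    specs: tuple[MutantSpec, ...]


def generate_mutant_inputs(config: SyntheticConfig, out_dir: str | Path) -> InputBundle:
    """Write a random but mutually consistent encoding-input bundle.

    Random 393-residue sequence, random k-site mutants whose wild-type
    letters match it, uniform-random PSSM percentages and disorder scores,
    and a Gaussian structure matrix keyed by mutant id.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=P53_LENGTH))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    specs = []
    for i in range(config.n_samples):
        positions = np.sort(rng.choice(P53_LENGTH, size=config.k_sites, replace=False) + 1)
        sites = []
        for pos in positions:
            wt = sequence[pos - 1]
            alternatives = [aa for aa in AMINO_ACIDS if aa != wt]
            sites.append((int(pos), wt, str(rng.choice(alternatives))))
        specs.append(
            MutantSpec(
                mutant_id=f"M{i + 1:05d}",
                sites=tuple(sites),
                label=1 if i < config.n_active else 0,
            )
        )

    pssm = PSSMMatrix(
        scores=rng.integers(0, 101, size=(P53_LENGTH, 20)) / 100.0, columns=PSSM_COLUMNS
    )
    disorder = DisorderProfile(scores=np.round(rng.random(P53_LENGTH), 4))
    structure = {
        s.mutant_id: StructureFeatureRecord(
            s.mutant_id, np.round(rng.standard_normal(N_STRUCTURE), 4)
        )
        for s in specs
    }

    paths = InputBundle(
        mutants=out_dir / "mutants.tsv",
        fasta=out_dir / "wild_type.fasta",
        pssm=out_dir / "pssm.txt",
        disorder=out_dir / "disorder.tsv",
        structure=out_dir / "structure_features.csv",
        sequence=sequence,
        specs=tuple(specs),
    )
    io.write_mutants(paths.mutants, specs)
    paths.fasta.write_text(f">synthetic wild-type ({P53_LENGTH} aa)\n{sequence}\n")
    io.write_pssm(paths.pssm, pssm, sequence)
    io.write_disorder(paths.disorder, disorder)
    io.write_structure_features(paths.structure, structure)
    return paths


def scaled_config(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """A copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
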