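import numpy as np
import pytest

from p53act.encoding import DisorderProfile, FeatureTable, LookupTables, PSSMMatrix
from p53act.io import read_fasta
from p53act.tables import p53_sequence_path


@pytest.fixture(scope="session")
def p53_sequence() -> str:
    return read_fasta(p53_sequence_path())


@pytest.fixture(scope="session")
def lookups() -> LookupTables:
    return LookupTables.default()


@pytest.fixture()
def tiny_sequence() -> str:
    return "ACDEFGHIK"


@pytest.fixture()
def tiny_pssm(tiny_sequence) -> PSSMMatrix:
    rng = np.random.default_rng(11)
    return PSSMMatrix(scores=rng.integers(0, 101, size=(len(tiny_sequence), 20)) / 100.0)


@pytest.fixture()
def tiny_disorder(tiny_sequence) -> DisorderProfile:
    rng = np.random.default_rng(12)
    return DisorderProfile(scores=rng.random(len(tiny_sequence)))


def random_feature_table(
    rng: np.random.Generator,
    n: int,
    p: int,
    *,
    ensure_both_classes: bool = True,
) -> FeatureTable:
    """A random labeled table used by oracle-equivalence checks."""
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, size=n)
    if ensure_both_classes:
        y[0], y[1] = 0, 1
    return FeatureTable(
        ids=[f"S{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(p)],
        X=X,
        y=y,
    )
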