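"""Discretization, mutual information and the greedy mRMR ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import mi_oracle, mrmr_oracle
from conftest import random_feature_table
from p53act.encoding import FeatureTable
from p53act.exceptions import EmptyInputError
from p53act.mrmr import (
    discretize,
    discretize_table,
    mrmr_rank,
    mutual_information,
)


# ---------------------------------------------------------------------------
# discretization


def test_discretize_three_states():
    states, (lo, hi) = discretize(np.array([-10.0, 0.0, 10.0]), alpha=0.5)
    # mean 0, thresholds +/- 0.5*std bracket only the middle value
    assert list(states) == [0, 1, 2]
    assert lo == -hi < 0


def test_discretize_constant_vector_single_state():
    states, (lo, hi) = discretize(np.full(7, 3.25))
    assert set(states) == {0}
    assert lo == hi


def test_discretize_shift_invariance():
    rng = np.random.default_rng(0)
    for shift in (-100.0, 0.5, 17.0):
        values = rng.standard_normal(50)
        base, _ = discretize(values)
        shifted, _ = discretize(values + shift)
        assert np.array_equal(base, shifted)


def test_discretize_empty_rejected():
    with pytest.raises(EmptyInputError):
        discretize(np.array([]))


def test_discretize_table_matches_per_column():
    table = random_feature_table(np.random.default_rng(1), 40, 6)
    disc = discretize_table(table, alpha=0.5)
    for j in range(6):
        states, (lo, hi) = discretize(table.X[:, j], alpha=0.5)
        assert np.array_equal(disc.states[:, j], states)
        assert disc.thresholds[j, 0] == pytest.approx(lo)
        assert disc.thresholds[j, 1] == pytest.approx(hi)


# ---------------------------------------------------------------------------
# mutual information


def test_mi_closed_forms():
    # constant has zero entropy -> zero MI against anything
    assert mutual_information([3] * 10, [0, 1] * 5) == 0.0
    # MI(x, x) = H(x) = log 2 for a balanced binary vector
    x = [0] * 8 + [1] * 8
    assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)
    # independent empirical joint -> exactly zero
    assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)


def test_mi_length_mismatch():
    with pytest.raises(ValueError):
        mutual_information([0, 1], [0, 1, 0])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=60),
    st.data(),
)
def test_mi_symmetry_and_nonnegativity(x, data):
    y = data.draw(st.lists(st.integers(0, 2), min_size=len(x), max_size=len(x)))
    a = mutual_information(x, y)
    b = mutual_information(y, x)
    assert a == pytest.approx(b, abs=1e-12)
    assert a >= -1e-12


def test_mi_agrees_with_sklearn():
    from sklearn.metrics import mutual_info_score

    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.integers(0, 3, size=80)
        y = rng.integers(0, 2, size=80)
        assert mutual_information(x, y) == pytest.approx(mutual_info_score(x, y), abs=1e-12)


def test_mi_matches_loop_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.integers(0, 3, size=50)
        y = rng.integers(0, 3, size=50)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# greedy ranking


def test_single_feature_ranking():
    table = random_feature_table(np.random.default_rng(5), 30, 1)
    disc = discretize_table(table)
    ranking = mrmr_rank(disc)
    assert ranking.names == ["f0"]
    assert ranking.criterion[0] == pytest.approx(ranking.relevance[0])
    assert ranking.redundancy[0] == 0.0


def test_first_pick_is_max_relevance():
    rng = np.random.default_rng(6)
    table = random_feature_table(rng, 60, 8)
    table.X[:, 3] = table.y + 0.01 * rng.standard_normal(60)  # strong signal
    disc = discretize_table(table)
    ranking = mrmr_rank(disc, 4)
    assert ranking.names[0] == "f3"
    from p53act.mrmr import _mi_columns

    relevances = _mi_columns(disc.states, disc.label_states)
    assert ranking.relevance[0] == pytest.approx(relevances.max())


def test_duplicate_feature_pays_full_self_redundancy():
    rng = np.random.default_rng(7)
    n = 80
    signal = rng.standard_normal(n)
    y = (signal > 0).astype(int)
    table = FeatureTable(
        ids=[f"s{i}" for i in range(n)],
        feature_names=["f", "f_copy"],
        X=np.column_stack([signal, signal]),
        y=y,
    )
    disc = discretize_table(table)
    ranking = mrmr_rank(disc)
    assert ranking.names == ["f", "f_copy"]  # tie broken to the lowest index
    # in round 2 the copy's criterion drops by MI(f, f) = H(f) relative to
    # its relevance: maximal self-redundancy
    self_mi = mutual_information(disc.states[:, 0], disc.states[:, 1])
    assert ranking.criterion[1] == pytest.approx(ranking.relevance[1] - self_mi, abs=1e-12)
    assert self_mi > ranking.relevance[1]  # so the criterion went negative


def test_duplicate_is_overtaken_by_independent_noise():
    rng = np.random.default_rng(7)
    n = 80
    signal = rng.standard_normal(n)
    y = (signal > 0).astype(int)
    table = FeatureTable(
        ids=[f"s{i}" for i in range(n)],
        feature_names=["f", "f_copy", "noise"],
        X=np.column_stack([signal, signal, rng.standard_normal(n)]),
        y=y,
    )
    ranking = mrmr_rank(discretize_table(table))
    assert ranking.names[0] == "f"
    assert ranking.names[1] == "noise"  # the exact copy is maximally redundant


def test_matches_bruteforce_oracle_small():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n, p = int(rng.integers(20, 60)), int(rng.integers(2, 8))
        table = random_feature_table(rng, n, p)
        disc = discretize_table(table)
        ranking = mrmr_rank(disc)
        sel, crit = mrmr_oracle(disc.states, disc.label_states, p)
        assert ranking.names == [f"f{j}" for j in sel]
        assert np.allclose(ranking.criterion, crit, atol=1e-10)


def test_column_permutation_only_permutes_ties():
    rng = np.random.default_rng(9)
    table = random_feature_table(rng, 50, 6)
    disc = discretize_table(table)
    full = mrmr_rank(disc)
    # reversing column order must yield the same feature sequence when
    # criterion values are distinct (generic continuous data)
    rev = FeatureTable(
        ids=list(table.ids),
        feature_names=list(reversed(table.feature_names)),
        X=table.X[:, ::-1].copy(),
        y=table.y,
    )
    ranking_rev = mrmr_rank(discretize_table(rev))
    assert ranking_rev.names == full.names


def test_n_select_bounds():
    table = random_feature_table(np.random.default_rng(10), 20, 3)
    with pytest.raises(ValueError):
        mrmr_rank(discretize_table(table), 4)
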