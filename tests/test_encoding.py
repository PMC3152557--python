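"""Feature-space geometry, windows, per-site blocks and table assembly."""

import numpy as np
import pytest

from p53act.encoding import (
    PER_SITE,
    FeatureTable,
    MutantSpec,
    StructureFeatureRecord,
    build_feature_table,
    encode_mutant,
    encode_site,
    extract_window,
    feature_dimension,
    feature_names,
    parse_feature_name,
    site_feature_names,
)
from p53act.exceptions import (
    ArityError,
    FeatureNameError,
    InvalidMutantError,
    MissingStructureError,
)
from p53act.synthetic import SyntheticConfig, generate_mutant_inputs
from p53act import io


N_STRUCT = 5408


@pytest.mark.parametrize("k,total", [(1, 5668), (2, 5929), (3, 6190), (4, 6451)])
def test_feature_dimension_totals(k, total):
    assert feature_dimension(k) == total
    assert len(feature_names(k)) == total


@pytest.mark.parametrize("k", [0, 5, -1])
def test_feature_dimension_rejects_bad_arity(k):
    with pytest.raises(ArityError):
        feature_dimension(k)


def test_extract_window_interior_and_boundaries():
    assert extract_window("ACDEFGHIK", 5).residues == "ACDEFGHIK"
    assert extract_window("ACDEFGHIK", 1).residues == "XXXXACDEF"
    assert extract_window("ACDEFGHIK", 9).residues == "FGHIKXXXX"
    with pytest.raises(InvalidMutantError):
        extract_window("ACDEFGHIK", 10)
    with pytest.raises(InvalidMutantError):
        extract_window("ACDEFGHIK", 0)


def test_extract_window_p53_hotspot(p53_sequence):
    # direct slice of residues 269..277 around the R273 hotspot
    expected = p53_sequence[268:277]
    window = extract_window(p53_sequence, 273)
    assert window.residues == expected == "SFEVRVCAC"
    assert window.positions == tuple(range(269, 278))


def test_per_site_block_length_and_order(tiny_sequence, tiny_pssm, tiny_disorder, lookups):
    window = extract_window(tiny_sequence, 5)
    block = encode_site(window, "M", tiny_pssm, tiny_disorder, lookups)
    names = site_feature_names(1, 1)
    assert block.shape == (PER_SITE,) == (260,)
    assert len(names) == 260
    # spot-check alignment of names and values
    idx = names.index("AA5_disorder")
    assert block[idx] == tiny_disorder.value(5)
    idx = names.index("MUT_SNP")
    assert block[idx] == lookups.snp.value("M")
    idx = names.index("AA1_PSSM-1-A")
    assert block[idx] == tiny_pssm.row(1)[0]
    idx = names.index("GRANTHAM")
    assert block[idx] == lookups.grantham.distance("F", "M")  # window center F5


def test_grantham_diagonal_and_symmetry(lookups):
    assert lookups.grantham.distance("L", "L") == 0.0
    assert lookups.grantham.distance("R", "W") == lookups.grantham.distance("W", "R")
    assert lookups.grantham.distance("G", "W") == 184  # published value


def test_aafactor_block_constant_window(tiny_pssm, tiny_disorder, lookups):
    from p53act.encoding import ResidueWindow

    window = ResidueWindow(residues="AAAAAAAAA", positions=tuple(range(1, 10)))
    block = encode_site(window, "A", tiny_pssm, tiny_disorder, lookups)
    names = site_feature_names(1, 1)
    factors = lookups.aafactor.values("A")
    got = [block[i] for i, n in enumerate(names) if "AAFactor" in n]
    assert got == list(factors) * 10  # 9 window residues + the substituted one


def test_pad_positions_are_neutral(tiny_sequence, tiny_pssm, tiny_disorder, lookups):
    window = extract_window(tiny_sequence, 1)  # 4 left pads
    block = encode_site(window, "M", tiny_pssm, tiny_disorder, lookups)
    names = site_feature_names(1, 1)
    for i in range(1, 5):  # window residues 1..4 are pads
        assert block[names.index(f"AA{i}_SNP")] == 0.0
        assert block[names.index(f"AA{i}_disorder")] == 0.0
        assert block[names.index(f"AA{i}_PSSM-8-G")] == 0.0


def _structure(mutant_id, seed=0):
    rng = np.random.default_rng(seed)
    return StructureFeatureRecord(mutant_id, rng.standard_normal(N_STRUCT))


def test_encode_mutant_distances_and_dimension(p53_sequence, lookups):
    rng = np.random.default_rng(5)
    pssm_full = np.random.default_rng(6).random((len(p53_sequence), 20))
    from p53act.encoding import DisorderProfile, PSSMMatrix

    pssm = PSSMMatrix(scores=pssm_full)
    disorder = DisorderProfile(scores=rng.random(len(p53_sequence)))
    sites = [(110, p53_sequence[109], "A"), (175, "R", "H"), (273, "R", "C")]
    sites = [(p, w, "A" if w != "A" else "G") for p, w, _ in sites]
    spec = MutantSpec("m3", tuple(sites), label=1)
    vec = encode_mutant(spec, p53_sequence, pssm, disorder, lookups, _structure("m3"))
    names = feature_names(3)
    assert vec.shape[0] == feature_dimension(3) == len(names)
    assert vec[names.index("DIST1-2")] == 65.0
    assert vec[names.index("DIST2-3")] == 98.0
    # determinism: identical inputs -> identical vectors, bit for bit
    vec2 = encode_mutant(spec, p53_sequence, pssm, disorder, lookups, _structure("m3"))
    assert np.array_equal(vec, vec2)
    # structure block sits at the tail in V order
    assert vec[names.index("V1")] == _structure("m3").values[0]
    assert vec[names.index("V5408")] == _structure("m3").values[-1]


def test_mutant_spec_invariants(p53_sequence):
    with pytest.raises(InvalidMutantError):
        MutantSpec("bad", ((175, "R", "R"),), 1)  # silent
    with pytest.raises(InvalidMutantError):
        MutantSpec("bad", ((273, "R", "C"), (175, "R", "H")), 1)  # not increasing
    with pytest.raises(ArityError):
        MutantSpec("bad", tuple((i, "R", "H") for i in (1, 2, 3, 4, 5)), 1)
    spec = MutantSpec("bad", ((175, "G", "H"),), 1)  # wrong wild-type letter
    with pytest.raises(InvalidMutantError, match="wild-type"):
        spec.validate_against(p53_sequence)


def _bundle_tables(tmp_path, config):
    bundle = generate_mutant_inputs(config, tmp_path / "bundle")
    return (
        list(bundle.specs),
        bundle.sequence,
        io.read_pssm(bundle.pssm),
        io.read_disorder(bundle.disorder),
        io.read_structure_features(bundle.structure),
    )


def test_build_feature_table_four_site(tmp_path, lookups):
    # the four-site study set: 31 mutants, 6451 features
    config = SyntheticConfig(k_sites=4, n_active=7, n_inactive=24, seed=2)
    specs, seq, pssm, disorder, structure = _bundle_tables(tmp_path, config)
    table = build_feature_table(specs, seq, pssm, disorder, lookups, structure)
    assert table.X.shape == (31, 6451)
    assert table.y.sum() == 7


def test_build_feature_table_errors_and_edge_cases(tmp_path, lookups):
    config = SyntheticConfig(k_sites=2, n_active=2, n_inactive=3, seed=4)
    specs, seq, pssm, disorder, structure = _bundle_tables(tmp_path, config)
    # empty list: 0 rows, full header
    empty = build_feature_table([], seq, pssm, disorder, lookups, structure, k=2)
    assert empty.n_samples == 0 and empty.n_features == 5929
    # duplicate ids rejected
    with pytest.raises(InvalidMutantError):
        build_feature_table(specs + [specs[0]], seq, pssm, disorder, lookups, structure)
    # mixed arity rejected
    one_site = MutantSpec("x1", ((specs[0].sites[0]),), 0)
    with pytest.raises(ArityError):
        build_feature_table(specs + [one_site], seq, pssm, disorder, lookups, structure)
    # missing structure record names the mutant
    del structure[specs[0].mutant_id]
    with pytest.raises(MissingStructureError, match=specs[0].mutant_id):
        build_feature_table(specs, seq, pssm, disorder, lookups, structure)


def test_row_permutation_leaves_columns_and_values(tmp_path, lookups):
    config = SyntheticConfig(k_sites=1, n_active=3, n_inactive=4, seed=9)
    specs, seq, pssm, disorder, structure = _bundle_tables(tmp_path, config)
    t1 = build_feature_table(specs, seq, pssm, disorder, lookups, structure)
    t2 = build_feature_table(specs[::-1], seq, pssm, disorder, lookups, structure)
    assert t1.feature_names == t2.feature_names
    order = [t2.ids.index(i) for i in t1.ids]
    assert np.array_equal(t1.X, t2.X[order])


@pytest.mark.parametrize("k", [1, 2, 4])
def test_feature_name_round_trip(k):
    for name in feature_names(k):
        assert parse_feature_name(name).canonical == name


@pytest.mark.parametrize(
    "bad",
    ["V0", "V5409", "AA10_SNP", "AP5.AA1_SNP", "AA1_PSSM-8-W", "DIST1-3", "MUT_disorder", "junk"],
)
def test_feature_name_rejects_malformed(bad):
    with pytest.raises(FeatureNameError):
        parse_feature_name(bad)


def test_feature_table_rejects_nonfinite():
    with pytest.raises(ValueError):
        FeatureTable(
            ids=["a", "b"],
            feature_names=["f1"],
            X=np.array([[1.0], [np.nan]]),
            y=np.array([0, 1]),
        )
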