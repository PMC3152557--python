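"""Hybrid feature encoding of multi-site p53 mutants.

A mutant with k simultaneous substitutions (k = 1..4) is represented by a
fixed-length vector that concatenates, per mutation site, eight feature
families computed on the 9-residue window centred on the site (the mutated
residue plus four neighbours on each side):

==============  =====  ==========================================================
family          count  content (per site)
==============  =====  ==========================================================
SNP              10    gain/loss propensity of the 9 window residues + of the
                       substituted residue
pro-pro          10    interface-conservation propensity, same layout
AAFactor         50    5 Atchley factors x 9 window residues + 5 for the
                       substituted residue
PSSM            180    20 conservation probabilities x 9 window positions
disorder          9    per-residue structural disorder of the window
GRANTHAM          1    physicochemical distance wild-type -> substituted residue
==============  =====  ==========================================================

The 260 x k per-site values are followed by k-1 inter-site distances
(absolute residue-index differences between consecutive sites) and by the
5408 precomputed structure descriptors V1..V5408 (V1-V4826: 2D surface map
of the mutant model; V4827-V5408: 3D alpha-carbon distance-difference map
against the wild type). Totals: 5668 / 5929 / 6190 / 6451 features for
k = 1 / 2 / 3 / 4.

Feature names are parseable: ``AA3_PSSM-8-G`` is the PSSM probability for
column 8 (G) at window residue 3; multi-site mutants prefix the site,
``AP2.AA8_PSSM-3-N``. :func:`parse_feature_name` inverts the scheme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ArityError,
    FeatureNameError,
    InvalidMutantError,
    MissingStructureError,
)
from .tables import (
    AMINO_ACIDS,
    PAD,
    PSSM_COLUMNS,
    AAFactorTable,
    GranthamMatrix,
    ScalarLookup,
    load_aafactors,
    load_grantham,
    load_propro,
    load_snp,
)

WINDOW_SIZE = 9
HALF_WINDOW = 4
N_STRUCTURE_2D = 4826
N_STRUCTURE_3D = 582
N_STRUCTURE = N_STRUCTURE_2D + N_STRUCTURE_3D
PER_SITE = 260  # 10 + 10 + 50 + 180 + 9 + 1

FAMILIES = (
    "SNP",
    "pro-pro",
    "AAFactor",
    "PSSM",
    "disorder",
    "GRANTHAM",
    "distance",
    "2D structure",
    "3D structure",
)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MutantSpec:
    """One mutant: 1-4 (position, wild-type, substituted) triples + label."""

    mutant_id: str
    sites: tuple[tuple[int, str, str], ...]
    label: int  # 1 = transcriptionally active, 0 = inactive

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple((int(p), w, m) for p, w, m in self.sites))
        k = len(self.sites)
        if not 1 <= k <= 4:
            raise ArityError(f"{self.mutant_id}: {k} sites, expected 1..4")
        positions = [p for p, _, _ in self.sites]
        if positions != sorted(positions) or len(set(positions)) != k:
            raise InvalidMutantError(f"{self.mutant_id}: positions must be strictly increasing")
        for p, wt, mut in self.sites:
            if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
                raise InvalidMutantError(f"{self.mutant_id}: non-standard residue in {wt}{p}{mut}")
            if wt == mut:
                raise InvalidMutantError(f"{self.mutant_id}: silent substitution {wt}{p}{mut}")
        if self.label not in (0, 1):
            raise InvalidMutantError(f"{self.mutant_id}: label must be 0 or 1")

    @property
    def k(self) -> int:
        return len(self.sites)

    def validate_against(self, sequence: str) -> None:
        for p, wt, _ in self.sites:
            if not 1 <= p <= len(sequence):
                raise InvalidMutantError(
                    f"{self.mutant_id}: position {p} outside 1..{len(sequence)}"
                )
            if sequence[p - 1] != wt:
                raise InvalidMutantError(
                    f"{self.mutant_id}: wild-type {wt} at {p} does not match "
                    f"sequence residue {sequence[p - 1]}"
                )

    def mutation_token(self) -> str:
        return "+".join(f"{w}{p}{m}" for p, w, m in self.sites)


@dataclass(frozen=True)
class ResidueWindow:
    """9 residues centred on a mutation site; X pads past the termini."""

    residues: str
    positions: tuple[int, ...]  # 1-based; out-of-range values are kept

    def __post_init__(self):
        if len(self.residues) != WINDOW_SIZE or len(self.positions) != WINDOW_SIZE:
            raise InvalidMutantError("window must hold exactly 9 residues")

    @property
    def center(self) -> str:
        return self.residues[HALF_WINDOW]


@dataclass(frozen=True)
class PSSMMatrix:
    """L x 20 per-position conservation scores for the wild-type sequence."""

    scores: np.ndarray
    columns: str = PSSM_COLUMNS

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError("PSSM must be L x 20")
        if not np.isfinite(scores).all():
            raise ValueError("PSSM contains non-finite entries")
        if len(self.columns) != 20:
            raise ValueError("PSSM column order must list 20 residues")

    def __len__(self) -> int:
        return self.scores.shape[0]

    def row(self, position: int) -> np.ndarray:
        """20 scores at a 1-based position; all-zero outside the sequence."""
        if 1 <= position <= len(self):
            return self.scores[position - 1]
        return np.zeros(20)


@dataclass(frozen=True)
class DisorderProfile:
    """One structural-disorder score per wild-type position."""

    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float).ravel()
        object.__setattr__(self, "scores", scores)
        if not np.isfinite(scores).all():
            raise ValueError("disorder profile contains non-finite entries")

    def __len__(self) -> int:
        return self.scores.shape[0]

    def value(self, position: int) -> float:
        if 1 <= position <= len(self):
            return float(self.scores[position - 1])
        return 0.0


@dataclass(frozen=True)
class StructureFeatureRecord:
    """Precomputed V1..V5408 structure descriptors for one mutant."""

    mutant_id: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if values.shape[0] != N_STRUCTURE:
            raise ValueError(
                f"{self.mutant_id}: {values.shape[0]} structure values, expected {N_STRUCTURE}"
            )
        if not np.isfinite(values).all():
            raise ValueError(f"{self.mutant_id}: non-finite structure values")


@dataclass(frozen=True)
class LookupTables:
    """The four scalar/tabular lookups used by the per-site encoder."""

    snp: ScalarLookup
    propro: ScalarLookup
    aafactor: AAFactorTable
    grantham: GranthamMatrix

    @classmethod
    def default(cls) -> "LookupTables":
        return cls(load_snp(), load_propro(), load_aafactors(), load_grantham())


@dataclass
class FeatureTable:
    """Samples x named features with binary activity labels."""

    ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        if len(self.ids) != n or self.y.shape != (n,):
            raise ValueError("ids / labels do not match the matrix")
        if len(self.feature_names) != p:
            raise ValueError("feature names do not match the matrix")
        if len(set(self.ids)) != n:
            raise InvalidMutantError("duplicate mutant ids")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if n and not np.isfinite(self.X).all():
            raise ValueError("feature table contains non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_indices(self, names: list[str]) -> np.ndarray:
        from .exceptions import UnknownFeatureError

        index = {name: i for i, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise UnknownFeatureError(f"unknown features: {missing[:5]}")
        return np.asarray([index[n] for n in names], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "label", ["active" if v else "inactive" for v in self.y])
        frame.insert(0, "mutant_id", self.ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        y = (frame["label"].astype(str) == "active").astype(int).to_numpy()
        names = [c for c in frame.columns if c not in ("mutant_id", "label")]
        return cls(
            ids=[str(v) for v in frame["mutant_id"]],
            feature_names=names,
            X=frame[names].to_numpy(dtype=float) if len(frame) else np.empty((0, len(names))),
            y=y,
        )


# ---------------------------------------------------------------------------
# feature-space geometry


def feature_dimension(k: int) -> int:
    """Total vector length for a k-site mutant (5668/5929/6190/6451)."""
    if k not in (1, 2, 3, 4):
        raise ArityError(f"number of mutation sites must be 1..4, got {k}")
    return PER_SITE * k + (k - 1) + N_STRUCTURE


def _site_prefix(site: int, k: int) -> str:
    return "" if k == 1 else f"AP{site}."


def site_feature_names(site: int, k: int) -> list[str]:
    """The 260 per-site feature names, in encoding order."""
    p = _site_prefix(site, k)
    names: list[str] = []
    names += [f"{p}AA{i}_SNP" for i in range(1, 10)] + [f"{p}MUT_SNP"]
    names += [f"{p}AA{i}_propro" for i in range(1, 10)] + [f"{p}MUT_propro"]
    for i in range(1, 10):
        names += [f"{p}AA{i}_AAFactor-{f}" for f in range(1, 6)]
    names += [f"{p}MUT_AAFactor-{f}" for f in range(1, 6)]
    for i in range(1, 10):
        names += [f"{p}AA{i}_PSSM-{j}-{aa}" for j, aa in enumerate(PSSM_COLUMNS, start=1)]
    names += [f"{p}AA{i}_disorder" for i in range(1, 10)]
    names += [f"{p}GRANTHAM"]
    return names


def feature_names(k: int) -> list[str]:
    """All feature names for a k-site mutant, in encoding order."""
    feature_dimension(k)  # arity check
    names: list[str] = []
    for s in range(1, k + 1):
        names += site_feature_names(s, k)
    names += [f"DIST{i}-{i + 1}" for i in range(1, k)]
    names += [f"V{i}" for i in range(1, N_STRUCTURE + 1)]
    return names


@dataclass(frozen=True)
class FeatureName:
    """Parsed feature name: (site, window residue, family, detail)."""

    family: str
    site: int | None = None  # 1..4, None for k=1 names and global families
    residue: int | None = None  # 1..9 window index; None for MUT/global
    is_mut: bool = False  # the substituted-residue variant of a family
    detail: str | None = None  # factor index, PSSM "j-X", V index, "i-j"

    @property
    def canonical(self) -> str:
        if self.family in ("2D structure", "3D structure"):
            return f"V{self.detail}"
        if self.family == "distance":
            return f"DIST{self.detail}"
        prefix = f"AP{self.site}." if self.site is not None else ""
        residue = "MUT" if self.is_mut else (f"AA{self.residue}" if self.residue else "")
        if self.family == "GRANTHAM":
            return f"{prefix}GRANTHAM"
        token = {"pro-pro": "propro"}.get(self.family, self.family)
        suffix = f"{token}-{self.detail}" if self.detail else token
        return f"{prefix}{residue}_{suffix}"


_NAME_RE = re.compile(
    r"^(?:AP(?P<site>[1-4])\.)?"
    r"(?:(?:AA(?P<res>[1-9])|(?P<mut>MUT))_)?"
    r"(?P<fam>SNP|propro|AAFactor-(?P<factor>[1-5])|"
    r"PSSM-(?P<col>\d{1,2})-(?P<colaa>[A-Z])|disorder|GRANTHAM)$"
)


def parse_feature_name(name: str) -> FeatureName:
    """Invert the naming scheme; raises :class:`FeatureNameError` otherwise."""
    m = re.match(r"^V(\d+)$", name)
    if m:
        idx = int(m.group(1))
        if not 1 <= idx <= N_STRUCTURE:
            raise FeatureNameError(f"{name}: structure index outside 1..{N_STRUCTURE}")
        family = "2D structure" if idx <= N_STRUCTURE_2D else "3D structure"
        return FeatureName(family=family, detail=str(idx))
    m = re.match(r"^DIST([1-3])-([2-4])$", name)
    if m:
        i, j = int(m.group(1)), int(m.group(2))
        if j != i + 1:
            raise FeatureNameError(f"{name}: distances join consecutive sites")
        return FeatureName(family="distance", detail=f"{i}-{j}")
    m = _NAME_RE.match(name)
    if not m:
        raise FeatureNameError(f"unparseable feature name: {name}")
    site = int(m.group("site")) if m.group("site") else None
    residue = int(m.group("res")) if m.group("res") else None
    is_mut = m.group("mut") is not None
    fam = m.group("fam")
    if fam.startswith("AAFactor"):
        family, detail = "AAFactor", m.group("factor")
    elif fam.startswith("PSSM"):
        col, colaa = int(m.group("col")), m.group("colaa")
        if not 1 <= col <= 20 or PSSM_COLUMNS[col - 1] != colaa:
            raise FeatureNameError(f"{name}: PSSM column {col} is {PSSM_COLUMNS[col - 1]}")
        family, detail = "PSSM", f"{col}-{colaa}"
    else:
        family, detail = {"propro": "pro-pro"}.get(fam, fam), None
    if family == "GRANTHAM":
        if residue is not None or is_mut:
            raise FeatureNameError(f"{name}: GRANTHAM carries no residue index")
    elif residue is None and not is_mut:
        raise FeatureNameError(f"{name}: missing AA1..AA9 or MUT residue token")
    if family in ("PSSM", "disorder") and is_mut:
        raise FeatureNameError(f"{name}: {family} is defined on window positions only")
    return FeatureName(family=family, site=site, residue=residue, is_mut=is_mut, detail=detail)


# ---------------------------------------------------------------------------
# encoding operations


def extract_window(sequence: str, position: int) -> ResidueWindow:
    """The 9-residue window centred on a 1-based position; X past termini."""
    if not 1 <= position <= len(sequence):
        raise InvalidMutantError(f"position {position} outside 1..{len(sequence)}")
    positions = tuple(range(position - HALF_WINDOW, position + HALF_WINDOW + 1))
    residues = "".join(
        sequence[p - 1] if 1 <= p <= len(sequence) else PAD for p in positions
    )
    return ResidueWindow(residues=residues, positions=positions)


def encode_site(
    window: ResidueWindow,
    mut_aa: str,
    pssm: PSSMMatrix,
    disorder: DisorderProfile,
    tables: LookupTables,
) -> np.ndarray:
    """The 260 per-site values, in the order of :func:`site_feature_names`."""
    if mut_aa not in AMINO_ACIDS:
        raise InvalidMutantError(f"substituted residue {mut_aa!r} is not standard")
    values: list[float] = []
    values += [tables.snp.value(aa) for aa in window.residues] + [tables.snp.value(mut_aa)]
    values += [tables.propro.value(aa) for aa in window.residues] + [tables.propro.value(mut_aa)]
    for aa in window.residues:
        values += tables.aafactor.values(aa)
    values += tables.aafactor.values(mut_aa)
    for p in window.positions:
        values += pssm.row(p).tolist()
    values += [disorder.value(p) for p in window.positions]
    values += [tables.grantham.distance(window.center, mut_aa)]
    return np.asarray(values, dtype=float)


def encode_mutant(
    spec: MutantSpec,
    sequence: str,
    pssm: PSSMMatrix,
    disorder: DisorderProfile,
    tables: LookupTables,
    structure: StructureFeatureRecord,
) -> np.ndarray:
    """The full hybrid vector: 260k per-site + (k-1) distances + V1..V5408."""
    spec.validate_against(sequence)
    if structure is None:
        raise MissingStructureError(f"no structure-feature record for {spec.mutant_id}")
    if structure.mutant_id != spec.mutant_id:
        raise MissingStructureError(
            f"structure record {structure.mutant_id} does not match {spec.mutant_id}"
        )
    blocks = [
        encode_site(extract_window(sequence, p), mut, pssm, disorder, tables)
        for p, _, mut in spec.sites
    ]
    positions = [p for p, _, _ in spec.sites]
    distances = np.asarray(
        [positions[i + 1] - positions[i] for i in range(spec.k - 1)], dtype=float
    )
    vector = np.concatenate(blocks + [distances, structure.values])
    assert vector.shape[0] == feature_dimension(spec.k)
    return vector


def build_feature_table(
    specs: list[MutantSpec],
    sequence: str,
    pssm: PSSMMatrix,
    disorder: DisorderProfile,
    tables: LookupTables,
    structure: dict[str, StructureFeatureRecord],
    k: int | None = None,
) -> FeatureTable:
    """Encode a homogeneous list of k-site mutants into one table."""
    if specs:
        ks = {s.k for s in specs}
        if len(ks) > 1:
            raise ArityError(f"mixed site counts in one table: {sorted(ks)}")
        k_specs = ks.pop()
        if k is not None and k != k_specs:
            raise ArityError(f"specs have {k_specs} sites, table expects {k}")
        k = k_specs
    elif k is None:
        raise ArityError("k must be given for an empty spec list")
    names = feature_names(k)
    ids = [s.mutant_id for s in specs]
    if len(set(ids)) != len(ids):
        raise InvalidMutantError("duplicate mutant ids in spec list")
    rows = []
    for spec in specs:
        if spec.mutant_id not in structure:
            raise MissingStructureError(f"no structure-feature record for {spec.mutant_id}")
        rows.append(
            encode_mutant(spec, sequence, pssm, disorder, tables, structure[spec.mutant_id])
        )
    X = np.vstack(rows) if rows else np.empty((0, len(names)))
    y = np.asarray([s.label for s in specs], dtype=int)
    return FeatureTable(ids=ids, feature_names=names, X=X, y=y)
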