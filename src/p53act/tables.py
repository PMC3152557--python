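"""Bundled amino-acid lookup tables.

Four per-residue/per-pair tables feed the sequence-derived features:

* ``snp`` — evolutionary gain/loss propensity of each residue type
  (placeholder values; see the data file header for provenance and how to
  substitute the published table),
* ``propro`` — conservation propensity at protein-protein interfaces
  (placeholder values, same caveat),
* Atchley's five factor scores (polarity, secondary structure, molecular
  volume, codon diversity, electrostatic charge),
* the Grantham physicochemical distance between residue pairs.

All loaders accept an optional path so users can swap in their own files;
the bundled files are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Column order of the PSI-BLAST PSSM output; feature suffixes like
#: "PSSM-8-G" use the 1-based index into this string.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"
#: Pad symbol used where a 9-residue window exits the sequence.
PAD = "X"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("p53act").joinpath("data", name)))


def _read_rows(path: Path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass(frozen=True)
class ScalarLookup:
    """One real value per standard amino acid; the pad symbol maps to 0."""

    name: str
    table: dict[str, float]

    def __post_init__(self):
        if set(self.table) != set(AMINO_ACIDS):
            raise ValueError(f"{self.name}: need exactly the 20 standard residues")
        for aa, v in self.table.items():
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{self.name}: non-finite value for {aa}")

    def value(self, aa: str) -> float:
        if aa == PAD:
            return 0.0
        return self.table[aa]


@dataclass(frozen=True)
class AAFactorTable:
    """Atchley factor scores: 5 numeric patterns per amino acid."""

    table: dict[str, tuple[float, float, float, float, float]]

    def __post_init__(self):
        if set(self.table) != set(AMINO_ACIDS):
            raise ValueError("AAFactorTable: need exactly the 20 standard residues")

    def values(self, aa: str) -> tuple[float, ...]:
        if aa == PAD:
            return (0.0,) * 5
        return self.table[aa]


@dataclass(frozen=True)
class GranthamMatrix:
    """Symmetric physicochemical distance between amino-acid pairs."""

    _pairs: dict[tuple[str, str], float] = field(repr=False)

    def distance(self, aa1: str, aa2: str) -> float:
        if aa1 == aa2:
            return 0.0
        return self._pairs[(aa1, aa2)] if (aa1, aa2) in self._pairs else self._pairs[(aa2, aa1)]


def load_snp(path: str | Path | None = None) -> ScalarLookup:
    rows = _read_rows(Path(path) if path else _data_path("snp_gain_loss.synthetic.tsv"))
    rows = [r for r in rows if r[0] != "aa"]
    return ScalarLookup("SNP", {aa: float(v) for aa, v in rows})


def load_propro(path: str | Path | None = None) -> ScalarLookup:
    rows = _read_rows(Path(path) if path else _data_path("propro_conservation.synthetic.tsv"))
    rows = [r for r in rows if r[0] != "aa"]
    return ScalarLookup("pro-pro", {aa: float(v) for aa, v in rows})


def load_aafactors(path: str | Path | None = None) -> AAFactorTable:
    rows = _read_rows(Path(path) if path else _data_path("atchley_factors.tsv"))
    rows = [r for r in rows if r[0] != "aa"]
    return AAFactorTable({r[0]: tuple(float(v) for v in r[1:6]) for r in rows})


def load_grantham(path: str | Path | None = None) -> GranthamMatrix:
    rows = _read_rows(Path(path) if path else _data_path("grantham.tsv"))
    rows = [r for r in rows if r[0] != "aa1"]
    pairs: dict[tuple[str, str], float] = {}
    for a, b, d in rows:
        v = float(d)
        if v < 0:
            raise ValueError(f"Grantham distance must be non-negative: {a}-{b}")
        pairs[(a, b)] = v
    expected = 190  # 20 choose 2
    if len(pairs) != expected:
        raise ValueError(f"Grantham table has {len(pairs)} pairs, expected {expected}")
    return GranthamMatrix(pairs)


def p53_sequence_path() -> Path:
    """Path of the bundled wild-type human p53 FASTA (UniProt P04637, 393 aa)."""
    return _data_path("p53_human.fasta")
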