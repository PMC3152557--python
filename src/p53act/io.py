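"""Readers and writers for the input/output file dialects.

* wild-type sequence: FASTA (via Biopython);
* PSSM: the PSI-BLAST ASCII matrix (``-Q`` output); per the declared
  convention the *conservation-probability* block (columns 23-42, printed as
  integer percentages) is ingested, divided by 100;
* disorder: two-column tabular text (position, score);
* mutant lists: delimited text with ``P175H+R273C``-style mutation tokens
  and an active/inactive label;
* structure features: header-bearing delimited matrix keyed by mutant id
  with columns V1..V5408; rows with missing values are dropped at load and
  counted in the log;
* feature tables / rankings: tab- or comma-separated text with headers.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .encoding import (
    N_STRUCTURE,
    DisorderProfile,
    FeatureTable,
    MutantSpec,
    PSSMMatrix,
    StructureFeatureRecord,
)
from .exceptions import InvalidMutantError
from .tables import PSSM_COLUMNS

logger = logging.getLogger("p53act")

_ACTIVE_TOKENS = {"active", "1", "true", "pos", "positive"}
_INACTIVE_TOKENS = {"inactive", "0", "false", "neg", "negative"}


def read_fasta(path: str | Path) -> str:
    """First record of a FASTA file as an upper-case residue string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# PSSM


def read_pssm(path: str | Path) -> PSSMMatrix:
    """Parse a PSI-BLAST ASCII PSSM; returns the probability block / 100."""
    probs: list[list[float]] = []
    expected_pos = 1
    for line in Path(path).read_text().splitlines():
        tokens = line.split()
        if len(tokens) < 42 or not tokens[0].isdigit():
            continue
        if int(tokens[0]) != expected_pos:
            continue
        # tokens: pos, aa, 20 log-odds, 20 percentages, (info, weight)
        probs.append([float(t) / 100.0 for t in tokens[22:42]])
        expected_pos += 1
    if not probs:
        raise ValueError(f"{path}: no PSSM rows found")
    return PSSMMatrix(scores=np.asarray(probs), columns=PSSM_COLUMNS)


def write_pssm(path: str | Path, matrix: PSSMMatrix, sequence: str) -> None:
    """Write an L x 20 probability matrix in the PSI-BLAST ASCII dialect."""
    if len(sequence) != len(matrix):
        raise ValueError("sequence length does not match the PSSM")
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            "
        + "  ".join(PSSM_COLUMNS)
        + "   "
        + "   ".join(PSSM_COLUMNS),
    ]
    for i, aa in enumerate(sequence):
        logodds = " ".join(f"{0:3d}" for _ in range(20))
        pct = " ".join(f"{int(round(v * 100)):3d}" for v in matrix.scores[i])
        lines.append(f"{i + 1:5d} {aa} {logodds}  {pct}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# disorder


def read_disorder(path: str | Path) -> DisorderProfile:
    frame = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["pos", "score"])
    frame = frame.sort_values("pos")
    if not (frame["pos"].to_numpy() == np.arange(1, len(frame) + 1)).all():
        raise ValueError(f"{path}: positions must run 1..L without gaps")
    return DisorderProfile(scores=frame["score"].to_numpy(dtype=float))


def write_disorder(path: str | Path, profile: DisorderProfile) -> None:
    lines = [f"{i + 1}\t{v:.6f}" for i, v in enumerate(profile.scores)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mutant lists

_SITE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation_token(token: str) -> tuple[tuple[int, str, str], ...]:
    """``"P175H+R273C"`` -> ((175, 'P', 'H'), (273, 'R', 'C'))."""
    sites = []
    for part in token.strip().split("+"):
        m = _SITE_RE.match(part.strip())
        if not m:
            raise InvalidMutantError(f"malformed mutation token: {part!r}")
        sites.append((int(m.group(2)), m.group(1), m.group(3)))
    return tuple(sites)


def _parse_label(raw: str) -> int:
    token = str(raw).strip().lower()
    if token in _ACTIVE_TOKENS:
        return 1
    if token in _INACTIVE_TOKENS:
        return 0
    raise InvalidMutantError(f"unrecognized activity label: {raw!r}")


def read_mutants(path: str | Path) -> list[MutantSpec]:
    """Read a delimited mutant list.

    Expected columns (tab-separated, header): ``mutant_id`` (optional),
    ``mutation`` (``P175H+R273C`` tokens) and ``label``.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "mutation" not in frame.columns or "label" not in frame.columns:
        raise InvalidMutantError(f"{path}: need 'mutation' and 'label' columns")
    specs = []
    for i, row in frame.iterrows():
        mutant_id = str(row["mutant_id"]) if "mutant_id" in frame.columns else str(row["mutation"])
        specs.append(
            MutantSpec(
                mutant_id=mutant_id,
                sites=parse_mutation_token(str(row["mutation"])),
                label=_parse_label(row["label"]),
            )
        )
    return specs


def write_mutants(path: str | Path, specs: list[MutantSpec]) -> None:
    lines = ["mutant_id\tmutation\tlabel"]
    for s in specs:
        label = "active" if s.label else "inactive"
        lines.append(f"{s.mutant_id}\t{s.mutation_token()}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structure-feature matrix


def read_structure_features(path: str | Path) -> dict[str, StructureFeatureRecord]:
    """Read the V1..V5408 matrix; silently-uncodeable rows are dropped.

    Missing values (empty cells, ``?`` or ``NA``) mark mutants whose
    structure could not be encoded; those rows are removed with a logged
    count, and the remaining rows must be complete.
    """
    frame = pd.read_csv(path, sep=None, engine="python", na_values=["?", "NA"], dtype=str)
    if "mutant_id" not in frame.columns:
        raise ValueError(f"{path}: need a 'mutant_id' column")
    expected = [f"V{i}" for i in range(1, N_STRUCTURE + 1)]
    missing_cols = [c for c in expected if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing structure columns, first: {missing_cols[0]}")
    values = frame[expected].apply(pd.to_numeric, errors="coerce")
    keep = values.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d structure rows with missing values", dropped)
    records = {}
    for mutant_id, row in zip(frame.loc[keep, "mutant_id"], values.loc[keep].to_numpy()):
        records[str(mutant_id)] = StructureFeatureRecord(str(mutant_id), row)
    return records


def write_structure_features(
    path: str | Path, records: dict[str, StructureFeatureRecord]
) -> None:
    header = "mutant_id," + ",".join(f"V{i}" for i in range(1, N_STRUCTURE + 1))
    lines = [header]
    for mutant_id, record in records.items():
        lines.append(mutant_id + "," + ",".join(f"{v:.4f}" for v in record.values))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tables and rankings


def write_feature_table(path: str | Path, table: FeatureTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> FeatureTable:
    return FeatureTable.from_frame(pd.read_csv(path, sep="\t"))
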