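"""One-shot orchestration: encode -> rank -> IFS -> report.

Every intermediate is persisted (feature table, ranked list, IFS curve,
optimal feature set), a machine-readable JSON report and a human-readable
text report are written, and the configuration is echoed next to the
outputs. All numbers in the reports are recomputed from the intermediates,
and a rerun with the same configuration and seed reproduces the report
byte for byte (the jackknife and mRMR stages are deterministic; the seed
only governs synthetic inputs upstream).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .encoding import FeatureTable, LookupTables, build_feature_table
from .exceptions import PipelineStageError
from .ifs import IFSCurve, ifs_run, summarize_families
from .mrmr import DEFAULT_ALPHA, discretize_table, mrmr_rank

logger = logging.getLogger("p53act")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Either ``table`` (a prebuilt feature table) or the five encoding inputs
    (``mutants``/``fasta``/``pssm``/``disorder``/``structure``) must be set.
    """

    out_dir: str = "p53act_run"
    table: str | None = None
    mutants: str | None = None
    fasta: str | None = None
    pssm: str | None = None
    disorder: str | None = None
    structure: str | None = None
    k_sites: int | None = None
    alpha: float = DEFAULT_ALPHA
    n_select: int | None = None  # ranking length; defaults to k_max
    k_max: int = 30
    step: int = 1
    standardize: bool = False
    plot: bool = False
    seed: int = 0

    _FIELDS_IN_REPORT = (
        "table", "mutants", "fasta", "pssm", "disorder", "structure",
        "k_sites", "alpha", "n_select", "k_max", "step", "standardize", "seed",
    )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a key=value config file ('#' comments allowed)."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        for f, typ in cls.__dataclass_fields__.items():
            if f not in values:
                continue
            raw = values[f]
            if raw in ("", "none", "None"):
                kwargs[f] = None
            elif f in ("k_sites", "n_select", "k_max", "step", "seed"):
                kwargs[f] = int(raw)
            elif f == "alpha":
                kwargs[f] = float(raw)
            elif f in ("standardize", "plot"):
                kwargs[f] = str(raw).lower() in ("1", "true", "yes", "on") if isinstance(raw, str) else bool(raw)
            else:
                kwargs[f] = raw
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={'' if v is None else v}" for k, v in sorted(asdict(self).items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    dataset: dict
    ranking_head: list[dict]
    ifs_curve: list[dict]
    optimal: dict
    config: dict
    version: str = field(default=__version__)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "dataset": self.dataset,
            "ranking_head": self.ranking_head,
            "ifs_curve": self.ifs_curve,
            "optimal": self.optimal,
        }


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, str(exc)) from exc
        logger.info("stage %-8s done in %.2fs", name, time.perf_counter() - start)
        return result

    return wrap


def _load_table(config: RunConfig) -> FeatureTable:
    if config.table:
        return io.read_feature_table(config.table)
    needed = (config.mutants, config.fasta, config.pssm, config.disorder, config.structure)
    if any(p is None for p in needed):
        raise ValueError("need either 'table' or all five encoding input paths")
    specs = io.read_mutants(config.mutants)
    sequence = io.read_fasta(config.fasta)
    pssm = io.read_pssm(config.pssm)
    disorder = io.read_disorder(config.disorder)
    structure = io.read_structure_features(config.structure)
    return build_feature_table(
        specs, sequence, pssm, disorder, LookupTables.default(), structure, k=config.k_sites
    )


def _standardized(table: FeatureTable) -> FeatureTable:
    std = table.X.std(axis=0)
    std[std == 0] = 1.0
    X = (table.X - table.X.mean(axis=0)) / std
    return FeatureTable(
        ids=list(table.ids), feature_names=list(table.feature_names), X=X, y=table.y
    )


def _plot_curve(curve: IFSCurve, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.ks, curve.mccs, marker="o", ms=3)
    ax.axvline(curve.optimal_k, ls="--", color="grey")
    ax.set_xlabel("number of features")
    ax.set_ylabel("jackknife MCC")
    ax.set_title(f"IFS curve (optimum: {curve.optimal_k} features, MCC {curve.optimal_mcc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute encode -> rank -> IFS, persist intermediates, build the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run_config.txt")

    table = _stage("encode")(_load_table, config)
    if config.standardize:
        table = _standardized(table)
    io.write_feature_table(out / "feature_table.tsv", table)

    k_max = min(config.k_max, table.n_features)
    n_select = config.n_select or k_max
    n_select = min(max(n_select, k_max), table.n_features)
    ranking = _stage("rank")(
        lambda: mrmr_rank(discretize_table(table, config.alpha), n_select)
    )
    ranking.write(out / "ranking.csv")

    curve = _stage("ifs")(ifs_run, table, ranking, k_max=k_max, step=config.step)
    curve.write(out / "ifs_curve.csv")
    optimal_frame = ranking.to_frame().head(curve.optimal_k)[["h", "name"]]
    optimal_frame.columns = ["order", "name"]
    optimal_frame.to_csv(out / "optimal_features.csv", index=False)
    if config.plot:
        _plot_curve(curve, out / "ifs_curve.png")

    summary = summarize_families(curve.optimal_features)
    report = RunReport(
        dataset={
            "n_samples": table.n_samples,
            "n_features": table.n_features,
            "n_active": int(table.y.sum()),
            "n_inactive": int((table.y == 0).sum()),
        },
        ranking_head=[
            {"h": i + 1, "name": ranking.names[i], "criterion": round(float(ranking.criterion[i]), 10)}
            for i in range(min(20, len(ranking)))
        ],
        ifs_curve=[
            {"n_features": int(k), "mcc": round(float(m), 10)}
            for k, m in zip(curve.ks, curve.mccs)
        ],
        optimal={
            "n_features": curve.optimal_k,
            "mcc": round(float(curve.optimal_mcc), 10),
            "features": curve.optimal_features,
            "families": summary.families,
            "sites": summary.sites,
        },
        config={f: getattr(config, f) for f in RunConfig._FIELDS_IN_REPORT},
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(_text_report(report))
    return report


def _text_report(report: RunReport) -> str:
    d = report.dataset
    o = report.optimal
    lines = [
        f"p53act {report.version} pipeline report",
        "",
        f"dataset: {d['n_samples']} mutants x {d['n_features']} features "
        f"({d['n_active']} active / {d['n_inactive']} inactive)",
        "",
        f"optimal feature set: {o['n_features']} features, jackknife MCC = {o['mcc']:.4f}",
        "family breakdown: "
        + ", ".join(f"{k}: {v}" for k, v in o["families"].items() if v),
        "",
        "top of the mRMR ranking:",
    ]
    for row in report.ranking_head[:10]:
        lines.append(f"  {row['h']:3d}  {row['name']:<28s} criterion {row['criterion']:+.6f}")
    return "\n".join(lines) + "\n"
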