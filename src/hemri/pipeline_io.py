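"""End-to-end orchestration, file I/O, configuration and report rendering.

``run_pipeline`` executes the full analysis on a participant table:

1. eligibility screening (participant flow report),
2. Dixon/Reed outlier screening per analyte x partition,
3. nonparametric reference intervals with 90% CIs per partition and for
   the pooled pregnant cohort,
4. rank-based partition comparisons,
5. out-of-range scoring of the pregnant cohort against manufacturer
   intervals,

and writes the flow report, an RI table (pooled pregnant + non-pregnant),
a trimester-stratified RI table with comparison p-values, the comparison
panel, the OOR table, an outlier-removal log, and a JSON manifest
(package/library versions, seed, config hash, per-stage counts).  All
outputs are deterministic given the seed; everything is computed before
anything is written, so a failing stage leaves no partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, analytes as panel
from .cohort_screening import ScreeningRules, screen_cohort
from .group_comparison import comparison_table
from .oor_analysis import oor_frame, oor_table
from .outlier_detection import dixon_reed_screen
from .ri_estimation import ReferenceInterval, nonparametric_ri
from .synthetic_data import DEMOGRAPHIC_COLUMNS, FLAG_COLUMNS

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "PipelineResult",
    "read_cohort",
    "run_pipeline",
    "write_tables",
]

log = logging.getLogger("hemri")

PREGNANT = ("T1", "T2", "T3")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Validated analysis settings; unknown keys are rejected on load."""

    cohort_path: str | None = None
    manufacturer_ri_path: str | None = None
    output_dir: str = "hemri_output"
    # screening
    systolic_max: float = 140.0
    diastolic_max: float = 90.0
    bmi_obese: float = 30.0
    # outlier screening
    outlier_iterate: bool = True
    outlier_min_n: int = 20
    # reference intervals
    p_low: float = 0.025
    p_high: float = 0.975
    confidence: float = 0.90
    ci_method: str = "auto"
    bootstrap_resamples: int = 2000
    rank_mode: str = "interpolate"
    # comparisons
    alpha: float = 0.05
    bonferroni: bool = False
    # OOR
    denominator_mode: str = "enrolled"
    seed: int = 0
    # per-analyte reporting decimals (display only)
    precision: Mapping[str, int] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def screening_rules(self) -> ScreeningRules:
        return ScreeningRules(
            systolic_max=self.systolic_max,
            diastolic_max=self.diastolic_max,
            bmi_obese=self.bmi_obese,
        )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a participant CSV.

    Requires the full demographic/flag schema plus at least one known
    analyte column; unknown columns are ignored with a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise PipelineError("read", f"malformed CSV {path}: {exc}") from exc
    required = list(DEMOGRAPHIC_COLUMNS) + list(FLAG_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError("read", f"missing required column(s): {missing}")
    known = set(required) | set(panel.ANALYTE_NAMES)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown column(s): %s", unknown)
        df = df.drop(columns=unknown)
    if not any(a in df.columns for a in panel.ANALYTE_NAMES):
        raise PipelineError("read", "no recognised analyte columns present")
    for flag in FLAG_COLUMNS:
        df[flag] = df[flag].astype(bool)
    return df


def read_manufacturer_ri(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a manufacturer interval CSV with columns analyte, low, high."""
    df = pd.read_csv(path)
    for col in ("analyte", "low", "high"):
        if col not in df.columns:
            raise PipelineError("read", f"manufacturer RI file lacks column {col!r}")
    return {
        str(r.analyte): (float(r.low), float(r.high)) for r in df.itertuples()
    }


def _ri_row(ri: ReferenceInterval) -> dict:
    return {
        "analyte": ri.analyte_name,
        "partition": ri.partition,
        "n": ri.n,
        "mean": ri.mean,
        "median": ri.median,
        "ri_low": ri.lower_limit,
        "ri_high": ri.upper_limit,
        "ci90_low_l": ri.lower_ci[0] if ri.lower_ci else np.nan,
        "ci90_low_u": ri.lower_ci[1] if ri.lower_ci else np.nan,
        "ci90_high_l": ri.upper_ci[0] if ri.upper_ci else np.nan,
        "ci90_high_u": ri.upper_ci[1] if ri.upper_ci else np.nan,
        "ci_method": ri.ci_method,
    }


@dataclass
class PipelineResult:
    flow: pd.DataFrame
    flow_report: dict
    ri_table: pd.DataFrame          # pooled pregnant + NP (published Table-2 layout)
    trimester_table: pd.DataFrame   # per-trimester RIs + comparison p-values
    comparisons: pd.DataFrame
    oor: pd.DataFrame
    outlier_log: pd.DataFrame
    manifest: dict


def run_pipeline(
    config: AnalysisConfig,
    cohort: pd.DataFrame | None = None,
    manufacturer: Mapping[str, tuple[float, float]] | None = None,
) -> PipelineResult:
    """Execute screening -> outlier exclusion -> RI -> comparisons -> OOR.

    ``cohort`` / ``manufacturer`` may be passed in memory; otherwise they
    are read from the paths in ``config`` (manufacturer intervals default
    to the analyzer-manual values shipped with the package).
    """
    t0 = time.perf_counter()
    if cohort is None:
        if config.cohort_path is None:
            raise PipelineError("read", "no cohort provided (path or frame)")
        cohort = read_cohort(config.cohort_path)
    if manufacturer is None:
        manufacturer = (
            read_manufacturer_ri(config.manufacturer_ri_path)
            if config.manufacturer_ri_path
            else dict(panel.MANUFACTURER_INTERVALS)
        )
    analyte_names = [a for a in panel.ANALYTE_NAMES if a in cohort.columns]
    partitions = [p for p in ("T1", "T2", "T3", "NP")
                  if (cohort["partition"] == p).any()]

    # -- screening ---------------------------------------------------------
    try:
        eligible, report = screen_cohort(cohort, config.screening_rules())
    except (KeyError, ValueError) as exc:
        raise PipelineError("screening", str(exc)) from exc
    log.info("screening: %d/%d eligible (%.1f%%) [%.2fs]",
             report.eligible, report.enrolled, report.eligible_percent,
             time.perf_counter() - t0)

    # -- outlier screening (independent per analyte x partition) ----------
    retained: dict[tuple[str, str], np.ndarray] = {}
    log_rows = []
    for analyte in analyte_names:
        for part in partitions:
            vals = eligible.loc[
                eligible["partition"] == part, analyte
            ].dropna().to_numpy()
            if vals.size == 0:
                continue
            res = dixon_reed_screen(
                vals, iterate=config.outlier_iterate,
                min_n=config.outlier_min_n,
                analyte_name=analyte, partition=part,
            )
            retained[(analyte, part)] = res.retained
            for rv in res.removed:
                log_rows.append({
                    "analyte": analyte, "partition": part, "value": rv.value,
                    "pass": rv.pass_index, "tail": rv.tail, "D": rv.d,
                    "R": rv.r, "ratio": rv.ratio, "n_copies": rv.count,
                })
    outlier_log = pd.DataFrame(
        log_rows, columns=["analyte", "partition", "value", "pass", "tail",
                           "D", "R", "ratio", "n_copies"],
    )

    # -- reference intervals ----------------------------------------------
    def _ri(values: np.ndarray, analyte: str, part: str) -> ReferenceInterval:
        return nonparametric_ri(
            values, p_low=config.p_low, p_high=config.p_high,
            confidence=config.confidence, ci_method=config.ci_method,
            n_boot=config.bootstrap_resamples, seed=config.seed,
            rank_mode=config.rank_mode, analyte_name=analyte, partition=part,
        )

    ri_rows, trimester_rows = [], []
    established: dict[str, tuple[float, float]] = {}
    for analyte in analyte_names:
        pooled = np.sort(np.concatenate(
            [retained[(analyte, p)] for p in PREGNANT
             if (analyte, p) in retained] or [np.array([])]
        ))
        if pooled.size >= 2:
            ri = _ri(pooled, analyte, "pregnant")
            ri_rows.append(_ri_row(ri))
            established[analyte] = (ri.lower_limit, ri.upper_limit)
        if (analyte, "NP") in retained and retained[(analyte, "NP")].size >= 2:
            ri_rows.append(_ri_row(_ri(retained[(analyte, "NP")], analyte, "NP")))
        for part in PREGNANT:
            if (analyte, part) in retained and retained[(analyte, part)].size >= 2:
                trimester_rows.append(
                    _ri_row(_ri(retained[(analyte, part)], analyte, part))
                )
    ri_table = pd.DataFrame(ri_rows)
    trimester_table = pd.DataFrame(trimester_rows)

    # -- comparisons -------------------------------------------------------
    comparisons = comparison_table(
        eligible, analyte_names, partitions=partitions,
        alpha=config.alpha, bonferroni=config.bonferroni,
    )
    if not trimester_table.empty and not comparisons.empty:
        pcols = ["analyte"] + [c for c in comparisons.columns if c.endswith("_p")]
        trimester_table = trimester_table.merge(
            comparisons[pcols], on="analyte", how="left"
        )

    # -- OOR scoring (pregnant cohort vs manufacturer intervals) -----------
    pregnant_all = cohort[cohort["partition"].isin(PREGNANT)]
    oor = pd.DataFrame()
    if len(pregnant_all):
        scored = [a for a in analyte_names if a in manufacturer]
        oor = oor_frame(oor_table(
            pregnant_all, manufacturer, established,
            analytes=scored, denominator_mode=config.denominator_mode,
        ))

    manifest = {
        "package": "hemri",
        "version": __version__,
        "libraries": {
            "numpy": np.__version__, "pandas": pd.__version__,
            "scipy": __import__("scipy").__version__,
        },
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "counts": {
            "enrolled": report.enrolled,
            "eligible": report.eligible,
            "outliers_removed": int(outlier_log["n_copies"].sum())
            if len(outlier_log) else 0,
            "analytes": len(analyte_names),
            "partitions": partitions,
        },
    }
    flow = pd.DataFrame([
        {"metric": k, "value": json.dumps(v) if isinstance(v, dict) else v}
        for k, v in report.to_dict().items()
    ])
    log.info("pipeline complete [%.2fs]", time.perf_counter() - t0)
    return PipelineResult(
        flow=flow, flow_report=report.to_dict(), ri_table=ri_table,
        trimester_table=trimester_table, comparisons=comparisons, oor=oor,
        outlier_log=outlier_log, manifest=manifest,
    )


def write_tables(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write every output table plus the JSON manifest; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in [
        ("flow_report.csv", result.flow),
        ("reference_intervals.csv", result.ri_table),
        ("trimester_intervals.csv", result.trimester_table),
        ("comparisons.csv", result.comparisons),
        ("oor_table.csv", result.oor),
        ("outlier_log.csv", result.outlier_log),
    ]:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2) + "\n")
    written.append(manifest_path)
    flow_json = out / "flow_report.json"
    flow_json.write_text(json.dumps(result.flow_report, indent=2) + "\n")
    written.append(flow_json)
    return written
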