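"""End-to-end run configuration and orchestration.

``run_pipeline`` executes load -> impute -> filter -> exposure -> life table
-> strata / period trend, and writes the output bundle (life-table CSVs, a
summary CSV, the exclusion report JSON, a text report and the resolved
configuration) to the output directory.  Everything downstream of the input
file is determined by the configuration, including the imputation seed, so a
rerun with the same inputs reproduces the bundle byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .bands import AgeBandSchema
from .cohort_io import (
    DAYS_PER_YEAR,
    Cohort,
    ExclusionReport,
    filter_eligible,
    impute_missing,
    load_cohort,
)
from .errors import ConfigError
from .exposure import ExposureTable, aggregate_exposure, crude_mortality_rate
from .lifetable import LifeTable, build_life_table
from .stratify import StratifiedResult, period_trend, stratified_life_tables

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one analysis run."""

    cohort_path: str
    column_map: Optional[dict] = None
    study_end: Optional[str] = None
    band_start: float = 20.0
    terminal_start: float = 65.0
    band_width: float = 5.0
    a: float = 0.5
    terminal_e_fixed: Optional[float] = None
    min_age: float = 20.0
    impute: bool = True
    seed: int = 0
    max_missing_fraction: float = 0.10
    route_column: str = "transmission"
    stratify_by: tuple[str, ...] = ()
    period_breaks: tuple[int, ...] = ()
    radix: float = 100_000.0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.band_width <= 0 or self.terminal_start <= self.band_start:
            raise ConfigError("invalid band layout")
        if not 0 <= self.a <= 1:
            raise ConfigError("a must lie in [0, 1]")
        if self.min_age < 0:
            raise ConfigError("min_age must be non-negative")
        if self.radix <= 0:
            raise ConfigError("radix must be positive")

    @property
    def schema(self) -> AgeBandSchema:
        return AgeBandSchema.from_uniform(
            self.band_start, self.terminal_start, self.band_width, self.a
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        unknown = set(loaded) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stratify_by", "period_breaks"):
            if key in loaded and loaded[key] is not None:
                loaded[key] = tuple(loaded[key])
        loaded.update({k: v for k, v in overrides.items() if v is not None})
        if "cohort_path" not in loaded:
            raise ConfigError("config needs cohort_path")
        return cls(**loaded)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stratify_by"] = list(self.stratify_by)
        d["period_breaks"] = list(self.period_breaks)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class PipelineResult:
    """Everything one run produced, in memory plus on disk."""

    config: RunConfig
    cohort: Cohort
    exclusions: ExclusionReport
    exposure: ExposureTable
    life_table: LifeTable
    strata: dict[str, StratifiedResult] = field(default_factory=dict)
    trend: Optional[StratifiedResult] = None
    report_text: str = ""
    output_files: list[Path] = field(default_factory=list)


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", str(label)).strip("_") or "blank"


def _descriptives(cohort: Cohort, exposure: ExposureTable) -> list[str]:
    df = cohort.data
    dur = (df["exit_date"] - df["date_of_diagnosis"]).dt.days / DAYS_PER_YEAR
    lines = [
        f"records analyzed: {len(df)}",
        f"total person-years: {exposure.total_person_years:.1f}",
        f"median follow-up (years): {float(dur.median()):.1f}",
        f"deaths: {int(exposure.total_deaths)}",
        f"crude mortality rate: {crude_mortality_rate(exposure):.1f} per 1,000 person-years",
        "",
        "counts by covariate:",
    ]
    for col in ["sex", "status"] + cohort.covariate_columns:
        counts = df[col].fillna("missing").value_counts()
        rendered = ", ".join(f"{k}={v}" for k, v in counts.head(10).items())
        lines.append(f"  {col}: {rendered}")
    return lines


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole analysis described by ``config`` and write outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = config.schema

    cohort = load_cohort(config.cohort_path, config.column_map, config.study_end)
    n_loaded = len(cohort)
    if config.impute:
        cohort = impute_missing(
            cohort,
            seed=config.seed,
            max_missing_fraction=config.max_missing_fraction,
            route_column=config.route_column,
        )
    cohort, exclusions = filter_eligible(cohort, min_age=config.min_age)

    exposure = aggregate_exposure(cohort, schema)
    life_table = build_life_table(
        exposure, radix=config.radix, terminal_e_fixed=config.terminal_e_fixed
    )

    strata: dict[str, StratifiedResult] = {}
    for var in config.stratify_by:
        strata[var] = stratified_life_tables(
            cohort, var, schema, radix=config.radix, terminal_e_fixed=config.terminal_e_fixed
        )
    trend = None
    if config.period_breaks:
        trend = period_trend(
            cohort,
            config.period_breaks,
            schema,
            radix=config.radix,
            terminal_e_fixed=config.terminal_e_fixed,
        )

    result = PipelineResult(
        config=config,
        cohort=cohort,
        exclusions=exclusions,
        exposure=exposure,
        life_table=life_table,
        strata=strata,
        trend=trend,
    )

    # ---- outputs -----------------------------------------------------------
    files: list[Path] = []

    f = outdir / "exclusions.json"
    exclusions.to_json(f)
    files.append(f)

    f = outdir / "life_table.csv"
    life_table.to_csv(f)
    files.append(f)

    summary_rows = []

    def _summary_row(variable: str, label: str, lt: Optional[LifeTable], exp) -> dict:
        row = {
            "variable": variable,
            "stratum": label,
            "deaths": exp.total_deaths,
            "person_years": exp.total_person_years,
            "e": np.nan,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if lt is not None:
            row.update(e=lt.e0, se=lt.se0, ci_low=float(lt.ci_low[0]), ci_high=float(lt.ci_high[0]))
        return row

    summary_rows.append(_summary_row("overall", "all", life_table, exposure))
    for var, res in {**strata, **({"period": trend} if trend else {})}.items():
        for label, exp in res.exposures.items():
            summary_rows.append(_summary_row(var, label, res.tables.get(label), exp))
            lt = res.tables.get(label)
            if lt is not None:
                f = outdir / f"life_table_{_safe_name(var)}_{_safe_name(label)}.csv"
                lt.to_csv(f)
                files.append(f)
    summary = pd.DataFrame(summary_rows)
    f = outdir / "summary.csv"
    summary.to_csv(f, index=False)
    files.append(f)

    lines = [
        "cohort life-table report",
        "========================",
        f"source: {config.cohort_path}",
        f"records loaded: {n_loaded}",
        f"records excluded: {exclusions.n_excluded} "
        + str({k: v for k, v in exclusions.counts.items() if v}),
        "",
    ]
    lines += _descriptives(cohort, exposure)
    first = schema.bands[0].label
    lines += [
        "",
        f"life expectancy at {schema.min_age:g} "
        f"(band {first}): {life_table.e0:.1f} years "
        f"(95% CI, {life_table.ci_low[0]:.1f} to {life_table.ci_high[0]:.1f})",
        "",
        "pooled life table:",
        life_table.to_text(),
    ]
    for var, res in strata.items():
        lines += ["", f"stratified by {var}:"]
        for _, r in res.summary_frame().iterrows():
            if r["failure"]:
                lines.append(f"  {r['stratum']}: failed ({r['failure']})")
            else:
                lines.append(
                    f"  {r['stratum']}: e={r['e']:.1f} (95% CI, {r['ci_low']:.1f} to {r['ci_high']:.1f})"
                )
    if trend is not None:
        lines += ["", "period trend (by diagnosis period):"]
        for _, r in trend.summary_frame().iterrows():
            if r["failure"]:
                lines.append(f"  {r['stratum']}: failed ({r['failure']})")
            else:
                lines.append(
                    f"  {r['stratum']}: e={r['e']:.1f} (95% CI, {r['ci_low']:.1f} to {r['ci_high']:.1f})"
                )
    report_text = "\n".join(lines) + "\n"
    f = outdir / "report.txt"
    f.write_text(report_text)
    files.append(f)

    f = outdir / "resolved_config.yaml"
    config.to_yaml(f)
    files.append(f)

    result.report_text = report_text
    result.output_files = files
    return result
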