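"""Stratified life tables, group comparisons, period trends, YLL, correlations.

Strata are defined by time-fixed attributes recorded at diagnosis (sex,
treatment ever received, baseline biomarker band, period of diagnosis, ...);
missing covariate values form their own ``"unknown"`` stratum so strata
always partition the cohort.  Group contrasts use a two-sample z-test on the
independent, asymptotically normal Chiang estimates.  Years of life lost
weight each death by a reference remaining life expectancy at the age band
of death; the bundled default reference is the Iranian general-population
table for 2015.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import AgeBandSchema, DEFAULT_SCHEMA
from .cohort_io import Cohort
from .errors import LifeTableError
from .exposure import ExposureTable, aggregate_exposure
from .lifetable import LifeTable, build_life_table

__all__ = [
    "IRAN_GENERAL_2015",
    "StratifiedResult",
    "ComparisonResult",
    "stratified_life_tables",
    "compare_life_expectancy",
    "compare_from_summaries",
    "period_trend",
    "years_of_life_lost",
    "ecological_correlation",
]

#: Remaining life expectancy of the Iranian general population (2015) by
#: 5-year band from age 20 (20-24 ... 60-64, 65+) — the bundled default
#: reference for years-of-life-lost tallies.
IRAN_GENERAL_2015 = (56.1, 51.5, 46.8, 42.1, 37.3, 32.6, 28.0, 23.6, 19.3, 15.2)

UNKNOWN_LABEL = "unknown"


@dataclass
class StratifiedResult:
    """Life tables per stratum of one covariate, plus pooled totals.

    Strata whose exposure cannot support a life table (e.g. no deaths in the
    open band) are reported in ``failures`` with the reason, never silently
    dropped.
    """

    variable: str
    tables: dict[str, LifeTable] = field(default_factory=dict)
    exposures: dict[str, ExposureTable] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    pooled_exposure: Optional[ExposureTable] = None

    @property
    def labels(self) -> list[str]:
        return list(self.exposures)

    def summary_frame(self, at_band: int = 0) -> pd.DataFrame:
        """One row per stratum: exposure totals and e/SE/CI at ``at_band``."""
        rows = []
        for label, exp in self.exposures.items():
            row = {
                "stratum": label,
                "deaths": exp.total_deaths,
                "person_years": exp.total_person_years,
                "e": np.nan,
                "se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "failure": self.failures.get(label, ""),
            }
            lt = self.tables.get(label)
            if lt is not None:
                row.update(
                    e=lt.e[at_band],
                    se=lt.se_e[at_band],
                    ci_low=lt.ci_low[at_band],
                    ci_high=lt.ci_high[at_band],
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _stratify(
    cohort: Cohort,
    labels: pd.Series,
    variable: str,
    schema: AgeBandSchema,
    radix: float,
    terminal_e_fixed: Optional[float],
    order: Optional[Sequence[str]] = None,
) -> StratifiedResult:
    result = StratifiedResult(variable=variable)
    result.pooled_exposure = aggregate_exposure(cohort, schema)
    seen = list(order) if order is not None else sorted(labels.unique())
    for label in seen:
        sub = cohort.data.loc[labels == label]
        exp = aggregate_exposure(sub, schema, group_label=str(label))
        result.exposures[str(label)] = exp
        if len(sub) == 0:
            result.failures[str(label)] = "empty stratum"
            continue
        try:
            result.tables[str(label)] = build_life_table(
                exp, radix=radix, terminal_e_fixed=terminal_e_fixed
            )
        except LifeTableError as err:
            result.failures[str(label)] = str(err)
    if not result.tables:
        raise LifeTableError(
            f"no stratum of {variable!r} supports a life table: {result.failures}"
        )
    return result


def stratified_life_tables(
    cohort: Cohort,
    by: str,
    schema: AgeBandSchema = DEFAULT_SCHEMA,
    radix: float = 100_000.0,
    terminal_e_fixed: Optional[float] = None,
) -> StratifiedResult:
    """One life table per level of covariate ``by`` (missing -> "unknown")."""
    if by not in cohort.data.columns:
        raise KeyError(f"covariate {by!r} not in cohort columns")
    labels = cohort.data[by].astype(object).where(cohort.data[by].notna(), UNKNOWN_LABEL)
    labels = labels.astype(str)
    return _stratify(cohort, labels, by, schema, radix, terminal_e_fixed)


class ComparisonResult(NamedTuple):
    """Two-sample z contrast of life expectancy at one reference band."""

    label1: str
    label2: str
    at_band: int
    e1: float
    e2: float
    se1: float
    se2: float

    @property
    def diff(self) -> float:
        return self.e1 - self.e2

    @property
    def se_diff(self) -> float:
        return float(np.sqrt(self.se1**2 + self.se2**2))

    @property
    def z(self) -> float:
        if self.se_diff == 0:
            return 0.0 if self.diff == 0 else float(np.sign(self.diff) * np.inf)
        return self.diff / self.se_diff

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def compare_life_expectancy(
    lt1: LifeTable, lt2: LifeTable, at_band: int = 0
) -> ComparisonResult:
    """z-test of ``e1 - e2`` at one band, treating the estimates as independent."""
    if lt1.schema != lt2.schema:
        raise ValueError("life tables must share the same age-band schema")
    return ComparisonResult(
        label1=lt1.group_label or "group1",
        label2=lt2.group_label or "group2",
        at_band=at_band,
        e1=float(lt1.e[at_band]),
        e2=float(lt2.e[at_band]),
        se1=float(lt1.se_e[at_band]),
        se2=float(lt2.se_e[at_band]),
    )


def compare_from_summaries(
    e1: float,
    ci1: tuple[float, float],
    e2: float,
    ci2: tuple[float, float],
    z_level: float = 1.96,
) -> ComparisonResult:
    """Contrast two published estimates given only their confidence intervals.

    The standard errors are recovered from the CI half-widths as
    ``(hi - lo) / (2·z_level)``.
    """
    se1 = (ci1[1] - ci1[0]) / (2.0 * z_level)
    se2 = (ci2[1] - ci2[0]) / (2.0 * z_level)
    if se1 < 0 or se2 < 0:
        raise ValueError("confidence bounds out of order")
    return ComparisonResult("summary1", "summary2", 0, e1, e2, se1, se2)


def period_trend(
    cohort: Cohort,
    period_breaks: Sequence[int],
    schema: AgeBandSchema = DEFAULT_SCHEMA,
    radix: float = 100_000.0,
    terminal_e_fixed: Optional[float] = None,
) -> StratifiedResult:
    """Life tables by calendar period of diagnosis.

    ``period_breaks`` are ordered calendar years; period ``i`` covers
    diagnosis years ``[breaks[i], breaks[i+1])``.  Records outside the breaks
    fall into an ``"outside_breaks"`` stratum (reported, typically failed).
    """
    breaks = list(period_breaks)
    if breaks != sorted(breaks) or len(breaks) < 2:
        raise ValueError("period_breaks must be >= 2 ordered calendar years")
    years = cohort.data["date_of_diagnosis"].dt.year
    labels = pd.Series("outside_breaks", index=cohort.data.index, dtype=object)
    order = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        lab = f"{lo}-{hi - 1}"
        order.append(lab)
        labels[(years >= lo) & (years < hi)] = lab
    if (labels == "outside_breaks").any():
        order.append("outside_breaks")
    return _stratify(cohort, labels, "period", schema, radix, terminal_e_fixed, order=order)


def years_of_life_lost(
    cohort: Cohort,
    reference_e: Sequence[float] | Mapping[float, float] = IRAN_GENERAL_2015,
    schema: AgeBandSchema = DEFAULT_SCHEMA,
) -> float:
    """Total years of life lost: each death weighted by the reference
    remaining life expectancy at its age band.

    ``reference_e`` is either one value per band (aligned with the schema) or
    a mapping ``band start -> remaining e``; a death in a band absent from
    the mapping is an error.
    """
    if isinstance(reference_e, Mapping):
        ref = np.full(len(schema), np.nan)
        for start, value in reference_e.items():
            ref[schema.index_of(float(start))] = value
    else:
        ref = np.asarray(reference_e, dtype=float)
        if len(ref) != len(schema):
            raise ValueError(
                f"reference_e: need one value per band ({len(schema)}), got {len(ref)}"
            )
    df = cohort.data
    died = df["status"] == "died"
    if not died.any():
        return 0.0
    exp = aggregate_exposure(cohort, schema)
    deaths = exp.deaths
    covered = deaths > 0
    if np.any(covered & np.isnan(ref)):
        missing = [schema.bands[j].label for j in np.flatnonzero(covered & np.isnan(ref))]
        raise ValueError(f"reference table has no value for bands with deaths: {missing}")
    return float(np.nansum(deaths * np.where(np.isnan(ref), 0.0, ref)))


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def ecological_correlation(
    group_values: Sequence[float], covariate_values: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation across group-level aggregates (e.g. provinces)."""
    x = np.asarray(group_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("group_values and covariate_values must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 paired groups")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))
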