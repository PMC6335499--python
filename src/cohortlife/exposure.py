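"""Lexis expansion: split follow-up time across age bands and aggregate.

Each subject enters observation at their age at diagnosis (left truncation)
and exits at death, loss to follow-up, or the administrative study end.  The
follow-up interval ``[entry_age, exit_age)`` is intersected with the age
bands; deaths are assigned to the band containing the exact exit age.  The
per-band deaths ``D_j`` and person-years ``PY_j`` are the sufficient
statistics for the whole life-table analysis.

Conventions
-----------
* Ages are exact real years; calendar durations are converted with
  days / 365.2425.  No integer-age rounding.
* Bands are half-open ``[start, start + n)``: a death at exactly age 25.0
  belongs to the 25-29 band.
* A censored record with zero-length follow-up contributes zero person-years
  and is retained with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bands import AgeBandSchema, DEFAULT_SCHEMA
from .cohort_io import DAYS_PER_YEAR, Cohort, PersonRecord

__all__ = [
    "ExposureTable",
    "split_person_years",
    "aggregate_exposure",
    "crude_mortality_rate",
]


@dataclass
class ExposureTable:
    """Deaths and person-years per age band, optionally for one stratum."""

    schema: AgeBandSchema
    deaths: np.ndarray
    person_years: np.ndarray
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        w = len(self.schema)
        if self.deaths.shape != (w,) or self.person_years.shape != (w,):
            raise ValueError(
                f"deaths/person_years must have one entry per band ({w})"
            )
        if np.any(self.deaths < 0) or np.any(self.person_years < 0):
            raise ValueError("deaths and person-years must be non-negative")

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    def __add__(self, other: "ExposureTable") -> "ExposureTable":
        if other.schema != self.schema:
            raise ValueError("cannot add exposure tables with different schemas")
        return ExposureTable(
            schema=self.schema,
            deaths=self.deaths + other.deaths,
            person_years=self.person_years + other.person_years,
        )

    def to_frame(self) -> pd.DataFrame:
        widths = self.schema.widths
        return pd.DataFrame(
            {
                "band": self.schema.labels,
                "band_start": self.schema.starts,
                "band_width": np.where(np.isinf(widths), np.nan, widths),
                "a": self.schema.a_values,
                "deaths": self.deaths,
                "person_years": self.person_years,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_frame().to_json(orient="records", indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _split_ages(
    entry: np.ndarray, exit_: np.ndarray, schema: AgeBandSchema
) -> np.ndarray:
    """Person-years per band for arrays of entry/exit ages; shape (n, w)."""
    starts = schema.starts
    ends = starts + schema.widths  # inf for terminal band
    lo = np.maximum(entry[:, None], starts[None, :])
    hi = np.minimum(exit_[:, None], ends[None, :])
    return np.clip(hi - lo, 0.0, None)


def split_person_years(
    record: PersonRecord, schema: AgeBandSchema = DEFAULT_SCHEMA
) -> tuple[np.ndarray, Optional[int]]:
    """Allot one record's follow-up to age bands.

    Returns the per-band person-years (their sum equals
    ``exit_age - entry_age`` exactly) and, if the subject died, the index of
    the band containing the exact age at death, else ``None``.
    """
    entry = record.entry_age
    exit_age = record.exit_age
    if not np.isfinite(entry) or not np.isfinite(exit_age):
        raise ValueError(f"record {record.person_id}: entry/exit age undefined")
    if entry < schema.min_age:
        raise ValueError(
            f"record {record.person_id}: entry age {entry:.2f} below schema start "
            f"{schema.min_age:g} (should have been filtered)"
        )
    if exit_age < entry:
        raise ValueError(
            f"record {record.person_id}: exit age {exit_age:.2f} < entry age {entry:.2f}"
        )
    if exit_age == entry and not record.died:
        warnings.warn(
            f"record {record.person_id}: zero-length follow-up contributes 0 person-years",
            stacklevel=2,
        )
    py = _split_ages(np.array([entry]), np.array([exit_age]), schema)[0]
    death_band = schema.index_of(exit_age) if record.died else None
    return py, death_band


def aggregate_exposure(
    cohort: Cohort | pd.DataFrame,
    schema: AgeBandSchema = DEFAULT_SCHEMA,
    group_label: Optional[str] = None,
) -> ExposureTable:
    """Sum deaths and person-years over a cohort, band by band (vectorised).

    Requires eligible, complete records (non-missing age, dates).  An empty
    cohort yields an all-zero table.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    w = len(schema)
    if len(df) == 0:
        return ExposureTable(schema, np.zeros(w), np.zeros(w), group_label)

    entry = df["age_at_diagnosis"].to_numpy(dtype=float)
    dur = (df["exit_date"] - df["date_of_diagnosis"]).dt.days.to_numpy(dtype=float)
    dur /= DAYS_PER_YEAR
    if np.any(~np.isfinite(entry)) or np.any(~np.isfinite(dur)):
        raise ValueError("aggregate_exposure needs complete ages and dates; impute/filter first")
    if np.any(dur < 0):
        raise ValueError("negative follow-up duration; filter_eligible first")
    if np.any(entry < schema.min_age):
        raise ValueError(
            f"entry age below schema start {schema.min_age:g}; filter_eligible first"
        )
    exit_age = entry + dur

    died = (df["status"] == "died").to_numpy(dtype=bool)
    n_zero = int(((dur == 0) & ~died).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} censored records with zero-length follow-up contribute 0 person-years",
            stacklevel=2,
        )

    py = _split_ages(entry, exit_age, schema).sum(axis=0)
    deaths = np.zeros(w)
    if died.any():
        bands = schema.index_of(exit_age[died])
        deaths = np.bincount(bands, minlength=w).astype(float)
    return ExposureTable(schema, deaths, py, group_label)


def crude_mortality_rate(exposure: ExposureTable, per: float = 1000.0) -> float:
    """Total deaths over total person-years, scaled ``per`` person-years."""
    total_py = exposure.total_person_years
    if total_py <= 0:
        raise ValueError("crude mortality rate undefined: zero total person-years")
    return per * exposure.total_deaths / total_py
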