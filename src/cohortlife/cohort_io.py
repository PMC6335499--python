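"""Reading, validating, filtering and imputing individual-level cohort records.

The canonical on-disk format is a UTF-8 CSV with one row per person and
columns ``person_id, sex, date_of_diagnosis, birth_date (optional),
age_at_diagnosis, exit_date, status`` plus any number of free covariate
columns (treatment, co-infection, region, ...).  Dates are ISO-8601
(``YYYY-MM-DD``); other headers can be mapped onto the canonical names via a
column-mapping dict or YAML file, but no other date dialect is accepted —
day/month ambiguity is not worth silent tolerance.

Follow-up runs from diagnosis to ``exit_date`` (death, loss to follow-up, or
administrative study end); subjects are left-truncated at their entry age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CohortError

__all__ = [
    "STATUSES",
    "PersonRecord",
    "Cohort",
    "ExclusionReport",
    "load_cohort",
    "filter_eligible",
    "impute_missing",
]

DAYS_PER_YEAR = 365.2425

STATUSES = ("died", "censored", "alive_at_study_end")
SEXES = ("male", "female")

#: canonical column names; age_at_diagnosis may be derived from birth_date
REQUIRED_COLUMNS = ("person_id", "sex", "date_of_diagnosis", "exit_date", "status")
CANONICAL_COLUMNS = REQUIRED_COLUMNS + ("birth_date", "age_at_diagnosis")

#: exclusion reasons in precedence order: the first reason a record trips is
#: reported as its primary reason.
EXCLUSION_REASONS = (
    "missing_diagnosis_date",
    "diagnosis_not_before_death",
    "under_age_minimum",
    "malformed_record",
)


@dataclass(frozen=True)
class PersonRecord:
    """One subject's follow-up interval, vital status, and covariates."""

    person_id: str
    sex: str | None
    date_of_diagnosis: pd.Timestamp | None
    age_at_diagnosis: float
    exit_date: pd.Timestamp | None
    status: str
    covariates: Mapping[str, object] = field(default_factory=dict)

    @property
    def died(self) -> bool:
        return self.status == "died"

    @property
    def follow_up_years(self) -> float:
        if self.date_of_diagnosis is None or self.exit_date is None:
            return float("nan")
        return (self.exit_date - self.date_of_diagnosis).days / DAYS_PER_YEAR

    @property
    def entry_age(self) -> float:
        return self.age_at_diagnosis

    @property
    def exit_age(self) -> float:
        return self.entry_age + self.follow_up_years


@dataclass
class Cohort:
    """An ordered collection of person records plus audit provenance.

    ``data`` holds one row per person in canonical columns; extra columns are
    covariates.  ``study_end`` is the administrative censoring date.
    """

    data: pd.DataFrame
    study_end: pd.Timestamp
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.data["person_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate person_id: {dup!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in CANONICAL_COLUMNS]

    def records(self) -> Iterator[PersonRecord]:
        cov_cols = self.covariate_columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield PersonRecord(
                person_id=d["person_id"],
                sex=d["sex"] if isinstance(d["sex"], str) else None,
                date_of_diagnosis=None if pd.isna(d["date_of_diagnosis"]) else d["date_of_diagnosis"],
                age_at_diagnosis=float(d["age_at_diagnosis"]) if not pd.isna(d["age_at_diagnosis"]) else float("nan"),
                exit_date=None if pd.isna(d["exit_date"]) else d["exit_date"],
                status=d["status"],
                covariates={c: d[c] for c in cov_cols},
            )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def replace(self, data: pd.DataFrame, note: str | None = None) -> "Cohort":
        out = Cohort(data=data, study_end=self.study_end, provenance=list(self.provenance))
        if note:
            out.log(note)
        return out


@dataclass
class ExclusionReport:
    """Audit of records removed by eligibility filtering.

    ``counts`` tallies every reason each excluded record tripped, so the sum
    of counts can exceed the number of excluded ids; ``excluded`` maps each
    removed id to its single primary reason (first in precedence order).
    """

    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS})
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def excluded_ids(self) -> list[str]:
        return list(self.excluded)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"counts": self.counts, "excluded": self.excluded, "n_excluded": self.n_excluded},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _read_column_map(column_map: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        loaded = yaml.safe_load(Path(column_map).read_text())
        if not isinstance(loaded, dict):
            raise CohortError(f"column map {column_map} must be a YAML mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    return dict(column_map)


def load_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
    study_end: str | pd.Timestamp | None = None,
) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    column_map:
        Optional mapping ``canonical_name -> file column name`` (dict or YAML
        file) for files whose headers differ from the canonical schema.
    study_end:
        Administrative censoring date; defaults to the latest exit date seen.

    Unparseable dates, ages and sex codes become missing values and are
    logged in provenance; an unknown ``status`` code is fatal because it
    changes the meaning of the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    if len(raw) == 0:
        raise CohortError(f"zero data rows in {path}")

    cmap = _read_column_map(column_map)
    rename = {v: k for k, v in cmap.items()}
    raw = raw.rename(columns=rename)

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortError(f"missing mandatory columns: {missing_cols}")
    if "age_at_diagnosis" not in raw.columns and "birth_date" not in raw.columns:
        raise CohortError("need either age_at_diagnosis or birth_date column")

    df = raw.copy()
    notes: list[str] = []

    for col in ("date_of_diagnosis", "exit_date", "birth_date"):
        if col not in df.columns:
            continue
        cell = df[col].astype("string").str.strip()
        parsed = pd.to_datetime(cell, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & cell.notna() & (cell != "")
        if bad.any():
            notes.append(f"{int(bad.sum())} unparseable {col} values set to missing")
        df[col] = parsed

    if "age_at_diagnosis" in df.columns:
        age = pd.to_numeric(df["age_at_diagnosis"], errors="coerce")
        bad = age.isna() & df["age_at_diagnosis"].notna()
        if bad.any():
            notes.append(f"{int(bad.sum())} unparseable age_at_diagnosis values set to missing")
        df["age_at_diagnosis"] = age.astype(float)
    else:
        df["age_at_diagnosis"] = np.nan
    if "birth_date" in df.columns:
        derivable = df["age_at_diagnosis"].isna() & df["birth_date"].notna() & df["date_of_diagnosis"].notna()
        if derivable.any():
            delta = (df.loc[derivable, "date_of_diagnosis"] - df.loc[derivable, "birth_date"]).dt.days
            df.loc[derivable, "age_at_diagnosis"] = delta / DAYS_PER_YEAR
            notes.append(f"{int(derivable.sum())} ages derived from birth_date")

    status = df["status"].astype("string").str.strip().str.lower()
    bad_status = ~status.isin(STATUSES)
    if bad_status.any():
        row = int(np.flatnonzero(bad_status.to_numpy())[0])
        raise CohortError(
            f"unknown status code {df['status'].iloc[row]!r} at data row {row + 1}"
        )
    df["status"] = status.astype(object)

    sex = df["sex"].astype("string").str.strip().str.lower()
    df["sex"] = sex.where(sex.isin(SEXES), other=pd.NA).astype(object)
    n_bad_sex = int((~sex.isin(SEXES) & sex.notna() & (sex != "")).sum())
    if n_bad_sex:
        notes.append(f"{n_bad_sex} unrecognized sex codes set to missing")

    df["person_id"] = df["person_id"].astype(str)

    if study_end is None:
        end = df["exit_date"].max()
        if pd.isna(end):
            raise CohortError("cannot infer study_end: no parseable exit dates")
    else:
        end = pd.Timestamp(study_end)

    cohort = Cohort(data=df.reset_index(drop=True), study_end=end)
    cohort.log(f"loaded {len(df)} records from {path}")
    for n in notes:
        cohort.log(n)
    return cohort


def _exclusion_reasons(df: pd.DataFrame, min_age: float) -> dict[str, pd.Series]:
    """Boolean mask per exclusion reason, evaluated independently."""
    diag = df["date_of_diagnosis"]
    exit_ = df["exit_date"]
    age = df["age_at_diagnosis"]
    died = df["status"] == "died"

    missing_diag = diag.isna()
    diag_not_before_death = died & diag.notna() & exit_.notna() & (diag >= exit_)
    under_age = age.notna() & (age < min_age)
    malformed = (
        exit_.isna()
        | age.isna()
        | (age >= 120)
        | (age < 0)
        | (~died & diag.notna() & exit_.notna() & (exit_ < diag))
    )
    return {
        "missing_diagnosis_date": missing_diag,
        "diagnosis_not_before_death": diag_not_before_death,
        "under_age_minimum": under_age,
        "malformed_record": malformed,
    }


def filter_eligible(cohort: Cohort, min_age: float = 20.0) -> tuple[Cohort, ExclusionReport]:
    """Drop records that cannot enter the life-table analysis.

    Retained records have a diagnosis date strictly before the death date (for
    deaths), a known age at diagnosis of at least ``min_age``, and well-formed
    dates.  Censored records with zero-length follow-up are retained (they
    contribute zero person-years downstream).  The report accounts for every
    removed record, with the primary reason chosen by the fixed precedence
    order ``missing_diagnosis_date > diagnosis_not_before_death >
    under_age_minimum > malformed_record``.
    """
    df = cohort.data
    masks = _exclusion_reasons(df, min_age)
    report = ExclusionReport()

    any_reason = np.zeros(len(df), dtype=bool)
    primary = np.full(len(df), "", dtype=object)
    for reason in EXCLUSION_REASONS:
        m = masks[reason].to_numpy(dtype=bool)
        report.counts[reason] = int(m.sum())
        newly = m & ~any_reason
        primary[newly] = reason
        any_reason |= m

    ids = df["person_id"].to_numpy()
    for i in np.flatnonzero(any_reason):
        report.excluded[str(ids[i])] = str(primary[i])

    kept = df.loc[~any_reason].reset_index(drop=True)
    out = cohort.replace(
        kept,
        note=(
            f"filtered: kept {len(kept)} of {len(df)} "
            f"(excluded {int(any_reason.sum())}, min_age={min_age})"
        ),
    )
    return out, report


def _missing_fraction(series: pd.Series) -> float:
    return float(series.isna().mean()) if len(series) else 0.0


def impute_missing(
    cohort: Cohort,
    seed: int,
    max_missing_fraction: float = 0.10,
    route_column: str = "transmission",
) -> Cohort:
    """Fill missing sex and age by seeded single hot-deck imputation.

    Missing sex is drawn from the empirical sex distribution of complete
    records in the same ``route_column`` category (falling back to the whole
    cohort); missing age is drawn from the empirical age distribution within
    the same (possibly just-imputed) sex.  The draw is fully determined by
    ``seed``.  If either variable is missing in more than
    ``max_missing_fraction`` of records the imputation refuses to run —
    single imputation is only defensible for modest missingness.
    """
    df = cohort.data.copy()
    frac_sex = _missing_fraction(df["sex"])
    frac_age = _missing_fraction(df["age_at_diagnosis"])
    for name, frac in (("sex", frac_sex), ("age_at_diagnosis", frac_age)):
        if frac > max_missing_fraction:
            raise CohortError(
                f"missing fraction of {name} is {frac:.3f} > {max_missing_fraction:g}; "
                "hot-deck imputation refused"
            )
    if frac_sex == 0.0 and frac_age == 0.0:
        return cohort.replace(df, note=f"imputation: nothing missing (seed={seed})")

    rng = np.random.default_rng(seed)
    n_sex = n_age = 0

    sex_missing = df.index[df["sex"].isna()]
    if len(sex_missing):
        have_route = route_column in df.columns
        observed = df["sex"].dropna()
        for i in sex_missing:
            pool = observed
            if have_route and not pd.isna(df.at[i, route_column]):
                same_route = df.loc[df[route_column] == df.at[i, route_column], "sex"].dropna()
                if len(same_route):
                    pool = same_route
            df.at[i, "sex"] = pool.iloc[rng.integers(len(pool))]
            n_sex += 1

    age_missing = df.index[df["age_at_diagnosis"].isna()]
    if len(age_missing):
        observed_age = df["age_at_diagnosis"].dropna()
        for i in age_missing:
            pool = observed_age
            same_sex = df.loc[df["sex"] == df.at[i, "sex"], "age_at_diagnosis"].dropna()
            if len(same_sex):
                pool = same_sex
            df.at[i, "age_at_diagnosis"] = pool.iloc[rng.integers(len(pool))]
            n_age += 1

    return cohort.replace(
        df,
        note=f"imputed {n_sex} sex and {n_age} age values (hot-deck, seed={seed})",
    )
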