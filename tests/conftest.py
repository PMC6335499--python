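"""Shared fixtures: tiny in-memory cohorts and CSV writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortlife import Cohort, PersonRecord
from cohortlife.cohort_io import DAYS_PER_YEAR


def make_record(
    entry_age: float,
    follow_up_years: float,
    status: str = "censored",
    person_id: str = "P0",
    sex: str = "male",
    diagnosis: str = "2000-01-01",
    **covariates,
) -> PersonRecord:
    """Record whose exit date realises ~follow_up_years (day-rounded)."""
    diag = pd.Timestamp(diagnosis)
    exit_date = diag + pd.Timedelta(days=round(follow_up_years * DAYS_PER_YEAR))
    return PersonRecord(
        person_id=person_id,
        sex=sex,
        date_of_diagnosis=diag,
        age_at_diagnosis=entry_age,
        exit_date=exit_date,
        status=status,
        covariates=covariates,
    )


def make_cohort(rows: list[dict], study_end: str = "2020-12-31") -> Cohort:
    """Cohort from plain dicts; dates given as ISO strings."""
    df = pd.DataFrame(rows)
    for col in ("date_of_diagnosis", "exit_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    if "person_id" not in df:
        df.insert(0, "person_id", [f"P{i}" for i in range(len(df))])
    if "sex" not in df:
        df["sex"] = "male"
    df["age_at_diagnosis"] = df["age_at_diagnosis"].astype(float)
    return Cohort(data=df, study_end=pd.Timestamp(study_end))


@pytest.fixture
def csv_writer(tmp_path):
    """Write a cohort CSV from a header and rows of strings."""

    def _write(rows: list[dict], name: str = "cohort.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def three_row_csv(csv_writer):
    rows = [
        dict(person_id="A", sex="male", date_of_diagnosis="2001-05-20",
             age_at_diagnosis="34.2", exit_date="2007-08-01", status="died",
             transmission="idu", art="no"),
        dict(person_id="B", sex="female", date_of_diagnosis="2010-01-01",
             age_at_diagnosis="28.0", exit_date="2016-12-30", status="alive_at_study_end",
             transmission="sexual", art="yes"),
        dict(person_id="C", sex="male", date_of_diagnosis="1995-03-10",
             age_at_diagnosis="41.7", exit_date="1999-01-15", status="censored",
             transmission="idu", art="no"),
    ]
    return csv_writer(rows)
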