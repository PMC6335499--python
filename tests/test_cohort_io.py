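"""Loading, eligibility filtering and hot-deck imputation of cohort records."""

import numpy as np
import pandas as pd
import pytest
import yaml

from cohortlife import (
    Cohort,
    CohortError,
    filter_eligible,
    impute_missing,
    load_cohort,
)

from conftest import make_cohort


class TestLoadCohort:
    def test_well_formed_rows_parse_directly(self, three_row_csv):
        cohort = load_cohort(three_row_csv)
        assert len(cohort) == 3
        assert cohort.data["age_at_diagnosis"].tolist() == [34.2, 28.0, 41.7]
        assert set(cohort.covariate_columns) == {"transmission", "art"}
        assert any("3 records" in p for p in cohort.provenance)

    def test_empty_diagnosis_date_cell_becomes_missing(self, csv_writer):
        path = csv_writer([
            dict(person_id="A", sex="male", date_of_diagnosis="",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="died"),
            dict(person_id="B", sex="male", date_of_diagnosis="2001-01-01",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="died"),
        ])
        cohort = load_cohort(path)
        assert pd.isna(cohort.data.loc[0, "date_of_diagnosis"])
        assert not pd.isna(cohort.data.loc[1, "date_of_diagnosis"])

    def test_unparseable_date_logged_and_missing(self, csv_writer):
        path = csv_writer([
            dict(person_id="A", sex="male", date_of_diagnosis="20/05/2001",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="died"),
        ])
        cohort = load_cohort(path)
        assert pd.isna(cohort.data.loc[0, "date_of_diagnosis"])
        assert any("unparseable date_of_diagnosis" in p for p in cohort.provenance)

    def test_header_only_file_is_fatal(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("person_id,sex,date_of_diagnosis,age_at_diagnosis,exit_date,status\n")
        with pytest.raises(CohortError, match="zero data rows"):
            load_cohort(path)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            load_cohort(tmp_path / "nope.csv")

    def test_unknown_status_fatal_with_row_number(self, csv_writer):
        path = csv_writer([
            dict(person_id="A", sex="male", date_of_diagnosis="2001-01-01",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="died"),
            dict(person_id="B", sex="male", date_of_diagnosis="2001-01-01",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="dead??"),
        ])
        with pytest.raises(CohortError, match="row 2"):
            load_cohort(path)

    def test_duplicate_person_id_fatal(self, csv_writer):
        path = csv_writer([
            dict(person_id="A", sex="male", date_of_diagnosis="2001-01-01",
                 age_at_diagnosis="30", exit_date="2005-01-01", status="died"),
            dict(person_id="A", sex="male", date_of_diagnosis="2002-01-01",
                 age_at_diagnosis="31", exit_date="2006-01-01", status="died"),
        ])
        with pytest.raises(CohortError, match="duplicate person_id"):
            load_cohort(path)

    def test_column_mapping_via_yaml(self, tmp_path, csv_writer):
        path = csv_writer([
            dict(id="A", gender="female", dx_date="2001-01-01",
                 dx_age="30", end_date="2005-01-01", outcome="censored"),
        ])
        cmap = tmp_path / "map.yaml"
        cmap.write_text(yaml.safe_dump({
            "person_id": "id", "sex": "gender", "date_of_diagnosis": "dx_date",
            "age_at_diagnosis": "dx_age", "exit_date": "end_date", "status": "outcome",
        }))
        cohort = load_cohort(path, column_map=cmap)
        assert cohort.data.loc[0, "sex"] == "female"

    def test_age_derived_from_birth_date(self, csv_writer):
        path = csv_writer([
            dict(person_id="A", sex="male", date_of_diagnosis="2000-01-01",
                 birth_date="1970-01-01", exit_date="2005-01-01", status="died"),
        ])
        cohort = load_cohort(path)
        assert cohort.data.loc[0, "age_at_diagnosis"] == pytest.approx(30.0, abs=0.02)


class TestFilterEligible:
    def _base(self, **overrides):
        row = dict(person_id="A", sex="male", date_of_diagnosis="2001-01-01",
                   age_at_diagnosis=30.0, exit_date="2005-01-01", status="died")
        row.update(overrides)
        return row

    def test_diagnosis_coinciding_with_death_excluded(self):
        cohort = make_cohort([
            self._base(person_id="A", date_of_diagnosis="2005-01-01"),
            self._base(person_id="B"),
        ])
        kept, report = filter_eligible(cohort)
        assert report.excluded == {"A": "diagnosis_not_before_death"}
        assert len(kept) == 1

    def test_diagnosis_after_death_excluded(self):
        cohort = make_cohort([self._base(date_of_diagnosis="2006-01-01")])
        kept, report = filter_eligible(cohort)
        assert report.excluded["A"] == "diagnosis_not_before_death"

    def test_under_age_minimum_excluded(self):
        cohort = make_cohort([self._base(age_at_diagnosis=19.4)])
        kept, report = filter_eligible(cohort)
        assert report.excluded["A"] == "under_age_minimum"
        assert len(kept) == 0

    def test_all_valid_cohort_unchanged_with_empty_report(self):
        cohort = make_cohort([self._base(), self._base(person_id="B", status="censored")])
        kept, report = filter_eligible(cohort)
        assert len(kept) == 2
        assert report.n_excluded == 0
        assert all(v == 0 for v in report.counts.values())

    def test_precedence_missing_diagnosis_wins(self):
        # trips both missing date and under-age: primary reason is the first
        cohort = make_cohort([self._base(date_of_diagnosis=None, age_at_diagnosis=10.0)])
        kept, report = filter_eligible(cohort)
        assert report.excluded["A"] == "missing_diagnosis_date"
        assert report.counts["under_age_minimum"] == 1  # still tallied
        assert sum(report.counts.values()) >= report.n_excluded

    def test_missing_age_is_malformed(self):
        cohort = make_cohort([self._base(age_at_diagnosis=np.nan)])
        _, report = filter_eligible(cohort)
        assert report.excluded["A"] == "malformed_record"

    def test_zero_length_censored_record_retained(self):
        cohort = make_cohort([
            self._base(status="censored", exit_date="2001-01-01"),
        ])
        kept, report = filter_eligible(cohort)
        assert len(kept) == 1

    def test_idempotent_and_conserves_records(self):
        cohort = make_cohort([
            self._base(),
            self._base(person_id="B", age_at_diagnosis=18.0),
            self._base(person_id="C", date_of_diagnosis=None),
        ])
        kept, report = filter_eligible(cohort)
        assert len(cohort) == len(kept) + report.n_excluded
        again, report2 = filter_eligible(kept)
        assert report2.n_excluded == 0
        pd.testing.assert_frame_equal(again.data, kept.data)

    def test_report_round_trips_to_json(self, tmp_path):
        cohort = make_cohort([self._base(age_at_diagnosis=12.0)])
        _, report = filter_eligible(cohort)
        payload = report.to_json(tmp_path / "r.json")
        assert "under_age_minimum" in payload
        assert (tmp_path / "r.json").exists()


class TestImputeMissing:
    def _cohort(self, n=40, missing_sex=0, missing_age=0):
        rows = []
        for i in range(n):
            rows.append(dict(
                person_id=f"P{i}",
                sex=None if i < missing_sex else ("male" if i % 3 else "female"),
                date_of_diagnosis="2001-01-01",
                age_at_diagnosis=np.nan if missing_sex <= i < missing_sex + missing_age
                else 25.0 + i % 20,
                exit_date="2010-01-01",
                status="censored",
                transmission="idu" if i % 2 else "sexual",
            ))
        return make_cohort(rows)

    def test_identical_seed_gives_identical_assignments(self):
        c = self._cohort(missing_sex=2, missing_age=2)
        out1 = impute_missing(c, seed=7)
        out2 = impute_missing(c, seed=7)
        pd.testing.assert_frame_equal(out1.data, out2.data)

    def test_completes_all_missing_values(self):
        out = impute_missing(self._cohort(missing_sex=3, missing_age=3), seed=1)
        assert out.data["sex"].notna().all()
        assert out.data["age_at_diagnosis"].notna().all()

    def test_never_alters_non_missing_fields(self):
        c = self._cohort(missing_sex=2, missing_age=2)
        out = impute_missing(c, seed=3)
        obs = c.data["sex"].notna()
        assert (out.data.loc[obs, "sex"] == c.data.loc[obs, "sex"]).all()
        obs_age = c.data["age_at_diagnosis"].notna()
        assert np.array_equal(
            out.data.loc[obs_age, "age_at_diagnosis"], c.data.loc[obs_age, "age_at_diagnosis"]
        )

    def test_no_missing_values_returns_cohort_unchanged(self):
        c = self._cohort()
        out = impute_missing(c, seed=5)
        pd.testing.assert_frame_equal(out.data, c.data)

    def test_excess_missingness_aborts_with_measured_fraction(self):
        c = self._cohort(n=50, missing_age=6)  # 12% missing age
        with pytest.raises(CohortError, match=r"0\.12"):
            impute_missing(c, seed=1)

    def test_hot_deck_draws_from_route_stratum(self):
        # all observed sex in route "sexual" is female -> imputed sex must be female
        rows = [dict(person_id=f"F{i}", sex="female", date_of_diagnosis="2001-01-01",
                     age_at_diagnosis=30.0, exit_date="2010-01-01", status="censored",
                     transmission="sexual") for i in range(10)]
        rows += [dict(person_id=f"M{i}", sex="male", date_of_diagnosis="2001-01-01",
                      age_at_diagnosis=30.0, exit_date="2010-01-01", status="censored",
                      transmission="idu") for i in range(10)]
        rows.append(dict(person_id="X", sex=None, date_of_diagnosis="2001-01-01",
                         age_at_diagnosis=30.0, exit_date="2010-01-01", status="censored",
                         transmission="sexual"))
        out = impute_missing(make_cohort(rows), seed=11)
        assert out.data.set_index("person_id").loc["X", "sex"] == "female"
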