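"""Eligibility rules, exposure potency classification, outcome window."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hdpsmatch.cohort import (apply_inclusion_exclusion, classify_exposure,
                              classify_outcome)
from hdpsmatch.simulate import ClaimsDataset

from conftest import index_statin, make_dataset, toy_patient


def _apply(dataset, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # raw toy data has no covariate flags
        return apply_inclusion_exclusion(dataset, **kw)


class TestExclusionRules:
    def test_underage_patient_excluded(self):
        ds = make_dataset(
            [toy_patient(1, age=39.0), toy_patient(2, age=40.0)],
            disp_rows=[index_statin(1), index_statin(2)])
        cohort, report = _apply(ds)
        assert list(cohort["patient_id"]) == [2]
        log = report.log.set_index("patient_id")["rule"]
        assert log.loc[1] == "age_under_40"

    def test_lookback_diabetes_diagnosis_excluded(self):
        ds = make_dataset(
            [toy_patient(1), toy_patient(2)],
            disp_rows=[index_statin(1), index_statin(2)],
            diag_rows=[{"patient_id": 1, "code": "250.2",
                        "days_relative_to_entry": -100}])
        cohort, report = _apply(ds)
        assert list(cohort["patient_id"]) == [2]
        assert report.log.iloc[0]["rule"] == "diabetes_diagnosis"

    @pytest.mark.parametrize("disp_extra, rule", [
        (index_statin(1, day=-30), "prior_statin"),
        (index_statin(1, product="atorvastatin", dose=20.0), "multiple_index_statins"),
        ({"patient_id": 1, "product": "niacin", "daily_dose": 1.0,
          "days_relative_to_entry": -10}, "other_lipid_lowering"),
        ({"patient_id": 1, "product": "A10_gliclazide", "daily_dose": 30.0,
          "days_relative_to_entry": 0}, "antidiabetic_dispensation"),
    ])
    def test_dispensation_rules(self, disp_extra, rule):
        ds = make_dataset([toy_patient(1)],
                          disp_rows=[index_statin(1), disp_extra])
        cohort, report = _apply(ds)
        assert len(cohort) == 0
        assert report.log.iloc[0]["rule"] == rule

    def test_all_eligible_all_retained(self):
        rows = [toy_patient(i) for i in range(1, 6)]
        ds = make_dataset(rows, disp_rows=[index_statin(i) for i in range(1, 6)])
        cohort, report = _apply(ds)
        assert len(cohort) == 5
        assert report.counts["n_excluded"].sum() == 0

    def test_flow_conservation_and_idempotence(self):
        rows = [
            toy_patient(1),                       # eligible
            toy_patient(2, age=35.0),             # age
            toy_patient(3, entry_year=1995),      # entry year
            toy_patient(4),                       # prior statin
            toy_patient(5),                       # eligible
        ]
        disp = [index_statin(i) for i in range(1, 6)]
        disp.append(index_statin(4, day=-100))
        ds = make_dataset(rows, disp_rows=disp)
        cohort, report = _apply(ds)
        assert len(cohort) + report.counts["n_excluded"].sum() == 5
        assert set(cohort["patient_id"]) == {1, 5}
        # idempotence: re-applying the rules to the retained set removes no one
        kept = set(cohort["patient_id"])
        ds2 = ClaimsDataset(
            patients=ds.patients[ds.patients["patient_id"].isin(kept)],
            events=ds.events,
            dispensations=ds.dispensations[ds.dispensations["patient_id"].isin(kept)],
            diagnoses=ds.diagnoses,
        )
        cohort2, report2 = _apply(ds2)
        assert report2.counts["n_excluded"].sum() == 0
        assert set(cohort2["patient_id"]) == kept

    def test_missing_required_column_is_schema_error(self):
        ds = make_dataset([{"patient_id": 1, "age": 50.0}],
                          disp_rows=[index_statin(1)])
        with pytest.raises(ValueError, match="entry_year"):
            apply_inclusion_exclusion(ds)


class TestClassifyExposure:
    @pytest.mark.parametrize("product, dose, expected", [
        ("rosuvastatin", 10.0, "high"),    # boundary inclusive
        ("rosuvastatin", 5.0, "lower"),
        ("atorvastatin", 20.0, "high"),
        ("atorvastatin", 10.0, "lower"),
        ("simvastatin", 40.0, "high"),
        ("simvastatin", 20.0, "lower"),
        ("pravastatin", 80.0, "lower"),    # never in the high list
        ("fluvastatin", 80.0, "lower"),
        ("lovastatin", 40.0, "lower"),
    ])
    def test_potency_thresholds(self, product, dose, expected):
        assert classify_exposure(product, dose) == expected

    def test_unknown_product_rejected(self):
        with pytest.raises(ValueError, match="unknown statin"):
            classify_exposure("ezetimibe", 10.0)
        with pytest.raises(ValueError):
            classify_exposure("simvastatin", 0.0)


class TestClassifyOutcome:
    def _run(self, disp_rows=None, diag_rows=None):
        disp = pd.DataFrame(disp_rows or [],
                            columns=["patient_id", "product", "daily_dose",
                                     "days_relative_to_entry"])
        diag = pd.DataFrame(diag_rows or [],
                            columns=["patient_id", "code", "days_relative_to_entry"])
        return classify_outcome(disp, diag, np.array([1]))

    def test_diagnosis_in_window_is_case(self):
        out = self._run(diag_rows=[{"patient_id": 1, "code": "E11.9",
                                    "days_relative_to_entry": 400}])
        assert out.loc[1] == 1

    def test_dispensation_beyond_window_is_noncase(self):
        rows = [{"patient_id": 1, "product": "A10_metformin", "daily_dose": 500.0,
                 "days_relative_to_entry": 731}]
        assert self._run(disp_rows=rows).loc[1] == 0
        rows[0]["days_relative_to_entry"] = 730  # last in-window day
        assert self._run(disp_rows=rows).loc[1] == 1

    def test_entry_day_record_not_an_outcome(self):
        out = self._run(diag_rows=[{"patient_id": 1, "code": "250.0",
                                    "days_relative_to_entry": 0}])
        assert out.loc[1] == 0

    def test_no_records_noncase(self):
        assert self._run().loc[1] == 0


class TestSyntheticFlagPrecedence:
    def test_synthetic_cohort_uses_flags_and_retains_everyone(self, small_dataset,
                                                              small_cohort):
        p = small_dataset.patients
        assert len(small_cohort) == len(p)
        merged = small_cohort.merge(p[["patient_id", "exposure", "outcome", "mi"]],
                                    on="patient_id", suffixes=("", "_src"))
        assert (merged["exposure"] == merged["exposure_src"]).all()
        assert (merged["outcome"] == merged["outcome_src"]).all()
        assert (merged["mi"] == merged["mi_src"]).all()
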