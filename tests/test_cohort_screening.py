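"""Eligibility rules, participant flow conservation, sample-size planning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemri import (
    CohortConfig,
    compute_bmi,
    evaluate_eligibility,
    generate_study,
    percentage,
    plan_sample_size,
    screen_cohort,
    summarize_flow,
)
from hemri import analytes as panel
from hemri.cohort_screening import RULE_ORDER, _REQUIRED_FIELDS
from hemri.synthetic_data import FLAG_COLUMNS


def make_record(partition="T1", **overrides):
    """A clean, eligible record; overrides flip individual fields."""
    rec = {
        "partition": partition, "age": 28, "weight_kg": 60.0, "height_m": 1.6,
        "systolic_bp": 110.0, "diastolic_bp": 70.0,
    }
    rec.update({flag: False for flag in FLAG_COLUMNS})
    rec.update(overrides)
    return rec


class TestBMI:
    @pytest.mark.parametrize(
        "weight,height,bmi,obese",
        [
            (75.0, 1.5, 33.33, True),
            (60.0, 1.6, 23.44, False),
            (76.8, 1.6, 30.0, True),  # boundary is inclusive
        ],
    )
    def test_bmi_and_obesity_boundary(self, weight, height, bmi, obese):
        assert compute_bmi(weight, height) == pytest.approx(bmi, abs=0.005)
        ok, reasons = evaluate_eligibility(
            make_record(weight_kg=weight, height_m=height)
        )
        assert ("obesity" in reasons) == obese

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0.0, 1.6)
        with pytest.raises(ValueError):
            compute_bmi(60.0, -1.0)


class TestEligibilityRules:
    def test_clean_record_is_eligible(self):
        ok, reasons = evaluate_eligibility(make_record())
        assert ok and reasons == []

    def test_positive_serology_excludes(self):
        ok, reasons = evaluate_eligibility(make_record(hbsag=True))
        assert not ok and reasons == ["serology"]

    def test_menstruating_excludes_only_non_pregnant(self):
        ok, _ = evaluate_eligibility(make_record("NP", menstruating=True))
        assert not ok
        ok, _ = evaluate_eligibility(make_record("T2", menstruating=True))
        assert ok

    def test_iron_folate_allowed_for_pregnant_only(self):
        ok, _ = evaluate_eligibility(make_record("T1", iron_folate=True))
        assert ok
        ok, reasons = evaluate_eligibility(make_record("NP", iron_folate=True))
        assert not ok and "medication" in reasons

    def test_bp_rule_is_systolic_over_140_or_diastolic_over_90(self):
        assert evaluate_eligibility(make_record(systolic_bp=140.0))[0]
        assert not evaluate_eligibility(make_record(systolic_bp=141.0))[0]
        assert evaluate_eligibility(make_record(diastolic_bp=90.0))[0]
        assert not evaluate_eligibility(make_record(diastolic_bp=91.0))[0]

    def test_age_bounds_inclusive(self):
        assert evaluate_eligibility(make_record(age=15))[0]
        assert evaluate_eligibility(make_record(age=49))[0]
        assert not evaluate_eligibility(make_record(age=14))[0]
        assert not evaluate_eligibility(make_record(age=50))[0]

    def test_missing_field_names_the_field(self):
        rec = make_record()
        del rec["hcv"]
        with pytest.raises(KeyError, match="hcv"):
            evaluate_eligibility(rec)

    def test_unknown_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            evaluate_eligibility(make_record(partition="T4"))

    @given(st.sets(st.sampled_from([
        "hiv", "chronic_disease", "malaria_6m", "substance_use",
        "chemical_exposure", "specimen_quality_fail", "febrile",
    ]), min_size=1))
    def test_exclusion_is_monotone_in_flags(self, flags):
        """Adding exclusion flags can never turn excluded into eligible."""
        rec = make_record(**{f: True for f in flags})
        ok, reasons = evaluate_eligibility(rec)
        assert not ok
        more = dict(rec, hbsag=True)
        ok2, reasons2 = evaluate_eligibility(more)
        assert not ok2 and set(reasons) <= set(reasons2)

    def test_reasons_follow_documented_order(self):
        rec = make_record(hiv=True, chronic_disease=True, substance_use=True)
        _, reasons = evaluate_eligibility(rec)
        order = [RULE_ORDER.index(r) for r in reasons]
        assert order == sorted(order)


class TestFlow:
    def test_fixture_cohort_reproduces_study_flow(self):
        """Exclusions 14+20+19+14 of 600 give 533 eligible (88.8%)."""
        cfg = CohortConfig(ineligible_fraction=0.0, outlier_rate=0.0,
                           random_seed=11)
        df = generate_study(cfg, panel.default_analytes()[:1])
        for part, k in [("T1", 14), ("T2", 20), ("T3", 19), ("NP", 14)]:
            rows = df.index[df["partition"] == part][:k]
            df.loc[rows, "hbsag"] = True
        report = summarize_flow(df)
        assert report.enrolled == 600
        assert report.eligible == 533
        assert report.eligible_percent == 88.8
        assert report.excluded_percent == 11.2
        assert dict(report.excluded_by_partition) == {
            "T1": 14, "T2": 20, "T3": 19, "NP": 14,
        }

    def test_flow_conserves_counts(self, default_cohort):
        report = summarize_flow(default_cohort)
        assert report.eligible + report.excluded == report.enrolled
        assert sum(report.excluded_by_reason.values()) == report.excluded
        assert sum(report.excluded_by_partition.values()) == report.excluded

    def test_screening_is_idempotent(self, default_cohort):
        eligible, _ = screen_cohort(default_cohort)
        again, report = screen_cohort(eligible)
        assert report.excluded == 0
        assert len(again) == len(eligible)

    def test_zero_exclusions_reports_100_percent(self):
        cfg = CohortConfig(n_per_partition=30, ineligible_fraction=0.0,
                           outlier_rate=0.0, random_seed=2)
        df = generate_study(cfg, panel.default_analytes()[:1])
        report = summarize_flow(df)
        assert report.eligible == report.enrolled
        assert report.eligible_percent == 100.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_flow(pd.DataFrame())


class TestSampleSize:
    @pytest.mark.parametrize(
        "per,k,rate,base,corrected",
        [
            (120, 4, 0.20, 480, 600),
            (120, 4, 0.0, 480, 480),
            (100, 1, 0.5, 100, 200),
        ],
    )
    def test_correction_formula(self, per, k, rate, base, corrected):
        plan = plan_sample_size(per, k, rate)
        assert plan.base_total == base
        assert plan.corrected_total == corrected

    def test_invalid_exclusion_rate(self):
        with pytest.raises(ValueError):
            plan_sample_size(120, 4, 1.0)

    def test_percentage_helper_rounding(self):
        assert percentage(533, 600) == 88.8
        assert percentage(234, 450) == 52.0
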