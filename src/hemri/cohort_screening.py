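"""Eligibility screening, participant-flow reporting and sample-size planning.

Screening applies the study's a priori / a posteriori exclusion rules to a
participant table: positive serology (HIV, HBsAg, HCV, syphilis, CRP),
parasitic infection, chronic disease and related medical history, recent
transfusion/donation/admission/surgery, malaria and TB history, medication
(iron/folate excepted for pregnant women, for whom it is routine),
substance use, obstetric complications, fever, recent exercise,
hypertension (systolic > 140 or diastolic > 90 mmHg), obesity
(BMI >= 30 kg/m2), hazardous chemical exposure, poor specimen quality,
and -- for the non-pregnant partition only -- menstruation, breastfeeding
and oral contraceptive use.

A subject may fire several rules; the flow report attributes each excluded
subject once, to the first firing rule in the documented ``RULE_ORDER``,
while the full reason list is available per record.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "EligibilityReport",
    "SampleSizePlan",
    "ScreeningRules",
    "compute_bmi",
    "evaluate_eligibility",
    "percentage",
    "plan_sample_size",
    "screen_cohort",
    "summarize_flow",
]

PREGNANT = ("T1", "T2", "T3")
VALID_PARTITIONS = ("T1", "T2", "T3", "NP")


@dataclass(frozen=True)
class ScreeningRules:
    """Configurable thresholds for the screening rules."""

    systolic_max: float = 140.0  # exclusive: > threshold excludes
    diastolic_max: float = 90.0
    bmi_obese: float = 30.0     # inclusive: >= threshold excludes
    age_min: int = 15           # inclusive bounds
    age_max: int = 49


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Share of ``total``, in percent, to the reporting precision (1 dp)."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    return round(100.0 * count / total, decimals)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError(
            f"weight and height must be positive, got ({weight_kg}, {height_m})"
        )
    return weight_kg / height_m**2


#: Screening rules in attribution order: (reason, fields used, predicate).
#: The order mirrors the study's exclusion summary (serology first, then
#: medical history, transfusion/donation, obesity, blood pressure) with
#: the remaining rules after.
RULE_ORDER: tuple[str, ...] = (
    "age_out_of_range",
    "serology",
    "parasite",
    "chronic_disease",
    "transfusion_donation",
    "admission_or_surgery",
    "malaria_or_tb",
    "obesity",
    "high_bp",
    "medication",
    "substance_use",
    "obstetric_complication",
    "febrile_or_exercise",
    "chemical_exposure",
    "menstruating",
    "breastfeeding",
    "oral_contraceptive",
    "specimen_quality",
)

_REQUIRED_FIELDS = (
    "partition", "age", "weight_kg", "height_m", "systolic_bp", "diastolic_bp",
    "hiv", "hbsag", "hcv", "syphilis", "crp", "hemoparasite",
    "intestinal_parasite", "chronic_disease", "transfusion_1y", "donation_3m",
    "admission_1y", "surgery_3y", "malaria_6m", "tb_2y", "medication",
    "iron_folate", "substance_use", "obstetric_complication",
    "chemical_exposure", "febrile", "exercise_prior", "menstruating",
    "breastfeeding", "oral_contraceptive", "specimen_quality_fail",
)


def evaluate_eligibility(
    record: Mapping[str, object],
    rules: ScreeningRules | None = None,
) -> tuple[bool, list[str]]:
    """Screen one participant record.

    Returns ``(eligible, reasons)`` where ``reasons`` lists every firing
    rule in :data:`RULE_ORDER`.  Rules specific to non-pregnant women
    (menstruation, breastfeeding, oral contraceptives, iron/folate
    supplementation) are evaluated only for partition ``NP``.

    Raises
    ------
    KeyError
        Naming the first missing required screening field.
    ValueError
        For an unknown partition label.
    """
    rules = rules or ScreeningRules()
    for name in _REQUIRED_FIELDS:
        if name not in record or pd.isna(record[name]):
            raise KeyError(f"missing required screening field: {name!r}")
    partition = record["partition"]
    if partition not in VALID_PARTITIONS:
        raise ValueError(f"unknown partition label: {partition!r}")
    non_pregnant = partition == "NP"

    bmi = compute_bmi(float(record["weight_kg"]), float(record["height_m"]))
    checks = {
        "age_out_of_range": not rules.age_min <= record["age"] <= rules.age_max,
        "serology": any(
            record[f] for f in ("hiv", "hbsag", "hcv", "syphilis", "crp")
        ),
        "parasite": record["hemoparasite"] or record["intestinal_parasite"],
        "chronic_disease": bool(record["chronic_disease"]),
        "transfusion_donation": record["transfusion_1y"] or record["donation_3m"],
        "admission_or_surgery": record["admission_1y"] or record["surgery_3y"],
        "malaria_or_tb": record["malaria_6m"] or record["tb_2y"],
        # inclusive boundary; epsilon absorbs float error in weight/height**2
        "obesity": bmi >= rules.bmi_obese - 1e-9,
        "high_bp": (
            float(record["systolic_bp"]) > rules.systolic_max
            or float(record["diastolic_bp"]) > rules.diastolic_max
        ),
        # iron/folate is routine for pregnant women and only exclusionary
        # (as "medication") for the non-pregnant partition
        "medication": record["medication"]
        or (non_pregnant and record["iron_folate"]),
        "substance_use": bool(record["substance_use"]),
        "obstetric_complication": (
            not non_pregnant and record["obstetric_complication"]
        ),
        "febrile_or_exercise": record["febrile"] or record["exercise_prior"],
        "chemical_exposure": bool(record["chemical_exposure"]),
        "menstruating": non_pregnant and record["menstruating"],
        "breastfeeding": non_pregnant and record["breastfeeding"],
        "oral_contraceptive": non_pregnant and record["oral_contraceptive"],
        "specimen_quality": bool(record["specimen_quality_fail"]),
    }
    reasons = [name for name in RULE_ORDER if checks[name]]
    return not reasons, reasons


@dataclass(frozen=True)
class EligibilityReport:
    """Participant flow: enrolled -> eligible, with exclusion breakdowns."""

    enrolled: int
    eligible: int
    excluded_by_reason: Counter = field(default_factory=Counter)
    excluded_by_partition: Counter = field(default_factory=Counter)

    @property
    def excluded(self) -> int:
        return self.enrolled - self.eligible

    @property
    def eligible_percent(self) -> float:
        """Eligible share of enrolment, one decimal."""
        return percentage(self.eligible, self.enrolled)

    @property
    def excluded_percent(self) -> float:
        return percentage(self.excluded, self.enrolled)

    def to_dict(self) -> dict:
        return {
            "enrolled": self.enrolled,
            "eligible": self.eligible,
            "excluded": self.excluded,
            "eligible_percent": self.eligible_percent,
            "excluded_percent": self.excluded_percent,
            "excluded_by_reason": dict(self.excluded_by_reason),
            "excluded_by_partition": dict(self.excluded_by_partition),
        }


def summarize_flow(
    records: pd.DataFrame,
    rules: ScreeningRules | None = None,
) -> EligibilityReport:
    """Screen every record and tabulate the participant flow.

    Each excluded subject is counted once under its first firing reason
    and once under its partition; ``eligible + excluded == enrolled``.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty participant table")
    by_reason: Counter = Counter()
    by_partition: Counter = Counter()
    eligible = 0
    for _, row in records.iterrows():
        ok, reasons = evaluate_eligibility(row, rules)
        if ok:
            eligible += 1
        else:
            by_reason[reasons[0]] += 1
            by_partition[row["partition"]] += 1
    return EligibilityReport(
        enrolled=len(records),
        eligible=eligible,
        excluded_by_reason=by_reason,
        excluded_by_partition=by_partition,
    )


def screen_cohort(
    records: pd.DataFrame,
    rules: ScreeningRules | None = None,
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Return the eligible subset and the flow report."""
    report = summarize_flow(records, rules)
    mask = [
        evaluate_eligibility(row, rules)[0] for _, row in records.iterrows()
    ]
    return records.loc[mask].reset_index(drop=True), report


@dataclass(frozen=True)
class SampleSizePlan:
    """Enrolment target inflated for anticipated exclusions."""

    per_partition_minimum: int
    n_partitions: int
    exclusion_rate: float

    @property
    def base_total(self) -> int:
        return self.per_partition_minimum * self.n_partitions

    @property
    def corrected_total(self) -> int:
        return math.ceil(self.base_total / (1.0 - self.exclusion_rate))

    @property
    def corrected_per_partition(self) -> int:
        return math.ceil(self.corrected_total / self.n_partitions)


def plan_sample_size(
    per_partition_minimum: int,
    n_partitions: int,
    exclusion_rate: float,
) -> SampleSizePlan:
    """Corrected enrolment: ``base / (1 - exclusion_rate)``, rounded up.

    The nonparametric reference-interval method needs at least 120
    subjects per partition; the enrolment target is inflated so that the
    expected post-exclusion count still meets the minimum.
    """
    if not 0.0 <= exclusion_rate < 1.0:
        raise ValueError(f"exclusion_rate must lie in [0, 1), got {exclusion_rate}")
    if per_partition_minimum < 1 or n_partitions < 1:
        raise ValueError("counts must be positive")
    return SampleSizePlan(per_partition_minimum, n_partitions, exclusion_rate)
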