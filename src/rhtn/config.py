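"""Study configuration: every threshold and window of the case definition
and the rate analysis lives in one validated object.

All intervals in the package are half-open ``[start, end)`` on whole days;
"within six months" is a fixed 183 days and "within one year" a fixed 365
days, so results do not depend on leap-year placement.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: default age bands: 18-39 open first band, 5-year bands to 85+, chosen to
#: nest the reporting categories 65-69 / 70-74 / 75-79 / >=80.
DEFAULT_AGE_BANDS: tuple[tuple[int, Optional[int]], ...] = (
    (18, 40),
    (40, 45),
    (45, 50),
    (50, 55),
    (55, 60),
    (60, 65),
    (65, 70),
    (70, 75),
    (75, 80),
    (80, 85),
    (85, None),
)


class BPOverride(BaseModel):
    """One blood-pressure threshold override rule.

    A rule matches when the measurement date falls in
    ``[period_start, period_end)`` (unbounded sides match everything) and
    the patient's age in whole years is in ``[min_age, max_age)``.  Rules
    are evaluated in listed order; the first match wins.
    """

    period_start: Optional[dt.date] = None
    period_end: Optional[dt.date] = None
    min_age: Optional[int] = None
    max_age: Optional[int] = None
    systolic: int
    diastolic: int

    def matches(self, date: dt.date, age: float) -> bool:
        if self.period_start is not None and date < self.period_start:
            return False
        if self.period_end is not None and date >= self.period_end:
            return False
        if self.min_age is not None and age < self.min_age:
            return False
        if self.max_age is not None and age >= self.max_age:
            return False
        return True


class StudyConfig(BaseModel):
    """All tunable settings of the phenotyping algorithm and rate analysis.

    Defaults encode the primary analysis: uncontrolled hypertension at
    >=140/90 mm Hg, repeat-prescription confirmation within 183 days,
    qualifying blood pressure within 365 days of starting the third drug,
    one-year adherence lookback with a 90-day discontinuation gap, binary
    adherence at a mean proportion-of-days-covered of 0.80, and direct
    standardisation to the final study year's hypertensive population.
    """

    study_start: dt.date = dt.date(1995, 1, 1)
    study_end: dt.date = dt.date(2015, 12, 31)
    bp_systolic_threshold: int = 140
    bp_diastolic_threshold: int = 90
    #: mean-PDC cut-off for binary adherence; ``None`` disables the
    #: adherence requirement entirely (sensitivity variant).
    adherence_threshold: Optional[float] = 0.80
    concurrency_confirm_window: int = 183
    bp_lookforward_window: int = 365
    adherence_lookback: int = 365
    discontinuation_gap: int = 90
    standard_population_year: int = 2015
    age_bands: tuple[tuple[int, Optional[int]], ...] = DEFAULT_AGE_BANDS
    bp_threshold_overrides: tuple[BPOverride, ...] = ()
    #: days' supply imputed for scripts that arrive without one.
    days_supply_default: int = 28
    #: which definition arms to run; sensitivity analyses restrict to one.
    arms: tuple[Literal["three_drug", "four_drug"], ...] = (
        "three_drug",
        "four_drug",
    )
    #: whether the class ``other`` counts toward regimen size.
    include_other_class: bool = True
    #: prevalent numerator requires continued eligibility (not just being
    #: alive) on 31 December; relaxable to alive-only.
    prevalence_requires_eligibility: bool = True
    random_seed: int = 0

    @field_validator(
        "concurrency_confirm_window",
        "bp_lookforward_window",
        "adherence_lookback",
        "discontinuation_gap",
        "days_supply_default",
    )
    @classmethod
    def _positive_window(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("windows must be strictly positive")
        return v

    @field_validator("adherence_threshold")
    @classmethod
    def _threshold_in_unit_interval(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError("adherence_threshold must lie in [0, 1] or be None")
        return v

    @model_validator(mode="after")
    def _check_dates_and_bands(self) -> "StudyConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        bands = list(self.age_bands)
        if not bands:
            raise ValueError("age_bands must be non-empty")
        if bands[0][0] != 18:
            raise ValueError("age_bands must start at 18")
        for (lo, hi), (nlo, _) in zip(bands, bands[1:]):
            if hi is None or hi != nlo:
                raise ValueError("age_bands must tile [18, inf) without gaps")
            if hi <= lo:
                raise ValueError("age band upper bound must exceed lower bound")
        if bands[-1][1] is not None:
            raise ValueError("last age band must be open-ended")
        if not self.arms:
            raise ValueError("at least one definition arm must be enabled")
        return self

    def age_band_label(self, age: float) -> str:
        for lo, hi in self.age_bands:
            if hi is None:
                if age >= lo:
                    return f"{lo}+"
            elif lo <= age < hi:
                return f"{lo}-{hi - 1}"
        raise ValueError(f"age {age} below the first age band")

    def age_band_labels(self) -> list[str]:
        out = []
        for lo, hi in self.age_bands:
            out.append(f"{lo}+" if hi is None else f"{lo}-{hi - 1}")
        return out


def resolve_bp_threshold(
    config: StudyConfig, date: dt.date, age: float
) -> tuple[int, int]:
    """Return the (systolic, diastolic) mm Hg threshold in force for a
    measurement taken on ``date`` for a patient of ``age`` whole years.

    Overrides are evaluated in listed order, first match wins; with no
    match the study defaults apply.  Used for the sensitivity variants
    (>=160/90 mm Hg in the early study period, >=150/90 mm Hg at age 80+).
    """
    for rule in config.bp_threshold_overrides:
        if rule.matches(date, age):
            return rule.systolic, rule.diastolic
    return config.bp_systolic_threshold, config.bp_diastolic_threshold
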