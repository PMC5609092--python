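"""Synthetic primary-care EHR generator with planted ground truth.

The generator emulates the statistical structure the phenotyping
algorithm assumes — stepped treatment intensification, heterogeneous
refill behaviour, blood-pressure readings correlated with regimen,
registration/diagnosis bookkeeping — without attempting to reproduce any
real database's demographics or absolute rates.  Patients are drawn from
a small set of archetypes:

* planted three-drug cases: built backwards from the case definition
  (adherent grids of two established classes plus an initiated thiazide,
  aligned repeats, a qualifying high reading 45 days after the third
  start), so the true index date is known exactly;
* planted four-drug cases: three established classes including a
  diuretic with controlled blood pressure throughout, plus an initiated
  fourth class (true index = first aligned repeat day);
* switchers: a third class replaces a first — concurrency is never
  confirmed, so these must produce no case;
* non-adherent pseudo-cases: a genuine concurrent triple with a high
  reading but sparse refills (mean PDC ~0.55), excluded unless the
  adherence requirement is disabled;
* controlled-on-three: an adherent triple whose readings stay below
  threshold;
* background: one or two classes, never eligible for a candidate.

Blood-pressure values are archetype-driven and clipped away from the
140/90 mm Hg boundary (controlled readings at most 138/88, qualifying
readings at least 141 systolic) so ground truth is exact by
construction; visit-level noise perturbs values inside those guards.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from rhtn.config import StudyConfig

_NONDIURETIC_POOL = [
    "ace_inhibitor",
    "calcium_channel_blocker",
    "beta_blocker",
    "angiotensin_receptor_blocker",
    "alpha_blocker",
]
_DIURETIC_POOL = ["thiazide_diuretic", "loop_diuretic"]

ARCHETYPES = (
    "planted_three",
    "planted_four",
    "switcher",
    "nonadherent",
    "controlled",
    "background",
)


class SimulationParams(BaseModel):
    """Knobs of the synthetic cohort.

    Archetype fractions must sum to at most 1; the remainder becomes
    background patients.  All randomness flows from ``seed``.
    """

    n_patients: int = Field(default=2000, ge=1)
    start_year: int = 1995
    end_year: int = 2015
    seed: int = 0

    planted_three_frac: float = Field(default=0.06, ge=0, le=1)
    planted_four_frac: float = Field(default=0.04, ge=0, le=1)
    switcher_frac: float = Field(default=0.10, ge=0, le=1)
    nonadherent_frac: float = Field(default=0.10, ge=0, le=1)
    controlled_frac: float = Field(default=0.10, ge=0, le=1)

    #: refill cadence (days between scripts) for the adherent /
    #: non-adherent mixture components; days' supply is fixed per script
    days_supply: int = 28
    adherent_refill_interval: int = 28
    nonadherent_refill_interval: int = 56
    #: s.d. of jitter added to refill dates for background patients (the
    #: constructed archetypes keep exact grids so ground truth is exact)
    refill_jitter_sd: float = 0.0

    #: blood-pressure model: archetype mean + age trend + visit noise,
    #: clipped away from the decision boundary (see module docstring)
    visit_interval_days: int = 180
    controlled_sbp_mean: float = 126.0
    controlled_dbp_mean: float = 78.0
    uncontrolled_sbp_mean: float = 155.0
    uncontrolled_dbp_mean: float = 96.0
    bp_age_slope: float = 0.2       # mm Hg per year of age over 60
    bp_noise_sd: float = 0.0

    age_at_onset_low: int = 40
    age_at_onset_high: int = 75
    male_fraction: float = 0.48

    #: annual probability a non-planted patient transfers out after two
    #: years of follow-up (planted cases are kept under follow-up past
    #: their onset so the ground truth stays satisfiable)
    annual_exit_prob: float = 0.0

    #: calendar mode for event years: None = uniform over feasible years;
    #: a year = triangular peak there (the rise-then-fall trend scenario)
    onset_mode_year: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        total = (
            self.planted_three_frac + self.planted_four_frac
            + self.switcher_frac + self.nonadherent_frac + self.controlled_frac
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"archetype fractions sum to {total:.3f} > 1")
        if self.end_year - self.start_year < 4:
            raise ValueError("calendar range must span at least 5 years")
        if self.onset_mode_year is not None and not (
            self.start_year < self.onset_mode_year < self.end_year
        ):
            raise ValueError("onset_mode_year must lie strictly inside the range")
        return self

    @property
    def planted_resistant_fraction(self) -> float:
        return self.planted_three_frac + self.planted_four_frac

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            study_start=dt.date(self.start_year, 1, 1),
            study_end=dt.date(self.end_year, 12, 31),
            random_seed=self.seed,
        )


def _archetype_counts(params: SimulationParams) -> list[tuple[str, int]]:
    n = params.n_patients
    counts = [
        ("planted_three", round(n * params.planted_three_frac)),
        ("planted_four", round(n * params.planted_four_frac)),
        ("switcher", round(n * params.switcher_frac)),
        ("nonadherent", round(n * params.nonadherent_frac)),
        ("controlled", round(n * params.controlled_frac)),
    ]
    used = sum(c for _, c in counts)
    if used > n:
        raise ValueError("archetype counts exceed n_patients; lower fractions")
    counts.append(("background", n - used))
    return counts


def _event_ordinal(params: SimulationParams, rng: np.random.Generator) -> int:
    """Ordinal day of a patient's pivotal drug change, placed so that the
    constructed index (up to +56 days) stays inside its calendar year."""
    lo, hi = params.start_year + 2, params.end_year
    if params.onset_mode_year is None:
        year = int(rng.integers(lo, hi + 1))
    else:
        year = int(round(rng.triangular(lo, params.onset_mode_year, hi)))
        year = min(max(year, lo), hi)
    day = int(rng.integers(10, 300))
    return dt.date(year, 1, 1).toordinal() + day


def _grid(start: int, stop: int, step: int) -> list[int]:
    return list(range(start, stop + 1, step))


class _PatientBuilder:
    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.study_end_ord = dt.date(params.end_year, 12, 31).toordinal()
        self.patients: list[dict] = []
        self.scripts: list[tuple[str, int, str, int]] = []
        self.bp: list[tuple[str, int, int, int]] = []
        self.truth: list[dict] = []

    # -- low-level emitters -------------------------------------------------

    def _add_scripts(self, pid: str, cls: str, dates: list[int],
                     jitter: float = 0.0) -> None:
        supply = self.p.days_supply
        for d in dates:
            if jitter > 0:
                d = int(round(d + self.rng.normal(0.0, jitter)))
            if d <= self.study_end_ord:
                self.scripts.append((pid, d, cls, supply))

    def _bp_value(self, controlled: bool, age: float) -> tuple[int, int]:
        p, rng = self.p, self.rng
        if controlled:
            s = p.controlled_sbp_mean + p.bp_age_slope * (age - 60)
            d = p.controlled_dbp_mean
            s += rng.normal(0.0, p.bp_noise_sd) if p.bp_noise_sd else 0.0
            d += rng.normal(0.0, p.bp_noise_sd) if p.bp_noise_sd else 0.0
            s = int(np.clip(round(s), 95, 138))
            d = int(np.clip(round(d), 50, 88))
        else:
            s = p.uncontrolled_sbp_mean + p.bp_age_slope * (age - 60)
            d = p.uncontrolled_dbp_mean
            s += rng.normal(0.0, p.bp_noise_sd) if p.bp_noise_sd else 0.0
            d += rng.normal(0.0, p.bp_noise_sd) if p.bp_noise_sd else 0.0
            s = int(np.clip(round(s), 141, 230))
            d = int(np.clip(round(d), 60, 120))
        return s, min(d, s - 10)

    def _routine_bp(self, pid: str, start: int, stop: int, age: float) -> None:
        for d in _grid(start, min(stop, self.study_end_ord),
                       self.p.visit_interval_days):
            s, dia = self._bp_value(True, age)
            self.bp.append((pid, d, s, dia))

    def _demographics(self, pid: str, event_ord: int, sex: str,
                      transfer_ord: Optional[int] = None) -> tuple[int, int]:
        """Emit the patient row; returns (birth_ord, diag_ord)."""
        rng, p = self.rng, self.p
        age = rng.uniform(p.age_at_onset_low, p.age_at_onset_high)
        birth_ord = int(event_ord - age * 365.25 - rng.integers(0, 365))
        diag_ord = event_ord - 422
        reg_ord = diag_ord - int(rng.integers(420, 3000))
        uts_ord = reg_ord - 30
        death = None
        self.patients.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": birth_ord,
                "death_date": death,
                "registration_date": reg_ord,
                "practice_uts_date": uts_ord,
                "transfer_out_date": transfer_ord,
                "last_collection_date": self.study_end_ord,
                "htn_diagnosis_date": diag_ord,
            }
        )
        return birth_ord, diag_ord

    def _pick_classes(self, k: int, with_diuretic: bool) -> list[str]:
        rng = self.rng
        nd = list(rng.choice(_NONDIURETIC_POOL, size=k - (1 if with_diuretic else 0),
                             replace=False))
        if with_diuretic:
            nd.append(str(rng.choice(_DIURETIC_POOL)))
        return [str(c) for c in nd]

    def _maybe_exit(self, diag_ord: int) -> Optional[int]:
        p = self.p
        if p.annual_exit_prob <= 0:
            return None
        t = diag_ord + 730
        while t < self.study_end_ord:
            if self.rng.random() < p.annual_exit_prob:
                return t + int(self.rng.integers(0, 365))
            t += 365
        return None

    # -- archetypes ---------------------------------------------------------

    def planted_three(self, pid: str) -> None:
        rng, p = self.rng, self.p
        t3 = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        birth, diag = self._demographics(pid, t3, sex)
        age = (t3 - birth) / 365.25
        a, b, c = self._pick_classes(3, with_diuretic=True)
        step = p.adherent_refill_interval
        for cls in (a, b):
            self._add_scripts(pid, cls, _grid(t3 - 392, t3 + 224, step))
        self._add_scripts(pid, c, _grid(t3, t3 + 224, step))
        self._routine_bp(pid, diag, t3 + 224, age)
        s, dia = self._bp_value(False, age)
        self.bp.append((pid, t3 + 45, s, dia))
        self.truth.append(
            {"patient_id": pid, "true_resistant": True,
             "true_arm": "three_drug", "true_onset": t3 + 45}
        )

    def planted_four(self, pid: str) -> None:
        rng, p = self.rng, self.p
        t4 = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        birth, diag = self._demographics(pid, t4, sex)
        age = (t4 - birth) / 365.25
        a, b, c = self._pick_classes(3, with_diuretic=True)
        d4 = str(rng.choice([x for x in _NONDIURETIC_POOL if x not in (a, b, c)]))
        step = p.adherent_refill_interval
        for cls in (a, b, c):
            self._add_scripts(pid, cls, _grid(t4 - 392, t4 + 224, step))
        self._add_scripts(pid, d4, _grid(t4, t4 + 224, step))
        self._routine_bp(pid, diag, t4 + 224, age)
        self.truth.append(
            {"patient_id": pid, "true_resistant": True,
             "true_arm": "four_drug", "true_onset": t4 + step}
        )

    def switcher(self, pid: str) -> None:
        rng, p = self.rng, self.p
        ts = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        birth, diag = self._demographics(pid, ts, sex)
        age = (ts - birth) / 365.25
        a, b, c = self._pick_classes(3, with_diuretic=True)
        step = p.adherent_refill_interval
        overlap = rng.random() < 0.5
        last_a = ts - 14 if overlap else ts - 56
        self._add_scripts(pid, a, _grid(ts - 392, last_a, step))
        self._add_scripts(pid, b, _grid(ts - 392, ts + 224, step))
        self._add_scripts(pid, c, _grid(ts, ts + 224, step))
        self._routine_bp(pid, diag, ts + 224, age)
        self.truth.append(
            {"patient_id": pid, "true_resistant": False,
             "true_arm": "none", "true_onset": None}
        )

    def nonadherent(self, pid: str) -> None:
        rng, p = self.rng, self.p
        t3 = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        birth, diag = self._demographics(pid, t3, sex)
        age = (t3 - birth) / 365.25
        a, b, c = self._pick_classes(3, with_diuretic=True)
        step = p.nonadherent_refill_interval
        # pre-initiation grids aligned so both classes cover the third
        # drug's start day; sparse refills keep the mean PDC near 0.55
        for cls in (a, b):
            self._add_scripts(pid, cls, _grid(t3 - 350, t3 - 14, step))
            self._add_scripts(pid, cls, _grid(t3 + 42, t3 + 224, step))
        self._add_scripts(pid, c, _grid(t3, t3 + 224, step))
        self._routine_bp(pid, diag, t3 + 224, age)
        s, dia = self._bp_value(False, age)
        self.bp.append((pid, t3 + 45, s, dia))
        self.truth.append(
            {"patient_id": pid, "true_resistant": False,
             "true_arm": "none", "true_onset": None}
        )

    def controlled(self, pid: str) -> None:
        rng, p = self.rng, self.p
        t3 = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        birth, diag = self._demographics(pid, t3, sex)
        age = (t3 - birth) / 365.25
        a, b, c = self._pick_classes(3, with_diuretic=True)
        step = p.adherent_refill_interval
        for cls in (a, b):
            self._add_scripts(pid, cls, _grid(t3 - 392, t3 + 224, step))
        self._add_scripts(pid, c, _grid(t3, t3 + 224, step))
        self._routine_bp(pid, diag, t3 + 224, age)
        self.truth.append(
            {"patient_id": pid, "true_resistant": False,
             "true_arm": "none", "true_onset": None}
        )

    def background(self, pid: str) -> None:
        rng, p = self.rng, self.p
        t0 = _event_ordinal(p, rng)
        sex = "male" if rng.random() < p.male_fraction else "female"
        transfer = None
        birth, diag = self._demographics(pid, t0, sex,
                                         transfer_ord=None)
        exit_ord = self._maybe_exit(diag)
        if exit_ord is not None:
            self.patients[-1]["transfer_out_date"] = exit_ord
        age = (t0 - birth) / 365.25
        n_classes = 1 if rng.random() < 0.5 else 2
        classes = self._pick_classes(
            n_classes, with_diuretic=(n_classes == 2 and rng.random() < 0.4)
        )
        adherent = rng.random() < 0.7
        step = (p.adherent_refill_interval if adherent
                else p.nonadherent_refill_interval)
        stop = diag + 30 + int(rng.integers(730, 5500))
        if exit_ord is not None:
            stop = min(stop, exit_ord)
        for cls in classes:
            self._add_scripts(pid, cls, _grid(diag + 30, stop, step),
                              jitter=p.refill_jitter_sd)
        self._routine_bp(pid, diag, stop, age)
        self.truth.append(
            {"patient_id": pid, "true_resistant": False,
             "true_arm": "none", "true_onset": None}
        )


def simulate(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(patients, prescriptions, bp_readings, ground_truth)``.

    Reproducible given ``params.seed``; tables match the schemas of
    :mod:`rhtn.tables` (dates as ``datetime64[ns]``).  ``ground_truth``
    has one row per patient with ``true_resistant``, ``true_arm`` in
    ``{three_drug, four_drug, none}`` and ``true_onset_date``.
    """
    rng = np.random.default_rng(params.seed)
    b = _PatientBuilder(params, rng)
    i = 0
    for archetype, count in _archetype_counts(params):
        fn = getattr(b, archetype)
        for _ in range(count):
            fn(f"P{i:06d}")
            i += 1

    def _d(o):
        if o is None or (isinstance(o, float) and np.isnan(o)):
            return pd.NaT
        return pd.Timestamp(dt.date.fromordinal(int(o)))

    patients = pd.DataFrame(b.patients)
    for c in ("birth_date", "death_date", "registration_date",
              "practice_uts_date", "transfer_out_date",
              "last_collection_date", "htn_diagnosis_date"):
        patients[c] = patients[c].map(_d)

    scripts = pd.DataFrame(
        b.scripts, columns=["patient_id", "issue_date", "drug_class", "days_supply"]
    )
    scripts["issue_date"] = scripts["issue_date"].map(_d)
    scripts = scripts.sort_values(
        ["patient_id", "issue_date", "drug_class"], kind="stable"
    ).reset_index(drop=True)

    bp = pd.DataFrame(
        b.bp, columns=["patient_id", "measure_date", "systolic", "diastolic"]
    )
    bp["measure_date"] = bp["measure_date"].map(_d)
    bp = bp.sort_values(
        ["patient_id", "measure_date"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(b.truth)
    truth["true_onset_date"] = truth.pop("true_onset").map(_d)
    return patients, scripts, bp, truth


def scenario_presets() -> dict[str, SimulationParams]:
    """Named study scenarios.

    ``clean``: noise-free recovery with 10% planted cases.
    ``switchers``: drug substitution only — zero true cases.
    ``nonadherent``: pseudo-resistant patients dominate, so disabling the
    adherence requirement inflates the case count.
    ``trend``: planted onsets drawn with a 2004 peak, yielding a
    rise-then-fall annual incidence shape.
    """
    return {
        "clean": SimulationParams(),
        "switchers": SimulationParams(
            planted_three_frac=0.0, planted_four_frac=0.0,
            switcher_frac=0.5, nonadherent_frac=0.0, controlled_frac=0.2,
        ),
        "nonadherent": SimulationParams(
            planted_three_frac=0.05, planted_four_frac=0.0,
            switcher_frac=0.05, nonadherent_frac=0.30, controlled_frac=0.10,
        ),
        "trend": SimulationParams(
            planted_three_frac=0.12, planted_four_frac=0.03,
            switcher_frac=0.05, nonadherent_frac=0.05, controlled_frac=0.05,
            onset_mode_year=2004,
        ),
    }


def get_preset(name: str) -> SimulationParams:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]
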