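"""Case ascertainment: the two definition arms, index dates, exclusion
and re-eligibility rules.

Three-drug arm: confirmed concurrent use of three antihypertensive
classes including a diuretic, plus a blood-pressure reading at or above
the uncontrolled threshold within 12 months of starting the third drug,
plus binary adherence over the one-year lookback at the index date.  The
index date is the later of the concurrency evidence (confirmation date)
and the qualifying reading's date.

Four-drug arm: confirmed concurrent use of four classes including a
diuretic plus adherence; no reading is required, and the index date is
the earliest day inside the confirmation window on which all four
classes simultaneously have active coverage and each has repeated.

Patients meet the definition at the earliest opportunity: the first
candidate (either arm, chronologically by achievable index date) to
satisfy everything produces the patient's single case record.  A
candidate rejected because blood pressure was controlled leaves the
patient re-eligible at future drug changes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd

from rhtn.adherence import assess_adherence
from rhtn.cohort import eligibility_windows, DAYS_PER_YEAR
from rhtn.config import StudyConfig, resolve_bp_threshold
from rhtn.drug_coding import DIURETIC_CLASSES
from rhtn.regimen import (
    CoverageTimeline,
    RegimenCandidate,
    build_timeline,
    confirm_candidate,
    detect_candidates,
    _to_ordinals,
)

REJECTION_REASONS = (
    "no_diuretic",
    "unconfirmed",
    "controlled_bp",
    "no_bp_reading",
    "non_adherent",
    "not_assessable",
)


@dataclasses.dataclass
class CaseRecord:
    patient_id: str
    index_ord: int
    arm: str  # three_drug | four_drug
    classes: frozenset[str]
    qualifying_bp: Optional[tuple[int, int, int]]  # (ordinal, sys, dia)
    mean_pdc: Optional[float]

    @property
    def index_date(self) -> dt.date:
        return dt.date.fromordinal(self.index_ord)


@dataclasses.dataclass
class RejectionRecord:
    patient_id: str
    candidate_ord: int
    arm: str
    reason: str
    re_eligible: bool

    def __post_init__(self) -> None:
        assert self.reason in REJECTION_REASONS


def _age_at(birth_ord: int, day: int) -> int:
    return int((day - birth_ord) // DAYS_PER_YEAR)


def evaluate_three_drug(
    candidate: RegimenCandidate,
    bp_dates: np.ndarray,
    bp_sys: np.ndarray,
    bp_dia: np.ndarray,
    scripts: pd.DataFrame,
    birth_ord: int,
    config: StudyConfig,
) -> CaseRecord | RejectionRecord:
    """Apply the blood-pressure and adherence requirements to a confirmed
    three-class candidate containing a diuretic.

    Readings are searched in ``(start, start + 365]`` days after the third
    drug's initiation; the first reading at or above the threshold in
    force on its date (period/age overrides respected) qualifies.
    """
    t0 = candidate.nth_start_date
    hi = t0 + config.bp_lookforward_window
    m = (bp_dates > t0) & (bp_dates <= hi)
    if not m.any():
        return RejectionRecord(candidate.patient_id, t0, "three_drug",
                               "no_bp_reading", re_eligible=False)
    order = np.argsort(bp_dates[m], kind="stable")
    dts, sy, di = bp_dates[m][order], bp_sys[m][order], bp_dia[m][order]
    qualifying = None
    for d, s, dia in zip(dts, sy, di):
        thr_s, thr_d = resolve_bp_threshold(
            config, dt.date.fromordinal(int(d)), _age_at(birth_ord, int(d))
        )
        if s >= thr_s or dia >= thr_d:
            qualifying = (int(d), int(s), int(dia))
            break
    if qualifying is None:
        return RejectionRecord(candidate.patient_id, t0, "three_drug",
                               "controlled_bp", re_eligible=True)

    index_ord = max(candidate.confirmation_date, qualifying[0])
    adh = assess_adherence(scripts, sorted(candidate.classes), index_ord,
                           config, candidate.patient_id)
    if not adh.assessable and config.adherence_threshold is not None:
        return RejectionRecord(candidate.patient_id, t0, "three_drug",
                               "not_assessable", re_eligible=False)
    if not adh.adherent:
        return RejectionRecord(candidate.patient_id, t0, "three_drug",
                               "non_adherent", re_eligible=False)
    return CaseRecord(candidate.patient_id, index_ord, "three_drug",
                      candidate.classes, qualifying, adh.mean_pdc)


def evaluate_four_drug(
    candidate: RegimenCandidate,
    timeline: CoverageTimeline,
    scripts: pd.DataFrame,
    config: StudyConfig,
) -> CaseRecord | RejectionRecord:
    """Apply the adherence requirement to a confirmed four-class candidate
    containing a diuretic; no blood-pressure reading is required.

    The index date is the earliest day in the confirmation window at
    which all four classes are simultaneously covered and each has had
    its repeat — i.e. the first day at/after the confirmation date on
    which all four coverages overlap.
    """
    t0 = candidate.nth_start_date
    hi = t0 + config.concurrency_confirm_window
    index_ord = None
    for day in range(candidate.confirmation_date, hi + 1):
        if all(timeline.is_active(c, day) for c in candidate.classes):
            index_ord = day
            break
    if index_ord is None:
        return RejectionRecord(candidate.patient_id, t0, "four_drug",
                               "unconfirmed", re_eligible=False)
    adh = assess_adherence(scripts, sorted(candidate.classes), index_ord,
                           config, candidate.patient_id)
    if not adh.assessable and config.adherence_threshold is not None:
        return RejectionRecord(candidate.patient_id, t0, "four_drug",
                               "not_assessable", re_eligible=False)
    if not adh.adherent:
        return RejectionRecord(candidate.patient_id, t0, "four_drug",
                               "non_adherent", re_eligible=False)
    return CaseRecord(candidate.patient_id, index_ord, "four_drug",
                      candidate.classes, None, adh.mean_pdc)


def _evaluate_patient(
    patient_id: str,
    scripts: pd.DataFrame,
    bp_dates: np.ndarray,
    bp_sys: np.ndarray,
    bp_dia: np.ndarray,
    window: tuple[int, int],
    birth_ord: int,
    config: StudyConfig,
    diuretic_classes: frozenset[str],
) -> tuple[Optional[CaseRecord], list[RejectionRecord]]:
    timeline = build_timeline(scripts, config, patient_id)
    study_end_ord = config.study_end.toordinal()
    window = (window[0], min(window[1], study_end_ord + 1))

    candidates: list[RegimenCandidate] = []
    if "three_drug" in config.arms:
        candidates += detect_candidates(timeline, 3, config, window)
    if "four_drug" in config.arms:
        candidates += detect_candidates(timeline, 4, config, window)
    candidates.sort(key=lambda c: (c.nth_start_date, c.n, sorted(c.classes)))

    rejections: list[RejectionRecord] = []
    outcomes: list[CaseRecord] = []
    seen_unconfirmed: set[tuple[int, int]] = set()
    for cand in candidates:
        arm = "three_drug" if cand.n == 3 else "four_drug"
        if not cand.classes & diuretic_classes:
            rejections.append(
                RejectionRecord(patient_id, cand.nth_start_date, arm,
                                "no_diuretic", re_eligible=False)
            )
            continue
        cand = confirm_candidate(cand, scripts, config)
        if not cand.confirmed:
            key = (cand.nth_start_date, cand.n)
            if key not in seen_unconfirmed:  # one rejection per initiation
                seen_unconfirmed.add(key)
                rejections.append(
                    RejectionRecord(patient_id, cand.nth_start_date, arm,
                                    "unconfirmed", re_eligible=False)
                )
            continue
        if cand.n == 3:
            res = evaluate_three_drug(cand, bp_dates, bp_sys, bp_dia,
                                      scripts, birth_ord, config)
        else:
            res = evaluate_four_drug(cand, timeline, scripts, config)
        if isinstance(res, CaseRecord):
            # the index must fall inside the patient's eligibility window
            if window[0] <= res.index_ord < window[1]:
                outcomes.append(res)
        else:
            rejections.append(res)

    if not outcomes:
        return None, rejections
    best = min(outcomes, key=lambda c: (c.index_ord, c.arm))
    # earliest opportunity wins; rejections after the index are moot
    rejections = [r for r in rejections if r.candidate_ord <= best.index_ord]
    return best, rejections


def ascertain(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    bp_readings: pd.DataFrame,
    config: StudyConfig,
    diuretic_classes: frozenset[str] = DIURETIC_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full case definition over a cohort.

    Returns ``(cases, rejections)`` DataFrames.  ``cases`` has one row
    per case patient with columns ``patient_id, index_date, index_ord,
    arm, classes, qualifying_bp_date, qualifying_systolic,
    qualifying_diastolic, mean_pdc, age_at_index``; ``rejections`` one
    row per rejected candidate with its reason and re-eligibility flag.
    """
    windows = eligibility_windows(patients, prescriptions, config)
    win_by_pid = windows.set_index("patient_id")

    rx_by_pid = dict(tuple(prescriptions.groupby("patient_id", sort=False)))
    bp_ord = _to_ordinals(bp_readings["measure_date"]) if len(bp_readings) else np.array([], dtype=int)
    bp_pid = bp_readings["patient_id"].to_numpy() if len(bp_readings) else np.array([])
    bp_sys = bp_readings["systolic"].to_numpy() if len(bp_readings) else np.array([])
    bp_dia = bp_readings["diastolic"].to_numpy() if len(bp_readings) else np.array([])
    bp_groups: dict[str, np.ndarray] = {}
    if len(bp_readings):
        order = np.argsort(bp_pid, kind="stable")
        sorted_pid = bp_pid[order]
        bounds = np.flatnonzero(np.r_[True, sorted_pid[1:] != sorted_pid[:-1], True])
        for i, j in zip(bounds[:-1], bounds[1:]):
            bp_groups[sorted_pid[i]] = order[i:j]

    case_rows, rej_rows = [], []
    for _, wrow in win_by_pid[win_by_pid["included"]].iterrows():
        pid = wrow.name
        scripts = rx_by_pid.get(pid)
        if scripts is None or len(scripts) == 0:
            continue
        sel = bp_groups.get(pid, np.array([], dtype=int))
        case, rejections = _evaluate_patient(
            pid,
            scripts,
            bp_ord[sel],
            bp_sys[sel],
            bp_dia[sel],
            (int(wrow["start"]), int(wrow["end"])),
            int(wrow["birth_ord"]),
            config,
            diuretic_classes,
        )
        for r in rejections:
            rej_rows.append(
                {
                    "patient_id": r.patient_id,
                    "candidate_date": dt.date.fromordinal(r.candidate_ord),
                    "arm": r.arm,
                    "reason": r.reason,
                    "re_eligible": r.re_eligible,
                }
            )
        if case is not None:
            qbp = case.qualifying_bp
            case_rows.append(
                {
                    "patient_id": case.patient_id,
                    "index_date": case.index_date,
                    "index_ord": case.index_ord,
                    "arm": case.arm,
                    "classes": ";".join(sorted(case.classes)),
                    "qualifying_bp_date": (
                        dt.date.fromordinal(qbp[0]) if qbp else None
                    ),
                    "qualifying_systolic": qbp[1] if qbp else None,
                    "qualifying_diastolic": qbp[2] if qbp else None,
                    "mean_pdc": case.mean_pdc,
                    "age_at_index": _age_at(int(wrow["birth_ord"]), case.index_ord),
                }
            )

    cases = pd.DataFrame(
        case_rows,
        columns=[
            "patient_id", "index_date", "index_ord", "arm", "classes",
            "qualifying_bp_date", "qualifying_systolic",
            "qualifying_diastolic", "mean_pdc", "age_at_index",
        ],
    )
    rejections = pd.DataFrame(
        rej_rows,
        columns=["patient_id", "candidate_date", "arm", "reason", "re_eligible"],
    )
    return cases, rejections
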