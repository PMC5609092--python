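"""Per-class drug coverage timelines and concurrent-regimen detection.

Scripts are expanded into covered days with stockpiling: issuing a new
script while supply from earlier scripts remains appends the leftover
days after the new supply, so coverage runs contiguously until the
accumulated supply is exhausted (carryover is uncapped).  An episode of a
class ends — a discontinuation — when a gap of at least
``discontinuation_gap`` days opens between the expected finishing date
and the next script of that class.

A regimen candidate is the event "an nth concurrent class was initiated":
a script of a class with no active coverage issued on a day when at least
n-1 other classes are covered.  Candidates are confirmed by repeat
prescriptions of every member class within the confirmation window.

All dates here are proleptic-Gregorian ordinals (``datetime.date
.toordinal``); intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from rhtn.config import StudyConfig

Interval = tuple[int, int]


@dataclasses.dataclass
class CoverageTimeline:
    """Coverage intervals per drug class for one patient."""

    patient_id: str
    #: class -> sorted disjoint [start, end) intervals in ordinal days
    intervals: dict[str, list[Interval]]
    #: (class, ordinal day of expected finish) discontinuation events
    discontinuations: list[tuple[str, int]]

    def active_classes(self, day: int) -> set[str]:
        """Classes with coverage on ``day``."""
        out = set()
        for cls, ivs in self.intervals.items():
            for s, e in ivs:
                if s <= day < e:
                    out.add(cls)
                    break
                if s > day:
                    break
        return out

    def is_active(self, cls: str, day: int) -> bool:
        for s, e in self.intervals.get(cls, ()):
            if s <= day < e:
                return True
            if s > day:
                return False
        return False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": self.patient_id, "drug_class": cls,
             "start": dt.date.fromordinal(s), "end": dt.date.fromordinal(e)}
            for cls, ivs in sorted(self.intervals.items())
            for s, e in ivs
        ]
        return pd.DataFrame(rows, columns=["patient_id", "drug_class", "start", "end"])


@dataclasses.dataclass
class RegimenCandidate:
    """A detected initiation of an nth concurrent class, pending
    repeat-prescription confirmation."""

    patient_id: str
    n: int
    classes: frozenset[str]
    nth_start_date: int  # ordinal day
    nth_class: str
    confirmed: bool = False
    confirmation_date: Optional[int] = None


def coverage_runs(
    dates: np.ndarray, supplies: np.ndarray
) -> list[Interval]:
    """Collapse scripts of one class into contiguous coverage runs with
    stockpiling.  ``dates`` are ordinal days (any order), ``supplies``
    positive day counts."""
    if len(dates) == 0:
        return []
    order = np.argsort(dates, kind="stable")
    dates = np.asarray(dates)[order]
    supplies = np.asarray(supplies)[order]
    runs: list[Interval] = []
    run_start = int(dates[0])
    expected_end = run_start + int(supplies[0])
    for d, s in zip(dates[1:], supplies[1:]):
        d, s = int(d), int(s)
        if d <= expected_end:
            # supply remains (or resumes exactly as it runs out): leftover
            # days are appended after the new supply
            expected_end += s
        else:
            runs.append((run_start, expected_end))
            run_start = d
            expected_end = d + s
    runs.append((run_start, expected_end))
    return runs


def build_timeline(
    scripts: pd.DataFrame, config: StudyConfig, patient_id: Optional[str] = None
) -> CoverageTimeline:
    """Build the per-class coverage timeline for one patient's scripts.

    ``scripts`` needs columns ``drug_class``, ``issue_date``
    (datetime-like), ``days_supply``; an empty frame yields an empty
    timeline.
    """
    if patient_id is None:
        patient_id = (
            str(scripts["patient_id"].iloc[0]) if len(scripts) else ""
        )
    intervals: dict[str, list[Interval]] = {}
    discontinuations: list[tuple[str, int]] = []
    if len(scripts) == 0:
        return CoverageTimeline(patient_id, intervals, discontinuations)

    dates_ord = _to_ordinals(scripts["issue_date"])
    supplies = scripts["days_supply"].to_numpy()
    for cls in np.unique(scripts["drug_class"].to_numpy()):
        m = (scripts["drug_class"] == cls).to_numpy()
        runs = coverage_runs(dates_ord[m], supplies[m])
        intervals[str(cls)] = runs
        for (s0, e0), (s1, _) in zip(runs, runs[1:]):
            if s1 - e0 >= config.discontinuation_gap:
                discontinuations.append((str(cls), e0))
    return CoverageTimeline(patient_id, intervals, discontinuations)


def _to_ordinals(series: pd.Series) -> np.ndarray:
    """datetime64 (or date) series -> proleptic ordinal ints."""
    s = pd.to_datetime(series)
    # days since 1970-01-01, shifted to toordinal() convention
    return (s.to_numpy().astype("datetime64[D]").astype(np.int64)
            + dt.date(1970, 1, 1).toordinal())


def detect_candidates(
    timeline: CoverageTimeline,
    n: int,
    config: StudyConfig,
    window: Optional[Interval] = None,
) -> list[RegimenCandidate]:
    """Detect initiations of an nth concurrent antihypertensive class.

    A candidate is emitted at each coverage-run start (a script of a class
    not currently covered) where at least ``n - 1`` other classes are
    active that day.  When more than ``n - 1`` are active, one candidate is
    emitted per ``n``-subset containing the newly started class; downstream
    confirmation and the earliest-index rule arbitrate.  ``window``
    optionally restricts start dates to ``[lo, hi)``.
    """
    if n not in (3, 4):
        raise ValueError("regimen size n must be 3 or 4")
    classes = set(timeline.intervals)
    if not config.include_other_class:
        classes = classes - {"other"}
    # run starts are exactly the days a class begins a new episode
    starts: list[tuple[int, str]] = []
    for cls in classes:
        for s, _ in timeline.intervals[cls]:
            starts.append((s, cls))
    starts.sort()

    out: list[RegimenCandidate] = []
    for day, cls in starts:
        if window is not None and not (window[0] <= day < window[1]):
            continue
        active = {
            c for c in classes
            if c != cls and timeline.is_active(c, day)
        }
        if len(active) < n - 1:
            continue
        if len(active) == n - 1:
            subsets: Iterable[frozenset[str]] = [frozenset(active)]
        else:
            subsets = (frozenset(c) for c in combinations(sorted(active), n - 1))
        for sub in subsets:
            out.append(
                RegimenCandidate(
                    patient_id=timeline.patient_id,
                    n=n,
                    classes=sub | {cls},
                    nth_start_date=day,
                    nth_class=cls,
                )
            )
    return out


def confirm_candidate(
    candidate: RegimenCandidate,
    scripts: pd.DataFrame,
    config: StudyConfig,
) -> RegimenCandidate:
    """Confirm concurrency by repeat prescriptions of all member classes.

    A repeat of class ``c`` is any script of ``c`` issued strictly after
    the nth drug's start and no more than ``concurrency_confirm_window``
    days later (the boundary day counts as within the window).  The
    confirmation date is the earliest day by which every member class has
    repeated.  The initiating script of the nth class is not its own
    repeat.
    """
    t0 = candidate.nth_start_date
    hi = t0 + config.concurrency_confirm_window
    dates_ord = _to_ordinals(scripts["issue_date"])
    cls_arr = scripts["drug_class"].to_numpy()
    latest_first_repeat = None
    for cls in candidate.classes:
        m = (cls_arr == cls) & (dates_ord > t0) & (dates_ord <= hi)
        if not m.any():
            return dataclasses.replace(candidate, confirmed=False,
                                       confirmation_date=None)
        first = int(dates_ord[m].min())
        if latest_first_repeat is None or first > latest_first_repeat:
            latest_first_repeat = first
    return dataclasses.replace(
        candidate, confirmed=True, confirmation_date=latest_first_repeat
    )
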