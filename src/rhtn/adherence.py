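"""Proxy adherence from prescribing records.

In the absence of dispensing data, adherence is proxied by the proportion
of days covered (PDC) over a one-year lookback from the index date: for
each drug class, from the first script inside the lookback until the
index date — or until the class's discontinuation date, if a gap of 90 or
more days separates the expected finishing date of a prescription from
the end of the observation period.  Leftover supply carries over
(stockpiling).  The patient-level measure is the arithmetic mean of the
per-class PDCs over the regimen's classes, and binary adherence is
mean PDC at or above the configured threshold (0.80 by default; the
boundary is inclusive).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rhtn.config import StudyConfig
from rhtn.regimen import coverage_runs, _to_ordinals


@dataclasses.dataclass
class ClassPDC:
    drug_class: str
    observation_start: int  # ordinal day
    observation_end: int    # ordinal day, exclusive
    covered_days: int
    pdc: float


@dataclasses.dataclass
class AdherenceResult:
    patient_id: str
    index_date: int  # ordinal
    per_class: dict[str, ClassPDC]
    mean_pdc: Optional[float]   # None when no class assessable
    #: True/False when assessed against a threshold; True with
    #: assessed=False when the adherence requirement is disabled.
    adherent: bool
    assessed: bool
    assessable: bool


def compute_class_pdc(
    dates_ord: np.ndarray,
    supplies: np.ndarray,
    index_ord: int,
    config: StudyConfig,
    drug_class: str = "",
) -> Optional[ClassPDC]:
    """PDC of one class over the lookback window before ``index_ord``.

    Only scripts issued in ``[index - lookback, index)`` enter the
    calculation.  Returns ``None`` when the class has no script in the
    window (the class is skipped, not averaged as zero).  The observation
    runs from the first in-window script to the index date, truncated at
    the first discontinuation: the end of a coverage run followed by a
    supply gap of at least ``discontinuation_gap`` days before the next
    script (or the index date, for the final run).
    """
    lo = index_ord - config.adherence_lookback
    dates_ord = np.asarray(dates_ord)
    supplies = np.asarray(supplies)
    m = (dates_ord >= lo) & (dates_ord < index_ord)
    if not m.any():
        return None
    runs = coverage_runs(dates_ord[m], supplies[m])
    obs_start = runs[0][0]

    obs_end = index_ord
    for i, (s, e) in enumerate(runs):
        nxt = runs[i + 1][0] if i + 1 < len(runs) else index_ord
        if nxt - e >= config.discontinuation_gap:
            obs_end = e
            break

    if obs_end <= obs_start:
        return None  # degenerate zero-length window; class skipped
    covered = 0
    for s, e in runs:
        if s >= obs_end:
            break
        covered += min(e, obs_end) - s
    return ClassPDC(
        drug_class=drug_class,
        observation_start=obs_start,
        observation_end=obs_end,
        covered_days=covered,
        pdc=covered / (obs_end - obs_start),
    )


def assess_adherence(
    scripts: pd.DataFrame,
    regimen_classes: Sequence[str],
    index_ord: int,
    config: StudyConfig,
    patient_id: str = "",
) -> AdherenceResult:
    """Mean proxy adherence over the regimen's classes at an index date.

    Classes with no script in the lookback are skipped; the mean runs
    over assessed classes only.  With every class skipped the result is
    flagged not assessable (the candidate cannot enter the case
    definition).  When ``config.adherence_threshold`` is ``None`` the
    requirement is disabled: the result is treated as adherent without
    assessment.
    """
    dates_ord = _to_ordinals(scripts["issue_date"])
    cls_arr = scripts["drug_class"].to_numpy()
    sup_arr = scripts["days_supply"].to_numpy()

    per_class: dict[str, ClassPDC] = {}
    for cls in sorted(regimen_classes):
        m = cls_arr == cls
        res = compute_class_pdc(dates_ord[m], sup_arr[m], index_ord, config, cls)
        if res is not None:
            per_class[cls] = res

    assessable = bool(per_class)
    mean_pdc = (
        float(np.mean([c.pdc for c in per_class.values()])) if assessable else None
    )
    if config.adherence_threshold is None:
        return AdherenceResult(patient_id, index_ord, per_class, mean_pdc,
                               adherent=True, assessed=False,
                               assessable=assessable)
    if not assessable:
        return AdherenceResult(patient_id, index_ord, per_class, None,
                               adherent=False, assessed=False, assessable=False)
    return AdherenceResult(
        patient_id, index_ord, per_class, mean_pdc,
        adherent=bool(mean_pdc >= config.adherence_threshold),
        assessed=True, assessable=True,
    )
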