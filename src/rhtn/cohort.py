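"""Cohort eligibility, person-time, annual rates, and direct age
standardisation.

Eligibility for a patient begins on the latest of: the 18th birthday, the
practice up-to-standard date plus one year, the registration date plus
one year, and the hypertension diagnosis date.  It ends on the earliest
of death, transfer out, the practice's last collection date, and the
study end.  Patients enter the treated-hypertension cohort from the later
of eligibility start and their first antihypertensive script.

Incidence: new cases per 100 person-years at risk (time before any index
date).  Prevalence: existing cases per 100 treated-hypertension patients
still eligible at the 31 December snapshot.  Crude confidence intervals
use exact Poisson (Garwood) limits; directly standardised rates weight
age-specific rates by a fixed standard population, with a weighted-
Poisson variance approximation for the interval.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rhtn.config import StudyConfig
from rhtn.regimen import _to_ordinals

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


def eligibility_windows(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-patient eligibility window and treated-cohort entry.

    Returns a frame indexed like ``patients`` with ordinal-day columns
    ``start``, ``end``, ``treated_start`` and a boolean ``included``
    (hypertension diagnosis present and treated time before the end).
    ``end`` is exclusive: the day after the last eligible day.
    """
    birth = pd.to_datetime(patients["birth_date"])
    eighteenth = birth + pd.DateOffset(years=18)
    uts1 = pd.to_datetime(patients["practice_uts_date"]) + pd.Timedelta(days=365)
    reg1 = pd.to_datetime(patients["registration_date"]) + pd.Timedelta(days=365)
    diag = pd.to_datetime(patients["htn_diagnosis_date"])

    start = pd.concat([eighteenth, uts1, reg1, diag], axis=1).max(axis=1)

    study_end = pd.Timestamp(config.study_end)
    end_candidates = pd.concat(
        [
            pd.to_datetime(patients["death_date"]),
            pd.to_datetime(patients["transfer_out_date"]),
            pd.to_datetime(patients["last_collection_date"]),
            pd.Series(study_end, index=patients.index),
        ],
        axis=1,
    )
    end = end_candidates.min(axis=1)

    first_rx = (
        prescriptions.groupby("patient_id")["issue_date"].min()
        if len(prescriptions)
        else pd.Series(dtype="datetime64[ns]")
    )
    first_rx = patients["patient_id"].map(first_rx)

    treated_start = pd.concat([start, pd.to_datetime(first_rx)], axis=1).max(axis=1)

    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "sex": patients["sex"].to_numpy(),
            "birth_ord": _to_ordinals(birth),
            "start": _to_ordinals(start),
            # end is the day AFTER the last eligible day (half-open window)
            "end": _to_ordinals(end) + 1,
            "treated_start": _to_ordinals(treated_start),
            "death_ord": np.where(
                patients["death_date"].notna(),
                _to_ordinals(pd.to_datetime(patients["death_date"]).fillna(study_end)),
                np.iinfo(np.int64).max,
            ),
        }
    )
    has_rx = first_rx.notna().to_numpy()
    out["included"] = (
        diag.notna().to_numpy()
        & has_rx
        & (out["treated_start"] < out["end"])
        & (out["treated_start"] <= dt.date.toordinal(config.study_end))
    )
    return out


def _year_bounds(year: int) -> tuple[int, int]:
    return dt.date(year, 1, 1).toordinal(), dt.date(year + 1, 1, 1).toordinal()


def person_years_at_risk(
    windows: pd.DataFrame,
    cases: pd.DataFrame,
    year: int,
) -> pd.Series:
    """Person-years each patient contributes to the at-risk denominator
    in ``year``: overlap of ``[treated_start, min(end, index))`` with the
    calendar year, in days / 365.25.  Patients rejected for poor adherence
    are not cases and therefore keep contributing in full."""
    y0, y1 = _year_bounds(year)
    w = windows[windows["included"]]
    stop = w["end"].to_numpy().copy()
    if len(cases):
        idx = w["patient_id"].map(
            cases.set_index("patient_id")["index_ord"]
        ).to_numpy()
        stop = np.fmin(stop, np.where(np.isnan(idx), np.inf, idx))
    lo = np.maximum(w["treated_start"].to_numpy(), y0)
    hi = np.minimum(stop, y1)
    days = np.clip(hi - lo, 0, None)
    return pd.Series(days / DAYS_PER_YEAR, index=w["patient_id"].to_numpy())


def crude_rate_ci(
    count: int, denom: float, per: float = 100.0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Crude rate per ``per`` with exact Poisson (Garwood) limits."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    rate = per * count / denom
    lo = 0.0 if count == 0 else per * stats.chi2.ppf(alpha / 2, 2 * count) / 2 / denom
    hi = per * stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2 / denom
    return rate, lo, hi


def annual_incidence(
    cases: pd.DataFrame,
    windows: pd.DataFrame,
    years: Sequence[int],
) -> pd.DataFrame:
    """Crude annual incidence rows: new cases per 100 person-years."""
    rows = []
    idx_year = (
        pd.Series(
            [dt.date.fromordinal(int(o)).year for o in cases["index_ord"]],
            index=cases.index,
        )
        if len(cases)
        else pd.Series(dtype=int)
    )
    for year in years:
        py = float(person_years_at_risk(windows, cases, year).sum())
        n = int((idx_year == year).sum())
        if py <= 0:
            warnings.warn(f"year {year}: zero person-years, row omitted")
            continue
        rate, lo, hi = crude_rate_ci(n, py)
        rows.append(
            {"year": year, "numerator": n, "denominator": py,
             "crude_rate": rate, "crude_lo": lo, "crude_hi": hi}
        )
    return pd.DataFrame(rows)


def prevalence_snapshot(
    cases: pd.DataFrame,
    windows: pd.DataFrame,
    year: int,
    config: StudyConfig,
) -> tuple[pd.Series, pd.Series]:
    """Boolean masks over ``windows`` rows: (prevalent case, in
    denominator) at the 31 December snapshot of ``year``.

    The snapshot day itself counts as eligible (closed upper bound);
    elsewhere windows are half-open.
    """
    snap = dt.date(year, 12, 31).toordinal()
    w = windows
    # end is exclusive; end == snap + 1 means the last eligible day IS the
    # snapshot, which counts (closed upper bound at year end)
    eligible = (
        w["included"].to_numpy()
        & (w["treated_start"] <= snap)
        & (w["end"] >= snap + 1)
    )
    alive = w["death_ord"].to_numpy() > snap
    if config.prevalence_requires_eligibility:
        denom = eligible
    else:
        denom = w["included"].to_numpy() & (w["treated_start"] <= snap) & alive
    if len(cases):
        idx = w["patient_id"].map(cases.set_index("patient_id")["index_ord"])
        is_case = idx.notna().to_numpy() & (idx.fillna(np.inf).to_numpy() <= snap)
    else:
        is_case = np.zeros(len(w), dtype=bool)
    numer = denom & alive & is_case
    return pd.Series(numer, index=w.index), pd.Series(denom, index=w.index)


def annual_prevalence(
    cases: pd.DataFrame,
    windows: pd.DataFrame,
    years: Sequence[int],
    config: StudyConfig,
) -> pd.DataFrame:
    """Crude annual prevalence rows: existing cases per 100 eligible
    treated-hypertension patients on 31 December."""
    rows = []
    for year in years:
        numer, denom = prevalence_snapshot(cases, windows, year, config)
        n, d = int(numer.sum()), int(denom.sum())
        if d <= 0:
            warnings.warn(f"year {year}: empty prevalence denominator, row omitted")
            continue
        rate, lo, hi = crude_rate_ci(n, d)
        rows.append(
            {"year": year, "numerator": n, "denominator": d,
             "crude_rate": rate, "crude_lo": lo, "crude_hi": hi}
        )
    return pd.DataFrame(rows)


def _age_at(birth_ord: np.ndarray, day: int) -> np.ndarray:
    """Age in whole years at an ordinal day (365.25-day years, floor)."""
    return np.floor((day - birth_ord) / DAYS_PER_YEAR).astype(int)


def stratified_rates(
    cases: pd.DataFrame,
    windows: pd.DataFrame,
    year: int,
    config: StudyConfig,
    kind: str = "incidence",
    by: Sequence[str] = ("age_band",),
) -> pd.DataFrame:
    """Numerators and denominators partitioned by age band and/or sex.

    For incidence the stratifying age is the age at 1 July of the year
    (person-time and incident cases use the same rule, so strata sum
    exactly to the totals); for prevalence, the age at the 31 December
    snapshot.
    """
    if kind not in ("incidence", "prevalence"):
        raise ValueError("kind must be 'incidence' or 'prevalence'")
    for b in by:
        if b not in ("age_band", "sex"):
            raise ValueError(f"cannot stratify by {b!r}")

    w = windows
    if kind == "incidence":
        ref_day = dt.date(year, 7, 1).toordinal()
        py = person_years_at_risk(w, cases, year)
        contrib = w[w["included"]].copy()
        contrib["denom_value"] = py.to_numpy()
        idx_map = (
            cases.set_index("patient_id")["index_ord"] if len(cases)
            else pd.Series(dtype=float)
        )
        idx = contrib["patient_id"].map(idx_map)
        y0, y1 = _year_bounds(year)
        contrib["numer_value"] = (
            idx.notna() & (idx >= y0) & (idx < y1)
        ).astype(int)
    else:
        ref_day = dt.date(year, 12, 31).toordinal()
        numer, denom = prevalence_snapshot(cases, w, year, config)
        contrib = w.copy()
        contrib["denom_value"] = denom.astype(float).to_numpy()
        contrib["numer_value"] = numer.astype(int).to_numpy()
        contrib = contrib[contrib["denom_value"] > 0]

    age = _age_at(contrib["birth_ord"].to_numpy(), ref_day)
    contrib = contrib.assign(
        age_band=[config.age_band_label(max(a, 18)) for a in age]
    )
    keys = list(by) if by else ["overall"]
    if not by:
        contrib = contrib.assign(overall="all")
    grouped = (
        contrib.groupby(keys, observed=True)[["numer_value", "denom_value"]]
        .sum()
        .reset_index()
        .rename(columns={"numer_value": "numerator", "denom_value": "denominator"})
    )
    grouped["rate"] = np.where(
        grouped["denominator"] > 0,
        100.0 * grouped["numerator"] / grouped["denominator"],
        0.0,
    )
    grouped["year"] = year
    return grouped


def standard_population(
    cases: pd.DataFrame,
    windows: pd.DataFrame,
    config: StudyConfig,
    kind: str = "incidence",
) -> pd.DataFrame:
    """Age-band weights from the standard year's hypertensive cohort:
    person-time (incidence) or persons (prevalence) per band."""
    strat = stratified_rates(
        cases, windows, config.standard_population_year, config, kind=kind
    )
    return strat[["age_band", "denominator"]].rename(
        columns={"denominator": "weight"}
    )


def direct_standardise(
    stratum_rates: pd.DataFrame,
    standard: pd.DataFrame,
    per: float = 100.0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Directly standardised rate per ``per`` with a weighted-Poisson
    interval.

    ``stratum_rates`` needs columns ``age_band, numerator, denominator``;
    ``standard`` needs ``age_band, weight``.  The band sets must match
    exactly (a mismatch is a hard error); bands with an empty denominator
    contribute rate zero with a logged warning.
    """
    sr = stratum_rates.set_index("age_band")
    st = standard.set_index("age_band")
    if set(sr.index) != set(st.index):
        raise ValueError(
            f"age-band mismatch: rates have {sorted(sr.index)}, "
            f"standard has {sorted(st.index)}"
        )
    st = st.loc[sr.index]
    wts = st["weight"].to_numpy(dtype=float)
    W = wts.sum()
    if W <= 0:
        raise ValueError("standard population has no positive weight")
    events = sr["numerator"].to_numpy(dtype=float)
    denom = sr["denominator"].to_numpy(dtype=float)
    empty = denom <= 0
    if empty.any():
        logger.warning(
            "empty strata contribute rate 0: %s", list(sr.index[empty])
        )
    rates = np.where(empty, 0.0, events / np.where(empty, 1.0, denom))
    std_rate = float(np.sum(wts * rates) / W)
    # weighted-Poisson variance of the standardised rate
    var = float(
        np.sum(
            (wts / W) ** 2
            * np.where(empty, 0.0, events / np.where(empty, 1.0, denom) ** 2)
        )
    )
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    return per * std_rate, per * max(std_rate - z * se, 0.0), per * (std_rate + z * se)
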