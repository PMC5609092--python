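import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rhtn.config import StudyConfig


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


def make_scripts(rows):
    """rows: (patient_id, iso date or ordinal-offset day, class, supply)."""
    recs = []
    for pid, date, cls, supply in rows:
        if isinstance(date, int):
            date = dt.date(2000, 1, 1) + dt.timedelta(days=date)
        recs.append(
            {"patient_id": pid, "issue_date": pd.Timestamp(date),
             "drug_class": cls, "days_supply": supply}
        )
    return pd.DataFrame(
        recs, columns=["patient_id", "issue_date", "drug_class", "days_supply"]
    )


DAY0 = dt.date(2000, 1, 1).toordinal()


def day_grid_coverage(dates, supplies, horizon=None):
    """Brute-force stockpile simulation: one pill taken per covered day,
    leftover supply accumulates without cap.  Returns the set of covered
    ordinal days.  Independent oracle for interval-based coverage."""
    if len(dates) == 0:
        return set()
    dates = [int(d) for d in dates]
    supplies = [int(s) for s in supplies]
    start = min(dates)
    if horizon is None:
        horizon = max(dates) + sum(supplies) + 1
    by_day = {}
    for d, s in zip(dates, supplies):
        by_day[d] = by_day.get(d, 0) + s
    stock = 0
    covered = set()
    for day in range(start, horizon):
        stock += by_day.get(day, 0)
        if stock > 0:
            covered.add(day)
            stock -= 1
    return covered


def day_grid_pdc(dates, supplies, index_ord, lookback=365, gap=90):
    """Day-grid PDC oracle: covered-day set from in-window scripts, runs
    as maximal consecutive covered days, observation truncated at the
    first run whose end precedes the next covered day (or the index) by
    >= gap days."""
    lo = index_ord - lookback
    pairs = [(d, s) for d, s in zip(dates, supplies) if lo <= d < index_ord]
    if not pairs:
        return None
    covered = day_grid_coverage([p[0] for p in pairs], [p[1] for p in pairs])
    obs_start = min(p[0] for p in pairs)
    days = sorted(covered)
    # maximal consecutive runs
    runs = []
    s = e = days[0]
    for d in days[1:]:
        if d == e + 1:
            e = d
        else:
            runs.append((s, e + 1))
            s = e = d
    runs.append((s, e + 1))
    obs_end = index_ord
    for i, (rs, re) in enumerate(runs):
        nxt = runs[i + 1][0] if i + 1 < len(runs) else index_ord
        if nxt - re >= gap:
            obs_end = re
            break
    if obs_end <= obs_start:
        return None
    n_cov = len([d for d in covered if obs_start <= d < obs_end])
    return obs_start, obs_end, n_cov, n_cov / (obs_end - obs_start)


def random_script_scenario(rng, n_max=10, span=600, supply_max=60):
    n = int(rng.integers(1, n_max + 1))
    dates = np.sort(rng.integers(0, span, size=n)) + DAY0
    supplies = rng.integers(1, supply_max + 1, size=n)
    return dates, supplies
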