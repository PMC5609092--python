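"""Trend analysis: log-linear count models with interaction blocks, and a
segmented (joinpoint) log-linear fit with annual-percent-change output.

The count model is a Poisson regression of events on calendar year, sex,
and age band with a log person-time offset, fitted by iteratively
reweighted least squares; Wald tests on the year-by-sex and
year-by-age-band interaction blocks ask whether the effect of sex or age
varies over time.

The segmented fit is a deliberately simple joinpoint re-implementation:
a continuous piecewise-linear least-squares fit of log(rate) on year,
joinpoints restricted to observed years with at least two observations
per segment, and the number of joinpoints chosen by sequential
residual-permutation tests (Bonferroni-adjusted at alpha = 0.05).  Each
segment's slope beta is reported as an annual percent change,
APC = 100 * (exp(beta) - 1), with a t-based confidence interval.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclasses.dataclass
class WaldResult:
    term: str
    statistic: float
    df: int
    p_value: float


@dataclasses.dataclass
class TrendFit:
    params: pd.Series          # coefficients on the log scale
    bse: pd.Series             # standard errors
    rate_ratios: pd.DataFrame  # columns: rr, lo, hi
    wald: dict[str, WaldResult]
    deviance: float
    model: object = dataclasses.field(repr=False, default=None)


def fit_count_trend(
    data: pd.DataFrame,
    interactions: Sequence[str] = ("year:sex", "year:age_band"),
    year_as_factor: bool = True,
) -> TrendFit:
    """Poisson trend model for stratified event counts.

    ``data`` needs columns ``events`` (non-negative integers),
    ``person_time`` (positive; zero-exposure cells are dropped), and the
    covariates ``year`` plus any of ``sex``/``age_band`` referenced by
    the requested interaction blocks.  Calendar year enters as a
    categorical factor by default (a linear-year variant via
    ``year_as_factor=False``).
    """
    d = data.copy()
    d = d[d["person_time"] > 0]
    if (d["events"] < 0).any():
        raise ValueError("negative event counts")
    if len(d) == 0:
        raise ValueError("no cells with positive person-time")

    year_term = "C(year)" if year_as_factor else "year"
    terms = [year_term]
    # main effects for every stratifying covariate present in the data
    for c in ("sex", "age_band"):
        if c in d.columns:
            terms.append(f"C({c})")
    for inter in interactions:
        a, b = inter.split(":")
        ta = year_term if a == "year" else f"C({a})"
        tb = year_term if b == "year" else f"C({b})"
        terms.append(f"{ta}:{tb}")
    formula = "events ~ " + " + ".join(terms)

    model = smf.glm(
        formula,
        data=d,
        family=sm.families.Poisson(),
        offset=np.log(d["person_time"].to_numpy(dtype=float)),
    )
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - surfaced with context
        raise RuntimeError(f"Poisson trend model failed to converge: {exc}")
    if not res.converged:
        raise RuntimeError("Poisson trend model did not converge")

    z = stats.norm.ppf(0.975)
    rr = pd.DataFrame(
        {
            "rr": np.exp(res.params),
            "lo": np.exp(res.params - z * res.bse),
            "hi": np.exp(res.params + z * res.bse),
        }
    )

    wald: dict[str, WaldResult] = {}
    for inter in interactions:
        a, b = inter.split(":")
        ta = year_term if a == "year" else f"C({a})"
        tb = year_term if b == "year" else f"C({b})"
        block = f"{ta}:{tb}"
        names = [p for p in res.params.index if _is_block_param(p, block)]
        if not names:
            continue
        contrast = np.zeros((len(names), len(res.params)))
        for i, nm in enumerate(names):
            contrast[i, list(res.params.index).index(nm)] = 1.0
        wt = res.wald_test(contrast, scalar=True)
        wald[inter] = WaldResult(
            term=inter,
            statistic=float(wt.statistic),
            df=len(names),
            p_value=float(wt.pvalue),
        )

    return TrendFit(
        params=res.params, bse=res.bse, rate_ratios=rr, wald=wald,
        deviance=float(res.deviance), model=res,
    )


def _is_block_param(name: str, block: str) -> bool:
    """Does a patsy parameter name (e.g. ``C(year)[T.1997]:C(sex)[T.male]``)
    belong to an interaction block (e.g. ``C(year):C(sex)``)?"""
    if ":" not in name:
        return False
    parts = name.split(":")
    want = block.split(":")
    if len(parts) != len(want):
        return False
    return all(p.split("[")[0] == w for p, w in zip(parts, want))


# ---------------------------------------------------------------------------
# segmented (joinpoint) trend


@dataclasses.dataclass
class Segment:
    start_year: float
    end_year: float
    slope: float
    slope_se: float
    apc: float
    apc_lo: float
    apc_hi: float


@dataclasses.dataclass
class SegmentedTrend:
    joinpoints: list[float]
    segments: list[Segment]
    rss: float
    n_points: int
    permutation_p: list[float]  # p-value of each sequential test performed

    def predict(self, years: np.ndarray) -> np.ndarray:
        """Fitted log-rate at ``years`` (continuous piecewise line)."""
        X = _design(np.asarray(years, dtype=float), self.joinpoints)
        return X @ self._beta

    _beta: np.ndarray = dataclasses.field(default=None, repr=False)


def _design(x: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in taus:
        cols.append(np.clip(x - t, 0.0, None))
    return np.column_stack(cols)


def _fit_taus(x: np.ndarray, y: np.ndarray, taus: Sequence[float]):
    X = _design(x, taus)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), X


def _best_fit(x: np.ndarray, y: np.ndarray, k: int, min_per_segment: int = 2):
    """Grid search over joinpoint placements at observed years; returns
    (taus, beta, rss, X) of the minimum-RSS continuous fit."""
    if k == 0:
        beta, rss, X = _fit_taus(x, y, ())
        return (), beta, rss, X
    n = len(x)
    best = None
    # candidate indices leave >= min_per_segment points in every segment
    # (the shared knot year counts for both adjoining segments)
    for idxs in itertools.combinations(range(min_per_segment - 1,
                                             n - min_per_segment + 1), k):
        ok = all(
            idxs[j + 1] - idxs[j] >= min_per_segment - 1
            for j in range(len(idxs) - 1)
        )
        if not ok:
            continue
        taus = tuple(x[i] for i in idxs)
        beta, rss, X = _fit_taus(x, y, taus)
        if best is None or rss < best[2] - 1e-12:
            best = (taus, beta, rss, X)
    if best is None:
        raise ValueError(f"too few points ({n}) for {k} joinpoint(s)")
    return best


def fit_segmented_trend(
    years: Sequence[float],
    rates: Sequence[float],
    max_joinpoints: int = 2,
    n_permutations: int = 499,
    seed: int = 0,
    alpha: float = 0.05,
) -> SegmentedTrend:
    """Fit a continuous piecewise log-linear trend to an annual rate
    series and report per-segment annual percent changes.

    The number of joinpoints is selected by sequential permutation tests
    of k vs k+1 joinpoints: residuals of the null (k-joinpoint) fit are
    permuted, both models refitted, and the improvement statistic
    compared; the k+1 model is accepted when p < alpha / max_joinpoints
    (Bonferroni over the sequence).  Deterministic given ``seed``.
    """
    x = np.asarray(years, dtype=float)
    y_rates = np.asarray(rates, dtype=float)
    if np.any(y_rates <= 0):
        raise ValueError("rates must be strictly positive for a log-linear fit")
    if len(x) < 2 * (max_joinpoints + 1):
        raise ValueError(
            f"need at least {2 * (max_joinpoints + 1)} points for "
            f"max_joinpoints={max_joinpoints}"
        )
    order = np.argsort(x)
    x, y = x[order], np.log(y_rates[order])
    rng = np.random.default_rng(seed)

    k = 0
    taus, beta, rss, X = _best_fit(x, y, 0)
    pvals: list[float] = []
    while k < max_joinpoints:
        taus1, beta1, rss1, X1 = _best_fit(x, y, k + 1)
        if rss < 1e-12:
            # the null fit is already exact; no evidence for more turns
            pvals.append(1.0)
            break
        stat = (rss - rss1) / rss1
        fitted0 = X @ beta
        resid0 = y - fitted0
        exceed = 0
        for _ in range(n_permutations):
            y_star = fitted0 + rng.permutation(resid0)
            _, _, rss0_s, _ = _best_fit(x, y_star, k)
            _, _, rss1_s, _ = _best_fit(x, y_star, k + 1)
            if rss1_s < 1e-300:
                stat_s = np.inf
            else:
                stat_s = (rss0_s - rss1_s) / rss1_s
            if stat_s >= stat:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        pvals.append(p)
        if p < alpha / max_joinpoints:
            k += 1
            taus, beta, rss, X = taus1, beta1, rss1, X1
        else:
            break

    # per-segment slopes: slope_j = beta1 + sum of the first j bend terms
    n, p_dim = X.shape
    dof = max(n - p_dim, 1)
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2 * XtX_inv
    tcrit = stats.t.ppf(1 - 0.025, dof)

    bounds = [x[0], *taus, x[-1]]
    segments: list[Segment] = []
    for j in range(len(taus) + 1):
        a = np.zeros(p_dim)
        a[1] = 1.0
        for i in range(j):
            a[2 + i] = 1.0
        slope = float(a @ beta)
        se = float(np.sqrt(max(a @ cov @ a, 0.0)))
        apc = 100.0 * (np.exp(slope) - 1.0)
        lo = 100.0 * (np.exp(slope - tcrit * se) - 1.0)
        hi = 100.0 * (np.exp(slope + tcrit * se) - 1.0)
        segments.append(
            Segment(bounds[j], bounds[j + 1], slope, se, apc, lo, hi)
        )

    out = SegmentedTrend(
        joinpoints=list(taus),
        segments=segments,
        rss=rss,
        n_points=n,
        permutation_p=pvals,
    )
    out._beta = beta
    return out
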