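import datetime as dt

import numpy as np
import pandas as pd
import pytest

import rhtn
from rhtn.cohort import (
    DAYS_PER_YEAR,
    annual_incidence,
    annual_prevalence,
    crude_rate_ci,
    direct_standardise,
    eligibility_windows,
    person_years_at_risk,
    standard_population,
    stratified_rates,
)
from rhtn.datasets import uk_cohort_annual_counts
from rhtn.simulate import get_preset, simulate


def one_patient(diag="2000-06-01", death=None, transfer=None):
    return pd.DataFrame(
        [{
            "patient_id": "P1", "sex": "female",
            "birth_date": pd.Timestamp("1950-01-01"),
            "death_date": pd.Timestamp(death) if death else pd.NaT,
            "registration_date": pd.Timestamp("1990-01-01"),
            "practice_uts_date": pd.Timestamp("1989-01-01"),
            "transfer_out_date": pd.Timestamp(transfer) if transfer else pd.NaT,
            "last_collection_date": pd.Timestamp("2015-12-31"),
            "htn_diagnosis_date": pd.Timestamp(diag) if diag else pd.NaT,
        }]
    )


def rx_for(pid="P1", date="2000-07-01"):
    return pd.DataFrame(
        [{"patient_id": pid, "issue_date": pd.Timestamp(date),
          "drug_class": "ace_inhibitor", "days_supply": 28}]
    )


class TestEligibility:
    def test_start_is_latest_of_four_candidates(self, config):
        w = eligibility_windows(one_patient(), rx_for(), config)
        assert w.loc[0, "start"] == dt.date(2000, 6, 1).toordinal()  # diagnosis

    def test_registration_plus_year_can_dominate(self, config):
        p = one_patient(diag="1990-06-01")
        p.loc[0, "registration_date"] = pd.Timestamp("1995-01-01")
        w = eligibility_windows(p, rx_for(), config)
        assert w.loc[0, "start"] == (
            dt.date(1995, 1, 1).toordinal() + 365
        )

    def test_no_diagnosis_excludes_patient(self, config):
        w = eligibility_windows(one_patient(diag=None), rx_for(), config)
        assert not bool(w.loc[0, "included"])

    def test_end_is_earliest_exit(self, config):
        w = eligibility_windows(
            one_patient(death="2010-03-03", transfer="2012-01-01"),
            rx_for(), config,
        )
        assert w.loc[0, "end"] == dt.date(2010, 3, 3).toordinal() + 1


class TestPersonYears:
    def test_full_year_noncase(self, config):
        w = eligibility_windows(one_patient(diag="2000-06-01"), rx_for(), config)
        py = person_years_at_risk(w, pd.DataFrame(), 2005)
        assert py.sum() == pytest.approx(365 / DAYS_PER_YEAR)

    def test_case_stops_contributing_at_index(self, config):
        w = eligibility_windows(one_patient(), rx_for(), config)
        cases = pd.DataFrame(
            [{"patient_id": "P1",
              "index_ord": dt.date(2005, 7, 1).toordinal()}]
        )
        py = person_years_at_risk(w, cases, 2005)
        expected = (dt.date(2005, 7, 1).toordinal()
                    - dt.date(2005, 1, 1).toordinal()) / DAYS_PER_YEAR
        assert py.sum() == pytest.approx(expected)
        assert person_years_at_risk(w, cases, 2006).sum() == 0.0

    def test_never_after_own_index(self, config):
        p = get_preset("clean").model_copy(update={"n_patients": 150, "seed": 9})
        pat, rx, bp, _ = simulate(p)
        cfg = p.study_config()
        w = eligibility_windows(pat, rx, cfg)
        cases, _ = rhtn.ascertain(pat, rx, bp, cfg)
        idx = cases.set_index("patient_id")["index_ord"]
        for year in (2000, 2008, 2015):
            py = person_years_at_risk(w, cases, year)
            y0 = dt.date(year, 1, 1).toordinal()
            for pid, t in idx.items():
                if t <= y0:
                    assert py.get(pid, 0.0) == 0.0


class TestWorkedExampleRates:
    """The published annual counts table reproduces its printed crude
    rates when fed through the crude-rate operation."""

    @pytest.mark.parametrize(
        "year,expected",
        [(1996, 0.96), (2004, 2.14)],
    )
    def test_crude_incidence(self, year, expected):
        t = uk_cohort_annual_counts().set_index("year")
        rate, lo, hi = crude_rate_ci(
            int(t.loc[year, "incident_cases"]), float(t.loc[year, "person_years"])
        )
        assert round(rate, 2) == expected
        assert lo <= rate <= hi

    @pytest.mark.parametrize(
        "year,expected",
        [(1995, 1.82), (2007, 8.20), (2015, 7.08)],
    )
    def test_crude_prevalence(self, year, expected):
        t = uk_cohort_annual_counts().set_index("year")
        rate, _, _ = crude_rate_ci(
            int(t.loc[year, "prevalent_cases"]),
            float(t.loc[year, "prevalent_denominator"]),
        )
        assert round(rate, 2) == expected

    def test_total_incident_cases(self):
        t = uk_cohort_annual_counts()
        assert int(t["incident_cases"].sum()) == 90973

    def test_zero_cases_zero_rate(self):
        rate, lo, hi = crude_rate_ci(0, 1000.0)
        assert rate == 0.0 and lo == 0.0 and hi > 0


class TestStandardisation:
    def test_equal_stratum_rates_return_that_rate_for_any_weights(self):
        rng = np.random.default_rng(0)
        bands = ["18-39", "40-64", "65+"]
        for _ in range(20):
            w = rng.uniform(1, 100, size=3)
            denom = rng.uniform(100, 1000, size=3)
            r = rng.uniform(0.001, 0.05)
            strat = pd.DataFrame(
                {"age_band": bands, "numerator": r * denom, "denominator": denom}
            )
            std = pd.DataFrame({"age_band": bands, "weight": w})
            rate, lo, hi = direct_standardise(strat, std)
            assert rate == pytest.approx(100 * r)
            assert lo <= rate <= hi

    def test_two_band_arithmetic(self):
        strat = pd.DataFrame(
            {"age_band": ["a", "b"], "numerator": [1.0, 3.0],
             "denominator": [100.0, 100.0]}
        )
        std = pd.DataFrame({"age_band": ["a", "b"], "weight": [1.0, 1.0]})
        rate, _, _ = direct_standardise(strat, std)
        assert rate == pytest.approx(2.0)

    def test_band_mismatch_is_hard_error(self):
        strat = pd.DataFrame(
            {"age_band": ["a"], "numerator": [1.0], "denominator": [10.0]}
        )
        std = pd.DataFrame({"age_band": ["b"], "weight": [1.0]})
        with pytest.raises(ValueError, match="mismatch"):
            direct_standardise(strat, std)

    def test_standardising_the_standard_year_recovers_the_crude_rate(self, config):
        """Weights equal to the year's own denominators make the
        standardised rate algebraically equal to the crude rate."""
        p = get_preset("clean").model_copy(update={"n_patients": 300, "seed": 21})
        pat, rx, bp, _ = simulate(p)
        cfg = p.study_config()
        w = eligibility_windows(pat, rx, cfg)
        cases, _ = rhtn.ascertain(pat, rx, bp, cfg)
        year = cfg.standard_population_year
        strat = stratified_rates(cases, w, year, cfg, kind="incidence")
        std = standard_population(cases, w, cfg, kind="incidence")
        rate, _, _ = direct_standardise(strat, std)
        inc = annual_incidence(cases, w, [year])
        assert rate == pytest.approx(float(inc["crude_rate"].iloc[0]))


class TestStratifiedConservation:
    def test_strata_partition_totals_every_year(self, config):
        p = get_preset("clean").model_copy(update={"n_patients": 400, "seed": 13})
        pat, rx, bp, _ = simulate(p)
        cfg = p.study_config()
        w = eligibility_windows(pat, rx, cfg)
        cases, _ = rhtn.ascertain(pat, rx, bp, cfg)
        years = range(1996, 2016)
        inc = annual_incidence(cases, w, years)
        prev = annual_prevalence(cases, w, years, cfg)
        for _, row in inc.iterrows():
            strat = stratified_rates(cases, w, int(row["year"]), cfg,
                                     kind="incidence", by=("age_band", "sex"))
            assert int(strat["numerator"].sum()) == int(row["numerator"])
            assert strat["denominator"].sum() == pytest.approx(
                row["denominator"], rel=1e-9
            )
        for _, row in prev.iterrows():
            strat = stratified_rates(cases, w, int(row["year"]), cfg,
                                     kind="prevalence", by=("age_band", "sex"))
            assert int(strat["numerator"].sum()) == int(row["numerator"])
            assert int(strat["denominator"].sum()) == int(row["denominator"])

    def test_single_stratum_equals_crude(self, config):
        p = get_preset("clean").model_copy(update={"n_patients": 100, "seed": 3})
        pat, rx, bp, _ = simulate(p)
        cfg = p.study_config()
        w = eligibility_windows(pat, rx, cfg)
        cases, _ = rhtn.ascertain(pat, rx, bp, cfg)
        strat = stratified_rates(cases, w, 2005, cfg, kind="incidence", by=())
        inc = annual_incidence(cases, w, [2005])
        assert float(strat["rate"].iloc[0]) == pytest.approx(
            float(inc["crude_rate"].iloc[0])
        )


def test_annual_case_counts_sum_to_total(config):
    p = get_preset("clean").model_copy(update={"n_patients": 400, "seed": 13})
    pat, rx, bp, _ = simulate(p)
    cfg = p.study_config()
    w = eligibility_windows(pat, rx, cfg)
    cases, _ = rhtn.ascertain(pat, rx, bp, cfg)
    inc = annual_incidence(cases, w, range(1995, 2016))
    assert int(inc["numerator"].sum()) == len(cases)
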