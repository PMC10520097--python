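"""Cohort engine: event order, conservation, aggregation and life expectancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1dsim.errors import CoverageError, UndefinedShareError, ValidationError
from t1dsim.markov import (CohortLedger, background_life_expectancy,
                           life_expectancy_at_onset, missing_prevalence,
                           mortality_shares, run_country, step_cohort)

from _oracles import microsim_country
from conftest import make_toy_inputs


class TestStepCohort:
    def test_zero_rates_leave_cohort_unchanged(self):
        inputs = make_toy_inputs()
        ledger = CohortLedger(birth_year=2000, size=1000.0, a_max=20)
        step_cohort(ledger, 0, 2000, inputs)
        assert ledger.alive_no_t1d[1] == 1000.0
        assert ledger.alive_diagnosed[1].sum() == 0.0
        assert ledger.state_total(1) == 1000.0

    def test_certain_death_absorbs_everyone(self):
        inputs = make_toy_inputs(incidence=500.0, q=1.0, smr=2.0, nondx=0.1)
        ledger = CohortLedger(birth_year=2000, size=1000.0, a_max=20)
        step_cohort(ledger, 0, 2000, inputs)
        assert ledger.alive_no_t1d[1] == 0.0
        assert ledger.alive_diagnosed[1].sum() == 0.0
        assert ledger.state_total(1) == pytest.approx(1000.0, rel=1e-12)

    def test_single_step_arithmetic_and_microsim_oracle(self):
        # cohort 1,000 at age 0: incidence 100/100k, nondx 0.2, q 0.005, SMR 3
        inputs = make_toy_inputs(incidence=100.0, q=0.005, smr=3.0, nondx=0.2)
        ledger = CohortLedger(birth_year=2000, size=1000.0, a_max=20)
        step_cohort(ledger, 0, 2000, inputs)
        q_t1d = 1.0 - (1.0 - 0.005) ** 3
        new_dx = 1000 * 0.001 * 0.8
        assert ledger.flow_deaths_after_dx[0] == pytest.approx(new_dx * q_t1d, rel=1e-12)
        assert ledger.alive_diagnosed[1].sum() == pytest.approx(new_dx * (1 - q_t1d), rel=1e-12)

        # per-individual simulation at n = 1e6 agrees within 3 binomial SE
        rng = np.random.default_rng(20240901)
        n = 1_000_000
        onsets = rng.binomial(n, 0.001)
        d_nondx = rng.binomial(onsets, 0.2)
        survivors = rng.binomial(onsets - d_nondx, 1 - q_t1d)
        expected = n * 0.001 * 0.8 * (1 - q_t1d)
        se = np.sqrt(n * 0.001 * 0.8 * (1 - q_t1d))
        assert abs(survivors - expected) < 3 * se

    def test_event_order_onset_before_background_death(self):
        # with q = 1 and SMR such that q_t1d < 1, onsets escape background
        # death and can survive the year as diagnosed
        with pytest.warns(UserWarning, match="SMR"):
            inputs = make_toy_inputs(incidence=10_000.0, q=0.9, smr=0.1)
        ledger = CohortLedger(birth_year=2000, size=1000.0, a_max=20)
        step_cohort(ledger, 0, 2000, inputs)
        assert ledger.alive_diagnosed[1].sum() > 0

    def test_missing_cell_names_country_age_year(self):
        inputs = make_toy_inputs(years=(2000, 2005))
        ledger = CohortLedger(birth_year=2004, size=10.0, a_max=20)
        step_cohort(ledger, 0, 2004, inputs)
        step_cohort(ledger, 1, 2005, inputs)
        with pytest.raises(CoverageError, match=r"toy.*age 2.*year 2006"):
            step_cohort(ledger, 2, 2006, inputs)

    @given(inc=st.floats(0, 5000), q=st.floats(0, 1), smr=st.floats(0, 10),
           nondx=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_conservation_property(self, inc, q, smr, nondx):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inputs = make_toy_inputs(incidence=inc, q=q, smr=smr, nondx=nondx,
                                     a_max=10)
        ledger = CohortLedger(birth_year=2000, size=1000.0, a_max=10)
        for age in range(11):
            step_cohort(ledger, age, 2000 + age, inputs)
        ledger.check_conservation(rtol=1e-9)
        for arr in (ledger.dead_onset_nondx, ledger.dead_after_dx,
                    ledger.dead_background):
            assert np.all(np.diff(arr[:ledger.ages_computed + 1]) >= -1e-12)


class TestRunCountry:
    def test_zero_incidence_means_zero_t1d_everything(self):
        inputs = make_toy_inputs(q=0.01, a_max=15, years=(1990, 2010))
        burden = run_country(inputs, 2006, 2010, a_max=15)
        assert np.all(burden.prevalence.values == 0)
        assert np.all(burden.deaths_onset_nondx.values == 0)
        assert np.all(burden.deaths_after_dx.values == 0)

    def test_deaths_decompose_cellwise(self, lmic_inputs):
        burden = run_country(lmic_inputs, 2019, 2021)
        summary = burden.summary_frame()
        # the three channels are the complete decomposition of deaths
        assert (summary.deaths_onset_nondx >= 0).all()
        assert (summary.deaths_after_dx >= summary.deaths_after_dx_excess).all()

    def test_stationary_inputs_match_analytic_profile(self):
        inputs = make_toy_inputs(incidence=200.0, q=0.01, smr=3.0, nondx=0.3,
                                 a_max=30, years=(1950, 2010))
        burden = run_country(inputs, 2000, 2005, a_max=30)
        # year-invariance
        assert np.allclose(burden.prevalence.values[:, 0:1],
                           burden.prevalence.values, rtol=1e-12)
        # closed-form single-cohort recursion in plain floats
        inc, q, smr, nd = 200.0 / 1e5, 0.01, 3.0, 0.3
        q_t1d = 1 - (1 - q) ** smr
        s, d = 1000.0, 0.0
        profile = []
        for age in range(31):
            qq = 1.0 if age == 30 else q
            qt = 1.0 if age == 30 else q_t1d
            onset = s * inc
            ndx = nd if age < 25 else 0.0
            new_dx = onset * (1 - ndx)
            s = (s - onset) * (1 - qq)
            d = (d + new_dx) * (1 - qt)
            profile.append(d)
        assert np.allclose(burden.prevalence.values[:, 0], profile, rtol=1e-9)

    def test_insufficient_history_names_earliest_birth_year(self):
        inputs = make_toy_inputs(years=(1990, 2010), a_max=30)
        with pytest.raises(CoverageError, match="1975"):
            run_country(inputs, 2005, 2010, a_max=30)

    def test_microsim_oracle_agreement(self):
        """Engine expectations match a per-individual stochastic simulation.

        Three populated cohorts, <= 20 ages, n = 1e5 per cohort; replicate
        means of every burden cell within 3 empirical standard errors.
        """
        from _oracles import microsim_mean_se
        from conftest import three_cohort_inputs
        inputs = three_cohort_inputs(incidence=800.0, q=0.02, smr=4.0,
                                     nondx=0.3, a_max=19, years=(1998, 2020))
        first, last = 2018, 2020
        burden = run_country(inputs, first, last, a_max=19)
        rng = np.random.default_rng(42)
        mean, se = microsim_mean_se(inputs, first, last, 19, rng, reps=50)
        for channel in mean:
            expected = getattr(burden, channel).values
            bound = 3 * se[channel] + 1e-6 * np.maximum(expected, 1.0)
            assert np.all(np.abs(mean[channel] - expected) <= bound), channel


class TestLifeExpectancy:
    def test_null_effect_reduces_to_background(self):
        inputs = make_toy_inputs(incidence=100.0, q=0.02, smr=1.0, nondx=0.0,
                                 a_max=40, years=(2000, 2050))
        le = life_expectancy_at_onset(inputs, 10, 2020)
        bg = background_life_expectancy(inputs, 10, 2020)
        assert le == pytest.approx(bg, abs=1e-9)

    def test_geometric_closed_form(self):
        # constant annual death probability 0.1, effectively unbounded ages
        inputs = make_toy_inputs(q=0.1, smr=1.0, a_max=400, years=(2000, 2001))
        le = life_expectancy_at_onset(inputs, 0, 2000, a_max=400)
        assert le == pytest.approx((1 - 0.1) / 0.1 + 0.5, abs=1e-6)

    def test_certain_nondx_death_gets_half_cycle(self):
        inputs = make_toy_inputs(q=0.01, smr=2.0, nondx=1.0, a_max=30,
                                 years=(2000, 2040))
        assert life_expectancy_at_onset(inputs, 5, 2010) == pytest.approx(0.5)

    def test_onset_beyond_terminal_age_rejected(self):
        inputs = make_toy_inputs(a_max=20)
        with pytest.raises(ValidationError):
            life_expectancy_at_onset(inputs, 25, 2000)

    def test_life_expectancy_non_increasing_in_smr(self):
        les = []
        for smr in (1.0, 2.0, 4.0, 8.0):
            inputs = make_toy_inputs(q=0.01, smr=smr, a_max=60, years=(2000, 2070))
            les.append(life_expectancy_at_onset(inputs, 10, 2010))
        assert all(a >= b for a, b in zip(les, les[1:]))


class TestMissingPrevalence:
    def test_zero_when_no_t1d_mortality_effect(self):
        inputs = make_toy_inputs(incidence=300.0, q=0.01, smr=1.0, nondx=0.0,
                                 a_max=15, years=(1990, 2010))
        assert missing_prevalence(inputs, 2008, a_max=15) == 0.0

    def test_single_cohort_brute_force(self):
        """Two hand-enumerated chains (factual vs counterfactual) at a_max=5."""
        inputs = make_toy_inputs(incidence=1000.0, q=0.05, smr=3.0, nondx=0.4,
                                 a_max=5, years=(2000, 2010))
        got = missing_prevalence(inputs, 2005, a_max=5)

        def chain(smr, nd):
            total = 0.0
            for birth in range(2000, 2006):
                age_at_2005 = 2005 - birth
                s, d = 1000.0, 0.0
                for age in range(age_at_2005 + 1):
                    q = 1.0 if age == 5 else 0.05
                    qt = 1.0 if age == 5 else 1 - (1 - 0.05) ** smr
                    onset = s * 0.01
                    new_dx = onset * (1 - nd)
                    s = (s - onset) * (1 - q)
                    d = (d + new_dx) * (1 - qt)
                total += d
            return total

        expected = chain(1.0, 0.0) - chain(3.0, 0.4)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_smr(self):
        vals = []
        for smr in (1.0, 2.0, 5.0):
            inputs = make_toy_inputs(incidence=300.0, q=0.02, smr=smr, nondx=0.2,
                                     a_max=12, years=(1995, 2010))
            vals.append(missing_prevalence(inputs, 2008, a_max=12))
        assert vals == sorted(vals)


class TestMortalityShares:
    @pytest.mark.parametrize("onset,after,expected", [
        (35_000, 140_000, (20, 80)),     # printed global decomposition
        (35_000, 17_600, (67, 33)),      # printed under-25 decomposition
        (0, 123.0, (0, 100)),
        (1, 1, (50, 50)),
    ])
    def test_share_pairs(self, onset, after, expected):
        assert mortality_shares(onset, after) == expected

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedShareError):
            mortality_shares(0.0, 0.0)

    def test_rounding_always_sums_to_100(self):
        for onset in range(0, 101, 7):
            shares = mortality_shares(onset, 100 - onset) if onset < 100 else (100, 0)
            assert sum(shares) == 100
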