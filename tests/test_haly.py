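"""Complication recursion, impermissible journeys and HALY decomposition."""

import numpy as np
import pytest
from scipy.special import logit

from t1dsim.errors import ParameterError, ValidationError
from t1dsim.haly import (COMPLICATIONS, ComplicationSpec, ImpermissibleJourney,
                         annual_hazard, default_registry,
                         disability_component, expected_disability,
                         halys_lost, prevalence_profile)
from t1dsim.mortality import CareLevel

from _oracles import enumerate_complication_paths
from conftest import make_toy_inputs


def spec(name="distal symmetric polyneuropathy", intercept=-4.0, b_h=0.0,
         b_d=0.0, weight=0.1):
    return ComplicationSpec(name, intercept, b_h, b_d, weight)


class TestAnnualHazard:
    def test_zero_coefficients_give_half(self):
        s = spec(intercept=0.0)
        assert annual_hazard(s, 8.0, 10) == pytest.approx(0.5)

    def test_logit_round_trip(self):
        s = spec(intercept=float(logit(0.02)))
        assert annual_hazard(s, 12.0, 25) == pytest.approx(0.02, rel=1e-12)

    def test_strictly_increasing_in_hba1c(self):
        s = spec(b_h=0.4)
        hazards = [annual_hazard(s, h, 5) for h in np.linspace(5, 15, 30)]
        assert np.all(np.diff(hazards) > 0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ParameterError):
            annual_hazard(spec(), 8.0, -1)


class TestPrevalenceProfile:
    def test_zero_hazards_stay_empty(self):
        registry = [spec(n, intercept=-50.0) for n in COMPLICATIONS[:3]]
        profile = prevalence_profile(registry, (), 9.0, 10)
        assert np.allclose(profile.marginals, 0.0, atol=1e-15)

    def test_single_complication_closed_form(self):
        # constant hazard 0.02 over 30 years: prevalence 1 - 0.98^30
        s = spec(intercept=float(logit(0.02)))
        profile = prevalence_profile([s], (), 8.0, 30)
        assert profile.marginals[30, 0] == pytest.approx(1 - 0.98 ** 30, rel=1e-12)

    def test_joint_sums_to_one_and_matches_marginal_recursions(self):
        registry = default_registry()
        profile = prevalence_profile(registry, (), 9.0, 15)
        assert np.allclose(profile.joint.sum(axis=1), 1.0, atol=1e-9)
        # with no journeys each marginal equals its own scalar recursion
        for c, s in enumerate(registry):
            p = 0.0
            for d in range(15):
                h = annual_hazard(s, 9.0, min(d, 30))
                p = p + (1 - p) * h
            assert profile.marginals[15, c] == pytest.approx(p, abs=1e-9)

    def test_blocked_journey_probability_is_exactly_zero(self):
        blind = spec("blindness", intercept=0.0, weight=0.2)           # hazard 0.5
        retino = spec("proliferative retinopathy", intercept=0.0)      # hazard 0.5
        journey = ImpermissibleJourney("blindness", "proliferative retinopathy")
        profile = prevalence_profile([blind, retino], [journey], 8.0, 6)
        # P(retinopathy de novo | already blind) = 0: the only path into
        # the joint state is acquiring both, or retinopathy first
        joint_both = profile.joint[:, 0b11]
        # brute-force enumeration agrees exactly
        dist = enumerate_complication_paths([blind, retino], [journey], 8.0, 6,
                                            annual_hazard)
        for d in range(7):
            assert profile.joint[d, 0b11] == pytest.approx(
                dist[d].get(frozenset({0, 1}), 0.0), abs=1e-12)
        # sanity: blocking reduces the both-complications mass
        free = prevalence_profile([blind, retino], (), 8.0, 6)
        assert joint_both[6] < free.joint[6, 0b11]

    def test_three_complications_four_years_match_enumeration(self):
        registry = [
            ComplicationSpec("blindness", logit(0.3), 0.0, 0.1, 0.19),
            ComplicationSpec("proliferative retinopathy", logit(0.2), 0.02, 0.0, 0.08),
            ComplicationSpec("overt nephropathy", logit(0.1), 0.01, 0.05, 0.10),
        ]
        journeys = [ImpermissibleJourney("blindness", "proliferative retinopathy")]
        profile = prevalence_profile(registry, journeys, 9.0, 4)
        dist = enumerate_complication_paths(registry, journeys, 9.0, 4,
                                            annual_hazard)
        for d in range(5):
            for state in range(8):
                key = frozenset(c for c in range(3) if state >> c & 1)
                assert profile.joint[d, state] == pytest.approx(
                    dist[d].get(key, 0.0), abs=1e-12)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ParameterError):
            prevalence_profile(default_registry(), (), 8.0, 0)


class TestDisability:
    def test_toy_expectation_arithmetic(self):
        # constant survival 10 years, one complication at probability 0.5,
        # weight 0.2 -> disability component 10 x 0.5 x 0.2 = 1.0
        py = np.ones(10)
        dis = np.full(10, 0.5 * 0.2)
        assert disability_component(py, dis) == pytest.approx(1.0)

    def test_multiplicative_combination_on_joint(self):
        a = spec("blindness", intercept=50.0, weight=0.5)    # certain each year
        b = spec("overt nephropathy", intercept=50.0, weight=0.5)
        profile = prevalence_profile([a, b], (), 8.0, 2)
        dis = expected_disability(profile, {"blindness": 0.5,
                                            "overt nephropathy": 0.5})
        # both certain from duration 1: combined weight 1 - 0.5^2 = 0.75
        assert dis[1] == pytest.approx(0.75, rel=1e-9)
        add = expected_disability(profile, {"blindness": 0.5,
                                            "overt nephropathy": 0.5},
                                  combine="additive_capped")
        assert add[1] == pytest.approx(1.0)


class TestHalysLost:
    def test_no_disease_effect_gives_zero_everything(self):
        inputs = make_toy_inputs(q=0.02, smr=1.0, a_max=30, years=(2000, 2040))
        registry = [ComplicationSpec(n, -50.0, 0.0, 0.0, 0.1) for n in COMPLICATIONS]
        # care level whose HbA1c maps to SMR 1
        result = halys_lost(inputs, 10, 2005, CareLevel("ideal", 6.0),
                            registry=registry,
                            knots=[(6.0, 1.0), (12.0, 1.0)])
        assert result.death == pytest.approx(0.0, abs=1e-9)
        assert result.disability == pytest.approx(0.0, abs=1e-9)
        assert result.total == pytest.approx(0.0, abs=1e-9)

    def test_full_disability_limit_matches_life_expectancy(self):
        inputs = make_toy_inputs(q=0.05, smr=1.0, a_max=25, years=(2000, 2040))
        registry = [ComplicationSpec("blindness", 50.0, 0.0, 0.0, 1.0)]
        result = halys_lost(inputs, 5, 2005, CareLevel("ideal", 6.0),
                            registry=registry, journeys=(),
                            knots=[(6.0, 1.0), (12.0, 1.0)])
        # complication certain from duration 1 with weight 1: everyone
        # disabled for every year after the first
        assert result.disability <= result.life_expectancy
        assert result.disability == pytest.approx(
            result.life_expectancy - 1.0, abs=0.05)

    def test_total_non_decreasing_in_hba1c(self):
        inputs = make_toy_inputs(q=0.01, smr=1.0, a_max=40, years=(2000, 2060))
        totals = [halys_lost(inputs, 10, 2010, CareLevel("x", h)).total
                  for h in (6.5, 8.0, 9.5, 11.0)]
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))
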