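"""Incidence building blocks: smoothing, APC curves, imputation, age shape."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1dsim.errors import FitError, ImputationError, ParameterError
from t1dsim.incidence import (CountryProfile, IncidenceObservation,
                              build_incidence_surface,
                              default_onset_distribution,
                              extrapolate_incidence, fit_apc_curves,
                              ratio_impute, smooth_series)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = pd.Series(5.0, index=range(2000, 2010))
        assert (smooth_series(s, 5) == 5.0).all()

    def test_linear_ramp_with_truncated_edges(self):
        s = pd.Series([1, 2, 3, 4, 5], index=range(5))
        out = smooth_series(s, 3)
        assert list(out) == [1.5, 2.0, 3.0, 4.0, 4.5]

    def test_window_one_is_identity(self):
        s = pd.Series([3.0, 1.0, 4.0], index=[1990, 1991, 1992])
        assert smooth_series(s, 1).equals(s)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_series(pd.Series([1.0]), 2)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=30),
           st.sampled_from([1, 3, 5, 7]))
    @settings(max_examples=60, deadline=None)
    def test_never_widens_range(self, values, window):
        s = pd.Series(values)
        out = smooth_series(s, window)
        assert out.min() >= s.min() - 1e-9
        assert out.max() <= s.max() + 1e-9


def _constant_growth_obs(n_countries=6, growth=0.03, years=(1985, 2015),
                         region="Europe and Central Asia"):
    rng = np.random.default_rng(7)
    obs = []
    for c in range(n_countries):
        base = rng.uniform(5, 30)
        for y in range(years[0], years[1] + 1):
            obs.append(IncidenceObservation(
                f"c{c}", region, y, 0, 14, base * (1 + growth) ** (y - years[0])))
    return obs


class TestAPCCurves:
    def test_constant_series_give_zero_apc(self):
        obs = []
        for c in range(3):
            for y in range(1990, 2001):
                obs.append(IncidenceObservation(f"c{c}", "South Asia", y, 0, 14, 10.0))
        g, _ = fit_apc_curves(obs)
        for year in (1985, 1995, 2015):
            assert g.apc_at(year) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constant_growth_within_tenth_point(self):
        g, _ = fit_apc_curves(_constant_growth_obs(growth=0.03))
        for year in range(1985, 2016):
            assert g.apc_at(year) == pytest.approx(3.0, abs=0.1)

    def test_region_without_data_falls_back_to_global(self):
        obs = _constant_growth_obs(region="Europe and Central Asia")
        obs += [IncidenceObservation("x0", "South Asia", 2000, 0, 14, 5.0)]
        g, regional = fit_apc_curves(obs)
        assert not regional["Europe and Central Asia"].fallback
        assert regional["South Asia"].fallback
        assert regional["South Asia"].apc_at(1999) == g.apc_at(1999)

    def test_insufficient_data_raises(self):
        obs = [IncidenceObservation("a", "South Asia", 2000, 0, 14, 5.0),
               IncidenceObservation("b", "South Asia", 2001, 0, 14, 6.0)]
        with pytest.raises(FitError):
            fit_apc_curves(obs)


class TestExtrapolation:
    def anchor(self, rate=10.0, year=2000):
        return IncidenceObservation("a", "South Asia", year, 0, 14, rate)

    def flat_curve(self, pct):
        from t1dsim.incidence import APCCurve
        return APCCurve("global", (1985, 2015), slope=0.0, intercept=pct)

    def test_zero_apc_is_constant(self):
        out = extrapolate_incidence(self.anchor(), self.flat_curve(0.0),
                                    range(1990, 2011))
        assert np.allclose(out, 10.0)

    def test_compound_growth_closed_form(self):
        out = extrapolate_incidence(self.anchor(), self.flat_curve(7.0),
                                    range(2000, 2011))
        assert out[2010] == pytest.approx(10 * 1.07 ** 10, rel=1e-12)

    def test_pre_floor_years_hold_floor_value(self):
        out = extrapolate_incidence(self.anchor(), self.flat_curve(5.0),
                                    range(1970, 2001))
        assert np.allclose(out.loc[1970:1974], out[1975])

    def test_forward_backward_round_trip(self):
        curve = self.flat_curve(4.2)
        fwd = extrapolate_incidence(self.anchor(), curve, range(2000, 2021))
        anchor2 = IncidenceObservation("a", "South Asia", 2020, 0, 14, fwd[2020])
        back = extrapolate_incidence(anchor2, curve, range(2000, 2021))
        assert back[2000] == pytest.approx(10.0, rel=1e-12)

    def test_nonpositive_anchor_rejected(self):
        with pytest.raises(ParameterError):
            extrapolate_incidence(self.anchor(rate=0.0), self.flat_curve(1.0),
                                  range(2000, 2005))


class TestRatioImpute:
    def prof(self, cid, region="South Asia", income="LMIC"):
        return CountryProfile(cid, region, income)

    def series(self, value, years=range(2000, 2006)):
        return pd.Series(float(value), index=list(years))

    def test_identical_single_donor_returned_unchanged(self):
        donor = (self.prof("d1"), self.series(12.0))
        out = ratio_impute(self.prof("t"), [donor])
        assert np.allclose(out, 12.0)

    def test_two_constant_donors_give_arithmetic_median(self):
        donors = [(self.prof("d1"), self.series(10.0)),
                  (self.prof("d2"), self.series(30.0))]
        out = ratio_impute(self.prof("t"), donors)
        assert np.allclose(out, 20.0)

    def test_duplicate_donor_countries_deduplicated(self):
        donors = [(self.prof("d1"), self.series(10.0)),
                  (self.prof("d2"), self.series(30.0)),
                  (self.prof("d2"), self.series(30.0))]
        out = ratio_impute(self.prof("t"), donors)
        assert np.allclose(out, 20.0)

    def test_stratum_widens_region_then_global(self):
        donors = [(self.prof("d1", region="Sub-Saharan Africa", income="LIC"),
                   self.series(8.0))]
        out = ratio_impute(self.prof("t"), donors)  # no regional match at all
        assert np.allclose(out, 8.0)

    def test_no_donors_raises(self):
        with pytest.raises(ImputationError):
            ratio_impute(self.prof("t"), [])


class TestOnsetDistribution:
    def test_default_density_properties(self):
        d = default_onset_distribution()
        assert d.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert 10 <= d.mode <= 14
        # adult-onset majority: median diagnosis age at or beyond 20
        assert d.median_age() >= 20

    def test_ssa_variant_peaks_strictly_later(self):
        default = default_onset_distribution()
        ssa = default_onset_distribution("sub-Saharan Africa")
        assert ssa.mode > default.mode

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            default_onset_distribution("atlantis")


class TestBuildSurface:
    def test_uniform_density_gives_flat_ages(self):
        from t1dsim.incidence import OnsetAgeDistribution
        dist = OnsetAgeDistribution(np.full(100, 0.01))
        level = pd.Series([7.0, 8.0], index=[2000, 2001])
        surf = build_incidence_surface(dist, level)
        assert np.allclose(surf.values[:, 0], 7.0)
        assert np.allclose(surf.values[:, 1], 8.0)

    def test_default_shape_peaks_in_childhood_every_year(self):
        surf = build_incidence_surface(default_onset_distribution(),
                                       pd.Series(10.0, index=range(1990, 2000)))
        argmax = surf.values.argmax(axis=0)
        assert np.all((argmax >= 10) & (argmax <= 14))

    def test_reference_weighted_mean_equals_level(self):
        dist = default_onset_distribution()
        level = pd.Series([12.0], index=[2005])
        surf = build_incidence_surface(dist, level)
        assert surf.values[:, 0].mean() == pytest.approx(12.0, rel=1e-9)
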