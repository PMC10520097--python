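"""Scenario projections: conservative and momentum futures.

The conservative scenario freezes incidence, SMR and non-diagnosis rates
at their last data-year values.  The momentum scenario continues each of
them at its average annual rate of change over a reference window (2012
to 2021 by default), implemented as the geometric mean of year-on-year
ratios — i.e. ``(v_end / v_start) ** (1 / n)`` per age — so that the
compounding is self-consistent.  The diagnosis-rate trend is applied to
the complement of the non-diagnosis rate so projected rates stay inside
[0, 1].  Future population must be supplied; if the population surface
stops short it is carried forward with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ScenarioError, ValidationError
from .markov import BurdenResult, CountryInputs, run_country
from .surfaces import AgeYearSurface


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str
    horizon_year: int
    momentum_window: tuple[int, int] = (2012, 2021)

    def __post_init__(self) -> None:
        if self.kind not in ("conservative", "momentum"):
            raise ValidationError(f"unknown scenario kind {self.kind!r}")
        if self.momentum_window[0] >= self.momentum_window[1]:
            raise ValidationError("momentum window start must precede its end")


def _annual_ratios(surface: AgeYearSurface, window: tuple[int, int],
                   mean: str, per_age: bool) -> np.ndarray:
    """Per-age average annual change ratio over the window."""
    w0, w1 = window
    v0 = surface.year_column(w0).astype(float)
    v1 = surface.year_column(w1).astype(float)
    n = w1 - w0
    if not per_age:
        m0, m1 = v0.mean(), v1.mean()
        r = (m1 / m0) ** (1.0 / n) if m0 > 0 and m1 > 0 else 1.0
        return np.full(v0.size, r)
    if mean == "geometric":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((v0 > 0) & (v1 > 0), (v1 / np.where(v0 > 0, v0, 1.0)) ** (1.0 / n), 1.0)
        return r
    if mean == "arithmetic":
        cols = surface.values[:, (surface.years >= w0) & (surface.years <= w1)]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(cols[:, :-1] > 0, cols[:, 1:] / np.where(cols[:, :-1] > 0, cols[:, :-1], 1.0), 1.0)
        return ratios.mean(axis=1)
    raise ValidationError(f"unknown mean kind {mean!r}")


def _extend_compound(surface: AgeYearSurface, horizon: int,
                     ratios: np.ndarray | None) -> AgeYearSurface:
    """Extend a surface to the horizon, compounding per-age ratios forward."""
    base = surface.extend_years(horizon)
    if ratios is None:
        return base
    vals = base.values.copy()
    last_data = int(surface.years[-1])
    last_col = surface.values[:, -1].astype(float)
    for year in range(last_data + 1, horizon + 1):
        k = year - last_data
        vals[:, year - base.years[0]] = last_col * ratios ** k
    cap = 1.0 if surface.unit == "probability" else np.inf
    return base.with_values(np.clip(vals, 0.0, cap))


def project_inputs(inputs: CountryInputs, scenario: ScenarioSpec,
                   mean: str = "geometric", per_age: bool = True) -> CountryInputs:
    """Produce the future-complete inputs for a scenario.

    Conservative: incidence, SMR and non-diagnosis rates are held at the
    last data year.  Momentum: each is compounded forward at its average
    annual change over the window (the non-diagnosis rate through its
    complement 1 - rate).  Population beyond its own horizon is carried
    constant with a warning.
    """
    horizon = scenario.horizon_year
    last_data = int(inputs.incidence.years[-1])
    if horizon <= last_data:
        return inputs

    if scenario.kind == "momentum":
        w0, w1 = scenario.momentum_window
        for name in ("incidence", "smr", "nondx_rate"):
            surf: AgeYearSurface = getattr(inputs, name)
            if not (surf.years[0] <= w0 and w1 <= surf.years[-1]):
                raise ScenarioError(
                    f"momentum scenario needs {name} coverage over "
                    f"{w0}-{w1}; surface stops at {surf.years[-1]}"
                )
        inc_r = _annual_ratios(inputs.incidence, (w0, w1), mean, per_age)
        smr_r = _annual_ratios(inputs.smr, (w0, w1), mean, per_age)
        # trend the complement of the non-diagnosis rate, then map back
        comp = inputs.nondx_rate.with_values(np.clip(1.0 - inputs.nondx_rate.values, 0.0, 1.0))
        comp_r = _annual_ratios(comp, (w0, w1), mean, per_age)
        comp_future = _extend_compound(comp, horizon, comp_r)
        nondx_future = comp_future.with_values(np.clip(1.0 - comp_future.values, 0.0, 1.0))
        incidence = _extend_compound(inputs.incidence, horizon, inc_r)
        smr = _extend_compound(inputs.smr, horizon, smr_r)
    else:
        incidence = inputs.incidence.extend_years(horizon)
        smr = inputs.smr.extend_years(horizon)
        nondx_future = inputs.nondx_rate.extend_years(horizon)

    if inputs.population.years[-1] < horizon:
        warnings.warn(
            f"{inputs.country_id}: population surface stops at "
            f"{inputs.population.years[-1]}; carrying it constant to {horizon}",
            stacklevel=2,
        )
    population = inputs.population.extend_years(horizon)
    background = inputs.background_mortality.extend_years(horizon)
    return replace(inputs, population=population, background_mortality=background,
                   incidence=incidence, nondx_rate=nondx_future, smr=smr)


def project_burden(inputs: CountryInputs, scenario: ScenarioSpec,
                   report_years: tuple[int, int], a_max: int = 99,
                   mean: str = "geometric", per_age: bool = True
                   ) -> tuple[BurdenResult, float]:
    """Run the engine on projected inputs and report prevalence growth.

    Returns the burden over ``report_years`` and the percentage growth in
    total prevalence between the first and last report year.
    """
    y0, y1 = report_years
    if y1 > scenario.horizon_year:
        raise ScenarioError("report years extend past the scenario horizon")
    future = project_inputs(inputs, scenario, mean=mean, per_age=per_age)
    burden = run_country(future, y0, y1, a_max=a_max)
    p0 = burden.total("prevalence", y0)
    p1 = burden.total("prevalence", y1)
    if p0 == 0:
        raise ScenarioError("zero prevalence in the base report year; growth undefined")
    return burden, (p1 / p0 - 1.0) * 100.0
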