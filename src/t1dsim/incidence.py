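"""Incidence surfaces from sparse observations.

Published T1D incidence exists for roughly half the world's countries,
mostly for children, mostly for scattered years.  This module turns such
observations into the complete (age, year) surfaces the cohort engine
needs: smoothing of noisy national series, a fitted trend in the annual
percentage change (APC) of incidence for extrapolation through time,
donor-country ratio imputation for countries without data, and an
onset-age distribution that spreads an all-age level across single ages
(with a separate, later-peaking variant for sub-Saharan Africa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, ImputationError, ParameterError, ValidationError
from .surfaces import AgeYearSurface

#: Years for which two or more countries contribute year-on-year changes.
DEFAULT_APC_SUPPORT = (1985, 2015)

#: Before this year incidence data are essentially absent; extrapolated
#: series are held constant at the floor-year value by default.
INCIDENCE_FLOOR_YEAR = 1975


@dataclass(frozen=True)
class IncidenceObservation:
    """One published incidence figure: a rate for a country, year and age band."""

    country_id: str
    region: str
    mid_year: int
    age_low: int
    age_high: int
    rate: float  # per 100,000 person-years
    income_group: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("incidence rate must be non-negative")
        if self.age_low > self.age_high:
            raise ValidationError("age band inverted")


def smooth_series(series: pd.Series, window: int) -> pd.Series:
    """Centred moving average with the window truncated at the boundaries.

    ``window`` must be odd; ``window=1`` is the identity.  Edge cells
    average over the observations that fall inside the (truncated)
    window, so a constant series is preserved exactly and the output
    never leaves the input range.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 1, got {window}")
    s = pd.Series(series).sort_index()
    if s.empty:
        raise ParameterError("series must have at least one point")
    half = window // 2
    vals = s.to_numpy(dtype=float)
    out = np.array([
        vals[max(0, i - half): i + half + 1].mean() for i in range(vals.size)
    ])
    return pd.Series(out, index=s.index)


@dataclass
class APCCurve:
    """Fitted line through pooled year-on-year percentage incidence changes.

    ``apc_at(year)`` evaluates the line (in percent per year) at any year
    by linear extension.  A regional curve with too little data carries
    ``fallback=True`` and delegates to the global curve.
    """

    scope: str
    support_years: tuple[int, int]
    slope: float
    intercept: float
    fallback: bool = False
    global_curve: "APCCurve | None" = None
    n_points: int = 0

    def apc_at(self, year: int) -> float:
        if self.fallback:
            if self.global_curve is None:
                raise FitError(f"fallback curve for {self.scope!r} has no global reference")
            return self.global_curve.apc_at(year)
        return self.intercept + self.slope * year

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "support_years": list(self.support_years),
            "slope": self.slope,
            "intercept": self.intercept,
            "fallback": self.fallback,
            "n_points": self.n_points,
        }


def _yearly_changes(obs: list[IncidenceObservation]) -> pd.DataFrame:
    """Per-country year-on-year percentage changes, assigned to the later year."""
    df = pd.DataFrame([{"country": o.country_id, "region": o.region,
                        "year": o.mid_year, "rate": o.rate} for o in obs])
    rows = []
    for country, g in df.groupby("country"):
        series = g.groupby("year")["rate"].mean().sort_index()
        for prev_year, year in zip(series.index[:-1], series.index[1:]):
            if year - prev_year == 1 and series[prev_year] > 0:
                change = (series[year] / series[prev_year] - 1.0) * 100.0
                rows.append({"country": country, "region": g["region"].iloc[0],
                             "year": int(year), "change_pct": change})
    return pd.DataFrame(rows, columns=["country", "region", "year", "change_pct"])


def _fit_line(points: pd.DataFrame, scope: str, support: tuple[int, int]) -> APCCurve:
    x = sm.add_constant(points["year"].to_numpy(dtype=float))
    fit = sm.OLS(points["change_pct"].to_numpy(dtype=float), x).fit()
    if x.ndim == 1 or x.shape[1] == 1:  # single year: constant only
        intercept, slope = float(fit.params[0]), 0.0
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    return APCCurve(scope=scope, support_years=support, slope=slope,
                    intercept=intercept, n_points=len(points))


def fit_apc_curves(obs: list[IncidenceObservation],
                   support: tuple[int, int] = DEFAULT_APC_SUPPORT
                   ) -> tuple[APCCurve, dict[str, APCCurve]]:
    """Fit the global APC trend line and per-region lines where possible.

    Year-on-year percentage changes are computed per country from
    consecutive-year observations, pooled by calendar year, and kept for
    years within ``support`` where at least two countries contribute.  An
    ordinary least-squares line of change versus year is fitted to the
    pooled points.  Regions that independently satisfy the two-country
    rule get their own line; the rest carry a fallback flag and evaluate
    to the global curve.
    """
    changes = _yearly_changes(obs)
    changes = changes[(changes["year"] >= support[0]) & (changes["year"] <= support[1])]

    def eligible(points: pd.DataFrame) -> pd.DataFrame:
        keep_years = points.groupby("year")["country"].nunique()
        keep_years = keep_years[keep_years >= 2].index
        return points[points["year"].isin(keep_years)]

    pooled = eligible(changes)
    if pooled.empty or pooled["year"].nunique() < 2:
        raise FitError(
            "global APC fit needs year-on-year changes from >= 2 countries "
            "in >= 2 distinct years"
        )
    global_curve = _fit_line(pooled, "global", support)

    regional: dict[str, APCCurve] = {}
    for region in sorted({o.region for o in obs}):
        pts = eligible(changes[changes["region"] == region])
        if pts.empty or pts["year"].nunique() < 2:
            regional[region] = APCCurve(scope=region, support_years=support,
                                        slope=0.0, intercept=0.0, fallback=True,
                                        global_curve=global_curve)
        else:
            regional[region] = _fit_line(pts, region, support)
    return global_curve, regional


def extrapolate_incidence(anchor: IncidenceObservation, curve: APCCurve,
                          target_years, floor_year: int = INCIDENCE_FLOOR_YEAR,
                          pre_floor: str = "hold") -> pd.Series:
    """Compound an anchor rate through time along an APC curve.

    Moving from year ``t`` to ``t+1`` multiplies by ``1 + APC(t+1)/100``;
    moving backwards divides, so a forward-then-backward traversal
    returns the anchor exactly.  Years before ``floor_year`` use the
    floor-year value (``pre_floor="hold"``), decay linearly to half of it
    over 25 years (``"decay50"``), or ramp linearly to zero over 25 years
    (``"ramp0"``).
    """
    if anchor.rate <= 0:
        raise ParameterError("anchor rate must be positive")
    if pre_floor not in ("hold", "decay50", "ramp0"):
        raise ParameterError(f"unknown pre-floor policy {pre_floor!r}")
    years = sorted(set(int(y) for y in target_years) | {anchor.mid_year, floor_year})
    lo, hi = min(years), max(years)
    grid = np.arange(lo, hi + 1)
    vals = np.empty(grid.size)
    i0 = int(anchor.mid_year - lo)
    vals[i0] = anchor.rate
    for i in range(i0 + 1, grid.size):
        vals[i] = vals[i - 1] * (1.0 + curve.apc_at(int(grid[i])) / 100.0)
    for i in range(i0 - 1, -1, -1):
        vals[i] = vals[i + 1] / (1.0 + curve.apc_at(int(grid[i + 1])) / 100.0)
    series = pd.Series(vals, index=grid)
    floor_val = series.get(floor_year, series.iloc[0])
    before = series.index < floor_year
    if before.any():
        offset = (floor_year - series.index[before]).to_numpy(dtype=float)
        if pre_floor == "hold":
            series.loc[before] = floor_val
        elif pre_floor == "decay50":
            series.loc[before] = floor_val * np.clip(1.0 - 0.5 * offset / 25.0, 0.5, 1.0)
        else:  # ramp0
            series.loc[before] = floor_val * np.clip(1.0 - offset / 25.0, 0.0, 1.0)
    return series.loc[[y for y in sorted(set(int(t) for t in target_years))]]


@dataclass(frozen=True)
class CountryProfile:
    """Covariate record used for donor selection and the imputation regression."""

    country_id: str
    region: str
    income_group: str


def _regression_log_prediction(donors: pd.DataFrame, target: CountryProfile) -> tuple[pd.Series, float]:
    """Log-linear OLS of mean incidence on region/income indicators.

    Returns per-donor predictions and the target prediction, on the log
    scale.  With a degenerate design (single level) the regression is
    neutral and all predictions coincide.
    """
    X = pd.get_dummies(donors[["region", "income_group"]], drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    y = np.log(donors["mean_rate"].to_numpy(dtype=float))
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    preds = pd.Series(X.to_numpy(dtype=float) @ fit.params, index=donors.index)
    row = pd.DataFrame({"region": [target.region], "income_group": [target.income_group]})
    row_d = pd.get_dummies(row, dtype=float).reindex(columns=X.columns.drop("const"), fill_value=0.0)
    target_pred = float(fit.params[0] + (row_d.to_numpy(dtype=float) @ fit.params[1:])[0])
    return preds, target_pred


def ratio_impute(target: CountryProfile,
                 donors: list[tuple[CountryProfile, pd.Series]]) -> pd.Series:
    """Impute a target country's incidence series from donor countries.

    Donors are drawn from the narrowest non-empty stratum — region and
    income group, then region, then the global pool — deduplicated by
    country, and combined as the arithmetic median series.  The median is
    scaled by the ratio of a log-linear regression prediction (incidence
    on region and income-group indicators, fitted on the full donor pool)
    for the target versus the median prediction within the stratum.
    """
    seen: set[str] = set()
    pool: list[tuple[CountryProfile, pd.Series]] = []
    for prof, series in donors:
        if prof.country_id not in seen and not pd.Series(series).dropna().empty:
            seen.add(prof.country_id)
            pool.append((prof, pd.Series(series).astype(float)))
    if not pool:
        raise ImputationError(f"no donors available for {target.country_id!r}")

    for predicate in (
        lambda p: p.region == target.region and p.income_group == target.income_group,
        lambda p: p.region == target.region,
        lambda p: True,
    ):
        stratum = [(p, s) for p, s in pool if predicate(p)]
        if stratum:
            break
    else:  # pragma: no cover - the global predicate always matches
        raise ImputationError(f"empty donor pool for {target.country_id!r}")

    median_series = pd.concat({p.country_id: s for p, s in stratum}, axis=1).median(axis=1)

    frame = pd.DataFrame({
        "region": [p.region for p, _ in pool],
        "income_group": [p.income_group for p, _ in pool],
        "mean_rate": [max(s.mean(), 1e-12) for _, s in pool],
    })
    preds, target_pred = _regression_log_prediction(frame, target)
    stratum_ids = {p.country_id for p, _ in stratum}
    in_stratum = [i for i, (p, _) in enumerate(pool) if p.country_id in stratum_ids]
    scale = float(np.exp(target_pred - np.median(preds.iloc[in_stratum])))
    return median_series * scale


@dataclass
class OnsetAgeDistribution:
    """Density of age at clinical onset over single years of age.

    The default variant peaks at ages 10-14 but carries the majority of
    its mass in adulthood (median onset age >= 20); the sub-Saharan
    Africa variant has a strictly later childhood peak, matching the
    regionally later onset pattern reported in the field.
    """

    density: np.ndarray
    region_variant: str = "default"

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValidationError("onset density must be non-negative")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValidationError("onset density must sum to 1")

    @property
    def mode(self) -> int:
        return int(np.argmax(self.density))

    def median_age(self) -> float:
        return float(np.searchsorted(np.cumsum(self.density), 0.5))

    @classmethod
    def bimodal(cls, a_max: int = 99, *, child_loc: float, child_scale: float,
                child_weight: float, adult_loc: float, adult_scale: float,
                variant: str = "default") -> "OnsetAgeDistribution":
        ages = np.arange(a_max + 1)
        child = stats.norm.pdf(ages, child_loc, child_scale)
        adult = stats.norm.pdf(ages, adult_loc, adult_scale)
        dens = child_weight * child / child.sum() + (1 - child_weight) * adult / adult.sum()
        return cls(dens / dens.sum(), variant)


def default_onset_distribution(variant: str = "default", a_max: int = 99
                               ) -> OnsetAgeDistribution:
    """Packaged onset-age densities: a childhood peak plus broad adult mass."""
    if variant == "default":
        d = OnsetAgeDistribution.bimodal(a_max, child_loc=12.0, child_scale=4.0,
                                         child_weight=0.35, adult_loc=40.0,
                                         adult_scale=20.0, variant=variant)
        if not 10 <= d.mode <= 14:
            raise ValidationError("default onset density must peak at ages 10-14")
        return d
    if variant in ("sub-Saharan Africa", "ssa"):
        return OnsetAgeDistribution.bimodal(a_max, child_loc=18.0, child_scale=5.0,
                                            child_weight=0.40, adult_loc=42.0,
                                            adult_scale=20.0,
                                            variant="sub-Saharan Africa")
    raise ParameterError(f"unknown onset-age variant {variant!r}")


def build_incidence_surface(onset_dist: OnsetAgeDistribution, level: pd.Series,
                            reference_weights: np.ndarray | None = None
                            ) -> AgeYearSurface:
    """Spread an all-age incidence level across ages via the onset density.

    Cell (a, y) = level(y) * shape(a), with the shape rescaled so the
    reference-population-weighted mean over ages equals level(y); with a
    uniform reference structure and a uniform density the surface is flat.
    """
    level = pd.Series(level).sort_index()
    ages = np.arange(onset_dist.density.size)
    w = (np.full(ages.size, 1.0 / ages.size) if reference_weights is None
         else np.asarray(reference_weights, dtype=float))
    if w.size != ages.size:
        raise ValidationError("reference weights must cover every age")
    w = w / w.sum()
    shape = onset_dist.density / float(w @ onset_dist.density)
    vals = np.outer(shape, level.to_numpy(dtype=float))
    years = level.index.to_numpy(dtype=int)
    return AgeYearSurface(ages, years, vals, "per100k_py")
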