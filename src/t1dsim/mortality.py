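"""Mortality ingredients: non-diagnosis death rates and predicted SMRs.

Two channels feed the cohort engine.  Deaths at clinical onset from
non-diagnosis come from a survey-based schedule of rates by world region
and era (before 2000, 2000-2010, after 2010), applied below age 25 and
set to zero in high-income countries.  Mortality among people living
with diagnosed T1D enters as a standardized mortality ratio (SMR),
predicted from country covariates where no published SMR exists, or
derived from a care level through the care -> mean HbA1c -> SMR chain.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler

from .errors import FitError, ParameterError, ValidationError
from .markov import INCOME_GROUPS, NONDX_AGE_CUTOFF, REGIONS

ERAS = ("pre-2000", "2000-2010", "post-2010")


@dataclass(frozen=True)
class CountryCovariates:
    """Country-level predictors for the SMR model."""

    region: str
    income_class: str
    infant_mortality: float      # per 1,000 live births
    doctors_per_capita: float    # per 1,000 population
    gdp_per_capita: float        # currency units per person
    under5_mortality: float      # per 1,000 live births
    urbanisation: float          # percent of population

    def __post_init__(self) -> None:
        for name in ("infant_mortality", "doctors_per_capita", "gdp_per_capita",
                     "under5_mortality", "urbanisation"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.urbanisation > 100:
            raise ValidationError("urbanisation is a percentage (<= 100)")
        if self.income_class not in INCOME_GROUPS:
            raise ValidationError(f"unknown income class {self.income_class!r}")

    def numeric_vector(self) -> np.ndarray:
        return np.array([self.infant_mortality, self.doctors_per_capita,
                         self.gdp_per_capita, self.under5_mortality,
                         self.urbanisation])


@dataclass(frozen=True)
class SMRDataPoint:
    """One observed SMR for a country, year and age band."""

    country_id: str
    year: int
    age_low: int
    age_high: int
    smr: float
    covariates: CountryCovariates

    def __post_init__(self) -> None:
        if self.smr <= 0:
            raise ValidationError("smr must be positive")


def era_of(year: int) -> str:
    """Survey-era bucket: the middle interval 2000-2010 is closed."""
    if year < 2000:
        return "pre-2000"
    if year <= 2010:
        return "2000-2010"
    return "post-2010"


@dataclass
class NonDxSchedule:
    """Survey-derived non-diagnosis death rates by (region, era).

    Queries return 0 for high-income countries and at ages >= 25
    regardless of the stored rates.
    """

    rates: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (region, era), rate in self.rates.items():
            if era not in ERAS:
                raise ValidationError(f"unknown era {era!r}")
            if not 0 <= rate <= 1:
                raise ValidationError(f"rate for ({region}, {era}) outside [0, 1]")

    def rate(self, region: str, income_class: str, year: int, age: int) -> float:
        if income_class == "HIC" or age >= NONDX_AGE_CUTOFF:
            return 0.0
        key = (region, era_of(year))
        if key not in self.rates:
            raise LookupError(f"no survey rate for region {region!r}, era {era_of(year)!r}")
        return self.rates[key]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NonDxSchedule":
        return cls({(r.region, r.era): float(r.rate) for r in df.itertuples()})


def nondx_rate(schedule: NonDxSchedule, region: str, income_class: str,
               year: int, age: int) -> float:
    """Era-bucketed non-diagnosis death rate (module-level convenience)."""
    return schedule.rate(region, income_class, year, age)


def default_nondx_schedule() -> NonDxSchedule:
    """Packaged survey schedule.

    Only the Sub-Saharan Africa pre-2010 rate of 0.60 is an externally
    anchored figure; the remaining cells are synthetic placeholders with
    a plausible region and era gradient, shipped so the model runs
    without the original survey microdata.
    """
    path = importlib.resources.files("t1dsim.data") / "nondx_survey_rates.csv"
    with importlib.resources.as_file(path) as p:
        return NonDxSchedule.from_frame(pd.read_csv(p))


# ---------------------------------------------------------------------------
# SMR prediction from covariates

@dataclass
class SMRPredictorConfig:
    k: int = 3
    max_smr: float = 30.0
    min_smr: float = 1.0
    categorical_weight: float = 1.0
    seed: int = 0


class SMRPredictor:
    """Distance-weighted k-nearest-neighbour SMR model.

    Numeric covariates are standardized; region and income class enter
    as one-hot columns scaled by ``categorical_weight`` so that matching
    categories shorten the distance.  Predictions are clipped to
    ``[min_smr, max_smr]`` (an SMR below 1 — mortality better than
    background — is treated as implausible by default).  The model is
    deterministic: identical training data, configuration and seed give
    bit-identical predictions.
    """

    def __init__(self, training: list[SMRDataPoint], config: SMRPredictorConfig):
        self.config = config
        self._regions = sorted({p.covariates.region for p in training})
        self._incomes = sorted({p.covariates.income_class for p in training})
        X = np.array([p.covariates.numeric_vector() for p in training])
        y = np.array([p.smr for p in training])
        self._degenerate = bool(np.all(np.all(X == X[0], axis=0))
                                and len({(p.covariates.region, p.covariates.income_class)
                                         for p in training}) == 1
                                and not np.allclose(y, y[0]))
        if self._degenerate:
            warnings.warn("degenerate SMR training set (identical covariates, "
                          "differing SMRs); falling back to the mean", stacklevel=2)
            self._mean = float(y.mean())
            return
        self._scaler = StandardScaler().fit(X)
        features = np.hstack([self._scaler.transform(X),
                              self._one_hot([p.covariates for p in training])])
        self._knn = KNeighborsRegressor(
            n_neighbors=min(config.k, len(training)), weights="distance"
        ).fit(features, y)

    def _one_hot(self, covs: list[CountryCovariates]) -> np.ndarray:
        w = self.config.categorical_weight
        out = np.zeros((len(covs), len(self._regions) + len(self._incomes)))
        for i, c in enumerate(covs):
            if c.region in self._regions:
                out[i, self._regions.index(c.region)] = w
            if c.income_class in self._incomes:
                out[i, len(self._regions) + self._incomes.index(c.income_class)] = w
        return out

    def predict(self, covariates: CountryCovariates, year: int | None = None) -> float:
        if self._degenerate:
            raw = self._mean
        else:
            x = np.hstack([
                self._scaler.transform(covariates.numeric_vector()[None, :]),
                self._one_hot([covariates]),
            ])
            raw = float(self._knn.predict(x)[0])
        return float(np.clip(raw, self.config.min_smr, self.config.max_smr))


def fit_smr_predictor(training: list[SMRDataPoint],
                      config: SMRPredictorConfig | None = None) -> SMRPredictor:
    """Fit the covariate -> SMR predictor (k-NN by default).

    The learner class is deliberately simple and exactly interpolating:
    a query equal to a training point returns that point's SMR.  The
    predictor object is the swap point for richer learners.
    """
    if len(training) < 5:
        raise FitError(f"SMR predictor needs >= 5 training points, got {len(training)}")
    return SMRPredictor(training, config or SMRPredictorConfig())


# ---------------------------------------------------------------------------
# HbA1c -> SMR mapping and the SMR age shape

#: Default knot table for the mean-HbA1c -> SMR relation.  The shape
#: (monotone, convex, SMR 1 near 7%) follows published excess-mortality
#: gradients by glycaemic control; the exact knots are configuration, not
#: an estimated fit.
DEFAULT_HBA1C_SMR_KNOTS: tuple[tuple[float, float], ...] = (
    (6.0, 1.0), (7.0, 1.5), (8.0, 2.3), (9.0, 3.5), (10.0, 5.2), (12.0, 9.0),
)


def smr_from_hba1c(knots, hba1c: float) -> float:
    """Piecewise-linear SMR for a mean HbA1c, clamped to the end knots."""
    knots = list(knots)
    if len(knots) < 2:
        raise ValidationError("need at least two (hba1c, smr) knots")
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise ValidationError("knot HbA1c values must be strictly increasing")
    if np.any(np.diff(ys) < 0):
        raise ValidationError("knot SMR values must be non-decreasing")
    return float(np.interp(hba1c, xs, ys))


@dataclass(frozen=True)
class CareLevel:
    """A named care level with its assumed achieved mean HbA1c."""

    name: str
    mean_hba1c: float

    def __post_init__(self) -> None:
        if not 4.0 <= self.mean_hba1c <= 20.0:
            raise ValidationError("mean HbA1c outside the plausible 4-20% range")

    def implied_smr(self, knots=DEFAULT_HBA1C_SMR_KNOTS) -> float:
        return smr_from_hba1c(knots, self.mean_hba1c)


#: Default care-level ladder.  "Minimal care" is a simple insulin regimen
#: with little or no self-monitoring, HbA1c testing or education; the
#: mean HbA1c attached to each level is configuration.
DEFAULT_CARE_LEVELS: dict[str, CareLevel] = {
    "minimal": CareLevel("minimal", 9.5),
    "intermediate": CareLevel("intermediate", 8.0),
    "best": CareLevel("best", 7.0),
}


def normalize_shape(shape: np.ndarray, reference_weights: np.ndarray | None = None
                    ) -> np.ndarray:
    """Rescale an age multiplier profile to reference-weighted mean 1."""
    shape = np.asarray(shape, dtype=float)
    w = (np.full(shape.size, 1.0 / shape.size) if reference_weights is None
         else np.asarray(reference_weights, dtype=float) / np.sum(reference_weights))
    return shape / float(w @ shape)


def apply_smr_shape(all_age_smr: float, shape: np.ndarray,
                    reference_weights: np.ndarray | None = None) -> np.ndarray:
    """Spread an all-age SMR across ages with a mean-1 multiplier profile.

    The age pattern of SMR is assumed common across countries and years;
    the packaged default shape is flat (no tabulated pattern exists), so
    this is the hook where an age profile would enter.
    """
    shape = np.asarray(shape, dtype=float)
    w = (np.full(shape.size, 1.0 / shape.size) if reference_weights is None
         else np.asarray(reference_weights, dtype=float) / np.sum(reference_weights))
    if abs(float(w @ shape) - 1.0) > 1e-6:
        raise ValidationError("shape must have reference-weighted mean 1 "
                              "(use normalize_shape first)")
    return all_age_smr * shape
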