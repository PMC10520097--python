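"""Dense (age, year) surfaces — the carrier type for every model input.

An :class:`AgeYearSurface` maps a rectangular grid of completed ages and
calendar years to non-negative values, tagged with a unit.  Population,
background mortality, incidence, standardized mortality ratios and
non-diagnosis rates are all stored this way, so the Markov engine can read
any input with a single ``at(age, year)`` call and fail loudly on gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

#: Allowed unit tags.
UNITS = ("persons", "per100k_py", "probability", "dimensionless")


@dataclass
class AgeYearSurface:
    """Rectangular table of values over (completed age, calendar year).

    Parameters
    ----------
    ages, years
        Consecutive integer ranges; ``ages`` normally spans 0..99.
    values
        Array of shape ``(len(ages), len(years))``; non-negative, and
        bounded by 1 when ``unit == "probability"``.
    unit
        One of :data:`UNITS`.
    """

    ages: np.ndarray
    years: np.ndarray
    values: np.ndarray
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        for name, idx in (("ages", self.ages), ("years", self.years)):
            if idx.ndim != 1 or idx.size == 0:
                raise ValidationError(f"{name} must be a non-empty 1-D range")
            if idx.size > 1 and not np.all(np.diff(idx) == 1):
                raise ValidationError(f"{name} must be consecutive integers")
        if self.values.shape != (self.ages.size, self.years.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.ages.size} ages x {self.years.size} years)"
            )
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("surface contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("surface contains negative values")
        if self.unit == "probability" and np.any(self.values > 1 + 1e-12):
            raise ValidationError("probability surface contains values > 1")

    # -- accessors ---------------------------------------------------------

    @property
    def a_max(self) -> int:
        return int(self.ages[-1])

    def has(self, age: int, year: int) -> bool:
        return (self.ages[0] <= age <= self.ages[-1]
                and self.years[0] <= year <= self.years[-1])

    def at(self, age: int, year: int, *, country: str | None = None) -> float:
        """Value at a single cell; raises :class:`CoverageError` on a gap."""
        if not self.has(age, year):
            who = f" for country {country!r}" if country else ""
            raise CoverageError(
                f"missing input cell{who}: age {age}, year {year} "
                f"(surface covers ages {self.ages[0]}..{self.ages[-1]}, "
                f"years {self.years[0]}..{self.years[-1]})"
            )
        return float(self.values[age - self.ages[0], year - self.years[0]])

    def year_column(self, year: int) -> np.ndarray:
        if not (self.years[0] <= year <= self.years[-1]):
            raise CoverageError(f"year {year} outside {self.years[0]}..{self.years[-1]}")
        return self.values[:, year - self.years[0]]

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(cls, value: float, ages, years, unit: str = "dimensionless"
                 ) -> "AgeYearSurface":
        ages = np.arange(ages[0], ages[-1] + 1) if not np.isscalar(ages) else np.arange(ages + 1)
        years = np.arange(years[0], years[-1] + 1)
        return cls(ages, years, np.full((ages.size, years.size), float(value)), unit)

    @classmethod
    def from_long(cls, df: pd.DataFrame, unit: str = "dimensionless") -> "AgeYearSurface":
        """Build from a long-format frame with columns (age, year, value)."""
        pivot = df.pivot_table(index="age", columns="year", values="value")
        ages = pivot.index.to_numpy(dtype=int)
        years = pivot.columns.to_numpy(dtype=int)
        if pivot.isna().any().any():
            missing = int(pivot.isna().sum().sum())
            raise ValidationError(f"long-format input is not rectangular: {missing} missing cells")
        return cls(ages, years, pivot.to_numpy(dtype=float), unit)

    # -- transforms --------------------------------------------------------

    def copy(self) -> "AgeYearSurface":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray) -> "AgeYearSurface":
        return replace(self, values=np.asarray(values, dtype=float))

    def extend_years(self, through_year: int) -> "AgeYearSurface":
        """Carry the last data year forward so the grid reaches ``through_year``.

        Needed to follow recent-onset cohorts beyond the data horizon; the
        carried values are the surface's own last column.
        """
        if through_year <= self.years[-1]:
            return self
        extra = through_year - int(self.years[-1])
        tail = np.repeat(self.values[:, -1:], extra, axis=1)
        return AgeYearSurface(
            self.ages,
            np.arange(self.years[0], through_year + 1),
            np.hstack([self.values, tail]),
            self.unit,
        )

    def to_long(self, country_id: str, metric: str) -> pd.DataFrame:
        aa, yy = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame({
            "country_id": country_id,
            "metric": metric,
            "age": aa.ravel(),
            "year": yy.ravel(),
            "value": self.values.ravel(),
        })
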