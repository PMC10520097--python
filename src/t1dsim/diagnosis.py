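"""Bounding historical diagnosis rates from observed incidence changes.

When access to care improves, observed incidence can rise far faster
than true incidence plausibly could, because previously missed cases
start being diagnosed.  The ratio of observed incidences between two
years factors exactly into the ratio of true incidences times the ratio
of diagnosis rates:

    observed_ratio = true_ratio * diagnosis_rate_ratio

Assuming a plausible true annual growth rate and a final diagnosis rate
(100% gives a bound) therefore pins down the earlier diagnosis rate.
The canonical worked case is Mali, where observed incidence under age 25
rose from 0.12 to 0.74 per 100,000 between 2007 and 2016.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class DiagnosisCase:
    """Observed incidence at two years plus the assumptions of the argument."""

    i0: float          # observed incidence per 100,000 in year y0
    y0: int
    i1: float          # observed incidence per 100,000 in year y1 > y0
    y1: int
    assumed_true_apc: float = 0.07      # proportion per year
    assumed_final_dx_rate: float = 1.0  # proportion in (0, 1]

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValidationError(
                "baseline observed incidence is zero; observed incidence can be "
                "entirely masked by non-diagnosis, so no ratio is defined"
            )
        if self.i1 <= 0:
            raise ValidationError("final observed incidence must be positive")
        if self.y1 <= self.y0:
            raise ValidationError("y1 must be after y0")
        if not 0 < self.assumed_final_dx_rate <= 1:
            raise ValidationError("final diagnosis rate must lie in (0, 1]")

    @property
    def n_years(self) -> int:
        return self.y1 - self.y0


def observed_ratio(case: DiagnosisCase) -> float:
    """Ratio of observed incidences i1/i0 (report at one decimal for display)."""
    return case.i1 / case.i0


def implied_annual_growth(ratio: float, n_years: int) -> float:
    """Constant annual growth that compounds to ``ratio`` over ``n_years``."""
    if ratio <= 0:
        raise ParameterError("ratio must be positive")
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    return ratio ** (1.0 / n_years) - 1.0


def true_ratio(apc: float, n_years: int) -> float:
    """Incidence ratio implied by a constant true annual growth rate."""
    if apc <= -1:
        raise ParameterError("annual growth must exceed -100%")
    return (1.0 + apc) ** n_years


def diagnosis_rate_ratio(observed: float, true_r: float) -> float:
    """Diagnosis-rate ratio left over once true growth is accounted for."""
    if observed <= 0 or true_r <= 0:
        raise ParameterError("both ratios must be positive")
    out = observed / true_r
    if out < 1:
        warnings.warn("diagnosis-rate ratio below 1: the assumptions imply a "
                      "deteriorating diagnosis rate", stacklevel=2)
    return out


def baseline_diagnosis_rate(dx_ratio: float, final_rate: float = 1.0) -> float:
    """Earlier-year diagnosis rate implied by the ratio and the final rate.

    With ``final_rate = 1`` this is an upper bound on the baseline rate.
    """
    if dx_ratio <= 0:
        raise ParameterError("diagnosis-rate ratio must be positive")
    if not 0 < final_rate <= 1:
        raise ParameterError("final rate must lie in (0, 1]")
    rate = final_rate / dx_ratio
    if rate > 1:
        raise ValidationError(
            f"implied baseline diagnosis rate {rate:.3f} exceeds 1; the assumed "
            "true growth is too fast for the observed change"
        )
    return rate


def full_chain(case: DiagnosisCase) -> dict:
    """Run the whole decomposition; report unrounded and display-rounded values.

    The chain is evaluated unrounded end to end; the rounded entries
    reproduce how such chains are conventionally printed (one decimal per
    step, nearest-integer percent for the baseline rate).
    """
    obs = observed_ratio(case)
    growth = implied_annual_growth(obs, case.n_years)
    true_r = true_ratio(case.assumed_true_apc, case.n_years)
    dx_ratio = diagnosis_rate_ratio(obs, true_r)
    baseline = baseline_diagnosis_rate(dx_ratio, case.assumed_final_dx_rate)
    return {
        "inputs": {
            "i0": case.i0, "y0": case.y0, "i1": case.i1, "y1": case.y1,
            "n_years": case.n_years,
            "assumed_true_apc": case.assumed_true_apc,
            "assumed_final_dx_rate": case.assumed_final_dx_rate,
        },
        "unrounded": {
            "observed_ratio": obs,
            "implied_annual_growth": growth,
            "true_ratio": true_r,
            "diagnosis_rate_ratio": dx_ratio,
            "baseline_diagnosis_rate": baseline,
        },
        "rounded": {
            "observed_ratio": round(obs, 1),
            "implied_annual_growth_pct": round(growth * 100, 1),
            "true_ratio": round(true_r, 1),
            "diagnosis_rate_ratio": round(dx_ratio, 1),
            "baseline_diagnosis_rate_pct": round(baseline * 100),
        },
    }
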