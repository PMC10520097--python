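"""Healthy-life-years lost: complications, disability and premature death.

The computation has two stages.  First, a care level fixes a mean HbA1c,
which maps to an SMR; the cohort engine then gives survival and life
expectancy at onset under that SMR.  Second, duration-dependent annual
hazards of eight chronic complications (a logistic function of mean
HbA1c and diabetes duration, following the structure of duration-cohort
complication models) drive a forward recursion over the joint
complication state space.  Complications are conditionally independent
given glycaemic control, persist once acquired, and two "impermissible
journeys" are blocked: de-novo proliferative retinopathy in an already
blind person, and de-novo hypertension/microalbuminuria in a person with
overt nephropathy.  Disability weights combine multiplicatively across
coexisting complications; weighted person-years lived plus the life
expectancy shortfall give HALYs lost, split into death and disability
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.special import expit, logit

from .errors import ParameterError, ValidationError
from .markov import (CountryInputs, background_life_expectancy,
                     life_expectancy_at_onset)
from .mortality import DEFAULT_HBA1C_SMR_KNOTS, CareLevel, smr_from_hba1c
from .surfaces import AgeYearSurface

#: The eight modelled complications.
COMPLICATIONS = (
    "distal symmetric polyneuropathy",
    "ulcer or amputation",
    "hypertension or microalbuminuria",
    "overt nephropathy",
    "proliferative retinopathy",
    "blindness",
    "non-fatal myocardial infarction",
    "non-fatal cerebrovascular disease",
)

#: Hazards are estimated out to this diabetes duration; beyond it the
#: duration-30 hazard is held constant by default.
DURATION_CAP = 30


@dataclass(frozen=True)
class ComplicationSpec:
    """Annual de-novo hazard parameters and disability weight for one complication.

    The hazard is ``expit(intercept + hba1c_coefficient * hba1c +
    duration_coefficient * duration)`` — an annual probability of first
    occurrence on the log-odds scale.  All parameters are configuration:
    published duration-cohort fits drop in here.
    """

    name: str
    intercept: float
    hba1c_coefficient: float
    duration_coefficient: float
    disability_weight: float
    persistent: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.disability_weight <= 1:
            raise ValidationError("disability weight must lie in [0, 1]")


@dataclass(frozen=True)
class ImpermissibleJourney:
    """A blocked de-novo transition: ``blocked`` cannot newly occur once
    ``blocker`` is present."""

    blocker: str
    blocked: str

    def __post_init__(self) -> None:
        if self.blocker == self.blocked:
            raise ValidationError("a complication cannot block itself")


DEFAULT_JOURNEYS: tuple[ImpermissibleJourney, ...] = (
    ImpermissibleJourney("blindness", "proliferative retinopathy"),
    ImpermissibleJourney("overt nephropathy", "hypertension or microalbuminuria"),
)


def default_registry() -> tuple[ComplicationSpec, ...]:
    """Packaged hazard parameters and GBD-style disability weights.

    The coefficients are synthetic defaults chosen to give plausible
    30-year cumulative frequencies at a mean HbA1c around 8-9% (higher
    for neuropathy and hypertension/microalbuminuria, lower for
    blindness and stroke), with hazards increasing in both HbA1c and
    duration; they are configuration, not estimates.
    """
    rows = [
        # name, intercept, hba1c_coef, duration_coef, weight
        ("distal symmetric polyneuropathy", -6.2, 0.35, 0.030, 0.13),
        ("ulcer or amputation", -8.0, 0.40, 0.040, 0.16),
        ("hypertension or microalbuminuria", -5.9, 0.32, 0.028, 0.05),
        ("overt nephropathy", -7.6, 0.38, 0.035, 0.10),
        ("proliferative retinopathy", -7.0, 0.40, 0.045, 0.08),
        ("blindness", -9.0, 0.38, 0.040, 0.19),
        ("non-fatal myocardial infarction", -8.4, 0.33, 0.050, 0.08),
        ("non-fatal cerebrovascular disease", -8.8, 0.32, 0.045, 0.07),
    ]
    registry = tuple(ComplicationSpec(n, a, b, c, w) for n, a, b, c, w in rows)
    if tuple(s.name for s in registry) != COMPLICATIONS:
        raise ValidationError("default registry must contain exactly the eight "
                              "modelled complications, in canonical order")
    return registry


def annual_hazard(spec: ComplicationSpec, hba1c: float, duration: float) -> float:
    """Annual probability of de-novo occurrence at a given HbA1c and duration."""
    if duration < 0:
        raise ParameterError("duration must be non-negative")
    return float(expit(spec.intercept + spec.hba1c_coefficient * hba1c
                       + spec.duration_coefficient * duration))


@dataclass
class ComplicationProfile:
    """Joint distribution over complication states at each diabetes duration.

    ``joint[d, s]`` is the probability of bitmask state ``s`` after ``d``
    years of diabetes; ``marginals[d, c]`` the probability of having
    complication ``c``.  The joint sums to 1 at every duration and its
    marginals equal the per-complication probabilities by construction.
    """

    names: tuple[str, ...]
    joint: np.ndarray  # (D+1, 2**n)

    @property
    def durations(self) -> np.ndarray:
        return np.arange(self.joint.shape[0])

    @property
    def marginals(self) -> np.ndarray:
        n = len(self.names)
        states = np.arange(self.joint.shape[1])
        has = np.array([(states >> c) & 1 for c in range(n)]).T  # (2**n, n)
        return self.joint @ has

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.joint < -tol):
            raise ValidationError("negative state probability")
        if np.any(np.abs(self.joint.sum(axis=1) - 1.0) > tol):
            raise ValidationError("joint distribution does not sum to 1")


def _effective_duration(d: int, cap: int, beyond: str) -> float | None:
    if d <= cap:
        return float(d)
    if beyond == "hold":
        return float(cap)
    if beyond == "linear":
        return float(d)
    if beyond == "zero":
        return None
    raise ParameterError(f"unknown beyond-cap policy {beyond!r}")


def prevalence_profile(registry, journeys, hba1c: float, D: int,
                       duration_cap: int = DURATION_CAP,
                       beyond: str = "hold") -> ComplicationProfile:
    """Forward recursion over the joint complication state space.

    Each year, every absent and unblocked complication occurs
    independently with its annual hazard; acquired complications persist.
    Hazards past ``duration_cap`` follow the ``beyond`` policy: ``hold``
    (reuse the cap hazard), ``linear`` (keep extrapolating the log-odds
    trend) or ``zero`` (no new occurrences).
    """
    if D < 1:
        raise ParameterError("D must be >= 1")
    registry = tuple(registry)
    names = tuple(s.name for s in registry)
    n = len(names)
    if n > 12:
        raise ParameterError("state space limited to 12 complications")
    idx = {name: c for c, name in enumerate(names)}
    block_mask = np.zeros(n, dtype=int)  # blocker bits per blocked complication
    for j in journeys or ():
        if j.blocker in idx and j.blocked in idx:
            block_mask[idx[j.blocked]] |= 1 << idx[j.blocker]

    n_states = 1 << n
    joint = np.zeros((D + 1, n_states))
    joint[0, 0] = 1.0
    for d in range(D):
        eff = _effective_duration(d, duration_cap, beyond)
        hazards = (np.zeros(n) if eff is None else
                   np.array([annual_hazard(s, hba1c, eff) for s in registry]))
        nxt = np.zeros(n_states)
        for s in range(n_states):
            p = joint[d, s]
            if p == 0.0:
                continue
            eligible = [c for c in range(n)
                        if not (s >> c) & 1 and not (s & block_mask[c])]
            base = p * float(np.prod([1.0 - hazards[c] for c in eligible]))
            nxt[s] += base
            # distribute over every non-empty subset of occurring complications
            for r in range(1, len(eligible) + 1):
                for combo in combinations(eligible, r):
                    q = p
                    for c in eligible:
                        q *= hazards[c] if c in combo else 1.0 - hazards[c]
                    if q == 0.0:
                        continue
                    target = s
                    for c in combo:
                        target |= 1 << c
                    if target != s:
                        nxt[target] += q
                    else:  # pragma: no cover
                        nxt[s] += q
        joint[d + 1] = nxt
    profile = ComplicationProfile(names, joint)
    profile.validate()
    return profile


def expected_disability(profile: ComplicationProfile, weights: dict[str, float] | None = None,
                        combine: str = "multiplicative") -> np.ndarray:
    """Expected disability weight at each duration.

    Coexisting complications combine as ``1 - prod(1 - w_c)`` over the
    joint state (``multiplicative``) or as the sum capped at 1
    (``additive_capped``).
    """
    names = profile.names
    if weights is None:
        raise ParameterError("weights mapping required")
    w = np.array([weights[name] for name in names])
    n = len(names)
    states = np.arange(profile.joint.shape[1])
    has = np.array([(states >> c) & 1 for c in range(n)]).T.astype(float)
    if combine == "multiplicative":
        state_w = 1.0 - np.prod(1.0 - has * w, axis=1)
    elif combine == "additive_capped":
        state_w = np.minimum(has @ w, 1.0)
    else:
        raise ParameterError(f"unknown combination rule {combine!r}")
    return profile.joint @ state_w


def person_years_by_duration(inputs: CountryInputs, onset_age: int, onset_year: int,
                             a_max: int | None = None) -> np.ndarray:
    """Expected person-years lived at each diabetes duration for one onset.

    Includes the non-diagnosis branch (those dying at onset contribute
    half a year at duration 0); survivors of a year contribute one
    person-year, within-year deaths half.
    """
    if a_max is None:
        a_max = int(inputs.background_mortality.a_max)
    horizon = onset_year + (a_max - onset_age)
    bg = inputs.background_mortality.extend_years(horizon)
    smr = inputs.smr.extend_years(horizon)
    nondx = inputs.nondx_rate.extend_years(horizon)
    cid = inputs.country_id
    p_nondx = nondx.at(onset_age, onset_year, country=cid)
    durations = a_max - onset_age + 1
    py = np.zeros(durations)
    py[0] += p_nondx * 0.5
    s = 1.0 - p_nondx
    for d in range(durations):
        age = onset_age + d
        year = onset_year + d
        q = 1.0 if age == a_max else bg.at(age, year, country=cid)
        q_t1d = min(1.0, 1.0 - (1.0 - q) ** smr.at(age, year, country=cid))
        py[d] += s * (1.0 - q_t1d) + s * q_t1d * 0.5
        s *= 1.0 - q_t1d
    return py


def disability_component(person_years: np.ndarray, disability_by_duration: np.ndarray
                         ) -> float:
    """Weighted person-years lived with disability (exposed for direct use)."""
    person_years = np.asarray(person_years, dtype=float)
    dis = np.asarray(disability_by_duration, dtype=float)
    n = min(person_years.size, dis.size)
    return float(person_years[:n] @ dis[:n])


@dataclass(frozen=True)
class HalyResult:
    total: float
    death: float
    disability: float
    life_expectancy: float
    reference_life_expectancy: float


def halys_lost(inputs: CountryInputs, onset_age: int, onset_year: int,
               care: CareLevel, registry=None, journeys=DEFAULT_JOURNEYS,
               knots=DEFAULT_HBA1C_SMR_KNOTS, reference_le: float | None = None,
               combine: str = "multiplicative", duration_cap: int = DURATION_CAP,
               beyond: str = "hold") -> HalyResult:
    """Healthy life years lost for one onset under a care level.

    The care level's mean HbA1c sets both the SMR (via the knot table,
    replacing the country's SMR surface) and the complication hazards.
    The death component is the background remaining life expectancy at
    onset minus the model life expectancy; the disability component is
    disability-weighted person-years lived.
    """
    registry = tuple(registry) if registry is not None else default_registry()
    smr_val = smr_from_hba1c(knots, care.mean_hba1c)
    care_inputs = replace(
        inputs, smr=inputs.smr.with_values(np.full_like(inputs.smr.values, smr_val))
    )
    a_max = int(inputs.background_mortality.a_max)
    model_le = life_expectancy_at_onset(care_inputs, onset_age, onset_year, a_max=a_max)
    if reference_le is None:
        reference_le = background_life_expectancy(inputs, onset_age, onset_year, a_max=a_max)
    death = reference_le - model_le

    durations = a_max - onset_age
    profile = prevalence_profile(registry, journeys, care.mean_hba1c,
                                 max(durations, 1), duration_cap=duration_cap,
                                 beyond=beyond)
    weights = {s.name: s.disability_weight for s in registry}
    dis_by_dur = expected_disability(profile, weights, combine=combine)
    py = person_years_by_duration(care_inputs, onset_age, onset_year, a_max=a_max)
    disability = disability_component(py, dis_by_dur)
    return HalyResult(total=death + disability, death=death, disability=disability,
                      life_expectancy=model_le, reference_life_expectancy=reference_le)
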