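"""Annual-step Markov cohort engine for diagnosed type 1 diabetes burden.

Each birth cohort is followed through five states: alive without T1D,
alive with diagnosed T1D (sub-indexed by age at onset), dead at clinical
onset from non-diagnosis, dead after diagnosis, and dead from background
causes.  Within a model year the event order is fixed:

1. clinical onset among the susceptible, at the incidence rate;
2. a fraction of new onsets dies undiagnosed (ages < 25, non-HIC only);
3. background deaths among the remaining susceptible;
4. deaths among the diagnosed (including this year's survivors of onset)
   at the SMR-scaled hazard ``q_t1d = 1 - (1 - q)**SMR``.

The SMR acts on the hazard scale so the death probability stays below 1
at high ages; ages are completed years, the terminal age ``a_max`` is
absorbing to death.  Aggregating cohorts gives prevalence (end-of-year
counts), cause-decomposed deaths, remaining life expectancy at onset
(with a half-cycle credit of 0.5 year in the year of death) and the
"missing prevalence" counterfactual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, UndefinedShareError, ValidationError
from .surfaces import AgeYearSurface

#: The seven world-region labels used throughout (the minimal-care table set).
REGIONS = (
    "East Asia and Pacific",
    "Europe and Central Asia",
    "Latin America and Caribbean",
    "Middle East and North Africa",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
)

INCOME_GROUPS = ("LIC", "LMIC", "UMIC", "HIC")

#: Age below which non-diagnosis deaths are modelled.
NONDX_AGE_CUTOFF = 25


@dataclass
class CountryInputs:
    """Everything the engine needs to simulate one country.

    ``nondx_rate`` is stored as a probability surface and is structurally
    zero at ages >= 25 and for high-income countries; construction
    enforces this rather than trusting the caller.
    """

    country_id: str
    region: str
    income_group: str
    population: AgeYearSurface
    background_mortality: AgeYearSurface
    incidence: AgeYearSurface
    nondx_rate: AgeYearSurface
    smr: AgeYearSurface

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.income_group not in INCOME_GROUPS:
            raise ValidationError(f"unknown income group {self.income_group!r}")
        expect = {"population": "persons", "background_mortality": "probability",
                  "incidence": "per100k_py", "nondx_rate": "probability"}
        for name, unit in expect.items():
            surf = getattr(self, name)
            if surf.unit != unit:
                raise ValidationError(f"{name} surface must carry unit {unit!r}, got {surf.unit!r}")
        nd = self.nondx_rate
        mask = nd.ages >= NONDX_AGE_CUTOFF
        if self.income_group == "HIC":
            if np.any(nd.values > 0):
                raise ValidationError("non-diagnosis rates must be zero for high-income countries")
        elif np.any(nd.values[mask, :] > 0):
            raise ValidationError(f"non-diagnosis rates must be zero at ages >= {NONDX_AGE_CUTOFF}")
        if np.any(self.smr.values < 1):
            warnings.warn(
                f"{self.country_id}: SMR surface contains values < 1 "
                "(mortality below background); permitted but unusual",
                stacklevel=2,
            )

    def counterfactual_no_t1d_mortality(self) -> "CountryInputs":
        """Same country with non-diagnosis deaths off and SMR pinned to 1."""
        return replace(
            self,
            nondx_rate=self.nondx_rate.with_values(np.zeros_like(self.nondx_rate.values)),
            smr=self.smr.with_values(np.ones_like(self.smr.values)),
        )


def structural_nondx_surface(rate_by_year, ages, years, income_group: str) -> AgeYearSurface:
    """Expand per-year rates into a surface obeying the structural zeros."""
    ages = np.arange(ages[0], ages[-1] + 1)
    years = np.arange(years[0], years[-1] + 1)
    vals = np.zeros((ages.size, years.size))
    if income_group != "HIC":
        for j, y in enumerate(years):
            vals[ages < NONDX_AGE_CUTOFF, j] = float(rate_by_year(int(y)))
    return AgeYearSurface(ages, years, vals, "probability")


@dataclass
class CohortLedger:
    """State counts for one birth cohort at every simulated age.

    Row ``a`` holds counts at the *start* of age ``a`` (equivalently the
    end of age ``a - 1``); ``alive_diagnosed[a, o]`` is the number alive
    at age ``a`` who were diagnosed at age ``o``.  Flow arrays record the
    events of the model year lived at age ``a``.
    """

    birth_year: int
    size: float
    a_max: int = 99
    alive_no_t1d: np.ndarray = field(init=False)
    alive_diagnosed: np.ndarray = field(init=False)
    dead_onset_nondx: np.ndarray = field(init=False)
    dead_after_dx: np.ndarray = field(init=False)
    dead_background: np.ndarray = field(init=False)
    # per-age flows (events during the year lived at age a)
    flow_onsets: np.ndarray = field(init=False)
    flow_incident_diagnosed: np.ndarray = field(init=False)
    flow_deaths_onset_nondx: np.ndarray = field(init=False)
    flow_deaths_after_dx: np.ndarray = field(init=False)
    flow_deaths_after_dx_excess: np.ndarray = field(init=False)
    flow_deaths_background: np.ndarray = field(init=False)
    ages_computed: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValidationError("cohort size must be non-negative")
        n = self.a_max + 2  # rows 0..a_max+1 (state after the terminal year)
        self.alive_no_t1d = np.zeros(n)
        self.alive_diagnosed = np.zeros((n, self.a_max + 1))
        self.dead_onset_nondx = np.zeros(n)
        self.dead_after_dx = np.zeros(n)
        self.dead_background = np.zeros(n)
        self.flow_onsets = np.zeros(self.a_max + 1)
        self.flow_incident_diagnosed = np.zeros(self.a_max + 1)
        self.flow_deaths_onset_nondx = np.zeros(self.a_max + 1)
        self.flow_deaths_after_dx = np.zeros(self.a_max + 1)
        self.flow_deaths_after_dx_excess = np.zeros(self.a_max + 1)
        self.flow_deaths_background = np.zeros(self.a_max + 1)
        self.alive_no_t1d[0] = self.size

    def state_total(self, age: int) -> float:
        return float(
            self.alive_no_t1d[age]
            + self.alive_diagnosed[age].sum()
            + self.dead_onset_nondx[age]
            + self.dead_after_dx[age]
            + self.dead_background[age]
        )

    def check_conservation(self, rtol: float = 1e-9) -> None:
        scale = max(self.size, 1.0)
        for a in range(self.ages_computed + 1):
            if abs(self.state_total(a) - self.size) > rtol * scale:
                raise ValidationError(
                    f"cohort {self.birth_year}: conservation violated at age {a}"
                )


def step_cohort(ledger: CohortLedger, age: int, year: int, inputs: CountryInputs
                ) -> CohortLedger:
    """Advance one cohort through the model year lived at ``age``.

    Mutates and returns ``ledger``, filling the state row for ``age + 1``
    and the flow entries for ``age``.  Event order is the fixed sequence
    documented in the module docstring.
    """
    if age > ledger.a_max:
        raise ValidationError(f"age {age} beyond terminal age {ledger.a_max}")
    if year != ledger.birth_year + age:
        raise ValidationError(
            f"cohort {ledger.birth_year} is at age {age} in year "
            f"{ledger.birth_year + age}, not {year}"
        )
    cid = inputs.country_id
    inc = inputs.incidence.at(age, year, country=cid) / 1e5
    if inc > 1:
        raise ValidationError(f"{cid}: incidence rate above 100,000/100k at age {age}, year {year}")
    nondx = inputs.nondx_rate.at(age, year, country=cid)
    q = 1.0 if age == ledger.a_max else inputs.background_mortality.at(age, year, country=cid)
    smr = inputs.smr.at(age, year, country=cid)
    q_t1d = min(1.0, 1.0 - (1.0 - q) ** smr)

    susceptible = ledger.alive_no_t1d[age]
    diagnosed = ledger.alive_diagnosed[age].copy()

    onsets = susceptible * inc
    deaths_nondx = onsets * nondx
    new_dx = onsets - deaths_nondx
    deaths_bg = (susceptible - onsets) * q
    diagnosed[age] += new_dx
    deaths_dx = diagnosed.sum() * q_t1d

    ledger.alive_no_t1d[age + 1] = (susceptible - onsets) * (1.0 - q)
    ledger.alive_diagnosed[age + 1] = diagnosed * (1.0 - q_t1d)
    ledger.dead_onset_nondx[age + 1] = ledger.dead_onset_nondx[age] + deaths_nondx
    ledger.dead_after_dx[age + 1] = ledger.dead_after_dx[age] + deaths_dx
    ledger.dead_background[age + 1] = ledger.dead_background[age] + deaths_bg

    ledger.flow_onsets[age] = onsets
    ledger.flow_incident_diagnosed[age] = new_dx
    ledger.flow_deaths_onset_nondx[age] = deaths_nondx
    ledger.flow_deaths_after_dx[age] = deaths_dx
    ledger.flow_deaths_after_dx_excess[age] = deaths_dx - diagnosed.sum() * q
    ledger.flow_deaths_background[age] = deaths_bg
    ledger.ages_computed = max(ledger.ages_computed, age + 1)
    return ledger


@dataclass
class BurdenResult:
    """Aggregated output of a country run.

    ``prevalence`` counts diagnosed people alive at the *end* of each
    (age, year) cell; the death channels are within-year flows.  The
    ``deaths_after_dx_excess`` channel is all-cause deaths among the
    diagnosed minus the background-equivalent deaths the same people
    would have suffered at SMR = 1 (the mapping of the published
    decomposition onto either reading is left to the caller).
    """

    country_id: str
    prevalence: AgeYearSurface
    incident_diagnosed: AgeYearSurface
    deaths_onset_nondx: AgeYearSurface
    deaths_after_dx: AgeYearSurface
    deaths_after_dx_excess: AgeYearSurface
    deaths_background: AgeYearSurface
    missing_prevalence: pd.Series | None = None
    life_expectancy_at_onset: pd.DataFrame | None = None

    @property
    def years(self) -> np.ndarray:
        return self.prevalence.years

    def total(self, channel: str, year: int, max_age: int | None = None) -> float:
        surf: AgeYearSurface = getattr(self, channel)
        col = surf.year_column(year)
        if max_age is not None:
            col = col[surf.ages <= max_age]
        return float(col.sum())

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for year in self.years:
            rows.append({
                "year": int(year),
                "prevalence": self.total("prevalence", year),
                "incident_diagnosed": self.total("incident_diagnosed", year),
                "deaths_onset_nondx": self.total("deaths_onset_nondx", year),
                "deaths_after_dx": self.total("deaths_after_dx", year),
                "deaths_after_dx_excess": self.total("deaths_after_dx_excess", year),
                "deaths_background": self.total("deaths_background", year),
            })
        return pd.DataFrame(rows)


def run_country(inputs: CountryInputs, first_year: int, last_year: int,
                a_max: int = 99, check: bool = False) -> BurdenResult:
    """Run one :class:`CohortLedger` per birth year and aggregate.

    Deterministic; requires input coverage for every (age, year) visited,
    i.e. birth years from ``first_year - a_max`` through ``last_year``.
    """
    if last_year < first_year:
        raise ValidationError("last_year before first_year")
    earliest_birth = first_year - a_max
    if not inputs.population.has(0, earliest_birth):
        raise CoverageError(
            f"{inputs.country_id}: population surface must cover age 0 back to "
            f"birth year {earliest_birth} (= first_year - a_max) to report {first_year}"
        )
    ages = np.arange(a_max + 1)
    years = np.arange(first_year, last_year + 1)
    shape = (ages.size, years.size)
    prev = np.zeros(shape)
    inc_dx = np.zeros(shape)
    d_nondx = np.zeros(shape)
    d_dx = np.zeros(shape)
    d_dx_excess = np.zeros(shape)
    d_bg = np.zeros(shape)

    for birth_year in range(earliest_birth, last_year + 1):
        size = inputs.population.at(0, birth_year, country=inputs.country_id)
        ledger = CohortLedger(birth_year=birth_year, size=size, a_max=a_max)
        top_age = min(a_max, last_year - birth_year)
        for age in range(top_age + 1):
            year = birth_year + age
            step_cohort(ledger, age, year, inputs)
            if first_year <= year <= last_year:
                j = year - first_year
                prev[age, j] = ledger.alive_diagnosed[age + 1].sum()
                inc_dx[age, j] = ledger.flow_incident_diagnosed[age]
                d_nondx[age, j] = ledger.flow_deaths_onset_nondx[age]
                d_dx[age, j] = ledger.flow_deaths_after_dx[age]
                d_dx_excess[age, j] = ledger.flow_deaths_after_dx_excess[age]
                d_bg[age, j] = ledger.flow_deaths_background[age]
        if check:
            ledger.check_conservation()

    def surf(v):
        return AgeYearSurface(ages, years, v, "persons")

    return BurdenResult(
        country_id=inputs.country_id,
        prevalence=surf(prev),
        incident_diagnosed=surf(inc_dx),
        deaths_onset_nondx=surf(d_nondx),
        deaths_after_dx=surf(d_dx),
        deaths_after_dx_excess=surf(np.maximum(d_dx_excess, 0.0)),
        deaths_background=surf(d_bg),
    )


def _survival_expectancy(q_by_age: np.ndarray) -> float:
    """Expected remaining years under an annual death-probability sequence.

    Survivors of a year contribute 1 person-year, decedents 0.5 (half-cycle
    credit).  The last entry is treated as the terminal, absorbing year.
    """
    e = 0.0
    s = 1.0
    for q in q_by_age:
        e += s * (1.0 - q) + s * q * 0.5
        s *= 1.0 - q
    return e + s * 0.0


def life_expectancy_at_onset(inputs: CountryInputs, onset_age: int, onset_year: int,
                             a_max: int | None = None, extend: bool = True) -> float:
    """Expected remaining years for a person with clinical onset at
    ``(onset_age, onset_year)``, including the non-diagnosis death risk
    at onset (those deaths are credited 0.5 year).

    Surfaces are carried forward past the data horizon when ``extend``.
    """
    if a_max is None:
        a_max = int(inputs.background_mortality.a_max)
    if onset_age > a_max:
        raise ValidationError(f"onset age {onset_age} beyond terminal age {a_max}")
    horizon = onset_year + (a_max - onset_age)
    bg, smr, nondx = inputs.background_mortality, inputs.smr, inputs.nondx_rate
    if extend:
        bg, smr, nondx = (s.extend_years(horizon) for s in (bg, smr, nondx))
    cid = inputs.country_id
    p_nondx = nondx.at(onset_age, onset_year, country=cid)
    q_seq = []
    for age in range(onset_age, a_max + 1):
        year = onset_year + (age - onset_age)
        q = 1.0 if age == a_max else bg.at(age, year, country=cid)
        q_seq.append(min(1.0, 1.0 - (1.0 - q) ** smr.at(age, year, country=cid)))
    e_dx = _survival_expectancy(np.array(q_seq))
    return p_nondx * 0.5 + (1.0 - p_nondx) * e_dx


def background_life_expectancy(inputs: CountryInputs, age: int, year: int,
                               a_max: int | None = None, extend: bool = True) -> float:
    """Remaining life expectancy at (age, year) under background mortality only."""
    cf = inputs.counterfactual_no_t1d_mortality()
    return life_expectancy_at_onset(cf, age, year, a_max=a_max, extend=extend)


def life_expectancy_table(inputs: CountryInputs, onset_ages, onset_years,
                          a_max: int | None = None) -> pd.DataFrame:
    rows = [
        {"onset_age": a, "onset_year": y,
         "life_expectancy": life_expectancy_at_onset(inputs, a, y, a_max=a_max)}
        for a in onset_ages for y in onset_years
    ]
    return pd.DataFrame(rows)


def missing_prevalence(inputs: CountryInputs, year: int, a_max: int = 99) -> float:
    """Counterfactual-minus-factual prevalent cases in ``year``.

    The counterfactual removes both T1D mortality channels (non-diagnosis
    deaths off, SMR = 1), all else equal; the difference is the number of
    people who would be alive with diagnosed T1D but are not.
    """
    factual = run_country(inputs, year, year, a_max=a_max)
    counter = run_country(inputs.counterfactual_no_t1d_mortality(), year, year, a_max=a_max)
    diff = counter.total("prevalence", year) - factual.total("prevalence", year)
    return max(0.0, diff)


def mortality_shares(deaths_onset: float, deaths_after_dx: float) -> tuple[int, int]:
    """Integer percentage split of T1D deaths by cause.

    Each share is rounded to the nearest integer; if the rounded pair does
    not sum to 100 the larger share absorbs the difference (this
    reproduces conventional printed splits such as 20/80 and 67/33).
    """
    if deaths_onset < 0 or deaths_after_dx < 0:
        raise ValidationError("death counts must be non-negative")
    total = deaths_onset + deaths_after_dx
    if total == 0:
        raise UndefinedShareError("both death channels are zero; shares undefined")
    p_onset = round(deaths_onset / total * 100)
    p_after = round(deaths_after_dx / total * 100)
    if p_onset + p_after != 100:
        if p_onset >= p_after:
            p_onset = 100 - p_after
        else:
            p_after = 100 - p_onset
    return int(p_onset), int(p_after)
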