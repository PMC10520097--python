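"""Synthetic country bundles, SMR training sets, and transcribed tables.

Real global inputs (UN population prospects, registry incidence, the
care-survey microdata) are out of scope, so this module provides two
substitutes: deterministic generators that emit complete, internally
consistent :class:`~t1dsim.markov.CountryInputs` bundles for five country
archetypes with known ground truth, and verbatim transcriptions of the
published 2021 country estimate tables (per-country prevalence and
incidence with the IDF Atlas comparison, and the minimal-care counts by
region and income group) used for table-level validation checks.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError, ValidationError
from .incidence import default_onset_distribution, build_incidence_surface
from .markov import CountryInputs, structural_nondx_surface
from .mortality import CountryCovariates, SMRDataPoint, era_of
from .surfaces import AgeYearSurface

# ---------------------------------------------------------------------------
# Country archetypes


@dataclass(frozen=True)
class CountryArchetype:
    """Generator parameters for one synthetic country type.

    The parameter ranges bracket the spread seen in published national
    estimates (incidence from well below 1 to above 50 per 100,000
    children; SMRs from near 1 in the best-resourced settings to several-
    fold elsewhere; non-diagnosis rates up to 60% in sub-Saharan Africa
    before 2010).
    """

    name: str
    region: str
    income_group: str
    base_incidence_per100k: float      # all-age level in the base year (2020)
    apc_pct: float                     # annual % change in incidence
    onset_variant: str                 # "default" or "sub-Saharan Africa"
    smr_2020: float
    smr_trend_pct: float               # annual % change in SMR
    nondx_era_rates: dict              # era -> proportion (empty for HIC)
    mortality_scale: float             # multiplier on the baseline q(age) curve
    pop_growth_pct: float              # annual % change in birth-cohort size
    births_2020: float                 # age-0 cohort size in 2020

    covariates: CountryCovariates | None = None


ARCHETYPES: dict[str, CountryArchetype] = {
    "HIC-high-incidence": CountryArchetype(
        "HIC-high-incidence", "Europe and Central Asia", "HIC",
        base_incidence_per100k=25.0, apc_pct=1.5, onset_variant="default",
        smr_2020=1.4, smr_trend_pct=-0.5, nondx_era_rates={},
        mortality_scale=0.6, pop_growth_pct=0.2, births_2020=60_000,
        covariates=CountryCovariates("Europe and Central Asia", "HIC",
                                     3.0, 4.0, 48_000, 4.0, 85.0)),
    "HIC-low-incidence": CountryArchetype(
        "HIC-low-incidence", "East Asia and Pacific", "HIC",
        base_incidence_per100k=3.0, apc_pct=2.0, onset_variant="default",
        smr_2020=1.6, smr_trend_pct=-0.5, nondx_era_rates={},
        mortality_scale=0.6, pop_growth_pct=-0.2, births_2020=80_000,
        covariates=CountryCovariates("East Asia and Pacific", "HIC",
                                     2.5, 2.5, 40_000, 3.0, 90.0)),
    "UMIC": CountryArchetype(
        "UMIC", "Latin America and Caribbean", "UMIC",
        base_incidence_per100k=8.0, apc_pct=2.5, onset_variant="default",
        smr_2020=2.8, smr_trend_pct=-1.0,
        nondx_era_rates={"pre-2000": 0.25, "2000-2010": 0.15, "post-2010": 0.08},
        mortality_scale=1.0, pop_growth_pct=0.8, births_2020=120_000,
        covariates=CountryCovariates("Latin America and Caribbean", "UMIC",
                                     12.0, 2.0, 9_000, 15.0, 78.0)),
    "LMIC": CountryArchetype(
        "LMIC", "South Asia", "LMIC",
        base_incidence_per100k=6.0, apc_pct=3.0, onset_variant="default",
        smr_2020=4.5, smr_trend_pct=-1.0,
        nondx_era_rates={"pre-2000": 0.45, "2000-2010": 0.35, "post-2010": 0.25},
        mortality_scale=1.6, pop_growth_pct=1.2, births_2020=220_000,
        covariates=CountryCovariates("South Asia", "LMIC",
                                     30.0, 0.9, 2_200, 38.0, 38.0)),
    "LIC-SSA": CountryArchetype(
        "LIC-SSA", "Sub-Saharan Africa", "LIC",
        base_incidence_per100k=4.0, apc_pct=3.0, onset_variant="sub-Saharan Africa",
        smr_2020=8.0, smr_trend_pct=-1.5,
        nondx_era_rates={"pre-2000": 0.60, "2000-2010": 0.60, "post-2010": 0.45},
        mortality_scale=2.4, pop_growth_pct=2.5, births_2020=180_000,
        covariates=CountryCovariates("Sub-Saharan Africa", "LIC",
                                     55.0, 0.2, 900, 80.0, 35.0)),
}


def _baseline_q(ages: np.ndarray) -> np.ndarray:
    """Stylized annual death probability by age: infant hump plus senescence."""
    infant = 0.02 * np.exp(-ages / 1.5)
    background = 5e-4
    senescent = 2.2e-5 * np.exp(0.095 * ages)
    return infant + background + senescent


def make_country(archetype: CountryArchetype | str, seed: int,
                 years: tuple[int, int] = (1900, 2040), a_max: int = 99,
                 birth_noise_sd: float = 0.0) -> CountryInputs:
    """Deterministically generate a complete input bundle for one archetype.

    All surfaces cover ``years`` for ages 0..``a_max``: a birth-cohort
    population propagated under the background mortality, a smoothly
    improving mortality surface, an incidence surface built from the
    archetype's onset-age variant and exponential level path (held
    constant before 1975), the era-bucketed non-diagnosis schedule and a
    trending, age-flat SMR surface floored at 1.  ``birth_noise_sd`` adds
    optional lognormal jitter to cohort sizes (seeded, so the bundle is
    bit-identical for a fixed seed either way).
    """
    if isinstance(archetype, str):
        if archetype not in ARCHETYPES:
            raise ParameterError(f"unknown archetype {archetype!r}; "
                                 f"choose from {sorted(ARCHETYPES)}")
        archetype = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    y0, y1 = years
    yy = np.arange(y0, y1 + 1)
    ages = np.arange(a_max + 1)

    # background mortality: baseline curve x archetype scale, improving 0.7%/yr
    q_age = _baseline_q(ages) * archetype.mortality_scale
    improvement = (1.0 - 0.007) ** (yy - 2000)
    q = np.clip(np.outer(q_age, improvement), 1e-6, 0.95)
    background = AgeYearSurface(ages, yy, q, "probability")

    # births series and population propagated by survivorship
    births = archetype.births_2020 * (1 + archetype.pop_growth_pct / 100.0) ** (yy - 2020)
    if birth_noise_sd > 0:
        births = births * rng.lognormal(0.0, birth_noise_sd, size=births.size)
    pop = np.zeros((ages.size, yy.size))
    pop[0] = births
    for a in range(1, ages.size):
        # cohorts born before the grid reuse the first-year survivors
        shifted = np.empty(yy.size)
        shifted[1:] = pop[a - 1, :-1] * (1 - q[a - 1, :-1])
        shifted[0] = pop[a - 1, 0] * (1 - q[a - 1, 0])
        pop[a] = shifted
    population = AgeYearSurface(ages, yy, pop, "persons")

    # incidence: level path with APC, held flat before 1975
    level = archetype.base_incidence_per100k * (
        1 + archetype.apc_pct / 100.0) ** (np.maximum(yy, 1975) - 2020)
    onset = default_onset_distribution(archetype.onset_variant, a_max=a_max)
    incidence = build_incidence_surface(onset, pd.Series(level, index=yy))

    nondx = structural_nondx_surface(
        lambda year: archetype.nondx_era_rates.get(era_of(year), 0.0),
        ages, yy, archetype.income_group)

    smr_level = np.maximum(
        archetype.smr_2020 * (1 + archetype.smr_trend_pct / 100.0) ** (yy - 2020), 1.0)
    smr = AgeYearSurface(ages, yy, np.tile(smr_level, (ages.size, 1)), "dimensionless")

    return CountryInputs(
        country_id=f"synthetic-{archetype.name}",
        region=archetype.region,
        income_group=archetype.income_group,
        population=population,
        background_mortality=background,
        incidence=incidence,
        nondx_rate=nondx,
        smr=smr,
    )


# ---------------------------------------------------------------------------
# SMR training sets with known ground truth


@dataclass(frozen=True)
class GeneratingFunction:
    """Declared ground truth behind a synthetic SMR training set."""

    description: str
    fn: object  # CountryCovariates -> float
    noise_sd: float = 0.0


def linear_under5_generating_function(slope: float = 0.2, intercept: float = 1.0,
                                      noise_sd: float = 0.0) -> GeneratingFunction:
    return GeneratingFunction(
        description=f"SMR = {intercept} + {slope} x under5_mortality",
        fn=lambda c: intercept + slope * c.under5_mortality,
        noise_sd=noise_sd,
    )


_REGION_BY_QUARTILE = ("Sub-Saharan Africa", "South Asia",
                       "Latin America and Caribbean", "Europe and Central Asia")
_INCOME_BY_QUARTILE = ("LIC", "LMIC", "UMIC", "HIC")


def sample_covariates(n: int, rng: np.random.Generator,
                      jitter: float = 0.002) -> list[CountryCovariates]:
    """Sample covariate records along a latent development gradient.

    Real country indicators are strongly collinear (infant and under-5
    mortality, GDP, doctor density and urbanisation all track a common
    development level), so records are generated from a single latent
    score with a small relative jitter rather than independently.  The
    jitter is kept well below the typical inter-point spacing so that
    recovery experiments measure the learner, not sampler noise.
    """
    d = rng.uniform(0.0, 1.0, size=n)

    def jit(x):
        return x * (1.0 + jitter * rng.standard_normal(n)) if jitter > 0 else x

    under5 = np.clip(jit(2.0 + 118.0 * (1.0 - d)), 0.5, 200.0)
    infant = np.clip(jit(0.72 * under5), 0.3, 150.0)
    gdp = np.clip(jit(600.0 * np.exp(4.6 * d)), 100.0, 200_000.0)
    doctors = np.clip(jit(0.2 + 4.3 * d ** 1.5), 0.01, 10.0)
    urban = np.clip(jit(15.0 + 75.0 * d), 1.0, 100.0)
    quart = np.minimum((d * 4).astype(int), 3)
    return [
        CountryCovariates(
            region=_REGION_BY_QUARTILE[quart[i]],
            income_class=_INCOME_BY_QUARTILE[quart[i]],
            infant_mortality=float(infant[i]),
            doctors_per_capita=float(doctors[i]),
            gdp_per_capita=float(gdp[i]),
            under5_mortality=float(under5[i]),
            urbanisation=float(min(urban[i], 100.0)),
        )
        for i in range(n)
    ]


def make_smr_training(n: int = 71, seed: int = 0,
                      generating: GeneratingFunction | None = None
                      ) -> tuple[list[SMRDataPoint], GeneratingFunction]:
    """Generate a synthetic SMR training set with declared ground truth.

    The default size of 71 mirrors the sparsity of the real published SMR
    evidence base.  Returns the points together with the generating
    function so recovery experiments can compare against it.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if generating is None:
        generating = linear_under5_generating_function()
    rng = np.random.default_rng(seed)
    covs = sample_covariates(n, rng)
    points = []
    for i, c in enumerate(covs):
        smr = float(generating.fn(c))
        if generating.noise_sd > 0:
            smr += float(rng.normal(0.0, generating.noise_sd))
        points.append(SMRDataPoint(
            country_id=f"synth-{i:03d}", year=int(rng.integers(1990, 2021)),
            age_low=0, age_high=24, smr=max(smr, 0.05), covariates=c))
    return points, generating


# ---------------------------------------------------------------------------
# Transcribed published tables

TABLE1_FILENAME = "table1_country_estimates_2021.csv"
TABLE2_FILENAME = "table2_minimal_care_2021.csv"

#: SHA-256 checksums of the shipped fixtures, pinned at transcription time.
FIXTURE_SHA256 = {
    TABLE1_FILENAME: "cddd3fa9b2b8202cd8c8183ee55c434bd820136660a479ee0445fcb3604e7db1",
    TABLE2_FILENAME: "07a3fb0b86f389221b8da885af309fb1924480457a236ab6ce2ce431629ca715",
}


def _load_fixture(filename: str) -> pd.DataFrame:
    path = importlib.resources.files("t1dsim.data") / filename
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = FIXTURE_SHA256[filename]
    if digest != expected:
        raise IntegrityError(
            f"fixture {filename} checksum mismatch: got {digest}, expected {expected}"
        )
    import io
    return pd.read_csv(io.BytesIO(raw))


def load_table1_fixture() -> pd.DataFrame:
    """Per-country 2021 prevalence and incidence with the IDF Atlas comparison.

    Columns: prevalence per 100,000 under 20 and all ages, the share of
    all diabetes that is T1D at ages 20-79, T1D Index incidence per
    100,000 under 15, the IDF Atlas incidence and its study mid-year
    (with a ``source_country`` column where the Atlas borrowed another
    country's study), and the printed percentage by which the Atlas
    figure is lower (negative = greater).  Ambiguous source cells carry a
    ``note``.
    """
    return _load_fixture(TABLE1_FILENAME)


def load_table2_fixture() -> pd.DataFrame:
    """Minimal-care counts among people under 25 with T1D in 2021, by world
    region and income group, plus the printed global total."""
    return _load_fixture(TABLE2_FILENAME)


@dataclass
class TableChecksReport:
    """Consistency statistics recomputed from the transcribed tables."""

    n_rows: int
    median_pct_atlas_lower: float
    median_interval: tuple[float, float]
    n_within_1pt: int
    n_rounding_consistent: int
    per_row: pd.DataFrame
    table2_region_sum: int
    table2_income_sum: int
    table2_global_total: int

    @property
    def region_sum_matches(self) -> bool:
        return self.table2_region_sum == self.table2_global_total

    @property
    def income_sum_matches(self) -> bool:
        return self.table2_income_sum == self.table2_global_total

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "median_pct_atlas_lower": self.median_pct_atlas_lower,
            "median_interval": list(self.median_interval),
            "n_within_1pt": self.n_within_1pt,
            "n_rounding_consistent": self.n_rounding_consistent,
            "table2_region_sum": self.table2_region_sum,
            "table2_income_sum": self.table2_income_sum,
            "table2_global_total": self.table2_global_total,
            "region_sum_matches": self.region_sum_matches,
            "income_sum_matches": self.income_sum_matches,
        }


def table_checks(table1: pd.DataFrame | None = None,
                 table2: pd.DataFrame | None = None) -> TableChecksReport:
    """Recompute the tables' internal consistency statistics.

    For every country the Atlas-versus-Index difference is recomputed as
    (Index - Atlas) / Atlas x 100 and compared with the printed integer
    column two ways: strictly (within +-1 point) and rounding-aware
    (propagating the +-0.05 rounding interval of the printed one-decimal
    incidence values, plus the +-1 integer rounding).  The median of the
    recomputed differences is reported with its rounding-propagated
    interval.  For the minimal-care table the regional and income-group
    counts are summed against the printed global total.
    """
    t1 = load_table1_fixture() if table1 is None else table1
    t2 = load_table2_fixture() if table2 is None else table2

    i = t1["index_inc_lt15_per100k"].to_numpy(dtype=float)
    a = t1["atlas_inc_lt15_per100k"].to_numpy(dtype=float)
    printed = t1["pct_atlas_lower"].to_numpy(dtype=float)
    recomputed = (i - a) / a * 100.0
    lo = (i - 0.05 - (a + 0.05)) / (a + 0.05) * 100.0
    hi = (i + 0.05 - (a - 0.05)) / (a - 0.05) * 100.0
    within = np.abs(recomputed - printed) <= 1.0
    consistent = (printed >= lo - 1.0) & (printed <= hi + 1.0)
    per_row = pd.DataFrame({
        "country": t1["country"],
        "recomputed_pct": recomputed,
        "printed_pct": printed,
        "within_1pt": within,
        "rounding_consistent": consistent,
    })

    regions = t2[t2["group_type"] == "region"]["minimal_care_n"].astype(int)
    incomes = t2[t2["group_type"] == "income"]["minimal_care_n"].astype(int)
    total = int(t2[t2["group_type"] == "global"]["minimal_care_n"].iloc[0])

    return TableChecksReport(
        n_rows=len(t1),
        median_pct_atlas_lower=float(np.median(recomputed)),
        median_interval=(float(np.median(lo)), float(np.median(hi))),
        n_within_1pt=int(within.sum()),
        n_rounding_consistent=int(consistent.sum()),
        per_row=per_row,
        table2_region_sum=int(regions.sum()),
        table2_income_sum=int(incomes.sum()),
        table2_global_total=total,
    )
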