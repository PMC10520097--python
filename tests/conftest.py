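import numpy as np
import pytest

from t1dsim.markov import CountryInputs
from t1dsim.surfaces import AgeYearSurface


def make_toy_inputs(*, incidence=0.0, q=0.0, smr=1.0, nondx=0.0,
                    cohort_size=1000.0, a_max=20, years=(1990, 2030),
                    region="South Asia", income_group="LMIC",
                    country_id="toy") -> CountryInputs:
    """Constant-rate country covering ages 0..a_max over the given years.

    ``incidence`` is per 100,000 person-years; ``nondx`` applies below
    age 25 (unless the income group is HIC, where it must be 0).
    """
    ages = np.arange(a_max + 1)
    yy = np.arange(years[0], years[1] + 1)

    def const(v, unit):
        return AgeYearSurface(ages, yy, np.full((ages.size, yy.size), float(v)), unit)

    nondx_vals = np.zeros((ages.size, yy.size))
    if income_group != "HIC":
        nondx_vals[ages < 25, :] = nondx
    return CountryInputs(
        country_id=country_id, region=region, income_group=income_group,
        population=const(cohort_size, "persons"),
        background_mortality=const(q, "probability"),
        incidence=const(incidence, "per100k_py"),
        nondx_rate=AgeYearSurface(ages, yy, nondx_vals, "probability"),
        smr=const(smr, "dimensionless"),
    )


def three_cohort_inputs(n=100_000, birth_years=(1999, 2009, 2018), **kw):
    """Toy world where only three birth cohorts are populated.

    Keeps the per-individual microsimulation comparison at a cell count
    where a per-cell three-standard-error bound is appropriate.
    """
    import numpy as np
    inputs = make_toy_inputs(cohort_size=0.0, **kw)
    pop = inputs.population.values.copy()
    for y in birth_years:
        pop[0, y - inputs.population.years[0]] = n
    return inputs.__class__(
        country_id=inputs.country_id, region=inputs.region,
        income_group=inputs.income_group,
        population=inputs.population.with_values(pop),
        background_mortality=inputs.background_mortality,
        incidence=inputs.incidence, nondx_rate=inputs.nondx_rate,
        smr=inputs.smr)


@pytest.fixture(scope="session")
def lmic_inputs():
    """A full synthetic LMIC bundle shared by the slower integration tests."""
    from t1dsim.synthetic import make_country
    return make_country("LMIC", seed=1, years=(1915, 2030))
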