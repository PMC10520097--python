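"""Independent oracles used by the test suite.

These deliberately re-derive quantities by different means than the
implementation: a stochastic per-individual microsimulation of the
illness-death process (realised with binomial draws, which is exactly
the aggregate of independent individuals), and exhaustive enumeration of
complication occurrence paths.
"""

import numpy as np


def microsim_country(inputs, first_year, last_year, a_max, rng, n_per_cohort=None):
    """Stochastic per-individual counterpart of the cohort engine.

    Follows every birth cohort with binomial draws for onset,
    non-diagnosis death, background death and diagnosed death in the
    fixed within-year event order.  Returns dict of (age, year) count
    arrays matching the BurdenResult channels.
    """
    years = np.arange(first_year, last_year + 1)
    shape = (a_max + 1, years.size)
    out = {k: np.zeros(shape) for k in
           ("prevalence", "incident_diagnosed", "deaths_onset_nondx",
            "deaths_after_dx", "deaths_background")}
    cid = inputs.country_id
    for birth_year in range(first_year - a_max, last_year + 1):
        size = (int(round(inputs.population.at(0, birth_year, country=cid)))
                if n_per_cohort is None else n_per_cohort)
        alive_s = size
        alive_d = 0
        top_age = min(a_max, last_year - birth_year)
        for age in range(top_age + 1):
            year = birth_year + age
            inc = inputs.incidence.at(age, year, country=cid) / 1e5
            nondx = inputs.nondx_rate.at(age, year, country=cid)
            q = 1.0 if age == a_max else inputs.background_mortality.at(age, year, country=cid)
            q_t1d = min(1.0, 1.0 - (1.0 - q) ** inputs.smr.at(age, year, country=cid))
            onsets = rng.binomial(alive_s, inc)
            d_nondx = rng.binomial(onsets, nondx)
            new_dx = onsets - d_nondx
            d_bg = rng.binomial(alive_s - onsets, q)
            d_dx = rng.binomial(alive_d + new_dx, q_t1d)
            alive_s -= onsets + d_bg
            alive_d += new_dx - d_dx
            if first_year <= year <= last_year:
                j = year - first_year
                out["prevalence"][age, j] += alive_d
                out["incident_diagnosed"][age, j] += new_dx
                out["deaths_onset_nondx"][age, j] += d_nondx
                out["deaths_after_dx"][age, j] += d_dx
                out["deaths_background"][age, j] += d_bg
    return out


def microsim_mean_se(inputs, first_year, last_year, a_max, rng, reps=20):
    """Replicate the microsimulation and return per-cell means and standard
    errors of the mean, channel by channel."""
    runs = [microsim_country(inputs, first_year, last_year, a_max, rng)
            for _ in range(reps)]
    mean, se = {}, {}
    for channel in runs[0]:
        stack = np.stack([r[channel] for r in runs])
        mean[channel] = stack.mean(axis=0)
        se[channel] = stack.std(axis=0, ddof=1) / np.sqrt(reps)
    return mean, se


def enumerate_complication_paths(registry, journeys, hba1c, D, hazard_fn,
                                 duration_cap=30):
    """Joint complication-state distribution by exhaustive path enumeration.

    Depth-first over years: at each year every absent, unblocked
    complication either occurs or not, each branch weighted by its
    Bernoulli probability.  Independent of the implementation's
    recursion over the aggregated state space.
    """
    names = [s.name for s in registry]
    n = len(names)
    blockers = {}
    for j in journeys or ():
        if j.blocked in names and j.blocker in names:
            blockers.setdefault(names.index(j.blocked), []).append(names.index(j.blocker))
    dist = [dict() for _ in range(D + 1)]
    dist[0][frozenset()] = 1.0

    def extend(state, prob, year):
        eff = min(year, duration_cap)
        hazards = {c: hazard_fn(registry[c], hba1c, eff) for c in range(n)}
        candidates = [c for c in range(n) if c not in state
                      and not any(b in state for b in blockers.get(c, []))]

        def branch(i, new_state, p):
            if i == len(candidates):
                dist[year + 1][frozenset(new_state)] = (
                    dist[year + 1].get(frozenset(new_state), 0.0) + p)
                return
            c = candidates[i]
            branch(i + 1, new_state | {c}, p * hazards[c])
            branch(i + 1, new_state, p * (1.0 - hazards[c]))

        branch(0, set(state), prob)

    for year in range(D):
        for state, prob in dist[year].items():
            extend(state, prob, year)
    return dist
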