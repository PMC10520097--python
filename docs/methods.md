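# Methods

## The cohort engine

The model is a deterministic annual-step Markov chain over five states,
run once per birth cohort and aggregated.  Ages are completed years,
0..99 by default; age 99 is absorbing to death.  The within-year event
order is fixed: onset among the susceptible, then non-diagnosis death
among the new onsets, then background death among the remaining
susceptible, then death among the diagnosed (including the year's new
entrants).  This order makes onset deaths a fraction of incident cases,
matching the survey definition of dying "soon after onset", and it is
pinned by tests: with cohort 1,000, incidence 100/100k, non-diagnosis
rate 0.2, background q 0.005 and SMR 3, deaths among the newly
diagnosed in the first year equal
1000 × 0.001 × 0.8 × (1 − 0.995³) and the survivors
1000 × 0.001 × 0.8 × 0.995³, as a per-individual microsimulation
confirms.

The SMR acts on the hazard scale, `q_t1d = 1 − (1 − q)^SMR`, capped at
1.  Direct multiplication `q × SMR` would exceed 1 at high ages; the
hazard form is monotone in SMR, reduces to `q` at SMR = 1, and keeps the
chain well defined for any SMR ≥ 0.  SMR values below 1 are accepted
but warned about.

Life expectancy uses a half-cycle correction: a person who dies within
a model year is credited 0.5 person-years in that year, survivors 1.0.
Life expectancy at onset includes the non-diagnosis death risk at the
onset itself (that branch contributes 0.5 years).  Prevalence counts
diagnosed people alive at the end of each year.  Surfaces are extended
beyond their data horizon by carrying the last year's values forward
when a recent-onset cohort must be followed to the terminal age; the
extension is explicit (`AgeYearSurface.extend_years`) and configurable
by supplying longer surfaces instead.

Deaths among the diagnosed are reported two ways: all-cause
(`deaths_after_dx`, the chain's flow) and the excess component
(all-cause minus the background-equivalent deaths the same people would
have suffered at SMR = 1).  Published decompositions of T1D deaths can
be read either way; both are exposed and the mapping is left to the
caller.

"Missing prevalence" is the difference between a counterfactual run
with non-diagnosis rates set to 0 and SMR set to 1, and the factual
run, all else equal.  It is non-negative whenever SMR ≥ 1 and is floored
at 0 against round-off.

## Incidence

Sparse observations are turned into complete (age, year) surfaces in
four steps.

- **Smoothing**: centred moving average, window truncated at the series
  boundaries, default window 5 years (the smoother itself is not
  dictated by any source; the truncated mean preserves constants and
  never widens the range).
- **APC trend**: per-country year-on-year percentage changes from
  consecutive-year observations are pooled by calendar year; years
  within 1985–2015 with at least two contributing countries enter an
  ordinary least-squares line of change versus year.  Regions meeting
  the two-country rule independently get their own line; others carry a
  fallback flag and evaluate to the global line.  The curve evaluates
  at any year by linear extension.
- **Extrapolation**: an anchor rate compounds along the curve; moving
  from year *t* to *t* + 1 multiplies by 1 + APC(*t* + 1)/100 and the
  backward step divides, so forward-then-backward returns the anchor to
  machine precision.  Incidence before 1975 is held at the 1975 value
  by default (data before then are essentially absent); linear decay to
  50 % over 25 years and a linear ramp to zero are selectable
  alternatives.
- **Ratio imputation** for countries with no data: donors come from the
  narrowest non-empty stratum (region × income group → region →
  global), deduplicated by country; their arithmetic median series is
  scaled by the ratio of a log-linear regression prediction (incidence
  on region and income-group indicators over the full donor pool) for
  the target versus the stratum median prediction.  The stratum
  widening order and the regression form are this package's choices and
  are deliberately replaceable.

The onset-age density is a mixture of two normal bumps discretized over
single years: the default variant (childhood bump at 12 ± 4 carrying
35 % of the mass, adult bump at 40 ± 20) peaks at ages 10–14 yet has a
median onset age of 26, reflecting the adult-onset majority; the
sub-Saharan Africa variant moves the childhood bump to 18 ± 5,
producing the regionally later peak.  An all-age incidence level is
spread across ages by rescaling the density so its
reference-population-weighted mean equals the level (uniform reference
weights by default).

## Mortality

Non-diagnosis death rates are a (region, era) lookup with eras before
2000, 2000–2010 (closed interval; the era labels alone do not decide
the boundary year, so the convention is fixed here and tested) and
after 2010.  Queries return 0 for high-income countries and at ages 25
and over, regardless of the stored rates.  Of the packaged schedule
only the Sub-Saharan-Africa pre-2010 value of 0.60 is externally
anchored; the other cells are synthetic placeholders with a plausible
gradient and are marked as such.

The SMR predictor is a distance-weighted k-nearest-neighbour regressor
(k = 3) on standardized numeric covariates (infant mortality, doctors
per capita, GDP per capita, under-5 mortality, urbanisation) with
region and income class as weighted one-hot columns, so matching
categories shorten the distance.  k-NN was chosen for transparency and
exact interpolation at support points; the predictor object is the
interface behind which gradient boosting or penalized regression could
be swapped.  Predictions are clipped to [1, 30] by default — an SMR
below 1 (mortality better than background) is treated as implausible —
and both bounds are configuration.

The mean-HbA1c → SMR relation enters as a monotone knot table with
piecewise-linear interpolation, clamped at the end knots.  The default
knots (SMR 1.0 at 6 %, rising to 9.0 at 12 %) encode the qualitative
shape of published excess-mortality gradients and are configuration,
not estimates.  The age pattern of SMR is exposed as a mean-1
multiplier profile; the packaged default is flat because no tabulated
pattern exists — this is a declared gap, not a finding.

## Diagnosis-rate inference

Observed incidence is true incidence times the diagnosis rate, so the
ratio of observed incidences between two years factors exactly into a
true-incidence ratio and a diagnosis-rate ratio.  The module evaluates
the chain unrounded end to end and reports display-rounded values
alongside (one decimal per step; nearest-integer percent for the
baseline rate).  For the Mali case (0.12 → 0.74 per 100,000 over
2007–2016) the elapsed time is 9 years; with 9 years the printed chain
6.2 → 22.4 % → 1.8 → 3.4 → 30 % reproduces exactly, whereas an
exponent of 6 is inconsistent with those same figures.

## Healthy life years

Stage one maps a care level to a mean HbA1c and, through the knot
table, to an SMR that replaces the country's SMR surface; the engine
then gives survival and life expectancy at onset.  Stage two runs a
forward recursion over the joint state space of eight complications
(2⁸ = 256 states): each year every absent complication occurs
independently with an annual hazard
`expit(intercept + b_h × HbA1c + b_d × duration)` unless an
impermissible journey blocks it (no de-novo proliferative retinopathy
once blind; no de-novo hypertension/microalbuminuria with overt
nephropathy); complications persist.  The packaged hazard coefficients
are synthetic defaults producing plausible 30-year cumulative
frequencies; published duration-cohort fits drop in via configuration.
Hazards beyond duration 30 hold the duration-30 value by default
(continuing the log-odds trend or zeroing new occurrences are
selectable) because no estimate exists out there.

HALYs lost = death component + disability component.  The death
component is background remaining life expectancy at onset minus model
life expectancy.  The disability component weights each expected
person-year lived (half-cycle rules as above; the non-diagnosis branch
contributes half a disability-free year) by the expected disability at
that duration, with coexisting complications combined multiplicatively,
`1 − Π(1 − w_c)`, on the joint distribution (additive-capped-at-1 is
available).  Disability weights are GBD-style configuration inputs.

## Projections

Conservative scenarios freeze incidence, SMR and non-diagnosis rates at
the last data year.  Momentum scenarios compound each forward at its
per-age average annual rate of change over 2012–2021, implemented as
the geometric mean of year-on-year ratios — `(v_end/v_start)^(1/n)` —
because the geometric mean is the unique average consistent with
compounding (an arithmetic mean and an all-age switch are options).
The diagnosis-rate trend is applied to the complement 1 − rate so the
projected rate cannot leave [0, 1].  Future population must be
supplied; carrying it constant is allowed with a warning.

## Synthetic data

Five archetypes (HIC-high-incidence, HIC-low-incidence, UMIC, LMIC,
LIC-SSA) generate complete, internally consistent input bundles:
births series with archetype growth, population propagated by
survivorship, a stylized mortality curve (infant hump plus Gompertz
senescence, improving 0.7 %/yr) scaled per archetype, incidence from
the onset density and an exponential level path held flat before 1975,
era-bucketed non-diagnosis rates and a trending age-flat SMR floored at
1.  Parameter ranges bracket the spread of published national
estimates.  Everything is deterministic for a fixed seed; optional
lognormal jitter on births is seeded.

What the generator does *not* emulate: migration, sub-national
heterogeneity, year-to-year incidence fluctuation, reporting error,
age-varying SMR, or correlation between incidence and mortality trends.
Passing tests on these bundles therefore demonstrates internal
correctness of the machinery (conservation, oracle agreement, parameter
recovery), not calibration to any real country.

The SMR training-set sampler draws covariates along a single latent
development score, because real development indicators are strongly
collinear; the relative jitter (0.2 %) is deliberately kept below the
typical inter-point spacing so that nearest-neighbour recovery error
measures the learner rather than sampler noise.  The default size of 71
points mirrors the sparsity of the real evidence base.

The transcribed 2021 reference tables ship with pinned SHA-256
checksums.  Ambiguous source cells (Morocco's dual study years;
Jamaica's and Togo's missing study year) carry a note field rather
than a silently chosen value.  The table checks recompute the
Atlas-versus-Index percentage per country and compare with the printed
integer column both strictly (± 1 point) and with the ± 0.05 rounding
interval of the printed one-decimal incidence values propagated; the
strict comparison cannot hold for low-incidence rows (two countries
printing 0.4 vs 0.4 show printed differences of both 0 and 5), which is
why the rounding-aware form is the primary check.  The median of the
recomputed percentages computed from one-decimal inputs is 26.3 with a
rounding-propagated interval of [20.8, 34.8]; a published median of
27.5 computed from unrounded values lies inside that interval but is
not recoverable exactly from the printed table.

## Numerical and testing choices

- Conservation of every cohort is enforced to 1e-9 relative.
- The engine's independent oracle is a per-individual stochastic
  simulation (binomial draws, which is exactly the aggregate of
  independent individuals) with the same rates and event order; tests
  compare replicate means against engine expectations within three
  empirical standard errors on a three-cohort, twenty-age world at
  n = 100,000 per cohort, a scale at which a per-cell three-sigma bound
  is appropriate.
- The complication recursion is checked against exhaustive
  occurrence-path enumeration (three complications, four years) to
  1e-12.
- Share pairs are rounded to nearest integers; if they fail to sum to
  100 the larger share absorbs the difference.
- Degenerate inputs fail loudly: missing surface cells name the
  country, age and year; even smoothing windows, non-monotone knot
  tables, inverted age bands, empty donor pools and tampered fixtures
  all raise typed errors.

## Problem sizes

Tests and the acceptance script run on deliberately small worlds:
toy countries of 10–60 ages, synthetic archetypes over 1915–2030 with
the default 100 ages, microsimulation at 100,000 individuals per cohort
with 50 replicates, 200-point training sets with 50 held-out queries.
These sizes make every check exact or tightly bounded while keeping a
full run in seconds.

## Known limitations

- No uncertainty intervals anywhere: the engine is deterministic and
  the survey and predictor inputs carry none.
- The packaged HbA1c knots, complication hazards, disability weights
  and non-SSA survey rates are plausible placeholders, not estimates;
  results using defaults illustrate structure, not real countries.
- Hypertension/microalbuminuria is modelled as independent with a
  blocked de-novo transition, not as a precursor state that progresses
  to overt nephropathy.
- The diagnosis-rate inference reports bounds; it does not feed back
  into the incidence inputs.
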