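"""Run the cohort engine on a synthetic lower-middle-income country.

Builds a complete input bundle (population, background mortality,
incidence, non-diagnosis rates, SMR), runs every birth cohort through
the five-state Markov chain and prints the headline burden per year.
"""

from t1dsim import make_country, run_country

inputs = make_country("LMIC", seed=1, years=(1915, 2025))
burden = run_country(inputs, 2015, 2021)

print(burden.summary_frame().round(0).to_string(index=False))
print()
print("Each row: diagnosed people alive at end of year (prevalence), new")
print("diagnosed cases, deaths at onset from non-diagnosis, all-cause deaths")
print("among the diagnosed (and their excess over background), and")
print("background deaths among people without T1D.")
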