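"""Predict standardized mortality ratios from country covariates.

Published SMRs for people living with T1D exist for only a sparse set of
country-years, so the model predicts them from development indicators.
This example trains the k-nearest-neighbour predictor on a synthetic set
with known ground truth (SMR = 1 + 0.2 x under-5 mortality), checks
recovery, and shows the care-level -> HbA1c -> SMR chain.
"""

import numpy as np

from t1dsim import fit_smr_predictor, make_smr_training, smr_from_hba1c
from t1dsim.mortality import DEFAULT_CARE_LEVELS, DEFAULT_HBA1C_SMR_KNOTS

training, truth = make_smr_training(200, seed=3)
print("generating function:", truth.description)
predictor = fit_smr_predictor(training)

held_out, _ = make_smr_training(50, seed=999)
errors = [predictor.predict(p.covariates) - p.smr for p in held_out]
print("held-out RMSE on 50 new countries: %.3f" % np.sqrt(np.mean(np.square(errors))))

for name, care in DEFAULT_CARE_LEVELS.items():
    smr = smr_from_hba1c(DEFAULT_HBA1C_SMR_KNOTS, care.mean_hba1c)
    print(f"care level {name:12s} mean HbA1c {care.mean_hba1c:4.1f}% -> SMR {smr:.2f}")
print()
print("An SMR of 3.5 means a person with T1D faces 3.5x the background")
print("mortality hazard of someone the same age in the same country-year.")
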