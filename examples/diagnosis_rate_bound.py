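"""Bound a historical diagnosis rate from an observed incidence change.

Observed incidence under 25 in Mali rose from 0.12 to 0.74 per 100,000
between 2007 and 2016.  Because observed incidence = true incidence x
diagnosis rate, the observed ratio factors into a true-incidence ratio
and a diagnosis-rate ratio.
"""

import json

from t1dsim import DiagnosisCase, full_chain

case = DiagnosisCase(i0=0.12, y0=2007, i1=0.74, y1=2016,
                     assumed_true_apc=0.07, assumed_final_dx_rate=1.0)
chain = full_chain(case)
print(json.dumps(chain["rounded"], indent=2))
print()
print("Even granting a rapid 7%/yr true increase (ratio 1.8), the observed")
print("6.2-fold rise needs a 3.4-fold improvement in the diagnosis rate --")
print("so at most ~30% of cases were being diagnosed in 2007.")
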