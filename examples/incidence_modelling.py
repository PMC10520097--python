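"""Incidence surfaces from sparse data: smoothing, trend, imputation, shape.

Walks the pipeline a data-poor country goes through: smooth a noisy
series, fit the annual-percentage-change (APC) trend on donor countries,
extrapolate an old study to the present, impute a series for a country
with no data at all, and spread an all-age level across ages with the
onset-age density.
"""

import numpy as np
import pandas as pd

from t1dsim import (IncidenceObservation, build_incidence_surface,
                    default_onset_distribution, extrapolate_incidence,
                    fit_apc_curves, ratio_impute, smooth_series)
from t1dsim.incidence import CountryProfile

rng = np.random.default_rng(0)

noisy = pd.Series(10 + rng.normal(0, 1.5, 11), index=range(2005, 2016))
print("smoothed 2010 value:", round(smooth_series(noisy, 5)[2010], 2),
      "(raw", round(noisy[2010], 2), ")")

obs = [IncidenceObservation(f"c{c}", "Europe and Central Asia", y, 0, 14,
                            base * 1.03 ** (y - 1985))
       for c, base in enumerate((8.0, 15.0, 22.0, 30.0))
       for y in range(1985, 2016)]
curve, regional = fit_apc_curves(obs)
print("fitted APC at 2000: %.2f %%/yr (true 3.0)" % curve.apc_at(2000))

anchor = IncidenceObservation("old-study", "Europe and Central Asia", 1995,
                              0, 14, 12.0)
series = extrapolate_incidence(anchor, curve, range(1995, 2022))
print("1995 study rate 12.0 extrapolated to 2021: %.1f" % series[2021])

target = CountryProfile("no-data", "Europe and Central Asia", "UMIC")
donors = [(CountryProfile(f"c{c}", "Europe and Central Asia", "UMIC"),
           pd.Series(v, index=range(2000, 2021)))
          for c, v in enumerate((9.0, 14.0, 21.0))]
print("imputed series (constant donors 9/14/21):",
      round(ratio_impute(target, donors).iloc[0], 1))

surface = build_incidence_surface(default_onset_distribution(),
                                  pd.Series([10.0], index=[2021]))
print("age of peak onset:", int(surface.values[:, 0].argmax()),
      "| median onset age:", default_onset_distribution().median_age())
print()
print("The childhood peak sits at 10-14 years while the median onset age is")
print("adult -- adult-onset T1D outnumbers childhood onset.")
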