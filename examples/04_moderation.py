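"""Simple-effects (moderation) analysis of recovery on neural variability.

Fits recovery = b0 + b1*V + b2*Ic + b3*(V*Ic) with mean-centered
interdependence and evaluates the conditional slope of recovery on mean
important-node variability for interdependent (M + SD) and independent
(M - SD) individuals, on the whole cohort and within each depression group.
"""

import numpy as np

import varicpm as v

rng = np.random.default_rng(5)
n = 60
v_mean = rng.uniform(0.4, 1.6, n)          # mean important-node variability
interdep = rng.standard_normal(n)          # interdependence (subscale diff)
groups = np.where(rng.random(n) < 0.47, "high", "low")
ic = interdep - interdep.mean()
# generating model: variability helps only interdependent individuals
recovery = 1.0 + 2.0 * v_mean + 0.3 * ic + 5.0 * v_mean * ic + 1.5 * rng.standard_normal(n)

results = v.simple_effects(v_mean, interdep, recovery, groups)
for label, res in results.items():
    print(f"[{label}]  n={res.n}")
    print(f"  slope at high interdependence (M+SD): "
          f"b = {res.slope_high.slope:6.2f}  SE = {res.slope_high.se:.2f}  "
          f"p = {res.slope_high.p:.4f}")
    print(f"  slope at low  interdependence (M-SD): "
          f"b = {res.slope_low.slope:6.2f}  SE = {res.slope_low.se:.2f}  "
          f"p = {res.slope_low.p:.4f}")
print("\nA positive high-interdependence slope with a flat low-interdependence "
      "slope is the moderation signature: variability predicts recovery only "
      "in interdependent individuals.")
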