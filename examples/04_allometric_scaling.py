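"""Allometric back-projection and the rabbit-to-human age map.

Fits a power law to the weight time course, scales the final-week cardiac
output back to younger ages (CO proportional to weight), and maps study
weeks to approximate human-equivalent ages.
"""

from coasim.allometry import fit_power_law, map_rabbit_to_human_age, scale_by_weight
from coasim.cohort import TIMEPOINTS_WEEKS, body_weights_kg

weights = body_weights_kg()
fit = fit_power_law(TIMEPOINTS_WEEKS, weights)
print(f"weight power law: w = {fit.a:.3f} * t^{fit.b:.3f} (t in weeks)")

co4 = 6.18  # control final-week cardiac output, ml/s
for t, w in zip(TIMEPOINTS_WEEKS, weights):
    co = scale_by_weight(co4, weights[-1], w, exponent=1.0)
    age = map_rabbit_to_human_age(t)
    print(f"  t = {t:4.0f} wk  w = {w:.2f} kg  CO = {co:.2f} ml/s  "
          f"human-equivalent age ~ {age:.1f} yr")
# CO scales linearly with weight (so the TP ratios reproduce the calibrated
# control values); the age map anchors week 0 at ~7 years and the final week
# at ~16 years.
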