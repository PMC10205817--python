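"""Full control-group pipeline: generate, tune, simulate, report.

Runs all four time points for a control subject and prints the simulated
mechanical stimuli at the proximal aorta together with the tuned boundary
conditions.  Takes ~10 s.
"""

import warnings

from coasim.pipeline import RunConfig, report_tables, run_group

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_group("control", seed=1, config=RunConfig())

print("TP  PP_sim  v_asc   strain  tension   P_sys")
print("     mmHg   cm/s      %     dyn/cm    mmHg")
for tp in bundle["timepoints"]:
    sol, rep = tp["solution"], tp["stimuli"]
    prox = rep.by_name("proximal")
    asc = rep.by_name("ascending")
    print(f"{tp['tp']}   {sol.inlet_pulse_pressure():5.1f}  {asc.v_peak_cm_s:6.1f} "
          f"{prox.strain_pct:7.1f} {prox.tension_dyn_cm:8.0f}  {prox.p_sys_mmhg:6.1f}")

hemo = report_tables(bundle)["hemodynamics"]
print("\nhemodynamics table:")
print(hemo.round(2).to_string(index=False))
# Proximal wall tension climbs from ~2500 to ~4000 dyn/cm across the study
# window while radial strain stays near 11-12 % and the final-week peak
# ascending velocity sits near 100 cm/s -- the control mechanical-stimulus
# baseline against which the coarctation groups are compared.
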