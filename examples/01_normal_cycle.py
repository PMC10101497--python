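"""Simulate the normal (undosed) menstrual cycle and summarise it.

Integrates the 13-state delay model from the packaged reference
parameters for four cycles, then reports the period and the per-hormone
peaks.  In a normal cycle LH, FSH, and estradiol peak in the late
follicular phase (the LH surge triggers ovulation) while progesterone and
inhibin peak in the luteal phase.
"""

from cycleopt import (cycle_metrics, reference_initial_state,
                      reference_parameters, simulate)

params = reference_parameters()
state = reference_initial_state()

traj = simulate(params, history=state, horizon=112.0)
m = cycle_metrics(traj, settle_cycles=1)

print(f"cycle length: {m.period:.2f} days")
print("hormone peaks (settled cycle):")
units = {"E2": "pg/mL", "P4": "ng/mL", "Inh": "IU/mL",
         "LH": "IU/L", "FSH": "IU/L"}
for h, v in m.peaks.items():
    print(f"  {h:>3}: {v:7.1f} {units[h]}  (at day {m.peak_times[h] % m.period:5.1f})")
print(f"LH surge present: {m.lh_surge}; anovulatory: {m.anovulatory}")
# The LH surge (~mid-cycle) marks ovulation; P4 > 5 ng/mL in the luteal
# phase confirms the cycle is ovulatory.
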