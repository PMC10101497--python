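"""Constant-dose monotherapy scans and the anovulation thresholds.

Scans constant exogenous estradiol and progesterone administered
continuously over one 28-day cycle, and refines the smallest anovulatory
doses by bisection.  Anovulation = progesterone below 5 ng/mL throughout
with no LH surge.
"""

import numpy as np

from cycleopt import (min_constant_dose, reference_initial_state,
                      reference_parameters, scan_monotherapy)

params = reference_parameters()
state = reference_initial_state()

e2_scan = scan_monotherapy("estrogen", np.arange(0, 150.1, 2.0), params, state)
anov = e2_scan.anovulatory_doses()
print(f"estrogen scan: anovulatory above ≈ {anov.min():.1f} pg/mL/day"
      if anov.size else "estrogen scan: no anovulatory dose in range")

p4_scan = scan_monotherapy("progesterone", np.arange(0, 4.01, 0.1),
                           params, state)
anov = p4_scan.anovulatory_doses()
if anov.size:
    print(f"progesterone scan: anovulatory window ≈ "
          f"[{anov.min():.1f}, {anov.max():.1f}] ng/mL/day")
    # above the window, the exogenous hormone itself pushes P4 back over
    # the 5 ng/mL criterion: the window is an interval, not a half-line

dose, total = min_constant_dose("estrogen", params, state, resolution=0.01)
print(f"minimum constant estrogen dose: {dose:.2f} pg/mL/day "
      f"-> 28-day total {total:.2f} pg/mL")
dose, total = min_constant_dose("progesterone", params, state, resolution=0.01)
print(f"minimum constant progesterone dose: {dose:.2f} ng/mL/day "
      f"-> 28-day total {total:.2f} ng/mL")
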