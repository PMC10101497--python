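"""Optimal time-varying dosing: estrogen monotherapy.

Solves the dose-minimisation problem min ∫ (P4 - P0)² + a1·u1 dt by
control parameterization (node values joined by modified-Akima cubics).
The dose weight a1 is tuned down by halving until the optimum suppresses
luteinization (max P4 < 5 ng/mL) — the weight that balances the
trade-off depends on the dose scale the parameterisation requires.  The
optimised total dose (AUC) is then compared with the minimum anovulatory
constant schedule.
"""

from cycleopt import (OCProblem, dose_savings, reference_initial_state,
                      reference_parameters, solve_oc, tune_weights)

params = reference_parameters()
state = reference_initial_state()

prob = OCProblem(case="estrogen", a1=0.4, n_nodes=15)
sol = tune_weights(prob, params, state, step=0.05, maxiter=150,
                   multistart=False)
sol = solve_oc(sol.problem, params, state, step=0.05, maxiter=400,
               multistart=False, init_nodes={"u1": sol.u1_nodes})

print(f"tuned dose weight a1 = {sol.problem.a1:g}")
print(f"objective J = {sol.objective:.2f}")
print(f"max P4 under optimal dosing = {sol.metrics.peaks['P4']:.2f} ng/mL "
      f"(luteinization suppressed: {sol.feasible})")
print(f"total dose (AUC u1) = {sol.auc_u1:.1f} pg/mL over 28 days")
peak_day = sol.problem.node_times[sol.u1_nodes.argmax()]
print(f"dominant dose around day {peak_day:.0f}")

savings = dose_savings(sol, params, state)["estrogen"]
print(f"constant-dose reference: {savings['constant_total']:.1f} pg/mL; "
      f"saved {savings['saved_percent']:.0f}% of the constant total")
# concentrating the dose where it breaks follicle recruitment lets the
# schedule undercut the constant regimen by a wide margin
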