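"""Parameter recovery on synthetic data.

Samples a noisy 28-day hormone table from the model at known parameters,
perturbs two identifiable parameters by ±20%, and refits them with the
staged weighted least-squares machinery.  The percentage errors of the
recovered values measure how well daily hormone data constrain the model.
"""

from cycleopt import (SyntheticSpec, fit_staged, generate_dataset,
                      reference_initial_state, reference_parameters)

params = reference_parameters()
state = reference_initial_state()

spec = SyntheticSpec(params=params, init_state=state, sigma=0.05, seed=1,
                     standardize=False, settle_cycles=0)
data = generate_dataset(spec)
print(f"synthetic dataset: {data.n_days} days, 5% multiplicative noise")

start = params.replace(e1=params.e1 * 0.8, p2=params.p2 * 1.25)
fit = fit_staged(data, start, state, stages=("c4",),
                 free={"c4": ("e1", "p2")}, maxiter=250, step=0.05)

for name in ("e1", "p2"):
    true = getattr(params, name)
    got = getattr(fit.params, name)
    print(f"  {name}: true {true:.4g}, recovered {got:.4g} "
          f"({100 * abs(got - true) / true:.1f}% error)")
print(f"final weighted objective: {fit.cost:.4g}")
# errors of a few percent show the two rates are identifiable from daily
# data even under assay-like noise
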