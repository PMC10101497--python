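# Methods

## Model

`cycleopt` implements a 13-state delay-differential-equation model of the
hypothalamic–pituitary–ovarian axis.  The pituitary submodel tracks the
reserve pools and blood concentrations of LH and FSH.  LH synthesis is
stimulated by estradiol (E2) through an order-8 Hill function with
half-saturation `Km_LH` and inhibited by progesterone (P4) through
`1/(1 + P4/Ki_LH_P)`; release of both gonadotropins from the reserve pool
is boosted by P4 and inhibited by E2, with the E2 release factor squared
for FSH so that estradiol restrains FSH release more strongly than LH
release.  FSH synthesis is inhibited by inhibin acting with a discrete
delay `tau` (the time the synthesis machinery takes to respond) and —
the contraception mechanism — directly by circulating progesterone
through `P4/w`.  The ovarian submodel advances a follicle cohort through
nine stages (recruited → growing → dominant follicle → two ovulatory
stages → four luteal stages); recruitment is FSH-driven and divided by
`1 + P4/q`, the second contraception term, and the follicular outflows
carry `LH^alpha` / `LH^gamma` powers so the mid-cycle LH surge flushes the
dominant follicle (ovulation).  Blood E2, P4, and inhibin are quasi-steady
linear combinations of the stage masses; exogenous doses enter these maps
additively through couplings `b1`, `b2` (both 1 by default, i.e. doses are
expressed directly as added blood concentrations).  Setting
`w = q = inf` removes both progesterone-inhibition terms and recovers the
predecessor formulation without a progesterone contraception mechanism.

Units: time in days; LH/FSH in IU/L (reserve pools IU); E2 pg/mL; P4
ng/mL; inhibin IU/mL; stage masses ng.  A distribution volume `v` (L)
converts release fluxes to concentrations.

## Numerics

The single delay acts on inhibin, which is algebraic in the state, so the
delayed term is reconstructed from the stored past rather than carried as
an extra state.  Integration is the method of steps: classical RK4 on a
fixed grid (default 0.01 d) with cubic-Hermite interpolation (values and
derivatives at grid nodes) for the `t - tau` inhibin lookup, keeping the
scheme fourth-order for `tau >= h`.  Halving the step changes hormone
trajectories by < 1e-4 relative on the reference cycle (tested), so the
default step is effectively converged for every quantity reported.
Pre-`t0` history is the initial state held constant; segment-wise
continuation (`continue_simulation`) carries the recent inhibin past so a
split run matches a single long one.  Concentrations entering fractional
powers are floored at zero to guard against sub-tolerance excursions.

## Cycle metrics and the anovulation call

Peaks are local maxima on the dense grid with quadratic refinement.  An
"LH surge" is a local maximum above 30 IU/L and at least 3x the window's
LH minimum — both configurable, chosen to separate the normal surge from
the residual oscillation of suppressed profiles.  The period is the mean
spacing of LH surges after discarding one transient cycle (falling back
to dominant E2 maxima when the surge is suppressed).  A window is
anovulatory when max P4 < 5 ng/mL and no surge occurs; dosing experiments
evaluate this over the single 28-day treatment window starting at t = 0,
matching continuous administration for one cycle.

## Reference parameter set (synthetic)

The packaged parameter files are synthetic: the supplementary sources
that would pin every rate constant are not shipped, so the reference set
was produced with the package's own machinery.  A designed 28-day daily
hormone table (`synth.designed_cycle_table`) encodes the canonical
population-mean cycle — E2 237 pg/mL peaking on day 13, LH 123 IU/L and
FSH 19.6 IU/L on day 14, inhibin 11.5 IU/mL on day 20, P4 17.9 ng/mL on
day 21, with realistic baselines — and the model was calibrated to four
repetitions of it by the staged procedure below.  The resulting closed
loop has a stable ~28.0-day limit cycle with a mid-cycle LH surge and
luteal P4/inhibin maxima.  Its quantitative dose–response landscape (the
estrogen anovulation threshold near 100 pg/mL/day, the progesterone
anovulation window near 2–4.5 ng/mL/day) is a property of this synthetic
parameterisation; the pipeline (scans → threshold refinement → optimal
control → savings) is independent of the particular set.  The
progesterone-inhibition scales were fixed at `w = 10` ng/mL and
`q = 4` ng/mL: of the candidates examined they preserved the normal-cycle
fit and period while producing the qualitative contraception phenomena
the mechanism terms exist for (a finite anovulatory progesterone window,
enhanced combination effect).

Known limitations of the reference set: the luteal P4 peak (~9 ng/mL)
sits below the designed 17.9 ng/mL — the weighted fit trades P4 peak
height against the other four hormones at this structural optimum — and
the estrogen threshold is higher than contraceptively realistic doses.
Both are documented properties of the shipped conditions, not of the
methods.

## Calibration

The objective is a weighted percentage-error sum: residuals are divided
by the observation (removing units), weighted 1 except at each hormone's
peak day (weighted by its z-score: E2 1.58, P4 1.39, Inh 1.35, LH 2.16,
FSH 1.80), summed over hormones and days, and normalised by `1/(M - N)`
(M residuals, N free parameters plus initial conditions) so that
repeating the 28-day table leaves the scale unchanged.  Four repetitions
are used so the fit rewards periodicity.  Stages: (c1) pituitary submodel
with E2/P4/Inh forced by periodic cubic splines through the data; (c2)
ovarian submodel with LH/FSH forcing; (c3) merged closed loop without
`w, q`; (c4) merged with `w, q`.  `fit_staged` optimises in log space
(positivity without constraints) with Nelder–Mead, 5000 iterations per
stage by default; model output is sampled at integer days from the fitted
initial state (the initial conditions are themselves estimated, so no
settling offset is applied).  Simulation failures during search are
penalised with an infinite cost.  Tests exercise the machinery on small
free-parameter subsets; full-vector refinement is possible but slow under
Nelder–Mead, which is why the packaged reference set was produced with a
bounded least-squares variant of the same staged objective.

## Synthetic data generator

`generate_dataset` samples the model itself: one period of the settled
limit cycle is rescaled linearly onto a 28-day grid (mirroring how
clinical cycle data are standardised to 28 days), sampled at days 1..28,
optionally repeated, with multiplicative log-normal noise per observation
(hormone assays are positive and right-skewed; the noise scale per
hormone is a fixture choice, default 0).  What passing recovery tests
show: daily data over one cycle constrain the targeted secretion
coefficients to a few percent under 5% noise (rate constants that move
the surge timing, such as the Hill half-saturation, are *not* recoverable
from a single unrepeated cycle — moving the surge produces a
doubly-penalised misfit with a spurious far-away basin — and are screened
out of the recovery studies).  What they do not show: identifiability of
the full 40+ parameter vector (many directions are sloppy), robustness to
assay bias, or between-woman variability — the generator emulates one
woman's mean cycle, not a population.

## Dosing experiments

Monotherapy scans simulate each constant dose over the 28-day window
(default grids 0.1-spaced) and record LH/P4 extrema and the anovulation
flag; `min_constant_dose` brackets the onset on the coarse grid and
bisects to 0.01 resolution, returning the threshold dose and its 28-day
total.  The combination map evaluates max P4 over an (E2exo, P4exo) grid;
level curves are extracted by per-row linear interpolation of the
monotone estrogen profiles, and the left anovulation boundary slope is an
ordinary least-squares fit to the 5 ng/mL curve restricted to the lower
estrogen range (the fitted range is reported with the estimate).
Period sensitivity uses central differences of the period with respect to
log-parameters at 1% perturbation; perturbations that break periodicity
are flagged unbounded rather than extrapolated.

## Optimal control

The dosing functional is `∫ (P4 - P0)^2 + a1 u1 + a2 u2^4 dt` over
[0, 28] d with target `P0 = 4` ng/mL (just below the 5 ng/mL criterion);
the quartic `u2` power convexifies and smooths the progesterone control.
Cases: estrogen monotherapy (a1 = 0.4), progesterone monotherapy
(a2 = 0.07), combination (a1 = 0.4, a2 = 0.7).  Those weight magnitudes
balance dose against tracking only at a particular dose scale; when the
parameterisation demands larger doses the dose term dominates and the
optimum tolerates P4 above 5 ng/mL.  `tune_weights` therefore implements
the standard recipe — halve the dose weights until the optimum is
feasible (max P4 < 5) — and the examples and acceptance study use it.
Feasibility for the control problem means luteinization is suppressed
(max P4 < 5 ng/mL); the stricter conjunctive anovulation call of the
dose scans (which also demands no LH surge) is not imposed on control
solutions, since the tracking objective targets P4 only and a weak
non-ovulatory LH excursion can persist under time-varying estrogen.  Controls are
parameterized by node values on a uniform grid (29 daily nodes by
default; scaled-down studies use 15) joined by modified-Akima piecewise
cubics — non-overshooting, clipped at zero — and optimised with L-BFGS-B
under bound constraints from several starts (threshold-level constant,
half level, and a seeded randomised start), because the landscape is
multimodal and strongly start-dependent.  The objective is evaluated by
trapezoidal quadrature on the dense solution grid (cross-checked against
a fine Riemann sum in tests).  AUC is the trapezoid of the control over
the window; dose savings compare it with the minimal anovulatory
constant total (for combination therapy, each control's AUC is spread
constantly and the partner's minimal constant dose found by bisection).
Multi-cycle re-dosing re-applies the contiguous "large-dose portion" of
the optimised estrogen control (nodes above 10% of its peak; a
degenerate single-node portion is spread over one day) either at fixed
intervals or whenever E2 crosses a trigger level (default 75 pg/mL) from
below; per-28-day-period anovulation flags are returned.  Under the
reference conditions the triggered heuristic yields partial suppression
(P4 held well below the normal luteal peak) rather than strict
anovulation in every period — sustaining the full criterion across many
cycles would require re-optimising each cycle, which the heuristic
deliberately does not do.

## Design choices where the design was open

- Period marker: LH-surge spacing (E2-peak fallback), configurable in
  effect through the surge thresholds.
- Stability check: `verify_periodicity` compares the last full cycle with
  its predecessor shifted by the most recent surge spacing (not the mean
  spacing, which still carries transient drift and misaligns the steep
  surge).
- `M` counts all residuals (days x hormones); `N` is computed from the
  stage's free-parameter list.
- Dose-schedule files are flat YAML; parameter files flat YAML or
  two-column CSV with names exactly as in the canonical parameter list
  (unknown keys rejected).
- The optimiser for control nodes is quasi-Newton with numerical
  gradients rather than a simplex: with ≤ 58 bound-constrained variables
  and a smooth quadrature objective it converges in minutes at the
  default tolerances.

## Dose-response landscape of the reference set

The estrogen anovulation onset sits near 102 pg/mL/day and the
progesterone window near [1.7, 4.4] ng/mL/day.  Two qualitative
properties differ from what a differently calibrated parameterisation
can show and are asserted as such in the tests: the anovulatory estrogen
set is a contiguous *interval* rather than a half-line (near the top of
the scan range the exogenous estradiol itself approaches the
LH-synthesis half-saturation and a weak, non-ovulatory LH excursion
re-crosses the 30 IU/L surge threshold), and the progesterone-monotherapy
optimum settles at a near-constant rate slightly above the minimal
anovulatory constant dose (the steep rise of endogenous P4 just below
the window's lower edge makes undercutting it costly for the tracking
term), so time-varying progesterone does not save total dose here while
time-varying estrogen saves a large fraction.

## Problem sizes used in the shipped studies

Unit tests run scans on coarsened grids (5 pg/mL estrogen spacing,
0.1–0.2 ng/mL progesterone) and optimal control with 8–10 nodes at a
0.05 d step; the acceptance study uses 0.1-grid progesterone scans,
bisection-refined thresholds, a 31 x 16 contour grid, and 15-node
control solves.  These sizes are the package's default study conditions;
all are arguments, and the full 29-node daily grid is the default for
interactive use.
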