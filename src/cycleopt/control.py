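"""Optimal time-varying dosing by control parameterization.

The dosing problem minimises

    J(u1, u2) = ∫ [ (P4(t) - P0)^2 + a1*u1(t) + a2*u2(t)^4 ] dt

over one 28-day treatment window, where ``u1`` is the exogenous estradiol
rate (pg/mL per day) and ``u2`` the exogenous progesterone rate (ng/mL
per day).  The tracking target ``P0`` sits just below the 5 ng/mL
anovulation threshold; the linear ``u1`` and quartic ``u2`` penalties
minimise total dose while keeping the optimised controls smooth.  The
controls are parameterized by their values on a node grid joined by
modified-Akima piecewise cubics (non-overshooting) and clipped at zero;
the node values are optimised with a bound-constrained quasi-Newton
method from several starting guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import minimize

from .dosing import TREATMENT_WINDOW, min_constant_dose
from .metrics import CycleMetrics, cycle_metrics
from .model import DoseSchedule
from .params import CycleState, ParameterSet
from .simulate import SimulationError, Trajectory, continue_simulation, simulate

__all__ = ["OCProblem", "OCSolution", "objective_J", "solve_oc",
           "tune_weights", "dose_savings", "multi_cycle_redose"]

CASES = ("estrogen", "progesterone", "combination")


@dataclass(frozen=True)
class OCProblem:
    """Specification of the dose-minimisation problem.

    Default weights follow the three studied cases: estrogen monotherapy
    ``a1 = 0.4``, progesterone monotherapy ``a2 = 0.07``, combination
    ``a1 = 0.4, a2 = 0.7``; the tracking target is 4 ng/mL.
    """

    case: str = "estrogen"
    p0: float = 4.0              # ng/mL, P4 tracking target (< 5)
    a1: float = 0.4              # weight on the linear u1 term
    a2: float = 0.07             # weight on the quartic u2 term
    t0: float = 0.0
    tf: float = TREATMENT_WINDOW
    n_nodes: int = 29            # daily nodes over [0, 28]
    u1_max: float = 100.0        # pg/mL/day upper bound
    u2_max: float = 10.0         # ng/mL/day upper bound
    u1_power: float = 1.0
    u2_power: float = 4.0

    def __post_init__(self):
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}")
        if not (0 <= self.p0 < 5.0):
            raise ValueError("target P0 must lie in [0, 5) ng/mL")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("weights must be non-negative")
        if self.tf <= self.t0:
            raise ValueError("tf must exceed t0")

    @property
    def node_times(self) -> np.ndarray:
        return np.linspace(self.t0, self.tf, self.n_nodes)

    @property
    def uses_u1(self) -> bool:
        return self.case in ("estrogen", "combination")

    @property
    def uses_u2(self) -> bool:
        return self.case in ("progesterone", "combination")

    @classmethod
    def from_file(cls, path) -> "OCProblem":
        raw = yaml.safe_load(open(path)) or {}
        return cls(**raw)


@dataclass(frozen=True)
class OCSolution:
    """Optimised node values with the resulting controls and trajectory."""

    problem: OCProblem
    u1_nodes: np.ndarray
    u2_nodes: np.ndarray
    objective: float
    trajectory: Trajectory
    metrics: CycleMetrics
    auc_u1: float                # pg/mL over the window
    auc_u2: float                # ng/mL over the window
    n_evals: int = 0
    converged: bool = True
    feasible: bool = True        # max P4 < 5 at the optimum

    def dose_schedule(self) -> DoseSchedule:
        return _nodes_to_dose(self.problem, self.u1_nodes, self.u2_nodes)

    def summary(self) -> dict:
        return {
            "case": self.problem.case,
            "objective": self.objective,
            "max_P4": self.metrics.peaks["P4"],
            "auc_u1": self.auc_u1,
            "auc_u2": self.auc_u2,
            "anovulatory": self.metrics.anovulatory,
            "feasible": self.feasible,
            "converged": self.converged,
        }


def _nodes_to_dose(prob: OCProblem, u1_nodes, u2_nodes) -> DoseSchedule:
    times = prob.node_times
    return DoseSchedule.from_nodes(
        times,
        e2_values=np.maximum(u1_nodes, 0.0) if prob.uses_u1 else None,
        p4_values=np.maximum(u2_nodes, 0.0) if prob.uses_u2 else None,
    )


def objective_J(
    traj: Trajectory,
    u1,
    u2,
    prob: OCProblem,
) -> float:
    """Evaluate the dosing functional by trapezoidal quadrature.

    ``u1``/``u2`` may be callables or arrays aligned with ``traj.t``; the
    trajectory must already be the solution under those controls.
    """
    m = (traj.t >= prob.t0) & (traj.t <= prob.tf)
    t = traj.t[m]
    p4 = traj.P4[m]
    u1v = np.asarray(u1(t) if callable(u1) else np.asarray(u1)[m], float)
    u2v = np.asarray(u2(t) if callable(u2) else np.asarray(u2)[m], float)
    integrand = (p4 - prob.p0) ** 2 \
        + prob.a1 * u1v ** prob.u1_power \
        + prob.a2 * u2v ** prob.u2_power
    return float(np.trapezoid(integrand, t))


def _evaluate(prob: OCProblem, params, history, u1_nodes, u2_nodes, step):
    dose = _nodes_to_dose(prob, u1_nodes, u2_nodes)
    traj = simulate(params, dose, history, horizon=prob.tf - prob.t0,
                    step=step)
    u1v, u2v = dose.sample(traj.t)
    J = objective_J(traj, u1v, u2v, prob)
    return J, traj, dose


def solve_oc(
    prob: OCProblem,
    params: ParameterSet,
    history: CycleState | None = None,
    init_nodes: dict | None = None,
    step: float = 0.02,
    maxiter: int = 400,
    multistart: bool = True,
    seed: int = 0,
) -> OCSolution:
    """Optimise the control nodes for the given case.

    Starting guesses: the threshold-level constant schedule, a mid-level
    constant, and (optionally) user-supplied ``init_nodes``; the best
    local optimum is returned.  The landscape depends strongly on the
    starting guess, hence the multi-start.  Non-convergence returns the
    best iterate with ``converged=False``; an optimum with max P4 >= 5 is
    flagged infeasible rather than raising.
    """
    nt = prob.n_nodes
    free_u1 = prob.uses_u1
    free_u2 = prob.uses_u2
    nfree = nt * (free_u1 + free_u2)

    def unpack(x):
        i = 0
        u1 = np.zeros(nt)
        u2 = np.zeros(nt)
        if free_u1:
            u1 = x[i:i + nt]
            i += nt
        if free_u2:
            u2 = x[i:i + nt]
        return u1, u2

    evals = [0]

    def fun(x):
        u1, u2 = unpack(x)
        evals[0] += 1
        try:
            J, _, _ = _evaluate(prob, params, history, u1, u2, step)
        except (SimulationError, ValueError):
            return 1e12
        return J

    starts = []
    const_guess = []
    if free_u1:
        try:
            d, _ = min_constant_dose("estrogen", params, history, step=step)
        except ValueError:
            d = 0.5 * prob.u1_max
        const_guess.append(np.full(nt, d))
    if free_u2:
        try:
            d, _ = min_constant_dose("progesterone", params, history, step=step)
        except ValueError:
            d = 0.5 * prob.u2_max
        const_guess.append(np.full(nt, d))
    starts.append(np.concatenate(const_guess))
    if multistart:
        starts.append(0.5 * starts[0])
        rng = np.random.default_rng(seed)
        starts.append(starts[0] * rng.uniform(0.3, 1.2, size=nfree))
    if init_nodes is not None:
        x0 = []
        if free_u1:
            x0.append(np.asarray(init_nodes.get("u1", np.zeros(nt)), float))
        if free_u2:
            x0.append(np.asarray(init_nodes.get("u2", np.zeros(nt)), float))
        starts.insert(0, np.concatenate(x0))

    bounds = []
    if free_u1:
        bounds += [(0.0, prob.u1_max)] * nt
    if free_u2:
        bounds += [(0.0, prob.u2_max)] * nt

    best = None
    for x0 in starts:
        res = minimize(fun, np.clip(x0, 0, None), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10,
                                "eps": 1e-3})
        if best is None or res.fun < best.fun:
            best = res
    u1, u2 = unpack(best.x)
    J, traj, dose = _evaluate(prob, params, history, u1, u2, step)
    met = cycle_metrics(traj, window=(prob.t0, prob.tf))
    u1v, u2v = dose.sample(traj.t)
    return OCSolution(
        problem=prob, u1_nodes=u1, u2_nodes=u2, objective=J,
        trajectory=traj, metrics=met,
        auc_u1=float(np.trapezoid(u1v, traj.t)),
        auc_u2=float(np.trapezoid(u2v, traj.t)),
        n_evals=evals[0], converged=bool(best.success),
        feasible=met.peaks["P4"] < 5.0,
    )


def tune_weights(
    prob: OCProblem,
    params: ParameterSet,
    history: CycleState | None = None,
    max_halvings: int = 8,
    **solve_kwargs,
) -> OCSolution:
    """Lower the dose weights until the optimum is anovulatory.

    Dose-penalty weights appropriate for one parameterisation can
    overwhelm the progesterone-tracking term under another (the trade-off
    scales with the dose magnitude the cycle requires).  Following the
    standard recipe, ``a1``/``a2`` are halved until the optimised
    schedule achieves max P4 < 5 ng/mL (luteinization suppressed — the
    feasibility notion for the control problem); the first feasible
    solution is returned (or the last attempt, flagged infeasible).
    """
    sol = None
    for _ in range(max_halvings + 1):
        sol = solve_oc(prob, params, history, **solve_kwargs)
        if sol.feasible:
            return sol
        prob = replace(prob,
                       a1=prob.a1 / 2.0 if prob.uses_u1 else prob.a1,
                       a2=prob.a2 / 2.0 if prob.uses_u2 else prob.a2)
    return sol


def dose_savings(
    oc: OCSolution,
    params: ParameterSet,
    history: CycleState | None = None,
    step: float = 0.01,
) -> dict:
    """Total-dose savings of the optimised schedule vs constant dosing.

    For monotherapy the reference is the minimum anovulatory constant
    dose times 28.  For combination therapy each control's AUC is spread
    constantly over the window and the partner hormone's minimal
    anovulatory constant dose is found by bisection; the saving is then
    quoted for the partner, mirroring the cross-comparison the constant-
    dose contour suggests.
    """
    out: dict = {"case": oc.problem.case}
    if oc.problem.case in ("estrogen", "progesterone"):
        hormone = oc.problem.case
        dose, total = min_constant_dose(hormone, params, history, step=step)
        auc = oc.auc_u1 if hormone == "estrogen" else oc.auc_u2
        out[hormone] = {
            "constant_dose_per_day": dose,
            "constant_total": total,
            "optimal_auc": auc,
            "saved": total - auc,
            "saved_percent": 100.0 * (total - auc) / total if total else 0.0,
        }
        return out

    # combination: two cross-comparisons against the constant-dose frontier
    def min_partner_e2(p4_const):
        lo, hi = 0.0, 60.0
        def anov(e2d):
            traj = simulate(params, DoseSchedule.constant(e2d, p4_const),
                            history, horizon=TREATMENT_WINDOW, step=step)
            return cycle_metrics(traj, window=(0, TREATMENT_WINDOW)).anovulatory
        if not anov(hi):
            return float("nan")
        while hi - lo > 0.01:
            mid = 0.5 * (lo + hi)
            if anov(mid):
                hi = mid
            else:
                lo = mid
        return hi

    def min_partner_p4(e2_const):
        lo, hi = 0.0, 4.0
        def anov(p4d):
            traj = simulate(params, DoseSchedule.constant(e2_const, p4d),
                            history, horizon=TREATMENT_WINDOW, step=step)
            return cycle_metrics(traj, window=(0, TREATMENT_WINDOW)).anovulatory
        found = None
        d = lo
        while d <= hi + 1e-9:
            if anov(d):
                found = d
                break
            d += 0.1
        if found is None:
            return float("nan")
        lo2, hi2 = max(found - 0.1, 0.0), found
        while hi2 - lo2 > 0.01:
            mid = 0.5 * (lo2 + hi2)
            if anov(mid):
                hi2 = mid
            else:
                lo2 = mid
        return hi2

    p4_spread = oc.auc_u2 / TREATMENT_WINDOW
    e2_req = min_partner_e2(p4_spread)
    e2_total = e2_req * TREATMENT_WINDOW
    out["estrogen"] = {
        "partner_constant_p4": p4_spread,
        "constant_total": e2_total,
        "optimal_auc": oc.auc_u1,
        "saved": e2_total - oc.auc_u1,
        "saved_percent": 100.0 * (e2_total - oc.auc_u1) / e2_total
        if np.isfinite(e2_total) and e2_total else float("nan"),
    }
    e2_spread = oc.auc_u1 / TREATMENT_WINDOW
    p4_req = min_partner_p4(e2_spread)
    p4_total = p4_req * TREATMENT_WINDOW
    out["progesterone"] = {
        "partner_constant_e2": e2_spread,
        "constant_total": p4_total,
        "optimal_auc": oc.auc_u2,
        "saved": p4_total - oc.auc_u2,
        "saved_percent": 100.0 * (p4_total - oc.auc_u2) / p4_total
        if np.isfinite(p4_total) and p4_total else float("nan"),
    }
    return out


# ---------------------------------------------------------------------------
# multi-cycle re-dosing
# ---------------------------------------------------------------------------

def _large_dose_portion(oc: OCSolution, frac: float = 0.1):
    """Contiguous interval where u1 exceeds ``frac`` of its peak, returned
    as (times_relative_to_start, values)."""
    times = oc.problem.node_times
    u1 = oc.u1_nodes
    peak = float(np.max(u1))
    if peak <= 0:
        raise ValueError("solution has no estrogen dose to re-apply")
    above = u1 >= frac * peak
    i_pk = int(np.argmax(u1))
    i0 = i_pk
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = i_pk
    while i1 < len(u1) - 1 and above[i1 + 1]:
        i1 += 1
    seg_t = times[i0:i1 + 1] - times[i0]
    seg_v = u1[i0:i1 + 1].copy()
    if len(seg_t) < 3 or seg_t[-1] < 1.0:
        # degenerate portion (single hot node): spread the peak over one day
        return np.array([0.0, 0.5, 1.0]), np.array([0.0, peak, 0.0])
    seg_v[0] = 0.0
    seg_v[-1] = 0.0   # ramp in/out of the re-applied bolus
    return seg_t, seg_v


def multi_cycle_redose(
    oc: OCSolution,
    params: ParameterSet,
    horizon: float = 280.0,
    trigger_E2: float = 75.0,
    mode: str = "triggered",
    interval: float = TREATMENT_WINDOW,
    first_start: float | None = None,
    history: CycleState | None = None,
    portion_frac: float = 0.1,
    step: float = 0.01,
) -> tuple[Trajectory, list[float], list[bool]]:
    """Re-apply the large-dose portion of the optimised estrogen control
    over many cycles.

    ``mode="fixed"``: applications at equal ``interval`` starting at
    ``first_start`` (default day 35).  ``mode="triggered"``: a new
    application starts whenever E2 crosses ``trigger_E2`` from below and
    no application is active (the rising-E2 biomarker rule).  Returns the
    full trajectory, the application start times, and per-28-day-period
    anovulation flags.
    """
    seg_t, seg_v = _large_dose_portion(oc, portion_frac)
    seg_len = float(seg_t[-1])

    def segment_dose(start):
        return DoseSchedule.from_nodes(start + seg_t, e2_values=seg_v)

    events: list[float] = []
    if mode == "fixed":
        t_first = 35.0 if first_start is None else first_start
        events = [0.0] + list(np.arange(t_first, horizon, interval))
        # initial optimised application at its own schedule
        traj = simulate(params, oc.dose_schedule(), history,
                        horizon=min(TREATMENT_WINDOW, horizon), step=step)
        t_cur = traj.t[-1]
        for ev in events[1:]:
            if ev > t_cur:
                traj = continue_simulation(traj, params, DoseSchedule.zero(),
                                           ev - t_cur, step)
                t_cur = traj.t[-1]
            span = min(seg_len, horizon - t_cur)
            if span <= 0:
                break
            traj = continue_simulation(traj, params, segment_dose(t_cur),
                                       span, step)
            t_cur = traj.t[-1]
        if t_cur < horizon:
            traj = continue_simulation(traj, params, DoseSchedule.zero(),
                                       horizon - t_cur, step)
    elif mode == "triggered":
        traj = simulate(params, oc.dose_schedule(), history,
                        horizon=min(TREATMENT_WINDOW, horizon), step=step)
        events = [float(oc.problem.node_times[int(np.argmax(oc.u1_nodes))])]
        t_cur = traj.t[-1]
        chunk = 1.0
        while t_cur < horizon - 1e-9:
            span = min(chunk, horizon - t_cur)
            traj = continue_simulation(traj, params, DoseSchedule.zero(),
                                       span, step)
            t_cur = traj.t[-1]
            seg = traj.window(t_cur - span, t_cur)
            rising = (seg.E2[:-1] < trigger_E2) & (seg.E2[1:] >= trigger_E2)
            if rising.any():
                t_trig = float(seg.t[:-1][rising][0])
                # rewind to the crossing and apply the bolus there
                keep = traj.t <= t_trig
                traj = Trajectory(traj.t[keep], traj.states[keep],
                                  traj.E2[keep], traj.P4[keep],
                                  traj.Inh[keep], traj.LH[keep],
                                  traj.FSH[keep])
                t_cur = traj.t[-1]
                events.append(t_cur)
                span = min(seg_len, horizon - t_cur)
                if span > 0:
                    traj = continue_simulation(traj, params,
                                               segment_dose(t_cur), span, step)
                    t_cur = traj.t[-1]
    else:
        raise ValueError("mode must be 'fixed' or 'triggered'")

    flags = []
    n_periods = int(horizon // TREATMENT_WINDOW)
    for k in range(n_periods):
        w = traj.window(k * TREATMENT_WINDOW, (k + 1) * TREATMENT_WINDOW)
        m = cycle_metrics(w, window=(w.t[0], w.t[-1]))
        flags.append(bool(m.anovulatory))
    return traj, events, flags
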