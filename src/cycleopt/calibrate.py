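"""Weighted least-squares calibration of the cycle model.

The objective is a percentage-error sum: each residual is divided by the
observation, removing unit differences between hormones, weighted 1
except at each hormone's peak day (weighted by the peak's z-score so the
fit reproduces maxima), and normalised by ``1/(M - N)`` where ``M`` counts
residuals and ``N`` free parameters plus initial conditions — repetition
of the 28-day table then leaves the objective scale unchanged.

Fitting is staged: the pituitary submodel is fitted first with the
ovarian hormones replaced by periodic-spline forcings of the data (c1),
then the ovarian submodel with gonadotropin forcings (c2), then the
merged closed-loop model without (c3) and finally with (c4) the
progesterone-inhibition terms ``w``/``q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from . import _kernel
from .model import DoseSchedule
from .params import PARAM_ORDER, STATE_ORDER, CycleState, ParameterSet
from .simulate import HORMONES, SimulationError, simulate

__all__ = ["HormoneDataset", "FitResult", "objective_wls", "residual_sums",
           "fit_staged", "PEAK_ZSCORES", "PITUITARY_PARAMS", "OVARIAN_PARAMS"]

#: z-score weights applied at each hormone's peak day
PEAK_ZSCORES = {"E2": 1.58, "P4": 1.39, "Inh": 1.35, "LH": 2.16, "FSH": 1.80}

PITUITARY_PARAMS = ("V0_LH", "V1_LH", "Km_LH", "Ki_LH_P", "k_LH", "c_LH_P",
                    "c_LH_E", "alpha_LH", "V_FSH", "Ki_FSH_Inh", "tau",
                    "k_FSH", "c_FSH_P", "c_FSH_E", "alpha_FSH", "v")
OVARIAN_PARAMS = ("b", "c1", "c2", "c3", "c4", "d1", "d2", "k1", "k2", "k3",
                  "k4", "alpha", "gamma", "e0", "e1", "e2", "e3", "p0", "p1",
                  "p2", "h0", "h1", "h2", "h3")


class HormoneDataset:
    """Daily observed hormone table with per-point weights.

    ``frame`` has columns ``day, E2, P4, Inh, LH, FSH`` (day 1..n); the
    weight table has the same shape and defaults to 1 everywhere.
    """

    def __init__(self, frame: pd.DataFrame, weights: pd.DataFrame | None = None):
        cols = ["day", *HORMONES]
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset missing column(s) {sorted(missing)}")
        frame = frame[cols].reset_index(drop=True)
        if (frame[list(HORMONES)] <= 0).any().any():
            raise ValueError("all observations must be positive")
        self.frame = frame
        if weights is None:
            weights = pd.DataFrame(1.0, index=frame.index, columns=list(HORMONES))
        self.weights = weights.reset_index(drop=True)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HormoneDataset":
        return cls(frame)

    @classmethod
    def from_csv(cls, path: str | Path,
                 weights_path: str | Path | None = None) -> "HormoneDataset":
        frame = pd.read_csv(path)
        weights = None
        if weights_path is not None:
            weights = pd.read_csv(weights_path)[list(HORMONES)]
        return cls(frame, weights)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    # -- transforms ---------------------------------------------------
    @property
    def n_days(self) -> int:
        return len(self.frame)

    @property
    def days(self) -> np.ndarray:
        return self.frame["day"].to_numpy(float)

    def values(self, hormone: str) -> np.ndarray:
        return self.frame[hormone].to_numpy(float)

    def with_peak_weights(self, zscores: dict[str, float] | None = None,
                          base_period: int = 28) -> "HormoneDataset":
        """Weight each hormone's peak day (per 28-day block) by its z-score."""
        z = dict(PEAK_ZSCORES if zscores is None else zscores)
        w = self.weights.copy()
        n_blocks = max(1, self.n_days // base_period)
        for h, zv in z.items():
            y = self.values(h)
            for b in range(n_blocks):
                blk = slice(b * base_period, min((b + 1) * base_period, self.n_days))
                i = b * base_period + int(np.argmax(y[blk]))
                w.loc[i, h] = zv
        return HormoneDataset(self.frame.copy(), w)

    def repeat(self, k: int) -> "HormoneDataset":
        """Tile the table ``k`` times (periodic continuation of the cycle)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        frames = pd.concat([self.frame] * k, ignore_index=True)
        frames["day"] = np.arange(1, len(frames) + 1)
        weights = pd.concat([self.weights] * k, ignore_index=True)
        return HormoneDataset(frames, weights)

    def forcing_splines(self, period: float = 28.0) -> dict:
        """Periodic cubic-spline interpolants of the first cycle of data.

        Each returned callable accepts any time (days) and wraps it onto
        the cycle, so delayed lookups at negative times are well-defined.
        """
        out = {}
        n = int(period)
        for h in HORMONES:
            y = self.values(h)[:n]
            x = np.arange(0.0, period + 1.0)
            yy = np.concatenate([[y[-1]], y])  # day 0 := day 28 (periodic)
            sp = CubicSpline(x, yy, bc_type="periodic")
            out[h] = (lambda t, sp=sp, period=period:
                      sp(np.mod(np.asarray(t, float), period)))
        return out


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _weighted_cost(pred: dict[str, np.ndarray], data: HormoneDataset,
                   hormones: tuple[str, ...], n_free: int) -> float:
    total = 0.0
    m = 0
    for h in hormones:
        obs = data.values(h)
        w = data.weights[h].to_numpy(float)
        r = (pred[h] - obs) / obs
        total += float(np.sum(w * r * r))
        m += len(obs)
    if m <= n_free:
        raise ValueError("need more data points than free parameters")
    return total / (m - n_free)


def _sample_days(params: ParameterSet, init_state: CycleState,
                 n_days: int, step: float) -> dict[str, np.ndarray]:
    traj = simulate(params, DoseSchedule.zero(), init_state,
                    horizon=float(n_days), step=step)
    idx = np.round(np.arange(1, n_days + 1) / step).astype(int)
    return {h: traj.hormone(h)[idx] for h in HORMONES}


def objective_wls(
    params: ParameterSet,
    init_state: CycleState,
    data: HormoneDataset,
    n_free: int = 0,
    step: float = 0.02,
    hormones: tuple[str, ...] = HORMONES,
) -> float:
    """Weighted percentage-error cost of the closed-loop model vs data.

    The model is simulated from ``init_state`` at zero dose over the full
    data span and sampled at integer days.  Simulation failures return
    ``+inf`` so optimizers treat the candidate as infeasible.
    """
    try:
        pred = _sample_days(params, init_state, data.n_days, step)
    except (SimulationError, ValueError, FloatingPointError):
        return math.inf
    return _weighted_cost(pred, data, hormones, n_free)


def residual_sums(params: ParameterSet, init_state: CycleState,
                  data: HormoneDataset, step: float = 0.02) -> dict[str, float]:
    """Plain per-hormone sums of squared residuals on the natural scale."""
    pred = _sample_days(params, init_state, data.n_days, step)
    return {h: float(np.sum((pred[h] - data.values(h)) ** 2)) for h in HORMONES}


# ---------------------------------------------------------------------------
# forced submodels (stages c1 / c2)
# ---------------------------------------------------------------------------

def _simulate_pituitary(params: ParameterSet, ic: np.ndarray, forc: dict,
                        n_days: int, step: float = 0.02,
                        use_w: bool = False) -> dict[str, np.ndarray]:
    """Pituitary submodel (RP_LH, LH, RP_FSH, FSH) with data-driven
    E2/P4/Inh forcing; the delayed inhibin is the forcing spline at t-tau.

    Forcings are pre-evaluated on the half-step grid so the RK4 loop is
    pure scalar arithmetic (this routine sits inside optimisation loops).
    """
    p = params
    n = int(round(n_days / step))
    th = 0.5 * step * np.arange(2 * n + 1)
    e2g = np.asarray(forc["E2"](th), float)
    p4g = np.asarray(forc["P4"](th), float)
    inhg = np.asarray(forc["Inh"](th - p.tau), float)
    # candidate-independent pieces of each term
    km8 = p.Km_LH ** 8
    hillg = p.V1_LH * e2g ** 8 / (km8 + e2g ** 8)
    syn_lh_g = (p.V0_LH + hillg) / (1.0 + p4g / p.Ki_LH_P)
    rel_lh_g = p.k_LH * (1.0 + p.c_LH_P * p4g) / (1.0 + p.c_LH_E * e2g)
    winv = p4g / p.w if use_w else 0.0
    syn_fsh_g = p.V_FSH / (1.0 + inhg / p.Ki_FSH_Inh + winv)
    den = 1.0 + p.c_FSH_E * e2g
    rel_fsh_g = p.k_FSH * (1.0 + p.c_FSH_P * p4g) / (den * den)
    states = _kernel.pituitary_loop(
        syn_lh_g, rel_lh_g, syn_fsh_g, rel_fsh_g, 1.0 / p.v,
        p.alpha_LH, p.alpha_FSH, np.asarray(ic, float), step, n)
    idx = np.round(np.arange(1, n_days + 1) / step).astype(int)
    return {"LH": states[idx, 1], "FSH": states[idx, 3]}


def _ovarian_masses(params: ParameterSet, ic: np.ndarray, forc: dict,
                    n_days: int, step: float = 0.02,
                    use_q: bool = False) -> np.ndarray:
    """Integrate the 9 ovarian stage masses under LH/FSH forcing;
    returns the masses sampled at integer days (n_days, 9)."""
    p = params
    n = int(round(n_days / step))
    th = 0.5 * step * np.arange(2 * n + 1)
    lhg = np.maximum(np.asarray(forc["LH"](th), float), 0.0)
    fshg = np.maximum(np.asarray(forc["FSH"](th), float), 0.0)
    out_rcf = p.c2 * lhg ** p.alpha
    out_grf = p.c3 * lhg
    out_dom = p.c4 * lhg ** p.gamma
    q = p.q if use_q else math.inf
    masses = _kernel.ovarian_loop(
        fshg, out_rcf, out_grf, out_dom, p.b, p.c1, p.d1, p.d2,
        p.k1, p.k2, p.k3, p.k4, p.p0, p.p1, p.p2, q,
        np.asarray(ic, float), step, n)
    idx = np.round(np.arange(1, n_days + 1) / step).astype(int)
    return masses[idx]


def _simulate_ovarian(params: ParameterSet, ic: np.ndarray, forc: dict,
                      n_days: int, step: float = 0.02,
                      use_q: bool = False) -> dict[str, np.ndarray]:
    """Ovarian submodel hormones (E2, P4, Inh) under LH/FSH forcing."""
    p = params
    m = _ovarian_masses(params, ic, forc, n_days, step, use_q)
    return {
        "E2": p.e0 + p.e1 * m[:, 1] + p.e2 * m[:, 2] + p.e3 * m[:, 8],
        "P4": p.p0 + p.p1 * m[:, 7] + p.p2 * m[:, 8],
        "Inh": p.h0 + p.h1 * m[:, 2] + p.h2 * m[:, 6] + p.h3 * m[:, 7],
    }


# ---------------------------------------------------------------------------
# staged fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of :func:`fit_staged` (or a single stage)."""

    params: ParameterSet
    init_state: CycleState
    cost: float
    m: int
    n_free: int
    stages: list = field(default_factory=list)   # (stage, cost, n_iter, converged)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "init_state": self.init_state.to_dict(),
                "cost": self.cost, "M": self.m, "N": self.n_free,
                "stages": list(self.stages)}


def _log_fit(cost_fn, x0_names, current: dict, maxiter: int, method: str):
    """Minimise ``cost_fn(values_dict)`` over log-transformed positives."""
    x0 = np.log([current[k] for k in x0_names])

    def wrapped(x):
        vals = dict(zip(x0_names, np.exp(x)))
        try:
            return cost_fn(vals)
        except (ValueError, FloatingPointError, OverflowError):
            return math.inf

    res = minimize(wrapped, x0, method=method,
                   options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-10}
                   if method == "Nelder-Mead" else {"maxiter": maxiter})
    best = dict(zip(x0_names, np.exp(res.x)))
    if res.fun > wrapped(x0):       # never move uphill from the start point
        best, res.fun = dict(zip(x0_names, np.exp(x0))), wrapped(x0)
    return best, float(res.fun), int(res.get("nit", 0) or 0), bool(res.success)


def fit_staged(
    data: HormoneDataset,
    init_guess: ParameterSet,
    init_state: CycleState | None = None,
    stages: tuple[str, ...] = ("c1", "c2", "c3", "c4"),
    free: dict[str, tuple[str, ...]] | None = None,
    maxiter: int = 5000,
    step: float = 0.02,
    method: str = "Nelder-Mead",
    wq_guess: tuple[float, float] = (0.5, 0.5),
) -> FitResult:
    """Staged weighted least-squares estimation.

    Stage ``c1`` fits the pituitary submodel against LH/FSH with the
    ovarian hormones forced from the data; ``c2`` fits the ovarian
    submodel against E2/P4/Inh with gonadotropin forcing; ``c3`` refines
    the merged model without the progesterone-inhibition terms; ``c4``
    introduces ``w``/``q`` (initialised at ``wq_guess``) and refines.
    ``free`` optionally restricts the free-parameter names per stage
    (state names prefixed ``ic:`` free the corresponding initial
    condition).  Parameters are optimised in log space, which enforces
    positivity without explicit constraints.
    """
    if init_state is None:
        init_state = CycleState()
    free = free or {}
    forc = data.forcing_splines()
    params = init_guess
    state_d = init_state.to_dict()
    stage_log: list = []
    last_cost = math.inf
    n_free_total = 0

    def stage_free(stage: str, default: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(free.get(stage, default))

    for stage in stages:
        if stage == "c1":
            names = stage_free("c1", PITUITARY_PARAMS
                               + ("ic:RP_LH", "ic:LH", "ic:RP_FSH", "ic:FSH"))
        elif stage == "c2":
            names = stage_free("c2", OVARIAN_PARAMS + tuple(
                "ic:" + s for s in STATE_ORDER[4:]))
        elif stage == "c3":
            names = stage_free("c3", PITUITARY_PARAMS + OVARIAN_PARAMS)
        elif stage == "c4":
            if math.isinf(params.w):
                params = params.replace(w=wq_guess[0], q=wq_guess[1])
            names = stage_free("c4", ("w", "q") + PITUITARY_PARAMS + OVARIAN_PARAMS)
        else:
            raise ValueError(f"unknown stage {stage!r}")

        pnames = [n for n in names if not n.startswith("ic:")]
        snames = [n[3:] for n in names if n.startswith("ic:")]
        current = {**{k: getattr(params, k) for k in pnames},
                   **{"ic:" + s: max(state_d[s], 1e-6) for s in snames}}
        n_free = len(current)

        def build(vals):
            p = params.replace(**{k: vals[k] for k in pnames})
            sd = dict(state_d)
            for s in snames:
                sd[s] = vals["ic:" + s]
            return p, CycleState(**sd)

        if stage == "c1":
            def cost_fn(vals):
                p, st = build(vals)
                ic4 = [st.RP_LH, st.LH, st.RP_FSH, st.FSH]
                pred = _simulate_pituitary(p, np.array(ic4), forc,
                                           data.n_days, step)
                return _weighted_cost(pred, data, ("LH", "FSH"), n_free)
        elif stage == "c2":
            def cost_fn(vals):
                p, st = build(vals)
                ic9 = st.to_vector()[4:]
                pred = _simulate_ovarian(p, ic9, forc, data.n_days, step)
                return _weighted_cost(pred, data, ("E2", "P4", "Inh"), n_free)
        else:
            def cost_fn(vals):
                p, st = build(vals)
                if stage == "c3":
                    p = p.without_p4_inhibition()
                return objective_wls(p, st, data, n_free=n_free, step=step)

        best, cost, nit, ok = _log_fit(cost_fn, list(current), current,
                                       maxiter, method)
        params, st = build(best)
        state_d = st.to_dict()
        stage_log.append((stage, cost, nit, ok))
        last_cost = cost
        n_free_total = n_free

    final_state = CycleState(**state_d)
    if "c3" in stages and "c4" not in stages:
        params = params.without_p4_inhibition()
    final_cost = objective_wls(params, final_state, data,
                               n_free=n_free_total, step=step)
    return FitResult(params, final_state, final_cost,
                     m=data.n_days * len(HORMONES), n_free=n_free_total,
                     stages=stage_log)
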