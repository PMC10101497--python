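"""Cycle metrics: period, hormone peaks, LH-surge and anovulation calls.

A cycle is called anovulatory when progesterone stays below 5 ng/mL over
the evaluation window and no LH surge occurs.  "Surge" is operationalised
as a local LH maximum exceeding an absolute threshold (default 30 IU/L)
and a multiple (default 3x) of the window's LH minimum; both settings are
exposed because suppressed profiles keep a small residual LH oscillation
that must not count as a surge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model import DoseSchedule
from .params import CycleState, ParameterSet
from .simulate import HORMONES, Trajectory, simulate

__all__ = ["CycleMetrics", "cycle_metrics", "verify_periodicity",
           "P4_ANOVULATION_THRESHOLD"]

#: ng/mL; a cycle whose P4 maximum stays below this (with no LH surge)
#: is classified anovulatory
P4_ANOVULATION_THRESHOLD = 5.0

LH_SURGE_ABS = 30.0     # IU/L
LH_SURGE_RATIO = 3.0    # x window LH minimum


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic refinement of a local maximum at grid index ``i``."""
    if i <= 0 or i >= len(y) - 1:
        return t[i], y[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return t[i], y[i]
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return t[i] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def _surge_times(t, lh, abs_threshold=LH_SURGE_ABS, ratio=LH_SURGE_RATIO):
    lh_min = float(np.min(lh))
    floor = max(abs_threshold, ratio * lh_min)
    # a surge is a prominent peak, not a slow drift of the baseline above
    # the absolute threshold (seen under heavy constant estrogen)
    idx, _ = find_peaks(lh, height=floor,
                        prominence=0.5 * abs_threshold,
                        distance=max(1, int(5.0 / (t[1] - t[0]))))
    return np.array([_refine_peak(t, lh, i)[0] for i in idx])


def _dominant_peak_times(t, y):
    """Times of the once-per-cycle dominant maxima of a hormone series."""
    span = np.max(y) - np.min(y)
    if span <= 0:
        return np.array([])
    idx, _ = find_peaks(y, prominence=0.5 * span,
                        distance=max(1, int(10.0 / (t[1] - t[0]))))
    return np.array([_refine_peak(t, y, i)[0] for i in idx])


@dataclass(frozen=True)
class CycleMetrics:
    """Summary of one simulated cycle (or dosing window)."""

    period: float                       # days; nan when undefined
    period_defined: bool
    peaks: dict = field(default_factory=dict)        # hormone -> max value
    troughs: dict = field(default_factory=dict)      # hormone -> min value
    peak_times: dict = field(default_factory=dict)   # hormone -> time of max
    lh_surge: bool = False
    anovulatory: bool = False

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "period_defined": self.period_defined,
            "peaks": dict(self.peaks),
            "troughs": dict(self.troughs),
            "peak_times": dict(self.peak_times),
            "lh_surge": self.lh_surge,
            "anovulatory": self.anovulatory,
        }


def cycle_metrics(
    traj: Trajectory,
    settle_cycles: int = 1,
    window: tuple[float, float] | None = None,
    surge_abs: float = LH_SURGE_ABS,
    surge_ratio: float = LH_SURGE_RATIO,
    nominal_period: float = 28.0,
) -> CycleMetrics:
    """Extract period, per-hormone extrema, and the anovulation call.

    Under zero dose, the first ``settle_cycles`` nominal periods are
    discarded as transient before measuring extrema.  Under dosing pass
    ``window=(0, 28)`` (the treatment window) instead.  The period is the
    mean spacing of LH surges, falling back to dominant E2 maxima when the
    surge is suppressed.
    """
    if window is not None:
        ev = traj.window(*window)
        period_traj = ev
    else:
        ev = traj.window(settle_cycles * nominal_period, traj.t[-1])
        period_traj = traj

    # period from LH surge spacing (discard early transient spacings)
    surges = _surge_times(period_traj.t, period_traj.LH, surge_abs, surge_ratio)
    if window is None and settle_cycles > 0:
        surges = surges[surges >= settle_cycles * nominal_period]
    if len(surges) >= 2:
        period = float(np.mean(np.diff(surges)))
        period_defined = True
    else:
        e2_peaks = _dominant_peak_times(period_traj.t, period_traj.E2)
        if len(e2_peaks) >= 2:
            period = float(np.mean(np.diff(e2_peaks)))
            period_defined = True
        else:
            period, period_defined = float("nan"), False

    peaks, troughs, peak_times = {}, {}, {}
    for name in HORMONES:
        y = ev.hormone(name)
        i = int(np.argmax(y))
        t_pk, v_pk = _refine_peak(ev.t, y, i)
        peaks[name] = float(max(v_pk, y[i]))
        peak_times[name] = float(t_pk)
        troughs[name] = float(np.min(y))

    ev_surges = _surge_times(ev.t, ev.LH, surge_abs, surge_ratio)
    lh_surge = len(ev_surges) > 0
    anovulatory = (peaks["P4"] < P4_ANOVULATION_THRESHOLD) and not lh_surge
    return CycleMetrics(period, period_defined, peaks, troughs, peak_times,
                        lh_surge, anovulatory)


def verify_periodicity(
    params: ParameterSet,
    history: CycleState | None = None,
    n_cycles: int = 9,
    rel_tol: float = 0.01,
    step: float = 0.01,
) -> tuple[bool, float]:
    """Check for a stable periodic solution at zero dose.

    Simulates ``n_cycles`` nominal cycles, estimates the period from LH
    surge spacing, and declares the solution periodic when every hormone
    series over the last full cycle matches the preceding cycle within
    ``rel_tol`` relative (scaled by the hormone's amplitude).
    """
    if n_cycles < 4:
        raise ValueError("n_cycles must be at least 4")
    traj = simulate(params, DoseSchedule.zero(), history,
                    horizon=n_cycles * 30.0, step=step)
    m = cycle_metrics(traj, settle_cycles=1)
    if not m.period_defined or not np.isfinite(m.period) or m.period <= 0:
        return False, float("nan")
    # use the last surge spacing for the shift: the mean spacing still
    # carries transient drift, and on steep surges a tiny period error
    # masquerades as a large pointwise mismatch
    surges = _surge_times(traj.t, traj.LH)
    period = float(surges[-1] - surges[-2]) if len(surges) >= 2 else m.period
    t_end = traj.t[-1]
    if t_end < 2 * period:
        return False, period
    ts = np.linspace(t_end - period, t_end, 200)
    ok = True
    for name in HORMONES:
        y = traj.hormone(name)
        a = np.interp(ts - period, traj.t, y)
        b = np.interp(ts, traj.t, y)
        scale = max(np.max(np.abs(b)), 1e-12)
        if np.max(np.abs(a - b)) / scale > rel_tol:
            ok = False
            break
    return ok, period
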