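"""Constant-dose experiments: monotherapy scans, combination contours,
threshold refinement, peak-suppression tables, and period sensitivity.

All experiments administer a constant exogenous dose continuously over a
single 28-day treatment window starting from the cycle-start state, and
classify the window as anovulatory when progesterone stays below 5 ng/mL
with no LH surge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import P4_ANOVULATION_THRESHOLD, cycle_metrics, verify_periodicity
from .model import DoseSchedule
from .params import PARAM_ORDER, CycleState, ParameterSet
from .simulate import HORMONES, SimulationError, Trajectory, simulate

__all__ = ["DoseScanResult", "ContourGrid", "scan_monotherapy",
           "percent_peak_decrease", "contour_map", "min_constant_dose",
           "sensitivity_cycle_length", "TREATMENT_WINDOW"]

#: days; constant doses are administered continuously for one cycle
TREATMENT_WINDOW = 28.0


def _constant_dose(hormone: str, dose: float) -> DoseSchedule:
    if hormone == "estrogen":
        return DoseSchedule.constant(e2exo=dose)
    if hormone == "progesterone":
        return DoseSchedule.constant(p4exo=dose)
    raise ValueError("hormone must be 'estrogen' or 'progesterone'")


def _window_metrics(params: ParameterSet, dose: DoseSchedule,
                    history: CycleState | None, step: float):
    traj = simulate(params, dose, history, horizon=TREATMENT_WINDOW, step=step)
    return cycle_metrics(traj, window=(0.0, TREATMENT_WINDOW)), traj


@dataclass(frozen=True)
class DoseScanResult:
    """Per-dose extrema of LH and P4 over the treatment window."""

    hormone: str                      # "estrogen" | "progesterone"
    doses: np.ndarray                 # pg/mL/day or ng/mL/day
    lh_max: np.ndarray
    lh_min: np.ndarray
    p4_max: np.ndarray
    p4_min: np.ndarray
    anovulatory: np.ndarray           # bool per dose
    failed: np.ndarray                # bool per dose (simulation failure)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": self.doses, "LH_max": self.lh_max, "LH_min": self.lh_min,
            "P4_max": self.p4_max, "P4_min": self.p4_min,
            "anovulatory": self.anovulatory, "failed": self.failed,
        })

    def anovulatory_doses(self) -> np.ndarray:
        return self.doses[self.anovulatory & ~self.failed]


def scan_monotherapy(
    hormone: str,
    grid: np.ndarray,
    params: ParameterSet,
    history: CycleState | None = None,
    step: float = 0.01,
) -> DoseScanResult:
    """Scan constant single-hormone doses over ``grid``.

    Each dose is simulated for the 28-day window and LH/P4 extrema plus
    the anovulation flag are recorded (typical protocol: a 0.1-spaced
    grid per hormone).  Failed simulations are flagged and skipped.
    """
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    n = len(grid)
    lh_max = np.full(n, np.nan)
    lh_min = np.full(n, np.nan)
    p4_max = np.full(n, np.nan)
    p4_min = np.full(n, np.nan)
    anov = np.zeros(n, bool)
    failed = np.zeros(n, bool)
    for i, d in enumerate(grid):
        try:
            m, _ = _window_metrics(params, _constant_dose(hormone, d),
                                   history, step)
        except SimulationError:
            failed[i] = True
            continue
        lh_max[i], lh_min[i] = m.peaks["LH"], m.troughs["LH"]
        p4_max[i], p4_min[i] = m.peaks["P4"], m.troughs["P4"]
        anov[i] = m.anovulatory
    return DoseScanResult(hormone, grid, lh_max, lh_min, p4_max, p4_min,
                          anov, failed)


def percent_peak_decrease(
    dose: DoseSchedule,
    params: ParameterSet,
    history: CycleState | None = None,
    step: float = 0.01,
) -> dict[str, float]:
    """Percentage decrease of each hormone's peak under ``dose``.

    The dosed peak over the 28-day treatment window is compared with the
    zero-dose peak of the settled normal cycle:
    ``100 * (peak0 - peak_d) / peak0`` per hormone (report rounded to
    integer percent when reproducing summary tables).
    """
    base = simulate(params, DoseSchedule.zero(), history,
                    horizon=3 * TREATMENT_WINDOW, step=step)
    m0 = cycle_metrics(base, settle_cycles=1)
    md, _ = _window_metrics(params, dose, history, step)
    return {h: 100.0 * (m0.peaks[h] - md.peaks[h]) / m0.peaks[h]
            for h in HORMONES}


# ---------------------------------------------------------------------------
# combination-dose contour map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourGrid:
    """Max-P4 surface over a grid of combined constant doses."""

    e2_grid: np.ndarray                 # pg/mL/day
    p4_grid: np.ndarray                 # ng/mL/day
    max_p4: np.ndarray                  # (len(p4_grid), len(e2_grid))
    anovulation_mask: np.ndarray        # max_p4 < 5 & no LH surge
    surge_mask: np.ndarray

    def level_curve(self, k: float) -> np.ndarray:
        """Points (E2exo, P4exo) where max P4 crosses level ``k``.

        For each progesterone row the estrogen dose at which the (mostly
        monotone-decreasing) max-P4 profile crosses ``k`` is located by
        linear interpolation; rows that never cross are skipped.
        """
        pts = []
        for j, p4d in enumerate(self.p4_grid):
            row = self.max_p4[j]
            for i in range(len(row) - 1):
                a, b = row[i], row[i + 1]
                if np.isnan(a) or np.isnan(b):
                    continue
                if (a - k) * (b - k) < 0:
                    frac = (a - k) / (a - b)
                    e2 = self.e2_grid[i] + frac * (self.e2_grid[i + 1]
                                                   - self.e2_grid[i])
                    pts.append((e2, p4d))
                    break
        return np.array(pts)

    def boundary_slope(self, k: float = P4_ANOVULATION_THRESHOLD,
                       e2_max: float = 30.0) -> tuple[float, tuple]:
        """Least-squares slope (ng/mL per pg/mL) of the left anovulation
        boundary: the ``k``-level curve restricted to E2exo < ``e2_max``."""
        pts = self.level_curve(k)
        pts = pts[pts[:, 0] < e2_max]
        if len(pts) < 2:
            return float("nan"), (float("nan"), float("nan"))
        slope, _ = np.polyfit(pts[:, 0], pts[:, 1], 1)
        return float(slope), (float(pts[:, 0].min()), float(pts[:, 0].max()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.max_p4, index=self.p4_grid,
                            columns=self.e2_grid)


def contour_map(
    e2_grid: np.ndarray,
    p4_grid: np.ndarray,
    params: ParameterSet,
    history: CycleState | None = None,
    step: float = 0.02,
) -> ContourGrid:
    """Max-P4 surface for combined constant estrogen + progesterone doses."""
    e2_grid = np.asarray(e2_grid, float)
    p4_grid = np.asarray(p4_grid, float)
    zmax = np.full((len(p4_grid), len(e2_grid)), np.nan)
    surge = np.zeros_like(zmax, dtype=bool)
    for j, p4d in enumerate(p4_grid):
        for i, e2d in enumerate(e2_grid):
            try:
                m, _ = _window_metrics(
                    params, DoseSchedule.constant(e2exo=e2d, p4exo=p4d),
                    history, step)
            except SimulationError:
                continue
            zmax[j, i] = m.peaks["P4"]
            surge[j, i] = m.lh_surge
    mask = (zmax < P4_ANOVULATION_THRESHOLD) & ~surge
    return ContourGrid(e2_grid, p4_grid, zmax, mask, surge)


def min_constant_dose(
    hormone: str,
    params: ParameterSet,
    history: CycleState | None = None,
    resolution: float = 0.01,
    coarse_step: float = 0.1,
    dose_max: float | None = None,
    step: float = 0.01,
) -> tuple[float, float]:
    """Smallest constant dose that induces anovulation.

    A coarse scan on a 0.1 grid brackets the onset; bisection then
    refines the threshold to ``resolution``.  The default search ranges
    cover the packaged reference conditions with margin.  Returns the per-day
    dose and the 28-day total (dose x 28).  Raises ``ValueError`` when no
    dose in range is anovulatory.
    """
    if dose_max is None:
        dose_max = 150.0 if hormone == "estrogen" else 8.0

    def anov(d: float) -> bool:
        m, _ = _window_metrics(params, _constant_dose(hormone, d),
                               history, step)
        return m.anovulatory

    grid = np.arange(0.0, dose_max + 1e-9, coarse_step)
    flags = np.array([anov(d) for d in grid])
    if not flags.any():
        raise ValueError(f"no anovulatory {hormone} dose in [0, {dose_max}]")
    i = int(np.argmax(flags))
    if i == 0:
        return 0.0, 0.0
    lo, hi = grid[i - 1], grid[i]
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if anov(mid):
            hi = mid
        else:
            lo = mid
    return hi, hi * TREATMENT_WINDOW


def sensitivity_cycle_length(
    params: ParameterSet,
    perturb_fraction: float = 0.01,
    names: tuple[str, ...] | None = None,
    history: CycleState | None = None,
) -> pd.DataFrame:
    """Local sensitivity of the cycle period to each parameter.

    Central finite differences of the period with respect to log-parameter:
    ``dT/dlog p ≈ (T(p*(1+f)) - T(p*(1-f))) / (2f)``, ranked by magnitude.
    A perturbation that destroys periodicity yields an undefined (inf)
    sensitivity, flagged in the output.
    """
    if perturb_fraction < 0:
        raise ValueError("perturb_fraction must be non-negative")
    if names is None:
        names = tuple(k for k in PARAM_ORDER
                      if k not in ("b1", "b2", "w", "q", "tau"))
    rows = []
    for name in names:
        base = getattr(params, name)
        if not np.isfinite(base) or base == 0 or perturb_fraction == 0:
            rows.append((name, 0.0, True))
            continue
        periods = []
        for sign in (+1, -1):
            p = params.replace(**{name: base * (1 + sign * perturb_fraction)})
            try:
                ok, T = verify_periodicity(p, history)
            except SimulationError:
                ok = False
            periods.append(T if ok else np.nan)
        if np.any(np.isnan(periods)):
            rows.append((name, np.inf, False))
        else:
            sens = (periods[0] - periods[1]) / (2 * perturb_fraction)
            rows.append((name, sens, True))
    df = pd.DataFrame(rows, columns=["parameter", "dT_dlogp", "defined"])
    return df.reindex(df["dT_dlogp"].abs().sort_values(ascending=False).index
                      ).reset_index(drop=True)
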