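"""Synthetic hormone datasets and cycle variants.

Two generators are provided.  :func:`designed_cycle_table` builds a *designed*
28-day daily table with the canonical phase structure of a normal cycle —
LH, FSH, and E2 peaking in the late follicular phase, P4 and inhibin in
the luteal phase — from smooth parametric bump shapes.  It is a synthetic
stand-in for a population-mean clinical table and anchors the packaged
reference calibration.  :func:`generate_dataset` instead samples the
*model itself* at a known parameter set (optionally with multiplicative
log-normal noise), which is what parameter-recovery studies need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import HormoneDataset
from .metrics import cycle_metrics, verify_periodicity
from .model import DoseSchedule
from .params import CycleState, ParameterSet
from .simulate import HORMONES, simulate

__all__ = ["SyntheticSpec", "generate_dataset", "cycle_variants",
           "designed_cycle_table"]


def _bump(d, center, height, sl, sr):
    """Asymmetric Gaussian bump (widths ``sl`` left, ``sr`` right of peak)."""
    d = np.asarray(d, float)
    s = np.where(d < center, sl, sr)
    return height * np.exp(-(((d - center) / s) ** 2))


def designed_cycle_table() -> pd.DataFrame:
    """Designed 28-day daily hormone table (synthetic).

    Peak placement and magnitudes follow the population-mean pattern for
    normally cycling women: E2 237 pg/mL on day 13, LH 123 IU/L and FSH
    19.6 IU/L on day 14, inhibin 11.5 IU/mL on day 20, P4 17.9 ng/mL on
    day 21, with realistic baselines elsewhere.
    """
    d = np.arange(1, 29, dtype=float)
    e2 = 40.0 + _bump(d, 13, 196.6, 2.2, 2.0) + _bump(d, 21, 100.0, 3.2, 3.2)
    lh = 8.0 + _bump(d, 14, 115.0, 0.9, 0.9)
    fsh = (7.0 + _bump(d, 2, 5.0, 4.0, 4.0) + _bump(d, 14, 12.55, 1.1, 1.1)
           + _bump(d, 28, 4.0, 4.0, 4.0))
    p4 = 0.5 + _bump(d, 21, 17.4, 2.8, 3.8)
    inh = 1.5 + _bump(d, 14, 2.5, 1.5, 1.5) + _bump(d, 20, 9.95, 3.5, 3.5)
    return pd.DataFrame({"day": d.astype(int), "E2": e2, "P4": p4,
                         "Inh": inh, "LH": lh, "FSH": fsh})


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a model-generated daily hormone dataset.

    ``sigma`` is the per-hormone log-normal noise scale (0 = noise-free);
    ``km_lh`` optionally overrides the E2 half-saturation of LH synthesis
    to produce cycle-length variants.  With ``standardize`` (default) one
    model period is rescaled linearly onto the 28-day grid, mirroring how
    clinical cycle data are standardized; without it, sampling is at
    integer days of model time, which round-trips exactly through the
    calibration objective.
    """

    params: ParameterSet
    init_state: CycleState | None = None
    cycles: int = 1
    sigma: dict[str, float] | float = 0.0
    seed: int = 0
    km_lh: float | None = None
    settle_cycles: int = 1
    standardize: bool = True

    def sigmas(self) -> dict[str, float]:
        if isinstance(self.sigma, dict):
            out = {h: float(self.sigma.get(h, 0.0)) for h in HORMONES}
        else:
            out = {h: float(self.sigma) for h in HORMONES}
        if any(s < 0 for s in out.values()):
            raise ValueError("noise sigma must be non-negative")
        return out


def generate_dataset(spec: SyntheticSpec) -> HormoneDataset:
    """Forward-simulate the model and sample a daily 28-day table.

    The generating parameters must yield a periodic solution; one model
    period (after ``settle_cycles`` transient cycles) is rescaled linearly
    to 28 days and sampled at days 1..28, repeated ``cycles`` times.
    Noise, when requested, is multiplicative log-normal per observation.
    """
    params = spec.params if spec.km_lh is None \
        else spec.params.replace(Km_LH=spec.km_lh)
    ok, period = verify_periodicity(params, spec.init_state)
    if not ok:
        raise ValueError("generating parameter set is not periodic; "
                         "cannot build a synthetic cycle table")
    traj = simulate(params, DoseSchedule.zero(), spec.init_state,
                    horizon=(spec.settle_cycles + 1.5) * period + 2.0)
    t0 = spec.settle_cycles * period
    days = np.arange(1, 29, dtype=float)
    if spec.standardize:
        # rescale one model period onto the 28-day grid
        ts = t0 + days / 28.0 * period
    else:
        ts = t0 + days
    rng = np.random.default_rng(spec.seed)
    sig = spec.sigmas()
    cols = {"day": np.tile(days, spec.cycles).astype(int)}
    for h in HORMONES:
        base = np.interp(ts, traj.t, traj.hormone(h))
        reps = []
        for _ in range(spec.cycles):
            y = base.copy()
            if sig[h] > 0:
                y = y * rng.lognormal(0.0, sig[h], size=y.shape)
            reps.append(y)
        cols[h] = np.concatenate(reps)
    df = pd.DataFrame(cols)
    df["day"] = np.arange(1, 28 * spec.cycles + 1)
    if (df[list(HORMONES)] <= 0).any().any():
        raise ValueError("generated series must be positive")
    return HormoneDataset.from_frame(df)


def cycle_variants(
    base: ParameterSet,
    km_values: list[float],
    init_state: CycleState | None = None,
) -> list[tuple[ParameterSet, float]]:
    """Cycle-length variants by overriding the E2 half-saturation ``Km_LH``.

    ``Km_LH`` sets the E2 level that triggers strong LH synthesis, so
    raising it postpones the surge and lengthens the cycle.  Returns each
    perturbed parameter set with its simulated period (nan when the
    perturbed model is no longer periodic).
    """
    out = []
    for km in km_values:
        p = base.replace(Km_LH=float(km))
        ok, period = verify_periodicity(p, init_state)
        out.append((p, period if ok else float("nan")))
    return out
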