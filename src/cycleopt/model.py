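"""Model equations: auxiliary hormone maps and the 13-state right-hand side.

The pituitary submodel tracks synthesis, release, and clearance of LH and
FSH.  LH synthesis is stimulated by estradiol through an order-8 Hill
function and inhibited by progesterone; release from the reserve pool is
bolstered by progesterone and inhibited by estradiol (with the estradiol
factor squared for FSH).  FSH synthesis is inhibited by inhibin acting
with delay ``tau`` and — the contraception mechanism — by circulating
progesterone scaled by ``w``.  The ovarian submodel advances follicular /
luteal mass through nine stages; recruitment is FSH-driven and inhibited
by progesterone scaled by ``q``.  Blood levels of E2, P4, and inhibin are
quasi-steady linear combinations of the stage masses plus any exogenous
dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy.interpolate import Akima1DInterpolator

from . import _kernel
from .params import CycleState, ParameterSet

__all__ = ["auxiliary_hormones", "rhs", "DoseSchedule"]


def auxiliary_hormones(
    state: CycleState | np.ndarray,
    dose_at_t: tuple[float, float],
    params: ParameterSet,
) -> tuple[float, float, float]:
    """Blood hormone levels (E2 pg/mL, P4 ng/mL, Inh IU/mL) for a state.

    ``dose_at_t`` is the exogenous (E2exo, P4exo) blood-concentration pair
    at the evaluation time.  Exogenous hormones enter linearly through the
    couplings ``b1``/``b2``; inhibin has no exogenous component.
    """
    y = state.to_vector() if isinstance(state, CycleState) else np.asarray(state, float)
    if y.shape != (13,):
        raise ValueError("state must have 13 components")
    if not np.all(np.isfinite(y)):
        raise ValueError("state components must be finite")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    e2exo, p4exo = float(dose_at_t[0]), float(dose_at_t[1])
    if e2exo < 0 or p4exo < 0:
        raise ValueError("doses must be non-negative")
    e2, p4, inh = _kernel.aux_hormones(y, e2exo, p4exo, params.to_vector())
    return float(e2), float(p4), float(inh)


def rhs(
    t: float,
    state: CycleState | np.ndarray,
    delayed_inh: float,
    dose: "DoseSchedule | tuple[float, float]",
    params: ParameterSet,
) -> np.ndarray:
    """Time-derivatives of the 13 state variables.

    ``delayed_inh`` must be the inhibin level at ``t - tau`` (computed from
    the delayed state through the auxiliary map).  ``dose`` may be a
    :class:`DoseSchedule` (evaluated at ``t``) or an explicit
    ``(E2exo, P4exo)`` pair.
    """
    y = state.to_vector() if isinstance(state, CycleState) else np.asarray(state, float)
    if y.shape != (13,):
        raise ValueError("state must have 13 components")
    if not (np.all(np.isfinite(y)) and np.isfinite(delayed_inh) and np.isfinite(t)):
        raise ValueError("non-finite input to rhs")
    if isinstance(dose, DoseSchedule):
        e2exo, p4exo = dose.at(t)
    else:
        e2exo, p4exo = float(dose[0]), float(dose[1])
    dy = np.empty(13)
    _kernel.rhs(y, float(delayed_inh), e2exo, p4exo, params.to_vector(), dy)
    return dy


# ---------------------------------------------------------------------------
# dose schedules
# ---------------------------------------------------------------------------

def _make_component(spec) -> Callable[[np.ndarray], np.ndarray]:
    """Build a vectorized non-negative dose component.

    ``spec`` is a scalar (constant rate), ``None``/0 (no dose), a callable,
    or a ``(times, values)`` node table joined by modified-Akima piecewise
    cubics (low-overshoot) and clipped at zero.
    """
    if spec is None:
        return lambda t: np.zeros_like(np.asarray(t, float))
    if callable(spec):
        return lambda t, f=spec: np.maximum(np.asarray(f(np.asarray(t, float)), float), 0.0)
    if np.isscalar(spec):
        val = float(spec)
        if val < 0:
            raise ValueError("constant dose must be non-negative")
        return lambda t: np.full_like(np.asarray(t, float), val)
    times, values = spec
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if np.any(values < 0):
        raise ValueError("dose node values must be non-negative")
    if len(times) < 2:
        return _make_component(float(values[0]))
    interp = Akima1DInterpolator(times, values, method="makima")
    lo, hi = times[0], times[-1]

    def f(t):
        t = np.asarray(t, float)
        out = interp(np.clip(t, lo, hi))
        return np.maximum(out, 0.0)

    return f


@dataclass(frozen=True)
class DoseSchedule:
    """Exogenous estradiol/progesterone administration over time.

    ``e2exo(t)`` in pg/mL per day and ``p4exo(t)`` in ng/mL per day, each
    constant, zero, or a piecewise-cubic (modified-Akima) interpolation of
    node values clipped at zero.
    """

    e2: Callable[[np.ndarray], np.ndarray]
    p4: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def zero(cls) -> "DoseSchedule":
        return cls(_make_component(None), _make_component(None))

    @classmethod
    def constant(cls, e2exo: float = 0.0, p4exo: float = 0.0) -> "DoseSchedule":
        return cls(_make_component(float(e2exo)), _make_component(float(p4exo)))

    @classmethod
    def from_nodes(
        cls,
        times: np.ndarray,
        e2_values: np.ndarray | None = None,
        p4_values: np.ndarray | None = None,
    ) -> "DoseSchedule":
        e2c = _make_component((times, e2_values)) if e2_values is not None \
            else _make_component(None)
        p4c = _make_component((times, p4_values)) if p4_values is not None \
            else _make_component(None)
        return cls(e2c, p4c)

    @classmethod
    def from_functions(cls, e2=None, p4=None) -> "DoseSchedule":
        return cls(_make_component(e2), _make_component(p4))

    @classmethod
    def from_file(cls, path: str | Path) -> "DoseSchedule":
        """Load from a YAML config.

        Keys: ``e2exo`` / ``p4exo``, each either a number (constant) or a
        mapping with ``times`` and ``values`` lists (interpolated nodes).
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        comps = {}
        for key, name in (("e2exo", "e2"), ("p4exo", "p4")):
            spec = raw.get(key)
            if spec is None:
                comps[name] = _make_component(None)
            elif isinstance(spec, (int, float)):
                comps[name] = _make_component(float(spec))
            elif isinstance(spec, dict):
                comps[name] = _make_component(
                    (np.asarray(spec["times"], float),
                     np.asarray(spec["values"], float)))
            else:
                raise ValueError(f"bad dose spec for {key}")
        return cls(comps["e2"], comps["p4"])

    def at(self, t: float) -> tuple[float, float]:
        return float(self.e2(np.array(t))), float(self.p4(np.array(t)))

    def sample(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.e2(times), float), np.asarray(self.p4(times), float)
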