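"""Parameter and state containers for the menstrual-cycle model.

The model tracks thirteen state variables: the pituitary reserve pools and
blood concentrations of luteinizing hormone (LH) and follicle-stimulating
hormone (FSH), and nine staged ovarian masses following a cohort of
follicles from recruitment through ovulation into four luteal stages.
Ovarian hormone concentrations (estradiol E2, progesterone P4, inhibin Inh)
are algebraic combinations of the staged masses plus any exogenous dose.

Units used throughout the package:

======================  =========
quantity                unit
======================  =========
time                    days
LH, FSH concentration   IU/L
RP_LH, RP_FSH           IU
ovarian stage masses    ng
E2                      pg/mL
P4                      ng/mL
Inh                     IU/mL
======================  =========
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "CycleState",
    "PARAM_ORDER",
    "STATE_ORDER",
    "load_parameters",
    "save_parameters",
    "reference_parameters",
    "reference_initial_state",
]

#: canonical ordering of the parameter vector used by the numerical kernel
PARAM_ORDER: tuple[str, ...] = (
    # pituitary LH
    "V0_LH", "V1_LH", "Km_LH", "Ki_LH_P", "k_LH", "c_LH_P", "c_LH_E",
    "alpha_LH",
    # pituitary FSH
    "V_FSH", "Ki_FSH_Inh", "tau", "k_FSH", "c_FSH_P", "c_FSH_E", "alpha_FSH",
    # distribution volume
    "v",
    # progesterone-inhibition scales (the contraception mechanism terms)
    "w", "q",
    # ovarian transfer chain
    "b", "c1", "c2", "c3", "c4", "d1", "d2", "k1", "k2", "k3", "k4",
    "alpha", "gamma",
    # secretion coefficients
    "e0", "e1", "e2", "e3", "p0", "p1", "p2", "h0", "h1", "h2", "h3",
    # exogenous couplings
    "b1", "b2",
)

#: canonical ordering of the state vector
STATE_ORDER: tuple[str, ...] = (
    "RP_LH", "LH", "RP_FSH", "FSH",
    "RcF", "GrF", "DomF", "Sc1", "Sc2",
    "Lut1", "Lut2", "Lut3", "Lut4",
)

#: index of the order-8 Hill exponent on E2 in LH synthesis (fixed, not a
#: free parameter)
HILL_EXPONENT = 8


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and coefficients of the cycle model.

    ``w`` and ``q`` (ng/mL) scale the inhibitory action of progesterone on
    FSH synthesis and on follicular recruitment; setting them to
    ``math.inf`` removes both terms and recovers the predecessor model
    without a progesterone contraception mechanism.  ``b1``/``b2`` couple
    exogenous estradiol/progesterone into the algebraic hormone maps
    (default 1: doses enter as blood concentrations).
    """

    # pituitary LH synthesis / release / clearance
    V0_LH: float = 500.0        # IU/day, basal LH synthesis
    V1_LH: float = 4500.0       # IU/day, E2-stimulated LH synthesis
    Km_LH: float = 140.0        # pg/mL, E2 half-saturation of LH synthesis
    Ki_LH_P: float = 12.0       # ng/mL, P4 inhibition of LH synthesis
    k_LH: float = 2.5           # 1/day, LH release
    c_LH_P: float = 0.26        # mL/ng, P4 enhancement of LH release
    c_LH_E: float = 0.004       # mL/pg, E2 inhibition of LH release
    alpha_LH: float = 14.0      # 1/day, LH clearance
    # pituitary FSH
    V_FSH: float = 375.0        # IU/day, FSH synthesis
    Ki_FSH_Inh: float = 3.5     # IU/mL, inhibin inhibition of FSH synthesis
    tau: float = 2.0            # days, inhibin action delay
    k_FSH: float = 1.9          # 1/day, FSH release
    c_FSH_P: float = 0.5        # mL/ng, P4 enhancement of FSH release
    c_FSH_E: float = 0.005      # mL/pg, E2 inhibition of FSH release (squared)
    alpha_FSH: float = 8.21     # 1/day, FSH clearance
    v: float = 2.5              # L, blood distribution volume
    # progesterone inhibition scales
    w: float = math.inf         # ng/mL, P4 inhibition of FSH synthesis
    q: float = math.inf         # ng/mL, P4 inhibition of recruitment
    # ovarian transfer chain
    b: float = 0.05             # recruitment source
    c1: float = 0.05            # FSH-driven RcF self-growth
    c2: float = 0.06            # RcF -> GrF transfer (x LH^alpha)
    c3: float = 0.01            # GrF -> DomF transfer (x LH)
    c4: float = 0.004           # DomF -> Sc1 transfer (x LH^gamma)
    d1: float = 0.6             # 1/day
    d2: float = 0.6             # 1/day
    k1: float = 0.6             # 1/day
    k2: float = 0.55            # 1/day
    k3: float = 0.5             # 1/day
    k4: float = 0.55            # 1/day
    alpha: float = 0.77         # exponent on LH in RcF outflow
    gamma: float = 1.4          # exponent on LH in DomF outflow
    # secretion coefficients
    e0: float = 30.0            # pg/mL
    e1: float = 3.0             # pg/mL per ng GrF
    e2: float = 12.0            # pg/mL per ng DomF
    e3: float = 1.5             # pg/mL per ng Lut4
    p0: float = 0.3             # ng/mL
    p1: float = 0.2             # ng/mL per ng Lut3
    p2: float = 0.1             # ng/mL per ng Lut4
    h0: float = 1.2             # IU/mL
    h1: float = 0.2             # IU/mL per ng DomF
    h2: float = 0.05            # IU/mL per ng Lut2
    h3: float = 0.12            # IU/mL per ng Lut3
    # exogenous couplings (dimensionless)
    b1: float = 1.0
    b2: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val) and f.name not in ("w", "q"):
                raise ValueError(f"parameter {f.name} must be finite, got {val}")
            if f.name == "tau":
                if val < 0:
                    raise ValueError("delay tau must be non-negative")
            elif f.name in ("b1", "b2"):
                if val < 0:
                    raise ValueError(f"{f.name} must be non-negative")
            elif f.name in ("e0", "p0", "h0", "b"):
                if val < 0:
                    raise ValueError(f"{f.name} must be non-negative")
            elif val <= 0:
                raise ValueError(f"parameter {f.name} must be positive, got {val}")

    def to_vector(self) -> np.ndarray:
        """Pack into the canonical float64 vector (order ``PARAM_ORDER``)."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec: Iterable[float]) -> "ParameterSet":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (len(PARAM_ORDER),):
            raise ValueError(f"expected {len(PARAM_ORDER)} parameters, got {vec.shape}")
        return cls(**dict(zip(PARAM_ORDER, vec.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_ORDER}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_ORDER)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)

    def without_p4_inhibition(self) -> "ParameterSet":
        """Copy with the progesterone contraception terms removed."""
        return self.replace(w=math.inf, q=math.inf)


@dataclass(frozen=True)
class CycleState:
    """The thirteen model state variables.

    Defaults are the estimated cycle-start (early follicular) conditions.
    """

    RP_LH: float = 167.57
    LH: float = 11.81
    RP_FSH: float = 14.48
    FSH: float = 11.41
    RcF: float = 2.10
    GrF: float = 4.12
    DomF: float = 0.46
    Sc1: float = 1.06
    Sc2: float = 1.67
    Lut1: float = 4.16
    Lut2: float = 13.03
    Lut3: float = 16.48
    Lut4: float = 10.29

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ValueError(f"state {f.name} must be finite")
            if val < 0:
                raise ValueError(f"state {f.name} must be non-negative, got {val}")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec: Iterable[float]) -> "CycleState":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (len(STATE_ORDER),):
            raise ValueError(f"expected {len(STATE_ORDER)} states, got {vec.shape}")
        return cls(**dict(zip(STATE_ORDER, vec.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in STATE_ORDER}


# ---------------------------------------------------------------------------
# parameter file I/O (flat YAML mapping, or two-column CSV name,value)
# ---------------------------------------------------------------------------

def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter file (``.yaml``/``.yml`` mapping or ``name,value`` CSV).

    Unknown keys are rejected so that files stay auditable against the
    canonical parameter list; missing keys fall back to defaults only for
    ``b1``/``b2`` (the exogenous couplings) — every other parameter must be
    present.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat YAML mapping")
    elif path.suffix.lower() == ".csv":
        raw = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().startswith("#"):
                    continue
                if row[0].strip().lower() in ("name", "parameter"):
                    continue
                raw[row[0].strip()] = row[1].strip()
    else:
        raise ValueError(f"unsupported parameter file format: {path.suffix}")
    parsed = {k: float(v) for k, v in raw.items()}
    missing = set(PARAM_ORDER) - set(parsed) - {"b1", "b2"}
    if missing:
        raise KeyError(f"{path}: missing parameter(s): {sorted(missing)}")
    return ParameterSet.from_dict(parsed)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    elif path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["name", "value"])
            for k, v in params.to_dict().items():
                wr.writerow([k, repr(v)])
    else:
        raise ValueError(f"unsupported parameter file format: {path.suffix}")


_DATA_DIR = Path(__file__).parent / "data"


def reference_parameters() -> ParameterSet:
    """The package's synthetic reference parameter set.

    Obtained by the staged calibration pipeline against the synthetic
    28-day hormone table shipped with the package (see
    :mod:`cycleopt.synth`); produces a stable ~28-day periodic solution
    with realistic hormone peaks.
    """
    return load_parameters(_DATA_DIR / "reference_params.yaml")


def reference_initial_state() -> CycleState:
    """Cycle-start state paired with :func:`reference_parameters`."""
    path = _DATA_DIR / "reference_state.yaml"
    if path.exists():
        raw = yaml.safe_load(path.read_text())
        return CycleState(**{k: float(v) for k, v in raw.items()})
    return CycleState()
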