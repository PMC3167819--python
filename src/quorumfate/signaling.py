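"""Intracellular signalling model of a single mammary stem cell.

Each stem cell carries seven coupled protein levels — secreted Dkk1 (K),
activated LEF/TCF (L), total E-cadherin (E), proliferation factor (P),
Notch receptor (N), HES (H) and differentiation factor (D) — driven by
micro-environmental inputs: ambient Wnt, extracellular Dkk1, bound
E-cadherin and DSL ligand presented by neighbouring cells.

The regulatory couplings are saturating Hill curves.  Wnt signal intensity
is the product of an increasing function of ambient Wnt and a decreasing
function of extracellular Dkk1; it drives LEF/TCF activation, gated by a
decreasing function of bound E-cadherin.  LEF/TCF up-regulates Dkk1 and PF
synthesis, down-regulates E-cadherin synthesis and slows Notch receptor
degradation.  Activated Notch (the minimum of receptor level and available
DSL) induces HES, which represses DF synthesis.  All species degrade with
first-order kinetics.

The system is deterministic; stochasticity enters only at the tissue level
(daughter placement and update order, see :mod:`quorumfate.fate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "RegulatoryCurve",
    "CellState",
    "CellInputs",
    "SignalingParams",
    "regulatory",
    "wnt_signal",
    "derivatives",
    "integrate_step",
    "default_params",
    "load_params",
    "save_params",
]

STATE_NAMES = ("dkk_produced", "lef_tcf", "ecad_total", "pf", "notch", "hes", "df")


@dataclass(frozen=True)
class RegulatoryCurve:
    """A saturating regulatory response.

    ``up`` curves rise from 0 at zero input to an asymptote of ``vmax``;
    ``down`` curves fall from ``vmax`` at zero input to an asymptote of 0.
    Both equal ``vmax / 2`` at ``half_sat``.  ``hill`` sets the steepness.
    """

    kind: str
    vmax: float
    half_sat: float
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("up", "down"):
            raise ValueError(f"curve kind must be 'up' or 'down', got {self.kind!r}")
        if not (self.vmax > 0 and self.half_sat > 0):
            raise ValueError("vmax and half_sat must be strictly positive")
        if self.hill < 1:
            raise ValueError("hill exponent must be >= 1")

    def __call__(self, value):
        x = np.asarray(value, dtype=float)
        if np.any(x < 0):
            raise ValueError("regulatory curve input must be non-negative")
        # small even exponents are special-cased for speed; the compiled
        # kernel uses the identical expressions so both routes agree
        # bit-exactly
        if self.hill == 2.0:
            xn = x * x
        elif self.hill == 4.0:
            x2 = x * x
            xn = x2 * x2
        elif self.hill == 6.0:
            x2 = x * x
            xn = x2 * x2 * x2
        else:
            xn = x ** self.hill
        kn = self.half_sat ** self.hill
        if self.kind == "up":
            out = self.vmax * xn / (kn + xn)
        else:
            out = self.vmax * kn / (kn + xn)
        return float(out) if np.isscalar(value) or out.ndim == 0 else out


def regulatory(value, curve: RegulatoryCurve):
    """Evaluate a regulatory curve at ``value`` (level units -> rate units)."""
    return curve(value)


@dataclass
class CellState:
    """The seven intracellular levels of one stem cell, plus its division clock."""

    dkk_produced: float = 0.0
    lef_tcf: float = 0.0
    ecad_total: float = 0.0
    pf: float = 0.0
    notch: float = 0.0
    hes: float = 0.0
    df: float = 0.0
    time_of_last_division: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dkk_produced, self.lef_tcf, self.ecad_total, self.pf,
             self.notch, self.hes, self.df], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], time_of_last_division: float = 0.0) -> "CellState":
        y = np.asarray(y, dtype=float)
        return cls(*y.tolist(), time_of_last_division=time_of_last_division)


@dataclass
class CellInputs:
    """Micro-environmental inputs to one stem cell, frozen over a tissue step.

    ``neighbor_ecad`` holds the six per-direction E-cadherin levels used to
    compute ``bound_ecad``; it is carried for auditing only — the dynamics
    consume the total ``bound_ecad``.
    """

    wnt_ext: float = 0.0
    dkk_ext: float = 0.0
    bound_ecad: float = 0.0
    dsl_sum: float = 0.0
    neighbor_ecad: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("wnt_ext", "dkk_ext", "bound_ecad", "dsl_sum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


_CURVE_FIELDS = (
    "wnt_signal_curve",
    "dkk_inhibition_curve",
    "dkk_synth_curve",
    "lef_ecad_curve",
    "ecad_synth_curve",
    "pf_synth_curve",
    "notch_deg_curve",
    "hes_synth_curve",
    "df_synth_curve",
)

_RATE_FIELDS = ("dkk_deg", "lef_deg", "ecad_deg", "pf_deg", "hes_deg", "df_deg")

_SCALAR_FIELDS = (
    "notch_synth",
    "ecad_binding_coeff",
    "pf_threshold",
    "df_threshold",
    "tau",
    "phi",
    "dsl_level",
    "wnt_ext",
    "ng_per_model_unit",
    "pericellular_factor",
)

#: number of entries in the packed parameter vector consumed by the kernel
PACKED_SIZE = 3 * len(_CURVE_FIELDS) + len(_RATE_FIELDS) + len(_SCALAR_FIELDS) + 7


@dataclass
class SignalingParams:
    """Every constant of the intracellular model plus fate/timing constants.

    Units: levels are dimensionless model units, rates are per hour, times
    are hours.  ``ng_per_model_unit`` converts one secreted Dkk1 model unit
    (per representative cell volume) to ng/mL in the shared bulk medium;
    ``pericellular_factor`` is the dimensionless enrichment of the
    close-environment concentration a cell actually senses relative to the
    bulk dilution (autocrine/juxtacrine secretion accumulates near the
    membrane before mixing).
    """

    # regulatory curves
    wnt_signal_curve: RegulatoryCurve        # S_w: Wnt signal vs ambient Wnt (up)
    dkk_inhibition_curve: RegulatoryCurve    # I_d: Wnt inhibition vs extracellular Dkk1 (down)
    dkk_synth_curve: RegulatoryCurve         # Dkk1 synthesis vs LEF/TCF (up)
    lef_ecad_curve: RegulatoryCurve          # LEF/TCF activation gate vs bound E-cadherin (down)
    ecad_synth_curve: RegulatoryCurve        # E-cadherin synthesis vs LEF/TCF (down)
    pf_synth_curve: RegulatoryCurve          # PF synthesis vs LEF/TCF (up)
    notch_deg_curve: RegulatoryCurve         # Notch receptor degradation rate vs LEF/TCF (down)
    hes_synth_curve: RegulatoryCurve         # HES synthesis vs activated Notch (up)
    df_synth_curve: RegulatoryCurve          # DF synthesis vs HES (down)
    # first-order degradation rates (/h)
    dkk_deg: float
    lef_deg: float
    ecad_deg: float
    pf_deg: float
    hes_deg: float
    df_deg: float
    # scalars
    notch_synth: float                       # sigma_N, constitutive Notch synthesis (level/h)
    ecad_binding_coeff: float                # kappa in (0, 1]
    pf_threshold: float                      # C_P: PF level licensing division
    df_threshold: float                      # C_M: DF level forcing differentiation
    tau: float                               # cell-cycle refractory period (h)
    phi: float                               # differentiated-cell lifespan (h)
    dsl_level: float                         # DSL presented per living neighbour cell
    wnt_ext: float                           # ambient Wnt level W0
    ng_per_model_unit: float                 # bulk Dkk1 unit conversion (ng/mL per model unit)
    pericellular_factor: float               # close-environment enrichment over bulk medium
    initial_state: CellState = field(default_factory=CellState)

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS + _SCALAR_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.ecad_binding_coeff <= 1):
            raise ValueError("ecad_binding_coeff must lie in (0, 1]")

    # -- packing for the compiled kernel ------------------------------------
    def pack(self) -> np.ndarray:
        """Flatten all constants into the float vector the kernel consumes."""
        out = np.empty(PACKED_SIZE, dtype=np.float64)
        i = 0
        for name in _CURVE_FIELDS:
            c: RegulatoryCurve = getattr(self, name)
            out[i:i + 3] = (c.vmax, c.half_sat, c.hill)
            i += 3
        for name in _RATE_FIELDS:
            out[i] = getattr(self, name)
            i += 1
        for name in _SCALAR_FIELDS:
            out[i] = getattr(self, name)
            i += 1
        out[i:i + 7] = self.initial_state.as_array()
        return out

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        curves = {
            name: {"kind": c.kind, "vmax": c.vmax, "half_sat": c.half_sat, "hill": c.hill}
            for name in _CURVE_FIELDS for c in (getattr(self, name),)
        }
        return {
            "schema": "quorumfate-params-v1",
            "curves": curves,
            "degradation": {n: getattr(self, n) for n in _RATE_FIELDS},
            "scalars": {n: getattr(self, n) for n in _SCALAR_FIELDS},
            "initial_state": {k: v for k, v in asdict(self.initial_state).items()
                              if k != "time_of_last_division"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignalingParams":
        kwargs = {name: RegulatoryCurve(**d["curves"][name]) for name in _CURVE_FIELDS}
        kwargs.update(d["degradation"])
        kwargs.update(d["scalars"])
        kwargs["initial_state"] = CellState(**d["initial_state"])
        return cls(**kwargs)

    def replace(self, **kwargs) -> "SignalingParams":
        return replace(self, **kwargs)


def save_params(params: SignalingParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path) -> SignalingParams:
    with open(path) as fh:
        return SignalingParams.from_dict(yaml.safe_load(fh))


def default_params() -> SignalingParams:
    """The calibrated parameter set shipped with the package."""
    text = resources.files("quorumfate").joinpath("params/default.yaml").read_text()
    return SignalingParams.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def wnt_signal(wnt_ext: float, dkk_ext: float, params: SignalingParams) -> float:
    """Wnt signal intensity: increasing in ambient Wnt, inhibited by Dkk1."""
    return params.wnt_signal_curve(wnt_ext) * params.dkk_inhibition_curve(dkk_ext)


def derivatives(state, inputs: CellInputs, params: SignalingParams) -> np.ndarray:
    """Time derivatives of the seven intracellular levels.

    ``state`` may be a :class:`CellState` or a 7-vector ordered as
    :data:`STATE_NAMES`.  Inputs are held fixed (they are frozen over a
    tissue step).
    """
    y = state.as_array() if isinstance(state, CellState) else np.asarray(state, dtype=float)
    k, lef, ecad, pf, notch, hes, df = y
    w = wnt_signal(inputs.wnt_ext, inputs.dkk_ext, params)
    d_k = params.dkk_synth_curve(lef) - params.dkk_deg * k
    d_l = w * params.lef_ecad_curve(inputs.bound_ecad) - params.lef_deg * lef
    d_e = params.ecad_synth_curve(lef) - params.ecad_deg * ecad
    d_p = params.pf_synth_curve(lef) - params.pf_deg * pf
    d_n = params.notch_synth - params.notch_deg_curve(lef) * notch
    n_act = min(notch, inputs.dsl_sum)
    d_h = params.hes_synth_curve(n_act) - params.hes_deg * hes
    d_d = params.df_synth_curve(hes) - params.df_deg * df
    return np.array([d_k, d_l, d_e, d_p, d_n, d_h, d_d])


def integrate_step(state: CellState, inputs: CellInputs, params: SignalingParams,
                   dt: float) -> CellState:
    """Advance one cell by a single RK4 step of size ``dt`` hours.

    Inputs are held constant over the step.  Levels are clipped at zero,
    so the integration is positivity-preserving for any step below the
    stability bound of the fastest degradation rate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = state.as_array()
    k1 = derivatives(y, inputs, params)
    k2 = derivatives(y + 0.5 * dt * k1, inputs, params)
    k3 = derivatives(y + 0.5 * dt * k2, inputs, params)
    k4 = derivatives(y + dt * k3, inputs, params)
    y_new = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    y_new = np.maximum(y_new, 0.0)
    return CellState.from_array(y_new, time_of_last_division=state.time_of_last_division)
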