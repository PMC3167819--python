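"""Extracellular environment: Dkk1 dosing, unit calibration, mutation scenarios.

Exogenous Dkk1 is a well-mixed bath concentration applied as a step
function in time.  Secreted Dkk1 acts locally: a stem cell senses its own
production plus that of its six immediate neighbours, converted to ng/mL
by the calibrated ``ng_per_model_unit`` factor.  Ambient Wnt is a global
constant.  Oncogenic defects are multiplicative increases on Notch
receptor synthesis, ambient Wnt level, or the amount of bound E-cadherin
required to inhibit LEF/TCF activation (the gate's half-saturation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lattice import Lattice, STEM
from .signaling import SignalingParams

__all__ = [
    "DoseSchedule",
    "MutationScenario",
    "UnitCalibration",
    "exogenous_dkk",
    "dkk_environment",
    "apply_mutation",
    "calibrate_dkk_unit",
]


@dataclass(frozen=True)
class DoseSchedule:
    """A step-function exposure to exogenous Dkk1.

    ``continuous`` and ``refreshed`` hold the bath at ``concentration`` for
    the full ``duration`` (daily refreshment keeps the level constant, so
    the two regimens coincide in a well-mixed model without extracellular
    decay).  ``single`` is one application whose effect is carried for at
    most 24 h (the medium is replaced daily).
    """

    concentration: float                      # ng/mL
    start: float = 0.0                        # h
    duration: float = 48.0                    # h
    regimen: str = "continuous"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.regimen not in ("continuous", "single", "refreshed"):
            raise ValueError(f"unknown regimen {self.regimen!r}")

    @property
    def effective_duration(self) -> float:
        return min(self.duration, 24.0) if self.regimen == "single" else self.duration


def exogenous_dkk(t: float, schedule: DoseSchedule | None) -> float:
    """Bath Dkk1 concentration (ng/mL) at time ``t``; half-open window."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if schedule is None:
        return 0.0
    if schedule.start <= t < schedule.start + schedule.effective_duration:
        return schedule.concentration
    return 0.0


@dataclass(frozen=True)
class MutationScenario:
    """Fractional increases modelling oncogenic signalling defects.

    ``mu_notch`` raises Notch receptor synthesis, ``mu_wnt`` raises the
    ambient Wnt (ligand expression) level, and ``mu_ecad`` raises the bound
    E-cadherin level required to inhibit LEF/TCF activation.
    """

    mu_notch: float = 0.0
    mu_wnt: float = 0.0
    mu_ecad: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_notch", "mu_wnt", "mu_ecad"):
            v = getattr(self, name)
            if v < 0 or v > 0.2:
                warnings.warn(
                    f"{name}={v} is outside the modelled defect range [0, 0.2]",
                    stacklevel=3)

    @property
    def is_normal(self) -> bool:
        return self.mu_notch == self.mu_wnt == self.mu_ecad == 0.0

    def label(self) -> str:
        if self.is_normal:
            return "normal"
        parts = [f"{n.split('_')[1]}+{getattr(self, n):.0%}"
                 for n in ("mu_notch", "mu_wnt", "mu_ecad") if getattr(self, n) > 0]
        return ",".join(parts)


def apply_mutation(params: SignalingParams, scenario: MutationScenario) -> SignalingParams:
    """Return a parameter set with the scenario's defects applied.

    Exactly one parameter changes per nonzero component: Notch synthesis
    rate, ambient Wnt level, or the half-saturation of the E-cadherin gate
    on LEF/TCF activation.  Everything else is untouched.
    """
    out = params
    if scenario.mu_notch:
        out = out.replace(notch_synth=out.notch_synth * (1.0 + scenario.mu_notch))
    if scenario.mu_wnt:
        out = out.replace(wnt_ext=out.wnt_ext * (1.0 + scenario.mu_wnt))
    if scenario.mu_ecad:
        gate = out.lef_ecad_curve
        out = out.replace(lef_ecad_curve=replace(
            gate, half_sat=gate.half_sat * (1.0 + scenario.mu_ecad)))
    return out


def dkk_environment(lattice: Lattice, site: int, params: SignalingParams,
                    schedule: DoseSchedule | None, t: float) -> float:
    """Total Dkk1 (ng/mL equivalent) in the close environment of a stem cell.

    Bath concentration plus the cell's own secreted Dkk1 and that of its
    stem-cell neighbours (differentiated cells no longer secrete),
    converted with ``ng_per_model_unit`` and amplified by the pericellular
    enrichment factor: freshly secreted ligand accumulates around the
    secreting cells at a concentration well above its bulk-medium dilution.
    """
    if lattice.status[site] != STEM:
        raise ValueError(f"site {site} does not hold a stem cell")
    secreted = lattice.state[site, 0]
    for j in lattice.neighbors(site):
        if lattice.status[j] == STEM:
            secreted += lattice.state[j, 0]
    return exogenous_dkk(t, schedule) \
        + params.ng_per_model_unit * params.pericellular_factor * secreted


@dataclass(frozen=True)
class UnitCalibration:
    """Conversion between secreted model units and ng/mL of Dkk1.

    The reference measurement is an ELISA of medium conditioned by 1e5
    MCF-7 cells in 200 µl for 24 h (38432 pg/ml), i.e. a representative
    volume of 2e-3 µl per cell.
    """

    ng_per_model_unit: float = float("nan")
    per_cell_volume_ul: float = 2e-3
    reference_secretion_pg_ml: float = 38432.0

    def __post_init__(self) -> None:
        if not (self.per_cell_volume_ul > 0 and self.reference_secretion_pg_ml > 0):
            raise ValueError("calibration constants must be strictly positive")


def calibrate_dkk_unit(steady_runs, calib: UnitCalibration = UnitCalibration(),
                       window_h: float = 72.0, trend_tol: float = 0.2) -> UnitCalibration:
    """Derive the Dkk1 unit conversion from untreated steady-state runs.

    For each replicate the total cell count (stem + differentiated) and the
    total secreted Dkk1 (model units, summed over stem cells) are averaged
    over the final ``window_h`` hours.  The medium volume is the per-cell
    volume times the mean cell count; the mean secreted amount per volume
    is equated to the reference ELISA concentration, giving ng/mL per model
    unit.

    Raises ``ValueError`` if the mean stem-cell trajectory still trends over
    the window (relative drift above ``trend_tol``), i.e. the runs are not
    at steady state.  The default tolerance (20% per window) separates a
    still-growing or collapsing tissue (drift well above 50%) from the
    equilibrium fluctuations of the churning mosaic (below ~15%).
    """
    if not steady_runs:
        raise ValueError("no replicates supplied")
    times = steady_runs[0].times
    sel = times >= times[-1] - window_h
    sc = np.mean([r.sc_count for r in steady_runs], axis=0)
    # steady-state guard: relative drift of the mean SC trajectory over the window
    slope = np.polyfit(times[sel], sc[sel], 1)[0]
    mean_sc = float(np.mean(sc[sel]))
    if mean_sc <= 0:
        raise ValueError("tissue is extinct; cannot calibrate at steady state")
    drift = abs(slope) * window_h / mean_sc
    if drift > trend_tol:
        raise ValueError(
            f"runs are not at steady state: relative SC drift {drift:.3f} "
            f"over the last {window_h:.0f} h exceeds {trend_tol}")
    total_cells = np.mean([np.mean(r.sc_count[sel] + r.diff_count[sel])
                           for r in steady_runs])
    secreted = np.mean([np.mean(r.secreted_dkk[sel]) for r in steady_runs])
    volume_ul = calib.per_cell_volume_ul * total_cells
    conc_model_units = secreted / volume_ul          # model units per µl of medium
    ng_per_ml = calib.reference_secretion_pg_ml / 1000.0
    return replace(calib, ng_per_model_unit=ng_per_ml / conc_model_units)


def mutation_audit(params: SignalingParams, scenario: MutationScenario) -> pd.DataFrame:
    """Tabulate which parameters a scenario changes (auditable diff)."""
    mutated = apply_mutation(params, scenario)
    rows = []
    for name, before, after in [
        ("notch_synth", params.notch_synth, mutated.notch_synth),
        ("wnt_ext", params.wnt_ext, mutated.wnt_ext),
        ("lef_ecad_curve.half_sat", params.lef_ecad_curve.half_sat,
         mutated.lef_ecad_curve.half_sat),
    ]:
        rows.append({"parameter": name, "before": before, "after": after,
                     "changed": before != after})
    return pd.DataFrame(rows)
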