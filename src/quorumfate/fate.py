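"""Threshold-driven fate decisions and the discrete tissue update loop.

A stem cell differentiates when its differentiation factor reaches the
threshold ``C_M`` (this takes precedence), divides symmetrically when its
proliferation factor is at or above ``C_P``, a vacant neighbouring site
exists and at least one cell cycle ``tau`` has elapsed since its last
division, and is quiescent otherwise — including the crowded case of a
division-licensed cell with no vacant neighbour, which is the quorum
mechanism that halts growth at confluence.  Stem cells are never removed
except by differentiation; differentiated cells occupy their site for a
lifespan ``phi`` and then die, freeing the site.

The per-step protocol (one *tissue step* of ``dt`` hours) is:

1. compute every stem cell's micro-environmental inputs from a synchronous
   snapshot of the lattice;
2. advance every stem cell's intracellular system by ``dt`` with those
   inputs frozen (``n_substeps`` RK4 steps);
3. execute fate decisions — first all differentiations, then divisions in
   uniformly random order (random order arbitrates competition for shared
   empty sites; a cell that loses the race stays quiescent this step);
4. execute scheduled differentiated-cell deaths.

Everything is deterministic given the ``numpy.random.Generator``.  The
compiled kernel in :mod:`quorumfate._kernel` implements this identical
protocol (same generator draw sequence), which is asserted bit-exactly in
the test suite.

This module is the readable reference implementation; it is the one to
read, instrument and extend.  Use the kernel for replicate sweeps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dosing
from .lattice import DIFFERENTIATED, EMPTY, STEM, Lattice, fisher_yates
from .signaling import CellInputs, CellState, SignalingParams, integrate_step

__all__ = ["Fate", "FateConfig", "decide_fate", "apply_division",
           "apply_differentiation", "tissue_step", "TissueSimulation"]


class Fate(enum.Enum):
    DIVIDE = "divide"
    DIFFERENTIATE = "differentiate"
    QUIESCENT = "quiescent"


@dataclass(frozen=True)
class FateConfig:
    """Thresholds and clocks of the fate decision.

    Simultaneous crossing of both thresholds resolves to differentiation
    (the anti-proliferative reading).  ``tau`` acts as a refractory period
    since the last division rather than an explicit phased cycle.
    """

    pf_threshold: float
    df_threshold: float
    tau: float
    phi: float
    precedence: str = "differentiate"

    def __post_init__(self) -> None:
        if not (self.pf_threshold > 0 and self.df_threshold > 0
                and self.tau > 0 and self.phi > 0):
            raise ValueError("thresholds, tau and phi must be strictly positive")
        if self.precedence != "differentiate":
            raise ValueError("only differentiation precedence is implemented")

    @classmethod
    def from_params(cls, params: SignalingParams) -> "FateConfig":
        return cls(pf_threshold=params.pf_threshold, df_threshold=params.df_threshold,
                   tau=params.tau, phi=params.phi)


def decide_fate(state: CellState, n_empty: int, now: float, config: FateConfig) -> Fate:
    """Fate of one stem cell given its state and the vacancy of its neighbourhood."""
    if state.df >= config.df_threshold:
        return Fate.DIFFERENTIATE
    if (state.pf >= config.pf_threshold and n_empty >= 1
            and now - state.time_of_last_division >= config.tau):
        return Fate.DIVIDE
    return Fate.QUIESCENT


def apply_division(lattice: Lattice, mother: int, now: float,
                   gen: np.random.Generator) -> int | None:
    """Symmetric division: place a daughter on a uniformly random empty neighbour.

    Both mother and daughter keep the mother's intracellular state with the
    proliferation factor reset to zero (division consumes the trigger) and
    the division clock restarted.  Returns the daughter site, or ``None``
    if no vacancy remained at execution time (lost race: the division is
    cancelled and the cell stays quiescent this step — no draw consumed).
    """
    empties = lattice.empty_neighbors(mother)
    if len(empties) == 0:
        return None
    daughter = int(empties[int(gen.random() * len(empties))])
    lattice.status[daughter] = STEM
    lattice.state[daughter] = lattice.state[mother]
    lattice.state[daughter, 3] = 0.0
    lattice.state[mother, 3] = 0.0
    lattice.time_of_last_division[daughter] = now
    lattice.time_of_last_division[mother] = now
    lattice.death_time[daughter] = np.inf
    lattice.frozen_ecad[daughter] = 0.0
    return daughter


def apply_differentiation(lattice: Lattice, site: int, now: float,
                          config: FateConfig) -> None:
    """Switch a stem site to differentiated; freeze ligands, schedule death."""
    lattice.status[site] = DIFFERENTIATED
    lattice.frozen_ecad[site] = lattice.state[site, 2]
    lattice.death_time[site] = now + config.phi


def _compute_inputs(lattice: Lattice, params: SignalingParams,
                    schedule: dosing.DoseSchedule | None, t: float,
                    stems: np.ndarray) -> dict[int, CellInputs]:
    inputs = {}
    for s in stems:
        s = int(s)
        _, bound = lattice.bound_ecadherin(s, params.ecad_binding_coeff)
        inputs[s] = CellInputs(
            wnt_ext=params.wnt_ext,
            dkk_ext=dosing.dkk_environment(lattice, s, params, schedule, t),
            bound_ecad=bound,
            dsl_sum=lattice.dsl_sum(s, params.dsl_level),
        )
    return inputs


def tissue_step(lattice: Lattice, params: SignalingParams,
                schedule: dosing.DoseSchedule | None, t: float, dt: float,
                gen: np.random.Generator, n_substeps: int = 10,
                event_log: list | None = None) -> float:
    """Advance the tissue by one step of ``dt`` hours; returns the new time."""
    config = FateConfig.from_params(params)
    stems = lattice.stem_sites()                       # ascending site order
    inputs = _compute_inputs(lattice, params, schedule, t, stems)

    dt_sub = dt / n_substeps
    for s in stems:
        s = int(s)
        cell = lattice.cell_state(s)
        for _ in range(n_substeps):
            cell = integrate_step(cell, inputs[s], params, dt_sub)
        lattice.state[s] = cell.as_array()

    t_new = t + dt

    # fate decisions: differentiation first (precedence), ascending order —
    # deterministic, so no arbitration needed
    for s in stems:
        s = int(s)
        if lattice.state[s, 6] >= config.df_threshold:
            apply_differentiation(lattice, s, t_new, config)
            if event_log is not None:
                event_log.append((t_new, s, "differentiate"))

    # division-eligible survivors, shuffled to arbitrate shared vacancies
    candidates = np.array([int(s) for s in stems
                           if lattice.status[s] == STEM
                           and lattice.state[s, 3] >= config.pf_threshold
                           and t_new - lattice.time_of_last_division[s] >= config.tau],
                          dtype=np.int64)
    fisher_yates(candidates, gen)
    for s in candidates:
        s = int(s)
        fate = decide_fate(lattice.cell_state(s), len(lattice.empty_neighbors(s)),
                           t_new, config)
        if fate is Fate.DIVIDE:
            daughter = apply_division(lattice, s, t_new, gen)
            if daughter is not None and event_log is not None:
                event_log.append((t_new, s, "divide"))

    # scheduled deaths of differentiated cells
    for s in np.flatnonzero((lattice.status == DIFFERENTIATED)
                            & (lattice.death_time <= t_new)):
        s = int(s)
        lattice.status[s] = EMPTY
        lattice.frozen_ecad[s] = 0.0
        lattice.death_time[s] = np.inf
        if event_log is not None:
            event_log.append((t_new, s, "die"))

    return t_new


@dataclass
class TissueSimulation:
    """Reference (pure-Python) simulation of the full multi-scale model.

    Seeds ``n_seed`` stem cells at random, then repeatedly applies
    :func:`tissue_step`.  Keeps an event log suitable for audits and
    animations.  Slow but transparent; the compiled kernel reproduces its
    trajectories bit-exactly from the same seed.
    """

    params: SignalingParams
    schedule: dosing.DoseSchedule | None = None
    n_rows: int = 20
    n_cols: int = 40
    n_seed: int = 36
    seed: int | np.random.Generator = 0
    tissue_dt: float = 1.0
    n_substeps: int = 10
    cycle_spread: float = 0.0
    log_events: bool = True

    def __post_init__(self) -> None:
        self.gen = (self.seed if isinstance(self.seed, np.random.Generator)
                    else np.random.default_rng(self.seed))
        self.lattice = Lattice(self.n_rows, self.n_cols)
        self.lattice.seed_random(self.n_seed, self.params.initial_state, self.gen,
                                 cycle_spread=self.cycle_spread)
        self.t = 0.0
        self.event_log: list = [] if self.log_events else None

    def step(self) -> None:
        self.t = tissue_step(self.lattice, self.params, self.schedule, self.t,
                             self.tissue_dt, self.gen, self.n_substeps,
                             self.event_log)

    def run(self, duration: float, record_every: float = 6.0) -> pd.DataFrame:
        """Run for ``duration`` hours, recording occupancy every ``record_every`` h."""
        n_steps = int(round(duration / self.tissue_dt))
        rec_stride = max(1, int(round(record_every / self.tissue_dt)))
        rows = [self._record()]
        for k in range(n_steps):
            self.step()
            if (k + 1) % rec_stride == 0:
                rows.append(self._record())
        return pd.DataFrame(rows)

    def _record(self) -> dict:
        n_stem, n_diff, n_empty = self.lattice.counts()
        # sequential accumulation in site order, matching the compiled kernel
        secreted = 0.0
        for s in self.lattice.stem_sites():
            secreted += float(self.lattice.state[s, 0])
        return {"t": self.t, "n_stem": n_stem, "n_diff": n_diff, "n_empty": n_empty,
                "secreted_dkk": secreted}

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.event_log, columns=["t", "site", "event"])
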