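"""Honeycomb lattice on a closed surface and neighbour-coupled quantities.

The tissue is a hexagonal grid wrapped into a torus (periodic in rows and
columns) so every site has exactly six neighbours and no edge can influence
the dynamics.  Sites are ``EMPTY``, hold a ``STEM`` cell carrying the full
intracellular state, or hold a ``DIFFERENTIATED`` cell that presents frozen
E-cadherin and DSL at the levels it had at the moment of differentiation.

Hexagonal adjacency uses odd-row offset coordinates; the row count must be
even so the offset pattern closes consistently around the torus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signaling import CellState, STATE_NAMES

__all__ = [
    "EMPTY", "STEM", "DIFFERENTIATED",
    "build_neighbor_table", "Lattice", "activated_notch", "fisher_yates",
]

EMPTY, STEM, DIFFERENTIATED = 0, 1, 2

_DEATH_NEVER = np.inf

# neighbour offsets (dr, dc) for odd-row-offset hexagonal coordinates,
# listed in a fixed direction order shared by every computation
_OFFSETS_EVEN_ROW = ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0))
_OFFSETS_ODD_ROW = ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1))


def build_neighbor_table(n_rows: int, n_cols: int) -> np.ndarray:
    """Site-index table of the six hexagonal neighbours on a torus.

    Site ``(r, c)`` maps to index ``r * n_cols + c``.
    """
    if n_rows % 2 != 0:
        raise ValueError("n_rows must be even for a consistent toroidal honeycomb")
    if n_rows < 4 or n_cols < 3:
        raise ValueError("lattice must be at least 4 rows x 3 columns")
    table = np.empty((n_rows * n_cols, 6), dtype=np.int64)
    for r in range(n_rows):
        offsets = _OFFSETS_ODD_ROW if r % 2 else _OFFSETS_EVEN_ROW
        for c in range(n_cols):
            for d, (dr, dc) in enumerate(offsets):
                table[r * n_cols + c, d] = ((r + dr) % n_rows) * n_cols + (c + dc) % n_cols
    return table


def activated_notch(notch_total: float, dsl_sum: float) -> float:
    """Activated Notch receptors: min of receptor level and available DSL."""
    if notch_total < 0 or dsl_sum < 0:
        raise ValueError("notch_total and dsl_sum must be non-negative")
    return min(notch_total, dsl_sum)


def fisher_yates(arr: np.ndarray, gen: np.random.Generator) -> None:
    """In-place shuffle drawing one uniform variate per swap.

    The explicit loop (rather than ``Generator.shuffle``) keeps the draw
    sequence identical between this reference implementation and the
    compiled simulation kernel, which shares the same ``Generator``.
    """
    for i in range(len(arr) - 1, 0, -1):
        j = int(gen.random() * (i + 1))
        arr[i], arr[j] = arr[j], arr[i]


@dataclass
class Lattice:
    """Occupancy and per-site state of the toroidal honeycomb tissue."""

    n_rows: int = 20
    n_cols: int = 40

    def __post_init__(self) -> None:
        self.neighbor_table = build_neighbor_table(self.n_rows, self.n_cols)
        n = self.n_sites
        self.status = np.full(n, EMPTY, dtype=np.int8)
        self.state = np.zeros((n, 7), dtype=np.float64)      # columns: STATE_NAMES
        self.time_of_last_division = np.zeros(n, dtype=np.float64)
        self.frozen_ecad = np.zeros(n, dtype=np.float64)     # differentiated sites only
        self.death_time = np.full(n, _DEATH_NEVER, dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    # -- geometry -----------------------------------------------------------
    def neighbors(self, site: int) -> np.ndarray:
        """The six neighbour indices of ``site`` in fixed direction order."""
        self._check_site(site)
        return self.neighbor_table[site]

    def empty_neighbors(self, site: int) -> np.ndarray:
        """Neighbour indices that are currently empty (direction order kept)."""
        nbr = self.neighbors(site)
        return nbr[self.status[nbr] == EMPTY]

    def _check_site(self, site: int) -> None:
        if not 0 <= site < self.n_sites:
            raise IndexError(f"site index {site} outside lattice of {self.n_sites} sites")

    # -- occupancy ----------------------------------------------------------
    def counts(self) -> tuple[int, int, int]:
        """(stem, differentiated, empty) site counts; always sums to n_sites."""
        n_stem = int(np.sum(self.status == STEM))
        n_diff = int(np.sum(self.status == DIFFERENTIATED))
        return n_stem, n_diff, self.n_sites - n_stem - n_diff

    def stem_sites(self) -> np.ndarray:
        return np.flatnonzero(self.status == STEM)

    def place_stem(self, site: int, state: CellState) -> None:
        self._check_site(site)
        self.status[site] = STEM
        self.state[site] = state.as_array()
        self.time_of_last_division[site] = state.time_of_last_division
        self.death_time[site] = _DEATH_NEVER
        self.frozen_ecad[site] = 0.0

    def seed_random(self, k: int, initial_state: CellState, gen: np.random.Generator,
                    cycle_spread: float = 0.0) -> np.ndarray:
        """Seed ``k`` stem cells on uniformly random distinct empty sites.

        Uses a partial Fisher–Yates draw (``k`` uniforms) so the compiled
        kernel can reproduce the same placement from the same generator.
        With ``cycle_spread > 0`` each seeded cell starts at a uniformly
        random phase of its division cycle (division clock set back by up
        to ``cycle_spread`` hours), modelling an asynchronously cycling
        inoculum rather than an artificially synchronised one.
        """
        if k > self.n_sites:
            raise ValueError("cannot seed more cells than lattice sites")
        arr = np.arange(self.n_sites)
        for i in range(k):
            j = i + int(gen.random() * (self.n_sites - i))
            arr[i], arr[j] = arr[j], arr[i]
        sites = arr[:k]
        for s in sites:
            self.place_stem(int(s), initial_state)
            if cycle_spread > 0:
                self.time_of_last_division[int(s)] = -cycle_spread * gen.random()
        return sites

    def cell_state(self, site: int) -> CellState:
        if self.status[site] != STEM:
            raise ValueError(f"site {site} does not hold a stem cell")
        return CellState.from_array(self.state[site],
                                    time_of_last_division=float(self.time_of_last_division[site]))

    # -- neighbour-coupled quantities ---------------------------------------
    def neighbor_ecad(self, site: int) -> np.ndarray:
        """Per-direction E-cadherin presented to ``site`` by its neighbours.

        Stem neighbours present their current level, differentiated
        neighbours their frozen level, empty sites nothing.
        """
        out = np.zeros(6, dtype=float)
        for d, j in enumerate(self.neighbors(site)):
            if self.status[j] == STEM:
                out[d] = self.state[j, 2]
            elif self.status[j] == DIFFERENTIATED:
                out[d] = self.frozen_ecad[j]
        return out

    def bound_ecadherin(self, site: int, kappa: float) -> tuple[np.ndarray, float]:
        """Per-direction and total bound E-cadherin of the stem cell at ``site``.

        Binding into direction ``i`` is ``kappa * min(E_self, E_i)`` for an
        occupied neighbour and 0 otherwise; the total is the sum over the
        six directions.
        """
        if self.status[site] != STEM:
            raise ValueError(f"site {site} does not hold a stem cell")
        e_self = self.state[site, 2]
        per_dir = np.zeros(6, dtype=float)
        total = 0.0
        for d, j in enumerate(self.neighbors(site)):
            if self.status[j] == STEM:
                per_dir[d] = kappa * min(e_self, self.state[j, 2])
            elif self.status[j] == DIFFERENTIATED:
                per_dir[d] = kappa * min(e_self, self.frozen_ecad[j])
            total += per_dir[d]
        return per_dir, total

    def dsl_sum(self, site: int, dsl_level: float) -> float:
        """Total DSL available to ``site``: ``dsl_level`` per living neighbour."""
        if self.status[site] != STEM:
            raise ValueError(f"site {site} does not hold a stem cell")
        nbr = self.neighbors(site)
        occupied = int(np.sum(self.status[nbr] != EMPTY))
        return dsl_level * occupied

    # -- export -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy per-site snapshot (one row per site)."""
        idx = np.arange(self.n_sites)
        status_name = np.array(["empty", "stem", "differentiated"])[self.status]
        df = pd.DataFrame({
            "site": idx,
            "row": idx // self.n_cols,
            "col": idx % self.n_cols,
            "status": status_name,
        })
        for k, name in enumerate(STATE_NAMES):
            df[name] = np.where(self.status == STEM, self.state[:, k], np.nan)
        df["frozen_ecad"] = np.where(self.status == DIFFERENTIATED, self.frozen_ecad, np.nan)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def snapshot(self, t: float) -> dict:
        """Compact JSON-ready snapshot for time-series visualisation."""
        return {
            "t": float(t),
            "status": self.status.tolist(),
            "pf": np.round(self.state[:, 3], 4).tolist(),
            "df": np.round(self.state[:, 6], 4).tolist(),
        }
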