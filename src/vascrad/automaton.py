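"""Cell-fate automaton: death, quiescence, proliferation, competition.

Each automaton update visits every cell exactly once in a fresh uniform
random order.  Per cell, with c the local oxygen concentration:

1. if c < c_ap the cell dies with probability p_d (site empties) —
   otherwise it is quiescent this step;
2. else if c < c_p, or no eligible neighbour site exists, the cell is
   marked quiescent;
3. else the quiescent flag is cleared and the cell divides with
   probability p_H (healthy) or p_T (tumour), placing an identical
   daughter in a uniformly chosen eligible neighbour.  A healthy cell
   displaced by a tumour daughter dies; the parent is flagged
   proliferating so the next oxygen solve applies its elevated
   consumption.  Daughters created during a step are not themselves
   processed until the next step.

Eligibility uses the Moore neighbourhood (8 sites, truncated at domain
edges): healthy cells may place daughters on empty non-vessel sites only;
tumour cells may also displace healthy cells (competition), but never
other tumour cells or vessels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .oxygen import build_consumption, relax_to_quasi_steady
from .parameters import ModelParameters
from .state import EMPTY, HEALTHY, TUMOUR, TissueState

__all__ = [
    "AutomatonConfig",
    "eligible_neighbours",
    "update_cell_fates",
    "run_automaton_step",
]

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class AutomatonConfig:
    """Automaton update frequency and the per-update fate probabilities.

    With K updates per cell cycle the per-update probabilities are chosen
    so that 1 − (1 − p)^K equals the per-cell-cycle value, preserving the
    per-cycle hazard whatever K is used.
    """

    updates_per_cell_cycle: int = 1
    p_d: float = 0.25
    p_H: float = 0.005
    p_T: float = 0.01

    @classmethod
    def from_params(cls, params: ModelParameters, K: int = 1) -> "AutomatonConfig":
        if K < 1:
            raise ValueError(f"updates_per_cell_cycle must be >= 1, got {K}")
        def rescale(p):
            return p if K == 1 else 1.0 - (1.0 - p) ** (1.0 / K)
        return cls(updates_per_cell_cycle=K, p_d=rescale(params.p_d),
                   p_H=rescale(params.p_H), p_T=rescale(params.p_T))

    @property
    def dt(self) -> float:
        """Automaton step length in cell cycles."""
        return 1.0 / self.updates_per_cell_cycle


def eligible_neighbours(state: TissueState, site: tuple[int, int],
                        cell_type: int | None = None) -> list[tuple[int, int]]:
    """Moore-neighbourhood sites where a daughter of the cell at ``site``
    could be placed.

    Healthy cells require empty non-vessel sites; tumour cells treat
    healthy-occupied sites as available (competition).  Raises if the site
    is empty or a vessel.
    """
    i, j = site
    if state.vessel_mask[i, j]:
        raise ValueError(f"site {site} is a vessel")
    occupant = int(state.cell_grid[i, j])
    if occupant == EMPTY:
        raise ValueError(f"site {site} is empty")
    if cell_type is None:
        cell_type = occupant
    elif cell_type != occupant:
        raise ValueError(f"site {site} holds type {occupant}, not {cell_type}")
    out = []
    for di, dj in _MOORE:
        ii, jj = i + di, j + dj
        if not (0 <= ii < state.N and 0 <= jj < state.N):
            continue
        if state.vessel_mask[ii, jj]:
            continue
        g = int(state.cell_grid[ii, jj])
        if cell_type == HEALTHY:
            if g == EMPTY:
                out.append((ii, jj))
        else:  # tumour: empty or healthy-occupied
            if g != TUMOUR:
                out.append((ii, jj))
    return out


@njit(cache=True)
def _fate_kernel(grid, quiescent, proliferating, daughter, oxygen, vessel,
                 order, u_death, u_div, u_pick,
                 c_ap, c_p, p_d, p_H, p_T):  # pragma: no cover - jitted
    n = order.shape[0]
    N = grid.shape[0]
    nbr_i = np.empty(8, np.int64)
    nbr_j = np.empty(8, np.int64)
    for k in range(n):
        i = order[k, 0]
        j = order[k, 1]
        if daughter[i, j]:
            continue  # placed this step; acts from the next step
        t = grid[i, j]
        if t == 0:
            continue
        c = oxygen[i, j]
        if c < c_ap:
            if u_death[k] < p_d:
                grid[i, j] = 0
                quiescent[i, j] = False
                proliferating[i, j] = False
            else:
                quiescent[i, j] = True
            continue
        cnt = 0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                ii = i + di
                jj = j + dj
                if ii < 0 or ii >= N or jj < 0 or jj >= N:
                    continue
                if vessel[ii, jj]:
                    continue
                g = grid[ii, jj]
                if t == 1:
                    ok = g == 0
                else:
                    ok = g != 2
                if ok:
                    nbr_i[cnt] = ii
                    nbr_j[cnt] = jj
                    cnt += 1
        if c < c_p or cnt == 0:
            quiescent[i, j] = True
            continue
        quiescent[i, j] = False
        p = p_H if t == 1 else p_T
        if u_div[k] < p:
            pick = int(u_pick[k] * cnt)
            if pick >= cnt:
                pick = cnt - 1
            ii = nbr_i[pick]
            jj = nbr_j[pick]
            grid[ii, jj] = t  # displaced healthy cell (if any) dies here
            daughter[ii, jj] = True
            quiescent[ii, jj] = False
            proliferating[ii, jj] = False
            proliferating[i, j] = True


def update_cell_fates(state: TissueState, params: ModelParameters,
                      config: AutomatonConfig,
                      rng: np.random.Generator) -> TissueState:
    """Apply the fate algorithm to every cell once, in random order.

    All randomness (visit order, death/division draws, daughter placement)
    is drawn from ``rng`` up front, so trajectories are exactly
    reproducible from the seed.  Mutates and returns ``state``.
    """
    occupied = np.argwhere(state.cell_grid > 0)
    n = len(occupied)
    if n == 0:
        return state
    order = occupied[rng.permutation(n)]
    u_death = rng.random(n)
    u_div = rng.random(n)
    u_pick = rng.random(n)
    daughter = np.zeros_like(state.vessel_mask)
    _fate_kernel(state.cell_grid, state.quiescent, state.proliferating,
                 daughter, state.oxygen, state.vessel_mask,
                 order, u_death, u_div, u_pick,
                 params.c_ap, params.c_p,
                 config.p_d, config.p_H, config.p_T)
    return state


def run_automaton_step(state: TissueState, params: ModelParameters,
                       config: AutomatonConfig, rng: np.random.Generator,
                       relax_kwargs: dict | None = None) -> TissueState:
    """One coupled automaton step.

    Relaxes oxygen to the quasi-steady field for the current occupancy
    (including proliferative consumption flagged by the previous step),
    clears the consumed proliferating flags, applies the fate update, and
    advances time by 1/K cell cycles.
    """
    consumption = build_consumption(state, params)
    relax_to_quasi_steady(state, consumption, params,
                          **(relax_kwargs or {}))
    state.proliferating[:] = False
    update_cell_fates(state, params, config, rng)
    state.time_nd += config.dt
    return state
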