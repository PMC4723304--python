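"""Oxygen reaction-diffusion on the tissue lattice.

The non-dimensional field obeys  ∂c/∂t = D_c ∇²c − f(c)  with
Michaelis-Menten uptake f(c) = m·r_c·c/(c + K_m), Dirichlet sources c = 1
at vessel sites, and no-flux outer boundaries.  The discretisation is a
five-point Laplacian with ghost-node reflection at the domain edges; the
same discrete system underlies both integration routes below.

Two routes to the quasi-steady field are provided:

* ``method="explicit"`` — repeated explicit Euler steps of length
  ``dt_oxygen_nd`` until the per-step change falls below tolerance (or the
  per-cell-cycle step budget is exhausted).  This is the literal
  fine-timescale integration and is retained for fidelity runs and as the
  oracle in cross-validation tests.
* ``method="direct"`` (default) — damped Newton iteration on the discrete
  steady-state equations, using a sparse LU factorisation of the Jacobian
  that is reused across automaton steps while the occupancy changes
  little.  The converged field satisfies the same discrete balance the
  explicit route relaxes towards, at a small fraction of the cost.  The
  automaton couples to oxygen through this quasi-steady field, which is
  justified by the separation between the oxygen and cell-cycle
  timescales (the diffusion time across the domain is a few percent of a
  cell cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .parameters import ModelParameters, stability_factor
from .state import HEALTHY, TUMOUR, TissueState

__all__ = [
    "build_consumption",
    "uptake_rate",
    "step_oxygen",
    "relax_to_quasi_steady",
    "RelaxInfo",
    "StabilityError",
]

#: clip magnitudes above this trigger a diagnostics warning
_CLIP_WARN = 1.0e-6
#: explicit 2-D stability limit for the five-point scheme
_STABILITY_LIMIT = 0.25


class StabilityError(RuntimeError):
    """Raised when the explicit scheme would violate its stability limit."""


@dataclass
class RelaxInfo:
    iterations: int
    converged: bool
    max_change: float
    method: str


def build_consumption(state: TissueState, params: ModelParameters) -> np.ndarray:
    """Per-site uptake multiplier m(x).

    Zero at empty and vessel sites, μ_H at healthy sites, μ_H·μ_T_ratio at
    tumour sites, multiplied further by the proliferative factor at sites
    flagged proliferating.
    """
    m = np.zeros((state.N, state.N), dtype=np.float64)
    m[state.cell_grid == HEALTHY] = params.mu_H
    m[state.cell_grid == TUMOUR] = params.mu_T
    m[state.proliferating & (state.cell_grid > 0)] *= params.r_p_factor
    m[state.vessel_mask] = 0.0
    return m


def uptake_rate(c, multiplier, params: ModelParameters):
    """Michaelis-Menten uptake m·r_c·c/(c + K_m), per cell cycle."""
    c = np.asarray(c, dtype=np.float64)
    if (c < 0).any():
        raise ValueError("negative oxygen concentration (field corruption)")
    return np.asarray(multiplier) * params.r_c * c / (c + params.K_m)


def _neighbour_sum(c: np.ndarray) -> np.ndarray:
    """Sum of the four lattice neighbours with ghost-node reflection
    (c_{-1} = c_{1}) at the domain edges."""
    up = np.concatenate((c[1:2, :], c[:-1, :]), axis=0)
    down = np.concatenate((c[1:, :], c[-2:-1, :]), axis=0)
    left = np.concatenate((c[:, 1:2], c[:, :-1]), axis=1)
    right = np.concatenate((c[:, 1:], c[:, -2:-1]), axis=1)
    return up + down + left + right


def _apply_clip(c: np.ndarray) -> None:
    over = max(c.max() - 1.0, 0.0)
    under = max(-c.min(), 0.0)
    if max(over, under) > _CLIP_WARN:
        warnings.warn(
            f"oxygen clip of magnitude {max(over, under):.3e} exceeds "
            f"{_CLIP_WARN:.0e}; check the time step", RuntimeWarning)
    np.clip(c, 0.0, 1.0, out=c)


def step_oxygen(state: TissueState, consumption: np.ndarray,
                params: ModelParameters) -> float:
    """One explicit finite-difference update of length ``dt_oxygen_nd``.

    Mutates ``state.oxygen`` in place and returns the maximum per-site
    change.  Refuses to step if the diffusion number exceeds the 2-D
    explicit limit of 0.25.
    """
    s = stability_factor(params)
    if s > _STABILITY_LIMIT:
        raise StabilityError(
            f"stability factor {s:.4g} exceeds the explicit limit "
            f"{_STABILITY_LIMIT}; reduce dt_oxygen")
    c = state.oxygen
    c[state.vessel_mask] = 1.0
    lap = _neighbour_sum(c) - 4.0 * c
    f = consumption * params.r_c * c / (c + params.K_m)
    c_new = c + params.dt_oxygen_nd * (params.D_c * lap - f)
    c_new[state.vessel_mask] = 1.0
    _apply_clip(c_new)
    change = float(np.abs(c_new - c).max())
    state.oxygen = c_new
    return change


class _SteadySolver:
    """Newton solver for the discrete steady state on a fixed vessel layout.

    Holds the (constant) five-point Laplacian restricted to non-vessel
    sites, the Dirichlet source vector, and the most recent sparse LU
    factorisation of the Jacobian, which stays valid across automaton
    steps while the occupancy changes little (modified Newton with
    refactorisation when convergence stalls).
    """

    def __init__(self, N: int, vessel_mask: np.ndarray):
        self.N = N
        self.vessel = vessel_mask.copy()
        unknown = ~vessel_mask
        self.unknown = unknown
        n_sites = N * N
        idx = np.arange(n_sites).reshape(N, N)
        # neighbour site indices with ghost-node reflection at the edges
        nbrs = [
            np.concatenate((idx[1:2, :], idx[:-1, :]), axis=0),
            np.concatenate((idx[1:, :], idx[-2:-1, :]), axis=0),
            np.concatenate((idx[:, 1:2], idx[:, :-1]), axis=1),
            np.concatenate((idx[:, 1:], idx[:, -2:-1]), axis=1),
        ]
        # unknown numbering
        self.umap = -np.ones(n_sites, dtype=np.int64)
        flat_unknown = unknown.ravel()
        self.umap[flat_unknown] = np.arange(flat_unknown.sum())
        self.n_unknown = int(flat_unknown.sum())
        rows, cols, vals = [], [], []
        b = np.zeros(self.n_unknown)
        site = idx.ravel()
        vflat = vessel_mask.ravel()
        for nb in nbrs:
            nb = nb.ravel()
            keep = flat_unknown
            r = self.umap[site[keep]]
            target = nb[keep]
            is_vessel = vflat[target]
            # vessel neighbours contribute the Dirichlet value 1 to the RHS
            np.add.at(b, r[is_vessel], 1.0)
            rows.append(r[~is_vessel])
            cols.append(self.umap[target[~is_vessel]])
            vals.append(np.ones((~is_vessel).sum()))
        rows.append(np.arange(self.n_unknown))
        cols.append(np.arange(self.n_unknown))
        vals.append(np.full(self.n_unknown, -4.0))
        self.A = sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_unknown, self.n_unknown))
        self.b = b
        self._lu = None

    def solve(self, c_grid: np.ndarray, m_grid: np.ndarray,
              params: ModelParameters, tol: float,
              max_iterations: int) -> tuple[np.ndarray, int, bool, float]:
        D = params.D_c
        r_c = params.r_c
        K_m = params.K_m
        flat_unknown = self.unknown.ravel()
        if self.n_unknown == 0:  # vessels everywhere: field is identically 1
            c_grid.fill(1.0)
            return c_grid, 0, True, 0.0
        c = c_grid.ravel()[flat_unknown].copy()
        m = m_grid.ravel()[flat_unknown] * r_c
        if not self.b.any() and not m.any():
            # no sources and no sinks: the no-flux dynamics conserve total
            # oxygen and flatten the field to its mean
            mean = float(c.mean())
            out = c_grid.ravel()
            change = float(np.abs(c - mean).max())
            out[flat_unknown] = mean
            return out.reshape(self.N, self.N), 1, True, change
        change = np.inf
        prev_change = np.inf
        for it in range(1, max_iterations + 1):
            u = m * c / (c + K_m)
            F = D * (self.A @ c + self.b) - u
            if self._lu is None or (it > 2 and change > 0.5 * prev_change):
                du = m * K_m / (c + K_m) ** 2
                J = (D * self.A - sparse.diags(du)).tocsc()
                self._lu = splu(J)
            delta = self._lu.solve(-F)
            c_new = np.clip(c + delta, 0.0, 1.0)
            prev_change = change
            change = float(np.abs(c_new - c).max())
            c = c_new
            if change < tol:
                out = c_grid.ravel()
                out[flat_unknown] = c
                out[~flat_unknown] = 1.0
                return out.reshape(self.N, self.N), it, True, change
        out = c_grid.ravel()
        out[flat_unknown] = c
        out[~flat_unknown] = 1.0
        return out.reshape(self.N, self.N), max_iterations, False, change


#: small cache of steady solvers keyed by vessel layout
_SOLVER_CACHE: dict = {}
_SOLVER_CACHE_MAX = 4


def _get_solver(state: TissueState) -> _SteadySolver:
    key = (state.N, state.vessel_mask.tobytes())
    solver = _SOLVER_CACHE.get(key)
    if solver is None:
        solver = _SteadySolver(state.N, state.vessel_mask)
        if len(_SOLVER_CACHE) >= _SOLVER_CACHE_MAX:
            _SOLVER_CACHE.pop(next(iter(_SOLVER_CACHE)))
        _SOLVER_CACHE[key] = solver
    return solver


def relax_to_quasi_steady(state: TissueState, consumption: np.ndarray,
                          params: ModelParameters, tol: float = 1.0e-6,
                          method: str = "direct",
                          max_iterations: int | None = None) -> RelaxInfo:
    """Relax ``state.oxygen`` to the quasi-steady field for the current
    occupancy, warm-starting from the field already stored in the state.

    ``tol`` is the convergence threshold on the maximum per-site change
    per iteration (explicit steps for ``method="explicit"``, Newton
    updates for ``method="direct"``).  A Newton update is close to the
    remaining error itself, whereas an explicit-step change understates
    it by the factor rate·Δt, so the direct route at a given ``tol`` is
    the more accurate of the two.  If the iteration budget is exhausted
    without convergence a warning is recorded and the field returned
    as-is.
    """
    c = state.oxygen
    c[state.vessel_mask] = 1.0
    if method == "explicit":
        budget = max_iterations if max_iterations is not None \
            else params.steps_per_cycle
        change = np.inf
        for it in range(1, budget + 1):
            change = step_oxygen(state, consumption, params)
            if change < tol:
                return RelaxInfo(it, True, change, method)
        warnings.warn(
            f"explicit relaxation budget of {budget} steps exhausted "
            f"(last change {change:.3e})", RuntimeWarning)
        return RelaxInfo(budget, False, change, method)
    if method != "direct":
        raise ValueError(f"unknown method {method!r}")

    budget = max_iterations if max_iterations is not None else 100
    solver = _get_solver(state)
    field, iters, converged, change = solver.solve(
        c, consumption, params, tol, budget)
    state.oxygen = field
    if not converged:
        warnings.warn(
            f"steady-state Newton budget of {budget} iterations exhausted "
            f"(last change {change:.3e})", RuntimeWarning)
    return RelaxInfo(iters, converged, change, method)
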