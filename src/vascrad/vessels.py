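"""Vessel point patterns: regular lattices, uniform-random placements, I/O.

Vessels are modelled as single-site point sources of oxygen on the cell
lattice.  A pattern is characterised by its coordinates and its density
Θ = v/N² (vessels per lattice site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VesselPattern",
    "generate_regular",
    "generate_random",
    "regular_grid_for_count",
    "regular_pattern_for_theta",
    "realisable_regular_thetas",
    "read_pattern_csv",
    "write_pattern_csv",
]


@dataclass(frozen=True)
class VesselPattern:
    """A set of distinct vessel coordinates on an N × N lattice."""

    N: int
    coords: np.ndarray  # (v, 2) integer lattice coordinates

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if len(coords):
            if coords.min() < 0 or coords.max() >= self.N:
                raise ValueError("vessel coordinates outside [0, N)^2")
            if len(np.unique(coords, axis=0)) != len(coords):
                raise ValueError("duplicate vessel coordinates")

    @property
    def v(self) -> int:
        return len(self.coords)

    @property
    def theta(self) -> float:
        """Vessel density Θ = v/N²."""
        return self.v / self.N**2

    def mask(self) -> np.ndarray:
        out = np.zeros((self.N, self.N), dtype=bool)
        if self.v:
            out[self.coords[:, 0], self.coords[:, 1]] = True
        return out


def _axis_positions(N: int, spacing: int, offset: int | None) -> np.ndarray:
    if spacing < 1:
        raise ValueError(f"spacing must be >= 1, got {spacing}")
    if offset is None:
        offset = spacing // 2
    return np.arange(offset, N, spacing, dtype=np.int64)


def generate_regular(N: int, spacing: int, spacing_y: int | None = None,
                     offset: int | None = None, offset_y: int | None = None,
                     add_central_vessel: bool = False) -> VesselPattern:
    """Regular rectangular vessel grid.

    Vessels sit at ``(i*spacing + offset, j*spacing_y + offset_y)`` inside
    the domain; offsets default to half the spacing so the grid is centred
    in its tile.  ``add_central_vessel`` additionally places a vessel at
    ``(N//2, N//2)`` (deduplicated), as used when seeding tumours at the
    domain centre.
    """
    if spacing_y is None:
        spacing_y = spacing
    xs = _axis_positions(N, spacing, offset)
    ys = _axis_positions(N, spacing_y, offset_y)
    coords = np.array([(x, y) for x in xs for y in ys], dtype=np.int64)
    coords = coords.reshape(-1, 2)
    if add_central_vessel:
        centre = np.array([[N // 2, N // 2]], dtype=np.int64)
        coords = np.unique(np.vstack([coords, centre]) if len(coords)
                           else centre, axis=0)
    return VesselPattern(N=N, coords=coords)


def generate_random(N: int, v: int, rng: np.random.Generator) -> VesselPattern:
    """``v`` distinct sites drawn uniformly without replacement."""
    if not 0 <= v <= N * N:
        raise ValueError(f"vessel count {v} outside [0, N^2] for N={N}")
    flat = rng.choice(N * N, size=v, replace=False)
    coords = np.column_stack(np.unravel_index(flat, (N, N))).astype(np.int64)
    return VesselPattern(N=N, coords=coords)


def regular_grid_for_count(N: int, kx: int, ky: int) -> VesselPattern:
    """Regular grid with exactly ``kx × ky`` vessels (kx columns of ky)."""
    pat = generate_regular(N, spacing=N // kx, spacing_y=N // ky)
    if pat.v != kx * ky:
        raise ValueError(f"could not realise a {kx}x{ky} grid on N={N}")
    return pat


def realisable_regular_thetas(N: int, k_min: int = 2, k_max: int | None = None,
                              max_axis_diff: int = 1) -> list[tuple[float, int, int]]:
    """Densities realisable by near-square regular grids on an N × N domain.

    Returns ``(theta, kx, ky)`` sorted by theta, for per-axis counts with
    ``|kx - ky| <= max_axis_diff``.  Regular densities are quantised; sweeps
    report the realised Θ, never the requested one.
    """
    if k_max is None:
        k_max = N // 2
    out = []
    for kx in range(k_min, k_max + 1):
        for ky in range(kx, min(kx + max_axis_diff, k_max) + 1):
            out.append((kx * ky / N**2, kx, ky))
    return sorted(out)


def regular_pattern_for_theta(N: int, theta: float, max_axis_diff: int = 1,
                              add_central_vessel: bool = False,
                              k_min: int = 2, k_max: int | None = None
                              ) -> VesselPattern:
    """The realisable near-square regular grid closest in density to ``theta``.

    The realised density is quantised by the integer per-axis counts; ties
    are broken toward the less anisotropic grid.
    """
    target = theta * N**2
    best = None
    for th, kx, ky in realisable_regular_thetas(N, k_min=k_min, k_max=k_max,
                                                max_axis_diff=max_axis_diff):
        v = kx * ky + (1 if add_central_vessel else 0)
        key = (abs(v - target), ky - kx)
        if best is None or key < best[0]:
            best = (key, kx, ky)
    _, kx, ky = best
    pat = regular_grid_for_count(N, kx, ky)
    if add_central_vessel:
        pat = generate_regular(N, spacing=N // kx, spacing_y=N // ky,
                               add_central_vessel=True)
    return pat


# ---------------------------------------------------------------------------
# coordinate I/O: two-column integer CSV, 0-based, header row "x,y"
# ---------------------------------------------------------------------------

def write_pattern_csv(pattern: VesselPattern, path) -> None:
    df = pd.DataFrame(pattern.coords, columns=["x", "y"])
    df.to_csv(path, index=False)


def read_pattern_csv(path, N: int) -> VesselPattern:
    df = pd.read_csv(path)
    if list(df.columns) != ["x", "y"]:
        raise ValueError(f"expected header 'x,y', got {list(df.columns)}")
    return VesselPattern(N=N, coords=df.to_numpy(dtype=np.int64))
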