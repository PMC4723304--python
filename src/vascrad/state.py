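"""Tissue state: the cell lattice, vessel sites, and the oxygen field."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vessels import VesselPattern

__all__ = ["EMPTY", "HEALTHY", "TUMOUR", "VESSEL_CODE", "TissueState"]

EMPTY = 0
HEALTHY = 1
TUMOUR = 2
#: code used for vessel sites in exported integer grids only
VESSEL_CODE = 9


@dataclass
class TissueState:
    """State of the N × N tissue lattice.

    ``cell_grid`` holds 0 (empty), 1 (healthy) or 2 (tumour) per site;
    vessel sites are tracked in ``vessel_mask`` and are never occupied by
    cells.  ``oxygen`` is the non-dimensional concentration field in [0, 1],
    and ``time_nd`` the elapsed time in cell cycles.
    """

    N: int
    cell_grid: np.ndarray
    quiescent: np.ndarray
    proliferating: np.ndarray
    vessel_mask: np.ndarray
    oxygen: np.ndarray
    time_nd: float = 0.0
    pattern: VesselPattern | None = None

    @classmethod
    def from_pattern(cls, pattern: VesselPattern, fill: str = "healthy",
                     c0: float = 1.0) -> "TissueState":
        """Build a state from a vessel pattern.

        ``fill`` is one of ``"healthy"``, ``"tumour"``, ``"empty"`` or
        ``"central-tumour"`` (a healthy field with one tumour cell at the
        domain centre).  Vessel sites are left unoccupied.
        """
        N = pattern.N
        grid = np.zeros((N, N), dtype=np.int8)
        vessel = np.zeros((N, N), dtype=bool)
        if len(pattern.coords):
            vessel[pattern.coords[:, 0], pattern.coords[:, 1]] = True
        if fill == "healthy":
            grid[~vessel] = HEALTHY
        elif fill == "tumour":
            grid[~vessel] = TUMOUR
        elif fill == "central-tumour":
            grid[~vessel] = HEALTHY
            centre = (N // 2, N // 2)
            if not vessel[centre]:
                grid[centre] = TUMOUR
            else:  # centre taken by a vessel: seed the nearest free site
                free = np.argwhere(~vessel)
                d2 = ((free - np.array(centre)) ** 2).sum(axis=1)
                i, j = free[np.argmin(d2)]
                grid[i, j] = TUMOUR
        elif fill != "empty":
            raise ValueError(f"unknown fill {fill!r}")
        return cls(
            N=N,
            cell_grid=grid,
            quiescent=np.zeros((N, N), dtype=bool),
            proliferating=np.zeros((N, N), dtype=bool),
            vessel_mask=vessel,
            oxygen=np.full((N, N), float(c0)),
            pattern=pattern,
        )

    # -- bookkeeping ------------------------------------------------------
    def cell_count(self, cell_type: int | None = None) -> int:
        if cell_type is None:
            return int((self.cell_grid > 0).sum())
        return int((self.cell_grid == cell_type).sum())

    @property
    def n_vessels(self) -> int:
        return int(self.vessel_mask.sum())

    def cellularity(self) -> float:
        """Cells divided by total domain size N² (vessel sites included in
        the denominator)."""
        return self.cell_count() / self.N**2

    def occupiable_occupancy(self) -> float:
        """Fraction of non-vessel sites occupied by cells."""
        occupiable = self.N**2 - self.n_vessels
        return self.cell_count() / occupiable if occupiable else 0.0

    def coded_grid(self) -> np.ndarray:
        """Integer grid for export: 0 empty, 1 healthy, 2 tumour, 9 vessel."""
        out = self.cell_grid.astype(np.int64).copy()
        out[self.vessel_mask] = VESSEL_CODE
        return out

    def copy(self) -> "TissueState":
        return TissueState(
            N=self.N,
            cell_grid=self.cell_grid.copy(),
            quiescent=self.quiescent.copy(),
            proliferating=self.proliferating.copy(),
            vessel_mask=self.vessel_mask.copy(),
            oxygen=self.oxygen.copy(),
            time_nd=self.time_nd,
            pattern=self.pattern,
        )

    def validate(self) -> None:
        """Check structural invariants (sites, bounds, vessel exclusivity)."""
        if self.cell_grid.shape != (self.N, self.N):
            raise ValueError("cell_grid shape mismatch")
        if (self.cell_grid[self.vessel_mask] != EMPTY).any():
            raise ValueError("cells present on vessel sites")
        if ((self.oxygen < 0) | (self.oxygen > 1)).any():
            raise ValueError("oxygen field out of [0, 1]")
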