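"""Ripley's K and variance-stabilised L functions for vessel patterns.

K(r) is the edge-corrected expected number of further points within
distance r of a typical point, scaled by intensity; under complete spatial
randomness (CSR) K(r) = πr², so the variance-stabilised transform
L(r) = sqrt(K(r)/π) satisfies L(r) = r.  Patterns more clustered than CSR
push L above r at small distances; regular patterns pull it below.

The scalar summary used to correlate organisation with simulation
outcomes is the arithmetic mean of L(r) over r = 0, 1, …, 19 cell
diameters — from adjacent sites out to a distance beyond which vessels no
longer influence one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .vessels import VesselPattern

__all__ = [
    "ripley_K",
    "ripley_L",
    "mean_L",
    "RipleySummary",
    "ripley_summary",
    "pearson",
    "PearsonResult",
]


def _pair_displacements(coords: np.ndarray):
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    iu = np.triu_indices(n, k=1)
    dx = np.abs(diff[..., 0][iu])
    dy = np.abs(diff[..., 1][iu])
    return dx, dy, np.hypot(dx, dy)


def ripley_K(coords, window: tuple[float, float], r_values,
             correction: str = "translation") -> np.ndarray:
    """Edge-corrected Ripley K estimates at each distance in ``r_values``.

    ``window`` is the rectangle [0, a] × [0, b].  The default translation
    correction weights each ordered pair by |W|/((a−|Δx|)(b−|Δy|)), which
    is exactly unbiased under CSR on a rectangle:

        K̂(r) = |W|/(n(n−1)) · Σ_{i≠j} e_ij · 1(d_ij ≤ r).

    ``correction="isotropic"`` instead weights pairs by the reciprocal
    fraction of the circle of radius d_ij centred on point i that lies
    inside the window.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    n = len(coords)
    if n < 2 or len(np.unique(coords, axis=0)) < 2:
        raise ValueError("degenerate pattern: need >= 2 distinct points")
    a, b = float(window[0]), float(window[1])
    area = a * b
    r_values = np.asarray(r_values, dtype=np.float64)

    if correction == "translation":
        dx, dy, d = _pair_displacements(coords)
        w = area / ((a - dx) * (b - dy))  # per unordered pair (symmetric)
        # ordered-pair sum = 2 x unordered
        contrib = 2.0 * w
        K = np.array([(contrib * (d <= r)).sum() for r in r_values])
        return area / (n * (n - 1)) * K
    if correction == "isotropic":
        w = _isotropic_weights(coords, a, b)
        d = w["d"]
        contrib = w["weight"]
        K = np.array([(contrib * (d <= r)).sum() for r in r_values])
        return area / (n * (n - 1)) * K
    raise ValueError(f"unknown correction {correction!r}")


def _isotropic_weights(coords: np.ndarray, a: float, b: float) -> dict:
    """Ordered-pair distances and Ripley isotropic weights 1/α_ij, where
    α_ij is the fraction of the circle of radius d_ij centred on point i
    lying inside the rectangle (corner overlaps handled exactly)."""
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    n = len(coords)
    mask = ~np.eye(n, dtype=bool)
    ds = []
    ws = []
    for i in range(n):
        x, y = coords[i]
        edges = np.array([x, a - x, y, b - y])  # left, right, bottom, top
        for j in range(n):
            if i == j:
                continue
            r = d[i, j]
            if r == 0:
                ds.append(r)
                ws.append(1.0)
                continue
            out = 0.0
            for e in edges:
                if e < r:
                    out += 2.0 * np.arccos(e / r)
            # corner overlap: arcs beyond two adjacent edges double-count
            for ex in (x, a - x):
                for ey in (y, b - y):
                    if ex * ex + ey * ey < r * r:
                        out -= (np.pi / 2.0 - np.arcsin(min(ex / r, 1.0))
                                - np.arcsin(min(ey / r, 1.0)))
            frac = max(1.0 - out / (2.0 * np.pi), 1.0e-12)
            ds.append(r)
            ws.append(1.0 / frac)
    return {"d": np.asarray(ds), "weight": np.asarray(ws)}


def ripley_L(K) -> np.ndarray:
    """Variance-stabilised transform L(r) = sqrt(K(r)/π)."""
    K = np.asarray(K, dtype=np.float64)
    if (K < 0).any():
        raise ValueError("negative K estimate")
    return np.sqrt(K / np.pi)


@dataclass
class RipleySummary:
    r_values: np.ndarray
    L: np.ndarray
    mean_L: float
    n_points: int
    window: tuple[float, float]


def ripley_summary(pattern: VesselPattern, r_max: int = 19,
                   correction: str = "translation") -> RipleySummary:
    """L(r) at integer distances 0..r_max and the scalar mean-L summary."""
    r_values = np.arange(r_max + 1, dtype=np.float64)
    window = (float(pattern.N), float(pattern.N))
    K = ripley_K(pattern.coords, window, r_values, correction=correction)
    L = ripley_L(K)
    return RipleySummary(r_values=r_values, L=L, mean_L=float(L.mean()),
                         n_points=pattern.v, window=window)


def mean_L(pattern: VesselPattern, r_max: int = 19,
           correction: str = "translation") -> float:
    """Mean of L(r) over r = 0, 1, …, r_max cell diameters."""
    return ripley_summary(pattern, r_max=r_max, correction=correction).mean_L


@dataclass
class PearsonResult:
    r: float
    p: float
    n: int
    valid: bool = True
    reason: str = ""


def pearson(x, y) -> PearsonResult:
    """Sample Pearson correlation with two-sided p from the t transform.

    Degenerate inputs (length < 3, zero variance) yield a flagged
    undefined result rather than a silent NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        return PearsonResult(float("nan"), float("nan"), n, False,
                             "need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(float("nan"), float("nan"), n, False,
                             "zero variance")
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), n)
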