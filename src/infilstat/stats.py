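"""Spatial statistics for 2-D point patterns.

Implements the pair correlation function g(r), the nearest-neighbour
distance distribution G(r), the spherical contact (empty-space)
distribution F(r) and the J-function J(r) = (1 - G)/(1 - F), together
with the three scalar summaries used for infiltration inference:

* ``g_max``  — the peak of the PCF, the maximum intensity of clustering;
* ``F_max``  — the largest observed empty-space distance, i.e. the radius
  of the largest circular void ("immune desert") in the pattern;
* ``J_min``  — the minimum of the J-function, the depth of clustering.

Under complete spatial randomness (CSR, a homogeneous Poisson process)
g(r) = 1 and J(r) = 1 for all r.  The PCF uses an analytic edge
correction: for each point the expected CSR count in an annulus is the
global intensity times the area of the annulus-window intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial import distance as sdist

from .patterns import PatternError, PointPattern, Window

__all__ = [
    "RadiusGrid",
    "StatCurve",
    "SummaryFeatures",
    "CurveKind",
    "pair_correlation",
    "nn_distribution",
    "spherical_contact",
    "j_function",
    "summary_features",
    "disc_window_area",
    "InsufficientPointsError",
]

FEATURE_NAMES = ("g_max", "F_max", "J_min")


class InsufficientPointsError(PatternError):
    """Raised when a pattern has too few points for a statistic."""


class CurveKind(str, Enum):
    PCF = "PCF"
    NN_CDF = "NN_CDF"
    SCD_CDF = "SCD_CDF"
    J = "J"


@dataclass(frozen=True)
class RadiusGrid:
    """Uniform radius grid: centres r_i = i * dr for i = 1..m, bin width dr.

    Annulus/bin i covers the half-open interval (r_i - dr/2, r_i + dr/2],
    ties assigned to the upper bin.  The default resolves the 0.02 mm
    hard core and reaches half the default window side.
    """

    dr: float = 0.01
    r_max: float = 0.75

    def __post_init__(self) -> None:
        if not (self.dr > 0 and self.r_max >= self.dr):
            raise ValueError("need dr > 0 and r_max >= dr")

    @property
    def r_values(self) -> np.ndarray:
        m = int(round(self.r_max / self.dr))
        return self.dr * np.arange(1, m + 1)

    @property
    def bin_edges(self) -> np.ndarray:
        """Edges (r_1 - dr/2, r_1 + dr/2, ..., r_m + dr/2)."""
        r = self.r_values
        return np.concatenate([[r[0] - self.dr / 2], r + self.dr / 2])

    @classmethod
    def for_window(cls, window: Window, dr: float = 0.01) -> "RadiusGrid":
        return cls(dr=dr, r_max=min(window.width, window.height) / 2)


@dataclass
class StatCurve:
    """A spatial statistic sampled on a radius grid.

    ``values`` may contain NaN where the statistic is undefined (the
    J-function beyond F_max).  For CDF kinds, ``observations`` optionally
    stores the raw distances underlying the empirical CDF.
    """

    kind: CurveKind
    grid: RadiusGrid
    values: np.ndarray
    observations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.r_values.shape:
            raise ValueError("values do not match the radius grid")

    @property
    def r(self) -> np.ndarray:
        return self.grid.r_values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kind": self.kind.value, "r": self.r, "value": self.values})


@dataclass(frozen=True)
class SummaryFeatures:
    """The feature triple (g_max, F_max, J_min) plus density d for one pattern."""

    g_max: float
    F_max: float
    J_min: float
    d: float
    seed: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {"g_max": self.g_max, "F_max": self.F_max, "J_min": self.J_min, "d": self.d}

    def vector(self, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, s) for s in subset], dtype=float)


# ---------------------------------------------------------------------------
# geometry: disc / annulus intersection with the window
# ---------------------------------------------------------------------------

def _quadrant_area(a: np.ndarray, b: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """Area of [0,a] x [0,b] intersected with the disc of given radius at the origin.

    Closed form, vectorised; a, b >= 0.
    """
    r = np.broadcast_to(np.asarray(radius, dtype=float), np.broadcast_shapes(
        np.shape(a), np.shape(b), np.shape(radius)))
    a = np.minimum(np.broadcast_to(np.asarray(a, dtype=float), r.shape), r)
    b = np.minimum(np.broadcast_to(np.asarray(b, dtype=float), r.shape), r)
    r2 = r * r
    corner_inside = a * a + b * b <= r2

    with np.errstate(invalid="ignore", divide="ignore"):
        # x0: abscissa where the arc crosses height b
        x0 = np.sqrt(np.maximum(r2 - b * b, 0.0))
        xa = np.minimum(a, r)

        def _int(x):
            # integral of sqrt(r^2 - t^2) dt from 0 to x
            x = np.minimum(x, r)
            s = np.sqrt(np.maximum(r2 - x * x, 0.0))
            ang = np.arcsin(np.clip(np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0), -1, 1))
            return 0.5 * (x * s + r2 * ang)

        arc_area = x0 * b + _int(xa) - _int(x0)

    area = np.where(corner_inside, a * b, np.where(a <= x0, a * b, arc_area))
    return np.where(r > 0, area, 0.0)


def disc_window_area(xy: np.ndarray, radius: np.ndarray, window: Window) -> np.ndarray:
    """Area of the disc of ``radius`` centred at each point, clipped to the window.

    ``xy`` has shape (n, 2); ``radius`` broadcasts against n (e.g. shape
    (1, m) for a radius grid), returning shape (n, m).
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    x = xy[:, :1]
    y = xy[:, 1:2]
    r = np.atleast_1d(np.asarray(radius, dtype=float))
    if r.ndim == 1:
        r = r[np.newaxis, :]
    total = np.zeros(np.broadcast_shapes(x.shape, r.shape), dtype=float)
    for dx in (x, window.width - x):
        for dy in (y, window.height - y):
            total = total + _quadrant_area(dx, dy, r)
    return total


# ---------------------------------------------------------------------------
# the four statistics
# ---------------------------------------------------------------------------

def pair_correlation(pattern: PointPattern, grid: RadiusGrid | None = None) -> StatCurve:
    """Pair correlation function g(r) with analytic annulus edge correction.

    For each point, the observed count of other points in the annulus
    (r - dr/2, r + dr/2] is divided by the expected CSR count, which is
    the global intensity n/area times the annulus-window intersection
    area; g(r) is the average of these ratios over points.
    """
    if pattern.n < 2:
        raise InsufficientPointsError("pair correlation requires at least 2 points")
    grid = grid or RadiusGrid.for_window(pattern.window)
    xy = pattern.xy
    n = pattern.n
    lam = n / pattern.window.area
    edges = grid.bin_edges
    m = len(grid.r_values)

    # condensed pairwise distances; bin with (lower, upper] convention
    dist = sdist.pdist(xy)
    iu, ju = np.triu_indices(n, 1)
    sel = (dist > edges[0]) & (dist <= edges[-1])
    # searchsorted(left): edges[k-1] < d <= edges[k]  ->  bin k-1
    idx = np.searchsorted(edges, dist[sel], side="left") - 1
    # per-point histogram of neighbour distances (each pair counts for both ends)
    counts = (np.bincount(iu[sel] * m + idx, minlength=n * m)
              + np.bincount(ju[sel] * m + idx, minlength=n * m)).reshape(n, m)

    disc_areas = disc_window_area(xy, edges[np.newaxis, :], pattern.window)
    annulus = disc_areas[:, 1:] - disc_areas[:, :-1]
    expected = lam * annulus
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, counts / expected, np.nan)
    values = np.nanmean(ratio, axis=0)
    return StatCurve(CurveKind.PCF, grid, values)


def _nn_distances(xy: np.ndarray) -> np.ndarray:
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    return d[:, 1]


def _ecdf_on_grid(observations: np.ndarray, grid: RadiusGrid) -> np.ndarray:
    obs = np.sort(np.asarray(observations, dtype=float))
    return np.searchsorted(obs, grid.r_values, side="right") / len(obs)


def nn_distribution(pattern: PointPattern, grid: RadiusGrid | None = None) -> StatCurve:
    """Nearest-neighbour distance CDF G(r), sampled on the grid."""
    if pattern.n < 2:
        raise InsufficientPointsError("nearest-neighbour distribution requires >= 2 points")
    grid = grid or RadiusGrid.for_window(pattern.window)
    nnd = _nn_distances(pattern.xy)
    return StatCurve(CurveKind.NN_CDF, grid, _ecdf_on_grid(nnd, grid), observations=nnd)


def spherical_contact(
    pattern: PointPattern,
    grid: RadiusGrid | None = None,
    n_reference: int | None = None,
    seed: int | np.random.Generator | None = None,
    reference_points: np.ndarray | None = None,
) -> StatCurve:
    """Spherical contact / empty-space CDF F(r).

    Distances from uniformly random reference locations in the window to
    the nearest pattern point.  By default the number of reference points
    equals the number of pattern points, so that F and G have equal
    denominators.  ``reference_points`` overrides random sampling (used
    for deterministic oracles).
    """
    if pattern.n < 1:
        raise InsufficientPointsError("spherical contact distribution requires >= 1 point")
    grid = grid or RadiusGrid.for_window(pattern.window)
    if reference_points is None:
        n_ref = n_reference if n_reference is not None else pattern.n
        if n_ref < 1:
            raise ValueError("n_reference must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        reference_points = rng.uniform(
            [0.0, 0.0], [pattern.window.width, pattern.window.height], size=(n_ref, 2)
        )
    else:
        reference_points = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    tree = cKDTree(pattern.xy)
    d, _ = tree.query(reference_points, k=1)
    d = np.atleast_1d(d)
    return StatCurve(CurveKind.SCD_CDF, grid, _ecdf_on_grid(d, grid), observations=d)


def j_function(G: StatCurve, F: StatCurve) -> StatCurve:
    """J(r) = (1 - G(r)) / (1 - F(r)); NaN where F(r) = 1 (beyond F_max).

    J < 1 indicates clustering, J > 1 dispersal, J = 1 CSR.
    """
    if G.kind is not CurveKind.NN_CDF or F.kind is not CurveKind.SCD_CDF:
        raise ValueError("j_function expects (NN_CDF, SCD_CDF) curves")
    if G.grid != F.grid:
        raise ValueError("G and F are on different radius grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(F.values < 1.0, (1.0 - G.values) / (1.0 - F.values), np.nan)
    return StatCurve(CurveKind.J, G.grid, values)


def summary_features(
    pattern: PointPattern,
    grid: RadiusGrid | None = None,
    seed: int | np.random.Generator | None = None,
    min_tail_count: int = 10,
) -> SummaryFeatures:
    """Compute (g_max, F_max, J_min, d) for one pattern.

    ``F_max`` is the largest observed empty-space distance (the smallest
    r with F(r) = 1); it depends on the random reference points, so the
    seed should be recorded alongside the features.  ``J_min`` is the
    minimum of J, clamped to [0, 1].  The minimum is searched over radii
    where the tail estimate 1 - F(r) rests on at least
    ``min_tail_count`` reference points: closer to F_max the ECDF ratio
    degenerates into a race between two extreme order statistics (with
    an atom at exactly 0 whenever the largest nearest-neighbour distance
    falls short of the largest void radius), which carries no
    information about clustering depth.  For patterns with fewer points
    than ``min_tail_count`` the full domain of definition is used.
    """
    grid = grid or RadiusGrid.for_window(pattern.window)
    g = pair_correlation(pattern, grid)
    G = nn_distribution(pattern, grid)
    F = spherical_contact(pattern, grid, seed=seed)
    J = j_function(G, F)
    g_max = float(np.nanmax(g.values))
    F_max = float(np.max(F.observations))
    tail_cut = 1.0 - min_tail_count / len(F.observations)
    defined = np.isfinite(J.values) & (F.values <= tail_cut)
    if not defined.any():
        defined = np.isfinite(J.values)
    J_min = float(np.min(J.values[defined])) if defined.any() else 1.0
    J_min = float(np.clip(J_min, 0.0, 1.0))
    seed_rec = seed if isinstance(seed, (int, np.integer)) else None
    return SummaryFeatures(g_max=g_max, F_max=F_max, J_min=J_min,
                           d=pattern.density, seed=seed_rec)


def curves_to_csv(curves: Sequence[StatCurve], path: str | Path) -> None:
    """Export curves as tidy CSV (columns kind, r, value)."""
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)
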