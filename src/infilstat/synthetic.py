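"""Synthetic two-compartment tumour point patterns.

A zero-mean Gaussian random field (GRF) with isotropic Gaussian
correlation of length scale ``l`` is thresholded at 0 to split the
window into tumour-nest and stroma compartments (accepted only when each
compartment covers at least 25% of the window).  Cells are then placed by rejection
sampling: candidates are uniform over the window, accepted only if their
compartment's quota is unfilled and they are at least one cell diameter
(0.02 mm hard core) from every accepted point.

The infiltration ratio rho = d_t / d_s (tumour-nest density over stromal
density) controls the per-compartment quotas; rho = 0 excludes cells
from nests entirely, rho = 1 yields a uniform hard-core pattern.  The
overall density d is drawn from Normal(333, 170) cells/mm^2 truncated
below at 150, matching the CD68+ macrophage densities observed in the
head-and-neck cohort the generator emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .patterns import PointPattern, Window, write_manifest, write_pattern

__all__ = [
    "TissueGeometry",
    "GenerationParams",
    "CompartmentQuota",
    "generate_geometry",
    "compartment_quotas",
    "place_points",
    "sample_density",
    "generate_pattern",
    "generate_training_set",
    "generate_validation_set",
    "simulate_patterns",
    "GenerationError",
    "DENSITY_MEAN",
    "DENSITY_SD",
    "DENSITY_MIN",
    "EXCLUSION_RADIUS",
    "L_RANGE",
    "RHO_GRID",
]

# Cohort-level defaults: CD68+ density distribution, hard-core diameter,
# nest length-scale range and the training grid of infiltration ratios.
DENSITY_MEAN = 333.0
DENSITY_SD = 170.0
DENSITY_MIN = 150.0
EXCLUSION_RADIUS = 0.02
L_RANGE = (0.1, 0.75)
RHO_GRID = np.round(np.arange(0.0, 0.5 + 1e-9, 0.02), 10)
MIN_AREA_FRACTION = 0.25


class GenerationError(RuntimeError):
    """Raised when geometry generation or point packing fails."""


@dataclass
class TissueGeometry:
    """Binary tumour/stroma mask on a square pixel grid over the window."""

    mask: np.ndarray  # bool, True = tumour nest
    l: float
    window: Window

    @property
    def resolution(self) -> int:
        return self.mask.shape[0]

    @property
    def area_fraction_tumour(self) -> float:
        return float(self.mask.mean())

    @property
    def area_fraction_stroma(self) -> float:
        return 1.0 - self.area_fraction_tumour

    def compartment_of(self, xy: np.ndarray) -> np.ndarray:
        """1 for tumour nest, 0 for stroma, for each (x, y) row in mm."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        res = self.resolution
        ix = np.clip((xy[:, 0] / self.window.width * res).astype(np.int64), 0, res - 1)
        iy = np.clip((xy[:, 1] / self.window.height * res).astype(np.int64), 0, res - 1)
        return self.mask[ix, iy].astype(np.int64)

    def mean_component_area(self) -> float:
        """Mean area (mm^2) of connected tumour-nest components."""
        labels, ncomp = ndimage.label(self.mask)
        if ncomp == 0:
            return 0.0
        pixel_area = self.window.area / self.mask.size
        sizes = np.bincount(labels.ravel())[1:]
        return float(sizes.mean() * pixel_area)


@dataclass
class GenerationParams:
    """Parameters of one synthetic pattern."""

    rho: float
    d: float
    l: float
    exclusion_radius: float = EXCLUSION_RADIUS
    window: Window = field(default_factory=Window)
    mask_resolution: int = 256
    max_rejections: int = 10_000

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.d <= 0:
            raise ValueError("density must be positive")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion radius must be >= 0")


@dataclass(frozen=True)
class CompartmentQuota:
    n_tumour: int
    n_stroma: int

    @property
    def total(self) -> int:
        return self.n_tumour + self.n_stroma


def _gaussian_random_field(rng: np.random.Generator, resolution: int,
                           l: float, extent: float) -> np.ndarray:
    """Stationary zero-mean GRF via FFT spectral synthesis.

    Gaussian correlation exp(-r^2 / (2 s^2)) with s = l / pi, so that by
    Rice's zero-crossing formula the mean chord length of the thresholded
    (level-0) excursion set equals l: the nest length scale l is then the
    mean tumour-nest width, matching its definition.
    """
    s = l / np.pi
    d = extent / resolution
    kx = 2.0 * np.pi * np.fft.fftfreq(resolution, d=d)[:, np.newaxis]
    ky = 2.0 * np.pi * np.fft.rfftfreq(resolution, d=d)[np.newaxis, :]
    # power spectrum of the Gaussian covariance ~ exp(-k^2 s^2 / 2)
    amplitude = np.exp(-(kx ** 2 + ky ** 2) * s ** 2 / 4.0)
    white = rng.standard_normal((resolution, resolution))
    fld = np.fft.irfft2(np.fft.rfft2(white) * amplitude, s=(resolution, resolution))
    return fld


def generate_geometry(l: float, window: Window | None = None, resolution: int = 256,
                      seed: int | np.random.Generator | None = None,
                      max_attempts: int = 100) -> TissueGeometry:
    """Sample a tissue geometry: zero-mean GRF thresholded at level 0.

    The tumour area fraction therefore varies from draw to draw
    (substantially so for large l); the geometry is regenerated until
    both compartments cover at least 25% of the window.
    """
    window = window or Window()
    if not (0 < l < min(window.width, window.height)):
        raise ValueError("nest length scale l must lie in (0, min window dimension)")
    if resolution < 64:
        raise ValueError("mask resolution must be >= 64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        fld = _gaussian_random_field(rng, resolution, l, window.width)
        mask = fld > 0.0
        frac = mask.mean()
        if MIN_AREA_FRACTION <= frac <= 1 - MIN_AREA_FRACTION:
            return TissueGeometry(mask=mask, l=l, window=window)
    raise GenerationError(
        f"no geometry with both area fractions >= {MIN_AREA_FRACTION} "
        f"after {max_attempts} attempts (l={l})"
    )


def compartment_quotas(params: GenerationParams, geometry: TissueGeometry) -> CompartmentQuota:
    """Split the total cell count N = round(d * A) so that densities satisfy
    (n_t / A_t) / (n_s / A_s) = rho up to integer rounding."""
    total = int(round(params.d * params.window.area))
    a_t = geometry.area_fraction_tumour
    a_s = geometry.area_fraction_stroma
    n_t = int(round(total * params.rho * a_t / (params.rho * a_t + a_s)))
    return CompartmentQuota(n_tumour=n_t, n_stroma=total - n_t)


@njit(cache=False)
def _greedy_fill(cand_xy, cand_comp, quota_t, quota_s, excl, width, height,
                 accepted_xy, accepted_comp, n_accepted, cell_count, cell_idx,
                 max_rejections):
    """Sequential acceptance of candidates under quota + hard-core rules.

    Spatial hash with cell size >= excl: any point within excl of a
    candidate lies in the 3x3 cell neighbourhood.  Returns
    (n_accepted, consumed, consecutive_rejections, status); status 0 =
    quotas filled, 1 = candidate batch exhausted, 2 = rejection limit hit.
    """
    ncx = cell_count.shape[0]
    ncy = cell_count.shape[1]
    cell_w = width / ncx
    cell_h = height / ncy
    excl2 = excl * excl
    n_t = 0
    n_s = 0
    for i in range(n_accepted):
        if accepted_comp[i] == 1:
            n_t += 1
        else:
            n_s += 1
    consec = 0
    consumed = 0
    for c in range(cand_xy.shape[0]):
        if n_t >= quota_t and n_s >= quota_s:
            return n_accepted, consumed, consec, 0
        consumed += 1
        x = cand_xy[c, 0]
        y = cand_xy[c, 1]
        comp = cand_comp[c]
        if comp == 1:
            if n_t >= quota_t:
                consec += 1
                if consec > max_rejections:
                    return n_accepted, consumed, consec, 2
                continue
        else:
            if n_s >= quota_s:
                consec += 1
                if consec > max_rejections:
                    return n_accepted, consumed, consec, 2
                continue
        ok = True
        if excl > 0.0:
            ix = int(x / cell_w)
            iy = int(y / cell_h)
            if ix >= ncx:
                ix = ncx - 1
            if iy >= ncy:
                iy = ncy - 1
            x0 = ix - 1 if ix > 0 else 0
            x1 = ix + 1 if ix < ncx - 1 else ncx - 1
            y0 = iy - 1 if iy > 0 else 0
            y1 = iy + 1 if iy < ncy - 1 else ncy - 1
            for gx in range(x0, x1 + 1):
                for gy in range(y0, y1 + 1):
                    for s in range(cell_count[gx, gy]):
                        j = cell_idx[gx, gy, s]
                        dx = accepted_xy[j, 0] - x
                        dy = accepted_xy[j, 1] - y
                        if dx * dx + dy * dy < excl2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
        if not ok:
            consec += 1
            if consec > max_rejections:
                return n_accepted, consumed, consec, 2
            continue
        # accept
        accepted_xy[n_accepted, 0] = x
        accepted_xy[n_accepted, 1] = y
        accepted_comp[n_accepted] = comp
        if excl > 0.0:
            ix = int(x / cell_w)
            iy = int(y / cell_h)
            if ix >= ncx:
                ix = ncx - 1
            if iy >= ncy:
                iy = ncy - 1
            cell_idx[ix, iy, cell_count[ix, iy]] = n_accepted
            cell_count[ix, iy] += 1
        n_accepted += 1
        if comp == 1:
            n_t += 1
        else:
            n_s += 1
        consec = 0
    if n_t >= quota_t and n_s >= quota_s:
        return n_accepted, consumed, consec, 0
    return n_accepted, consumed, consec, 1


def place_points(params: GenerationParams, geometry: TissueGeometry,
                 quota: CompartmentQuota,
                 seed: int | np.random.Generator | None = None) -> PointPattern:
    """Fill the compartment quotas by uniform rejection sampling with a hard core."""
    window = params.window
    total = quota.total
    excl = params.exclusion_radius
    # centres at pairwise distance >= excl are discs of radius excl/2; random
    # sequential packing stalls near coverage ~0.55, so cap the fraction at 0.45
    # -- per compartment, since low rho crowds all points into the stroma
    disc = math.pi * (excl / 2) ** 2
    for n_c, frac in ((quota.n_tumour, geometry.area_fraction_tumour),
                      (quota.n_stroma, geometry.area_fraction_stroma)):
        if n_c and n_c * disc >= 0.45 * frac * window.area:
            raise GenerationError(
                f"hard-core packing infeasible: {n_c} points with exclusion "
                f"{excl} mm in a compartment of {frac * window.area:.3f} mm^2"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cell = max(excl, 1e-6)
    ncx = max(1, int(window.width / cell))
    ncy = max(1, int(window.height / cell))
    # a 0.02 mm cell holds at most 4 points pairwise >= 0.02 apart; 8 is safe
    cell_count = np.zeros((ncx, ncy), dtype=np.int64)
    cell_idx = np.zeros((ncx, ncy, 8), dtype=np.int64)
    accepted_xy = np.empty((total, 2), dtype=np.float64)
    accepted_comp = np.empty(total, dtype=np.int64)
    n_accepted = 0
    consec_budget = params.max_rejections

    if total == 0:
        return PointPattern(np.empty((0, 2)), window)

    # backstop against slow grinding towards jamming: cap total proposals
    total_budget = 200 * total + 10_000
    while True:
        batch = max(4 * total, 1024)
        cand = rng.uniform([0.0, 0.0], [window.width, window.height], size=(batch, 2))
        comp = geometry.compartment_of(cand)
        n_accepted, consumed, consec, status = _greedy_fill(
            cand, comp, quota.n_tumour, quota.n_stroma, excl,
            window.width, window.height, accepted_xy, accepted_comp,
            n_accepted, cell_count, cell_idx, consec_budget,
        )
        total_budget -= consumed
        if status == 0:
            return PointPattern(accepted_xy[:n_accepted].copy(), window)
        if status == 1 and total_budget <= 0:
            raise GenerationError(
                f"packing stalled: proposal budget exhausted with "
                f"{n_accepted}/{total} points placed (rho={params.rho}, "
                f"d={params.d}, l={params.l})"
            )
        if status == 2:
            raise GenerationError(
                f"packing failed after {params.max_rejections} consecutive "
                f"rejections with {n_accepted}/{total} points placed "
                f"(rho={params.rho}, d={params.d}, l={params.l})"
            )
        consec_budget = params.max_rejections - consec  # carry over across batches
        if consec_budget <= 0:
            raise GenerationError(
                f"packing failed after {params.max_rejections} consecutive "
                f"rejections with {n_accepted}/{total} points placed"
            )


def sample_density(rng: int | np.random.Generator | None = None,
                   mean: float = DENSITY_MEAN, sd: float = DENSITY_SD,
                   minimum: float = DENSITY_MIN) -> float:
    """Draw an overall cell density from Normal(mean, sd) truncated at ``minimum``."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    while True:
        d = rng.normal(mean, sd)
        if d >= minimum:
            return float(d)


def generate_pattern(params: GenerationParams,
                     seed: int | np.random.SeedSequence | None = None
                     ) -> tuple[PointPattern, TissueGeometry]:
    """Generate one pattern: geometry, quotas, hard-core placement."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    geom_ss, place_ss = ss.spawn(2)
    geometry = generate_geometry(params.l, params.window, params.mask_resolution,
                                 np.random.default_rng(geom_ss))
    quota = compartment_quotas(params, geometry)
    pattern = place_points(params, geometry, quota, np.random.default_rng(place_ss))
    return pattern, geometry


def simulate_patterns(rhos: Sequence[float],
                      seed: int | np.random.SeedSequence | None = None,
                      l_range: tuple[float, float] = L_RANGE,
                      window: Window | None = None,
                      density_mean: float = DENSITY_MEAN,
                      density_sd: float = DENSITY_SD,
                      density_min: float = DENSITY_MIN,
                      mask_resolution: int = 256,
                      max_retries: int = 20,
                      ) -> Iterator[tuple[dict, PointPattern]]:
    """Yield (metadata, pattern) for each requested rho.

    For every entry of ``rhos``: d ~ truncated Normal, l ~ U(l_range), one
    geometry + placement, all reproducible from the master seed.  A failed
    generation is logged in the metadata of the retry and resampled with a
    fresh sub-seed, up to ``max_retries`` times.
    """
    window = window or Window()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(rhos))
    for i, (rho, child) in enumerate(zip(rhos, children)):
        tries = child.spawn(max_retries)
        last_err: Exception | None = None
        for t, tss in enumerate(tries):
            rng = np.random.default_rng(tss)
            d = sample_density(rng, density_mean, density_sd, density_min)
            l = float(rng.uniform(*l_range))
            params = GenerationParams(rho=float(rho), d=d, l=l, window=window,
                                      mask_resolution=mask_resolution)
            try:
                pattern, _ = generate_pattern(params, tss.spawn(1)[0])
            except GenerationError as exc:  # pragma: no cover - rare
                last_err = exc
                continue
            meta = {"index": i, "rho": float(rho), "d": d, "l": l,
                    "n": pattern.n, "seed": int(tss.generate_state(1)[0] % (2 ** 31)),
                    "retries": t}
            yield meta, pattern
            break
        else:  # pragma: no cover - rare
            raise GenerationError(f"pattern {i} (rho={rho}) failed after "
                                  f"{max_retries} retries: {last_err}")


def _write_set(rhos: np.ndarray, out_dir: str | Path, seed, prefix: str,
               l_range: tuple[float, float], window: Window | None,
               mask_resolution: int) -> pd.DataFrame:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, pattern in simulate_patterns(rhos, seed, l_range, window,
                                           mask_resolution=mask_resolution):
        pid = f"{prefix}_{meta['index']:06d}"
        fname = f"{pid}.csv"
        write_pattern(pattern, out_dir / fname)
        rows.append({"pattern_id": pid, "file": fname, "rho": meta["rho"],
                     "l": meta["l"], "d": meta["d"], "seed": meta["seed"]})
    return write_manifest(rows, out_dir / f"{prefix}_manifest.csv")


def generate_training_set(rho_grid: Sequence[float] | None = None,
                          reps_per_rho: int = 1200,
                          l_range: tuple[float, float] = L_RANGE,
                          out_dir: str | Path = "training",
                          seed: int | None = None,
                          window: Window | None = None,
                          mask_resolution: int = 256) -> pd.DataFrame:
    """Training ensemble: every rho on the grid repeated ``reps_per_rho`` times."""
    grid = np.asarray(RHO_GRID if rho_grid is None else rho_grid, dtype=float)
    if grid.size == 0 or reps_per_rho < 1:
        raise ValueError("need a non-empty rho grid and reps_per_rho >= 1")
    rhos = np.repeat(grid, reps_per_rho)
    return _write_set(rhos, out_dir, seed, "train", l_range, window, mask_resolution)


def generate_validation_set(n_patterns: int = 3680,
                            rho_range: tuple[float, float] = (0.0, 0.5),
                            l_range: tuple[float, float] = L_RANGE,
                            out_dir: str | Path = "validation",
                            seed: int | None = None,
                            window: Window | None = None,
                            mask_resolution: int = 256) -> pd.DataFrame:
    """Validation ensemble: rho ~ U(rho_range), independent of the training grid."""
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    ss = np.random.SeedSequence(seed)
    rho_ss, gen_ss = ss.spawn(2)
    rhos = np.random.default_rng(rho_ss).uniform(*rho_range, size=n_patterns)
    return _write_set(rhos, out_dir, gen_ss, "val", l_range, window, mask_resolution)
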