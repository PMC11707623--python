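"""Kernel utilization distributions with MCP-area-matched bandwidths.

A utilization distribution (UD) is a probability-density surface over
space.  Bandwidth selection follows the home-range-matching rule: starting
from a small bandwidth, increase in fixed increments until the area of the
95% volume contour of the resulting UD first reaches the area of the 95%
minimum convex polygon of the same points.  Exact equality is unattainable
on a discrete raster, so "equals" is operationalized as the first crossing
on the bandwidth step grid — deterministic, and consistent with the
monotone growth of contour area in bandwidth.

Individual-level UDs are fit per animal-season.  The population-level UD
averages over repeated random draws of one season per animal (so
multi-season animals do not dominate), each draw re-tuned to the pooled
MCP area on one fixed shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .config import RunConfig, stage_rng
from .data import TelemetryDataset
from .grid import GridError, GridSpec
from .homerange import mcp

#: Kernel support truncation, in bandwidths. Mass outside < 1e-6.
TRUNC_SIGMA = 5.0


class UDError(ValueError):
    pass


@dataclass
class UDRaster:
    """Gridded probability density (per m^2), integrating to 1 over the grid."""

    grid: GridSpec
    density: np.ndarray           # (nrows, ncols)
    bandwidth: float
    level: str = "individual"     # "individual" | "population"
    ids: tuple = ()

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, float)
        if self.density.shape != self.grid.shape:
            raise UDError("density shape does not match grid")
        if self.bandwidth <= 0:
            raise UDError("bandwidth must be > 0")

    def total_mass(self) -> float:
        return float(np.nansum(self.density) * self.grid.cell_area)

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.total_mass() - 1.0) <= tol


@dataclass
class CellSet:
    """Cells of a volume contour: the minimal high-density region holding
    at least ``isopleth`` of the UD's probability volume."""

    grid: GridSpec
    members: np.ndarray           # flat row-major cell indices, density-ordered
    isopleth: float

    @property
    def area(self) -> float:
        return float(len(self.members) * self.grid.cell_area)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.nrows * self.grid.ncols, dtype=bool)
        m[self.members] = True
        return m.reshape(self.grid.shape)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        row, col = self.grid.point_to_cell(pts[:, 0], pts[:, 1])
        return self.mask()[row, col]


def kde_ud(points: np.ndarray, bandwidth: float, grid: GridSpec,
           level: str = "individual", ids: tuple = ()) -> UDRaster:
    """Bivariate Gaussian KDE evaluated at cell centers, renormalized.

    density(c) = (1/n) sum_i N2(center(c) - p_i; sigma = bandwidth * I),
    with the kernel truncated at 5 bandwidths (mass error < 1e-6), then
    renormalized so that sum(density) * cell_area = 1.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 1:
        raise UDError("need at least one point")
    if bandwidth <= 0:
        raise UDError("bandwidth must be > 0")
    if not grid.covers(pts, margin=3.0 * bandwidth):
        raise GridError(
            f"grid does not cover points with margin >= 3*bandwidth "
            f"({3.0 * bandwidth:.1f} m)")
    xc = grid.x_centers()
    yc = grid.y_centers()
    dens = np.zeros(grid.shape, float)
    half = TRUNC_SIGMA * bandwidth
    inv2h2 = 0.5 / bandwidth**2
    for px, py in pts:
        j0 = max(0, int(np.floor((px - half - grid.x0) / grid.cellsize)))
        j1 = min(grid.ncols, int(np.ceil((px + half - grid.x0) / grid.cellsize)) + 1)
        i0 = max(0, int(np.floor((py - half - grid.y0) / grid.cellsize)))
        i1 = min(grid.nrows, int(np.ceil((py + half - grid.y0) / grid.cellsize)) + 1)
        wx = np.exp(-inv2h2 * (xc[j0:j1] - px) ** 2)
        wy = np.exp(-inv2h2 * (yc[i0:i1] - py) ** 2)
        dens[i0:i1, j0:j1] += np.outer(wy, wx)
    dens /= 2.0 * np.pi * bandwidth**2 * len(pts)
    total = dens.sum() * grid.cell_area
    if total <= 0:
        raise UDError("degenerate density (no mass on grid)")
    dens /= total
    return UDRaster(grid=grid, density=dens, bandwidth=float(bandwidth),
                    level=level, ids=tuple(ids))


def volume_contour(ud: UDRaster, isopleth: float) -> CellSet:
    """Minimal-prefix volume contour.

    Cells are sorted by density descending, ties broken by row-major index;
    the shortest prefix whose cumulative probability volume reaches the
    isopleth is the contour.
    """
    if not (0.0 < isopleth < 1.0):
        raise UDError(f"isopleth {isopleth} outside (0, 1)")
    if not ud.is_normalized(tol=1e-6):
        raise UDError("UD is not normalized")
    flat = ud.density.ravel(order="C")
    order = np.argsort(-flat, kind="stable")   # stable => row-major tie-break
    cum = np.cumsum(flat[order]) * ud.grid.cell_area
    total = cum[-1]
    # first index where cumulative volume reaches isopleth (relative fp guard)
    k = int(np.argmax(cum >= isopleth * total * (1.0 - 1e-12)))
    return CellSet(grid=ud.grid, members=order[:k + 1], isopleth=isopleth)


def contour_area(points: np.ndarray, h: float, grid: GridSpec,
                 isopleth: float) -> float:
    return volume_contour(kde_ud(points, h, grid), isopleth).area


@dataclass
class TuningTrace:
    """Record of (bandwidth, contour area) pairs evaluated during tuning."""
    target_area: float
    evaluated: list = field(default_factory=list)   # (h, area)


def tune_bandwidth(points: np.ndarray, target_area: float, grid: GridSpec,
                   h0: float, step: float, h_max: float = 500.0,
                   outer_isopleth: float = 0.95,
                   warm_start: float | None = None,
                   ) -> tuple[float, UDRaster, TuningTrace]:
    """First bandwidth on the grid {h0, h0+step, ...} whose 95% volume
    contour reaches ``target_area``.

    ``warm_start`` (a bandwidth from a previous similar tuning) only moves
    the scan's entry point; the returned bandwidth is the same first
    crossing a plain upward scan would find, because the scan walks down
    whenever the entry point already crosses the target.
    """
    if target_area <= 0 or h0 <= 0 or step <= 0:
        raise UDError("target_area, h0 and step must be > 0")
    trace = TuningTrace(target_area=float(target_area))
    cache: dict[int, float] = {}

    def area_at(k: int) -> float:
        if k not in cache:
            h = h0 + k * step
            cache[k] = contour_area(points, h, grid, outer_isopleth)
            trace.evaluated.append((h, cache[k]))
        return cache[k]

    k_max = int(np.floor((h_max - h0) / step))
    k = 0
    if warm_start is not None and warm_start > h0:
        k = min(int(round((warm_start - h0) / step)), k_max)
    if area_at(k) >= target_area:
        while k > 0 and area_at(k - 1) >= target_area:
            k -= 1
    else:
        while k < k_max and area_at(k) < target_area:
            k += 1
        if area_at(k) < target_area:
            raise UDError(
                f"no bandwidth <= {h_max} m reaches target area "
                f"{target_area:.1f} m^2; trace: {trace.evaluated[-3:]}")
    h = h0 + k * step
    ud = kde_ud(points, h, grid)
    return h, ud, trace


def _bandwidth_cap(target_area: float) -> float:
    """Upper bound on the bandwidth any tuning can need.

    A single Gaussian blob has the largest 95% contour at a given
    bandwidth deficit: its contour area is pi * chi2_{0.95,2} * h^2, so the
    crossing bandwidth never exceeds sqrt(target / (pi * 5.99)); a 1.5x
    safety factor absorbs discretization.
    """
    return 1.5 * float(np.sqrt(target_area / (np.pi * chi2.ppf(0.95, 2))))


def _grid_for(points: np.ndarray, target_area: float, cfg: RunConfig) -> GridSpec:
    margin = max(cfg.grid_margin, 3.0 * _bandwidth_cap(target_area))
    return GridSpec.from_points(points, cfg.grid_cell, margin)


def individual_uds(data: TelemetryDataset, cfg: RunConfig,
                   ) -> dict[tuple[str, str], UDRaster]:
    """One area-matched UD per animal-season, on a per-season grid."""
    out: dict[tuple[str, str], UDRaster] = {}
    for key in data.season_keys():
        pts = data.season_points(*key)
        target = mcp(pts, cfg.mcp_percent).area
        grid = _grid_for(pts, target, cfg)
        h, ud, _ = tune_bandwidth(
            pts, target, grid, h0=cfg.bandwidth_step, step=cfg.bandwidth_step,
            h_max=3.0 * _bandwidth_cap(target) + cfg.bandwidth_step,
            outer_isopleth=cfg.outer_isopleth)
        ud.level = "individual"
        ud.ids = key
        out[key] = ud
    return out


def population_ud(data: TelemetryDataset, cfg: RunConfig,
                  rng: np.random.Generator | None = None,
                  n_iterations: int | None = None) -> UDRaster:
    """Season-resampled population UD on one fixed grid.

    Each iteration draws one season per animal uniformly, pools the points,
    recomputes the pooled 95% MCP, re-tunes the bandwidth to its area, and
    evaluates the UD on the shared grid; the cellwise mean over iterations
    is renormalized.  Tuning warm-starts at the previous iteration's
    bandwidth (entry point only; the first-crossing rule is unchanged).
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "population_ud")
    n_iter = int(n_iterations if n_iterations is not None
                 else cfg.pop_ud_iterations)
    by_animal: dict[str, list[str]] = {}
    for a, s in data.season_keys():
        by_animal.setdefault(a, []).append(s)
    if len(by_animal) < 2:
        raise UDError("population UD needs >= 2 animals")
    for a, seasons in by_animal.items():
        if not seasons:
            raise UDError(f"animal {a} has no retained seasons")
    all_pts = data.points()
    target_cap = mcp(all_pts, cfg.mcp_percent).area
    grid = _grid_for(all_pts, target_cap, cfg)
    h_cap = _bandwidth_cap(target_cap)
    acc = np.zeros(grid.shape, float)
    warm = None
    mean_h = 0.0
    for _ in range(n_iter):
        pooled = np.vstack([
            data.season_points(a, seasons[rng.integers(len(seasons))])
            for a, seasons in by_animal.items()])
        target = mcp(pooled, cfg.mcp_percent).area
        h, ud, _ = tune_bandwidth(
            pooled, target, grid, h0=cfg.bandwidth_step,
            step=cfg.bandwidth_step, h_max=3.0 * h_cap + cfg.bandwidth_step,
            outer_isopleth=cfg.outer_isopleth, warm_start=warm)
        warm = h
        mean_h += h / n_iter
        acc += ud.density
    acc /= n_iter
    acc /= acc.sum() * grid.cell_area
    return UDRaster(grid=grid, density=acc, bandwidth=mean_h,
                    level="population", ids=tuple(sorted(by_animal)))
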