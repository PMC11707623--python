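"""Percent minimum convex polygon home ranges.

The percent MCP peels outlying relocations before taking the convex hull:
retain the floor(percent * n) points nearest the arithmetic centroid of
all points (Euclidean distance, ties at the retention boundary broken by
observation id for determinism), then hull the survivors.  With
percent = 1 the MCP is the plain convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .data import TelemetryDataset


class HomeRangeError(ValueError):
    pass


class DegenerateGeometryError(HomeRangeError):
    pass


@dataclass
class MCPolygon:
    percent: float
    vertices: np.ndarray          # (k, 2) closed ring (first == last)
    retained: np.ndarray          # indices/ids of retained points
    area: float                   # m^2
    animal_id: str | None = None
    season_id: str | None = None

    @property
    def area_ha(self) -> float:
        return self.area / 1e4

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def mcp(points: np.ndarray, percent: float,
        ids: np.ndarray | None = None) -> MCPolygon:
    """Percent minimum convex polygon of a point set.

    ``ids`` (default: 0..n-1) break distance ties at the retention
    boundary and identify the retained points in the result.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    n = len(pts)
    if n < 5:
        raise HomeRangeError(f"MCP needs >= 5 points, got {n}")
    if not (0.0 < percent <= 1.0):
        raise HomeRangeError(f"percent {percent} outside (0, 1]")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    centroid = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    order = np.lexsort((ids, d))           # distance, then id (stable peel)
    n_keep = n if percent == 1.0 else int(np.floor(percent * n))
    keep = order[:n_keep]
    hull = MultiPoint(pts[keep]).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise DegenerateGeometryError(
            "retained points are collinear or coincident; no polygonal hull")
    ring = np.asarray(hull.exterior.coords)
    return MCPolygon(percent=percent, vertices=ring, retained=ids[keep],
                     area=float(hull.area))


def filter_seasons(data: TelemetryDataset, min_obs: int,
                   complete_flags: dict | None = None,
                   ) -> tuple[TelemetryDataset, pd.DataFrame]:
    """Drop animal-seasons with fewer than ``min_obs`` relocations or
    flagged incomplete (e.g., ended by mortality or transmitter loss).

    ``complete_flags`` maps (animal_id, season_id) -> bool; missing keys
    default to complete.  Returns the retained dataset and a removal
    report (animal_id, season_id, n_obs, reason).
    """
    complete_flags = complete_flags or {}
    removals = []
    keep_mask = np.ones(len(data.obs), dtype=bool)
    grouped = data.obs.groupby(["animal_id", "season_id"], sort=False)
    for key, idx in grouped.groups.items():
        n = len(idx)
        reasons = []
        if n < min_obs:
            reasons.append(f"n={n} < {min_obs}")
        if not complete_flags.get(key, True):
            reasons.append("incomplete")
        if reasons:
            keep_mask[data.obs.index.get_indexer(idx)] = False
            removals.append({"animal_id": key[0], "season_id": key[1],
                             "n_obs": n, "reason": "; ".join(reasons)})
    report = pd.DataFrame(removals,
                          columns=["animal_id", "season_id", "n_obs", "reason"])
    return data.subset(keep_mask), report


@dataclass
class AreaCurve:
    """Mean MCP area as a function of subsample size (stabilization check)."""
    sample_sizes: list
    mean_area: list               # m^2, one per size
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_size": self.sample_sizes,
                             "mean_mcp_area_m2": self.mean_area,
                             "n_iterations": self.n_iterations})


def mcp_area_curve(data: TelemetryDataset, sizes, n_iter: int,
                   rng: np.random.Generator, percent: float = 0.95,
                   ) -> AreaCurve:
    """Subsampling stabilization analysis of MCP area vs sample size.

    For each size: repeatedly pick a season uniformly among seasons with at
    least that many relocations, subsample that many observations without
    replacement, and compute the percent-MCP area; report the mean.
    """
    sizes = list(sizes)
    season_pts = {k: data.season_points(*k) for k in data.season_keys()}
    means = []
    for size in sizes:
        eligible = [k for k, p in season_pts.items() if len(p) >= size]
        if not eligible:
            raise HomeRangeError(f"no season has >= {size} observations")
        areas = np.empty(n_iter)
        for it in range(n_iter):
            pts = season_pts[eligible[rng.integers(len(eligible))]]
            sub = pts[rng.choice(len(pts), size=size, replace=False)]
            areas[it] = mcp(sub, percent).area
        means.append(float(areas.mean()))
    return AreaCurve(sample_sizes=sizes, mean_area=means, n_iterations=n_iter)


def mcp_summary(data: TelemetryDataset, cfg_percent: float = 0.95,
                ) -> tuple[dict, pd.DataFrame]:
    """Per-season MCPs plus a summary table (animal, season, class, n, ha)."""
    polys = {}
    rows = []
    for a, s in data.season_keys():
        sub = data.obs[(data.obs["animal_id"] == a)
                       & (data.obs["season_id"] == s)]
        pts = sub[["x", "y"]].to_numpy(float)
        poly = mcp(pts, cfg_percent, ids=sub["obs_id"].to_numpy())
        poly.animal_id, poly.season_id = a, s
        polys[(a, s)] = poly
        rows.append({"animal_id": a, "season_id": s,
                     "repro_class": sub["repro_class"].iloc[0],
                     "n_obs": len(sub), "mcp_area_ha": poly.area_ha})
    return polys, pd.DataFrame(rows)
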