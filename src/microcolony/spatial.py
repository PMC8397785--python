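"""Point-pattern statistics for cells in a growth chamber.

Covers the intercellular-distance profile (mean distance from each focal
cell to its k nearest neighbors for a ladder of k), the bounding-rectangle
colony density (cells divided by the area of the smallest rectangle
enclosing them), the exclusion of solitary cells far from the colony, and
switch-aligned normalized density time series with cross-chamber averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

from .io import AnalysisConfig, ChamberMeta


class DegenerateGeometryError(ValueError):
    """Too few points or zero extent: the statistic is undefined."""


class ReferenceError_(ValueError):
    """No frame close enough to the normalization reference time."""


@dataclass
class KnnProfile:
    """Mean intercellular distance as a function of neighbor count k.

    ``mean_dist_um[i]`` averages, over focal cells, the mean distance from a
    focal cell to its ``k_list[i]`` nearest neighbors; undefined entries
    (k > n-1) are NaN with ``defined[i]`` False rather than silently
    truncated.  ``per_focal`` keeps the per-focal-cell means for dispersion.
    """

    k_list: tuple[int, ...]
    mean_dist_um: np.ndarray
    sd_um: np.ndarray
    n_focal: int
    defined: np.ndarray
    per_focal: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.k_list),
                "mean_dist_um": self.mean_dist_um,
                "sd_um": self.sd_um,
                "n_focal": self.n_focal,
                "defined": self.defined,
            }
        )


def knn_distance_profile(points: np.ndarray, k_list=(10, 20, 30, 40, 50, 60, 70, 80, 90, 100)) -> KnnProfile:
    """Intercellular-distance profile of a 2-D point set.

    For each focal point the Euclidean distances to its k nearest neighbors
    (focal excluded, ties broken by distance then index) are averaged over
    neighbors, then over focal points.  k values with k > n-1 are flagged
    undefined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise DegenerateGeometryError("need at least two points")
    kmax = max(k for k in k_list)
    k_query = min(kmax, n - 1)
    tree = cKDTree(pts)
    # +1 because the nearest hit of each point is itself
    dists, _ = tree.query(pts, k=k_query + 1)
    dists = dists[:, 1:]  # drop self
    cum = np.cumsum(dists, axis=1)
    means = np.full(len(k_list), np.nan)
    sds = np.full(len(k_list), np.nan)
    defined = np.zeros(len(k_list), dtype=bool)
    per_focal: dict[int, np.ndarray] = {}
    for i, k in enumerate(k_list):
        if k <= n - 1:
            focal_means = cum[:, k - 1] / k
            per_focal[k] = focal_means
            means[i] = focal_means.mean()
            sds[i] = focal_means.std(ddof=1) if n > 1 else 0.0
            defined[i] = True
    return KnnProfile(tuple(k_list), means, sds, n, defined, per_focal)


def bounding_rectangle_density(points: np.ndarray, rotated: bool = False) -> tuple[float, float]:
    """(area, density) of the smallest rectangle enclosing the points.

    Axis-aligned by default, matching how chamber images are analyzed; with
    ``rotated=True`` the minimum-area rotated rectangle (over convex-hull
    edge directions) is used instead for sensitivity checks.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise DegenerateGeometryError("density needs at least two points")
    if not rotated:
        extent = pts.max(axis=0) - pts.min(axis=0)
        area = float(extent[0] * extent[1])
    else:
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
        area = np.inf
        for i in range(len(hull)):
            edge = hull[(i + 1) % len(hull)] - hull[i]
            norm = np.linalg.norm(edge)
            if norm == 0:
                continue
            u = edge / norm
            v = np.array([-u[1], u[0]])
            proj_u = hull @ u
            proj_v = hull @ v
            area = min(area, float((proj_u.max() - proj_u.min()) * (proj_v.max() - proj_v.min())))
    if area <= 0:
        raise DegenerateGeometryError("zero-area extent: density undefined")
    return area, n / area


def exclude_solitary(points: np.ndarray, factor: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Drop points far from the colony.

    A point is solitary when its nearest-neighbor distance exceeds
    ``factor`` times the median nearest-neighbor distance of the set.
    Returns (kept points, indices of excluded points); deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return pts, np.empty(0, dtype=int)
    tree = cKDTree(pts)
    nn = tree.query(pts, k=2)[0][:, 1]
    cutoff = factor * np.median(nn)
    excluded = np.flatnonzero(nn > cutoff)
    kept = np.delete(pts, excluded, axis=0)
    return kept, excluded


@dataclass
class DensitySeries:
    """Colony density per frame, aligned and normalized to a nutrient switch.

    ``frame`` holds columns rel_time_h (switch at 0), n_cells, area_um2,
    density (cells/um^2) and normalized (density relative to the reference
    frame ``norm_offset_h`` hours before the switch, exactly 1 there).
    """

    frame: pd.DataFrame
    switch_time_h: float
    norm_offset_h: float
    chamber_id: str = ""


def density_time_series(
    table: pd.DataFrame,
    meta: ChamberMeta,
    offset_h: float = 4.0,
    solitary_factor: float = 5.0,
    fixed_rectangle: bool | None = None,
) -> DensitySeries:
    """Bounding-rectangle density over time, switch-aligned and normalized.

    For switch experiments (``meta.switch_time`` set) the rectangle is fixed
    from the cell coordinates of the last pre-switch frame (after solitary
    exclusion); otherwise it is recomputed per frame.  Time is re-expressed
    relative to the switch and the series divided by its value at
    ``switch - offset_h`` (nearest frame within half a frame interval).
    """
    switch = meta.switch_time
    if fixed_rectangle is None:
        fixed_rectangle = switch is not None
    if switch is None:
        switch = float(table["time_h"].max())  # align to movie end for constant feeds

    frames = sorted(table["frame"].unique())
    fixed_area = None
    if fixed_rectangle:
        pre = table[table["time_h"] < switch]
        if pre.empty:
            raise DegenerateGeometryError("no pre-switch frames to fix the rectangle")
        last_pre = pre[pre["frame"] == pre["frame"].max()]
        pts = last_pre[["x_um", "y_um"]].to_numpy()
        kept, _ = exclude_solitary(pts, solitary_factor)
        fixed_area, _ = bounding_rectangle_density(kept)

    rows = []
    for f in frames:
        sub = table[table["frame"] == f]
        t = float(sub["time_h"].iloc[0])
        pts = sub[["x_um", "y_um"]].to_numpy()
        kept, _ = exclude_solitary(pts, solitary_factor)
        n = len(kept)
        if fixed_rectangle:
            area = fixed_area
            density = n / area
        else:
            try:
                area, density = bounding_rectangle_density(kept)
            except DegenerateGeometryError:
                area, density = np.nan, np.nan
        rows.append((t - switch, n, area, density))
    df = pd.DataFrame(rows, columns=["rel_time_h", "n_cells", "area_um2", "density"])

    ref_rel = -offset_h
    i_ref = int(np.argmin(np.abs(df["rel_time_h"].to_numpy() - ref_rel)))
    if abs(df["rel_time_h"].iloc[i_ref] - ref_rel) > meta.frame_interval_h / 2 + 1e-9:
        raise ReferenceError_(
            f"no frame within half an interval of the reference time {ref_rel} h"
        )
    ref_density = df["density"].iloc[i_ref]
    if not np.isfinite(ref_density) or ref_density <= 0:
        raise ReferenceError_("reference density undefined or zero")
    df["normalized"] = df["density"] / ref_density
    return DensitySeries(df, float(switch), offset_h, meta.chamber_id)


def normalize_series(series: DensitySeries) -> DensitySeries:
    """Renormalize to the reference frame; idempotent."""
    df = series.frame.copy()
    i_ref = int(np.argmin(np.abs(df["rel_time_h"].to_numpy() + series.norm_offset_h)))
    df["normalized"] = df["normalized"] / df["normalized"].iloc[i_ref]
    return DensitySeries(df, series.switch_time_h, series.norm_offset_h, series.chamber_id)


def average_series(
    series_list: list[DensitySeries],
    grid: np.ndarray | None = None,
    column: str = "normalized",
) -> pd.DataFrame:
    """Pointwise mean and Student-t 95% CI envelope over chambers.

    Each series is linearly interpolated onto a common relative-time grid
    (by default the overlap of all series at the first series' resolution).
    With a single series the mean is returned with NaN CI and a warning
    column ``n`` of 1.
    """
    if not series_list:
        raise ValueError("need at least one series")
    if grid is None:
        lo = max(s.frame["rel_time_h"].min() for s in series_list)
        hi = min(s.frame["rel_time_h"].max() for s in series_list)
        base = series_list[0].frame["rel_time_h"].to_numpy()
        grid = base[(base >= lo - 1e-9) & (base <= hi + 1e-9)]
    grid = np.asarray(grid, dtype=float)
    mat = np.vstack(
        [
            np.interp(grid, s.frame["rel_time_h"].to_numpy(), s.frame[column].to_numpy())
            for s in series_list
        ]
    )
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n >= 2:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        lo_ci, hi_ci = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo_ci = np.full_like(mean, np.nan)
        hi_ci = np.full_like(mean, np.nan)
    return pd.DataFrame(
        {"rel_time_h": grid, "mean": mean, "ci_lo": lo_ci, "ci_hi": hi_ci, "n": n}
    )


def knn_profile_per_condition(
    tables: list[pd.DataFrame],
    config: AnalysisConfig,
    frame: int | None = None,
) -> pd.DataFrame:
    """Pooled k-NN profile over chambers at one frame (default: last frame).

    Per-chamber profiles are computed on that chamber's cells only; the
    pooled mean at each k averages per-focal means across chambers where the
    k is defined.
    """
    rows = []
    for i, table in enumerate(tables):
        f = frame if frame is not None else int(table["frame"].max())
        pts = table.loc[table["frame"] == f, ["x_um", "y_um"]].to_numpy()
        if len(pts) < 2:
            continue
        prof = knn_distance_profile(pts, config.k_list)
        for k, m, d in zip(prof.k_list, prof.mean_dist_um, prof.defined):
            rows.append((i, k, m, bool(d), len(pts)))
    return pd.DataFrame(rows, columns=["chamber", "k", "mean_dist_um", "defined", "n_cells"])
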