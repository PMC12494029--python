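"""Spatial organization of FA metrics in migrating cells.

Per-frame FA observations (position + z-scored value) are recentred on the
cell centroid and rotated by one common angle so the window-mean migration
direction points along +x; the aligned observations are binned on a
regular grid and time-averaged, yielding maps of FA-integrated area,
traction force and FAK activity whose front/rear asymmetry and pairwise
correlations quantify the polarized mechanochemical pattern (high force
and FAK activity at the leading edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d, pearsonr

DEFAULT_GRID_UM = 2.0
DEFAULT_WINDOW_S = 600.0


@dataclass
class AlignedObservations:
    """FA observations in migration-aligned coordinates (+x = direction of
    motion, origin = cell centroid)."""

    table: pd.DataFrame  # columns: frame, x_um, y_um, plus value columns
    rotation_rad: float
    translations_um: dict[int, np.ndarray]


def recenter_align(
    fa_obs: pd.DataFrame,
    cell_centroids: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
    min_net_um: float = 1.0,
) -> AlignedObservations:
    """Recentre each frame on the cell centroid and rotate into the
    migration frame.

    ``fa_obs`` needs columns ``frame, time_s, x_um, y_um`` (+ values);
    ``cell_centroids`` needs ``frame, time_s, x_um, y_um`` with a centroid
    for every frame in the window.  Only frames within ``window_s`` of the
    start are used.  Raises when the net centroid displacement over the
    window is below ``min_net_um`` (no defined migration direction).
    """
    cents = cell_centroids.sort_values("frame")
    t0 = cents["time_s"].iloc[0]
    cents = cents[cents["time_s"] <= t0 + window_s]
    frames = cents["frame"].to_numpy()
    if np.any(np.diff(frames) != 1):
        raise ValueError("cell centroid must be available in every window frame")
    p0 = cents[["x_um", "y_um"]].iloc[0].to_numpy()
    p1 = cents[["x_um", "y_um"]].iloc[-1].to_numpy()
    net = p1 - p0
    if np.linalg.norm(net) < min_net_um:
        raise ValueError(
            f"net displacement {np.linalg.norm(net):.2f} um < {min_net_um} um: "
            "cell is not migrating; no alignment direction defined"
        )
    angle = float(np.arctan2(net[1], net[0]))
    rot = np.array([[np.cos(-angle), -np.sin(-angle)],
                    [np.sin(-angle), np.cos(-angle)]])

    obs = fa_obs[fa_obs["frame"].isin(frames)].copy()
    translations: dict[int, np.ndarray] = {}
    out_xy = np.empty((len(obs), 2))
    cent_map = {
        int(f): cents.loc[cents["frame"] == f, ["x_um", "y_um"]].iloc[0].to_numpy()
        for f in frames
    }
    for i, (_, row) in enumerate(obs.iterrows()):
        c = cent_map[int(row["frame"])]
        translations[int(row["frame"])] = -c
        out_xy[i] = rot @ (np.array([row["x_um"], row["y_um"]]) - c)
    obs["x_um"], obs["y_um"] = out_xy[:, 0], out_xy[:, 1]
    return AlignedObservations(table=obs, rotation_rad=-angle, translations_um=translations)


@dataclass
class SpatialMap:
    """Time-averaged 2D map of a z-scored FA metric.

    ``values`` holds the per-bin mean (NaN where no samples landed),
    ``counts`` the per-bin sample count; ``x_edges``/``y_edges`` are the
    bin edges in aligned micrometres.
    """

    values: np.ndarray
    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])


def time_average_map(
    aligned: AlignedObservations,
    value_col: str,
    grid_um: float = DEFAULT_GRID_UM,
    extent_um: float | None = None,
) -> SpatialMap:
    """Bin aligned observations on a regular grid; per-bin mean over time
    and FAs.  Bins without samples are undefined (NaN)."""
    tab = aligned.table
    if len(tab) == 0:
        raise ValueError("no observations to map")
    x = tab["x_um"].to_numpy()
    y = tab["y_um"].to_numpy()
    v = tab[value_col].to_numpy()
    if extent_um is None:
        extent_um = grid_um * np.ceil(
            (max(np.abs(x).max(), np.abs(y).max()) + grid_um) / grid_um
        )
    edges = np.arange(-extent_um, extent_um + grid_um / 2, grid_um)
    mean, xe, ye, _ = binned_statistic_2d(x, y, v, statistic="mean", bins=[edges, edges])
    count, *_ = binned_statistic_2d(x, y, v, statistic="count", bins=[edges, edges])
    return SpatialMap(values=mean, counts=count.astype(int), x_edges=xe, y_edges=ye)


def leading_edge_mask(map_: SpatialMap) -> np.ndarray:
    """Default analysis region: the front (x > 0) half-plane of the aligned
    frame — the leading edge of the migrating cell."""
    return (map_.x_centers > 0)[:, None] & np.ones(map_.values.shape[1], bool)[None, :]


def map_correlation(
    map_a: SpatialMap,
    map_b: SpatialMap,
    region_mask: np.ndarray | None = None,
    min_bins: int = 10,
) -> float:
    """Pearson correlation of two maps over jointly defined bins within a
    region (default: the leading-edge half-plane).  Symmetric and bounded
    in [-1, 1]; raises when fewer than ``min_bins`` bins are shared."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share a grid")
    if region_mask is None:
        region_mask = leading_edge_mask(map_a)
    joint = (
        np.isfinite(map_a.values) & np.isfinite(map_b.values) & region_mask
    )
    n = int(joint.sum())
    if n < min_bins:
        raise ValueError(f"only {n} jointly defined bins in region (need >= {min_bins})")
    r, _ = pearsonr(map_a.values[joint], map_b.values[joint])
    return float(r)
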