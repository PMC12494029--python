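"""Synthetic observations of a polarized migrating cell.

Emulates the spatial regime seen at the leading edge: traction force and
FAK activity share one front-loaded spatial pattern (high at the cell
front, low at the rear), while FA-integrated area follows an independent
side-loaded pattern — so an aligned, time-averaged map should show a high
force-FAK correlation and a low area-FAK correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_polarized_observations(
    n_fas: int = 40,
    n_frames: int = 60,
    frame_interval_s: float = 10.0,
    speed_um_per_min: float = 1.0,
    direction_rad: float = 0.0,
    cell_axes_um: tuple[float, float] = (15.0, 10.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FA observations and cell centroids for a cell translating at
    constant velocity.

    FAs ride with the cell at fixed body-frame positions.  Body-frame
    value fields (already on the z-score scale):

    * force and FAK: front-loaded gradient ``x_body / ax`` (+ independent
      noise each) — co-located patterns;
    * area: side-loaded pattern ``|y_body| / ay`` (+ noise) — independent
      of the front-rear axis.

    Returns ``(fa_obs, cell_centroids)`` tables suitable for
    :func:`fawave.spatial.recenter_align`.
    """
    rng = np.random.default_rng(seed)
    ax, ay = cell_axes_um
    # FA positions in the body frame (x forward), inside the ellipse
    phi = rng.uniform(0, 2 * np.pi, n_fas)
    rad = np.sqrt(rng.uniform(0, 1, n_fas))
    xb = ax * rad * np.cos(phi)
    yb = ay * rad * np.sin(phi)

    step = speed_um_per_min * frame_interval_s / 60.0
    heading = np.array([np.cos(direction_rad), np.sin(direction_rad)])
    rot = np.array([[heading[0], -heading[1]], [heading[1], heading[0]]])

    obs_rows, cent_rows = [], []
    for t in range(n_frames):
        centroid = t * step * heading
        cent_rows.append((t, t * frame_interval_s, centroid[0], centroid[1]))
        world = centroid + (rot @ np.vstack([xb, yb])).T
        force = xb / ax + rng.normal(0, noise_sd, n_fas)
        fak = xb / ax + rng.normal(0, noise_sd, n_fas)
        area = np.abs(yb) / ay + rng.normal(0, noise_sd, n_fas)
        for k in range(n_fas):
            obs_rows.append(
                (t, t * frame_interval_s, world[k, 0], world[k, 1],
                 force[k], fak[k], area[k])
            )
    fa_obs = pd.DataFrame(
        obs_rows,
        columns=["frame", "time_s", "x_um", "y_um",
                 "z_force_nN", "z_fak_ratio", "z_area_um2"],
    )
    cents = pd.DataFrame(cent_rows, columns=["frame", "time_s", "x_um", "y_um"])
    return fa_obs, cents
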