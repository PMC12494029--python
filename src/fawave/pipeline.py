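"""End-to-end orchestration: stack -> per-FA tables -> dynamics results.

The image chain per frame: Costes background + bleed-through correction on
the FRET triplet, FA segmentation on the YPet channel, pillar detection
and reference-lattice fitting on the pillar channel (anchors = pillars far
from any FA, presumed unloaded), FA-to-pillar assignment, and the
beam-equation force.  Multi-frame stacks are tracked into FA trajectories
whose trace table feeds the dynamics stage (z-scores, rates, lags,
periods, force-trend classes).

Identical configuration and inputs give byte-identical trace tables; every
result bundle carries the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from . import dynamics, fret, segmentation, tracking, traction
from .synthetic.stack import ImageStack


@dataclass
class PipelineConfig:
    """Single-document pipeline configuration.

    Defaults carry the analysis constants: bleed-through constants
    alpha/beta, the 0.2-20 um^2 FA area gate, the 2 um displacement gate,
    the 7-frame retention rule, the 0.01 nN/min force-slope threshold on a
    5-min rolling window, and the 150-s lag search bound.
    """

    alpha: float = fret.DEFAULT_ALPHA
    beta: float = fret.DEFAULT_BETA
    pillar_radius_um: float = 1.0
    pillar_height_um: float = 8.0
    pillar_youngs_modulus_pa: float = 2e6
    pillar_pitch_um: float = 4.0
    area_gate_um2: tuple[float, float] = segmentation.AREA_GATE_UM2
    log_sigma_px: float = 1.0
    max_disp_um: float = tracking.MAX_DISPLACEMENT_UM
    min_track_frames: int = tracking.MIN_TRACK_FRAMES
    slope_window_s: float = 300.0
    slope_min_nn_per_min: float = 0.01
    max_lag_s: float = 150.0
    anchor_clearance_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        spec_fields = ("pillar_radius_um", "pillar_height_um",
                       "pillar_youngs_modulus_pa", "pillar_pitch_um")
        for name in spec_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def pillar_spec(self) -> traction.PillarSpec:
        return traction.PillarSpec(
            radius_um=self.pillar_radius_um,
            height_um=self.pillar_height_um,
            youngs_modulus_pa=self.pillar_youngs_modulus_pa,
            pitch_um=self.pillar_pitch_um,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "area_gate_um2" in raw:
            raw["area_gate_um2"] = tuple(raw["area_gate_um2"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StackAnalysis:
    """Result bundle for one analysed stack."""

    fa_table: pd.DataFrame  # per frame per FA
    pillar_table: pd.DataFrame  # per frame per pillar
    tracks: list
    trace_table: pd.DataFrame  # per retained track per frame
    config_hash: str
    log: dict = dc_field(default_factory=dict)


def analyze_stack(stack: ImageStack, config: PipelineConfig | None = None) -> StackAnalysis:
    """Run the full image chain on a multichannel stack."""
    cfg = config or PipelineConfig()
    spec = cfg.pillar_spec
    px = stack.pixel_size_um
    dt = stack.frame_interval_s
    log: dict = {"n_frames": stack.data.shape[0]}

    ypet = stack.channel("ypet")
    # bleach correction referenced to the Costes (cell-free) background of
    # the first frame
    _, _, bg0 = fret.costes_threshold(stack.channel("ecfp")[0], stack.channel("fret")[0])
    if bg0.any():
        ypet, _ = fret.bleach_correct(ypet, bg0)
    filtered = segmentation.preprocess(ypet, log_sigma_px=cfg.log_sigma_px)
    segments = segmentation.segment_stack(filtered, px, cfg.area_gate_um2)
    log["fas_detected"] = [len(s) for s in segments]

    # pillar detection and reference lattice
    pillar_frames = [
        traction.detect_pillar_centroids(f, spec, px) for f in stack.channel("pillars")
    ]
    all_fa_xy = np.array(
        [s.centroid_um for frame in segments for s in frame] or np.empty((0, 2))
    ).reshape(-1, 2)
    cents0 = pillar_frames[0]
    if len(all_fa_xy):
        d = np.linalg.norm(cents0[:, None, :] - all_fa_xy[None, :, :], axis=-1).min(axis=1)
        anchor_mask = d > cfg.anchor_clearance_um
    else:
        anchor_mask = np.ones(len(cents0), bool)
    lattice = traction.fit_reference_grid(cents0, anchor_mask, pitch_um=spec.pitch_um)
    field_ = traction.build_pillar_field(pillar_frames, lattice, spec)
    log["n_pillars"] = field_.node_index.shape[0]
    log["n_anchor_pillars"] = int(anchor_mask.sum())

    pillar_rows = []
    nodes = field_.node_positions_um
    for t in range(field_.centroids_um.shape[0]):
        for p in range(nodes.shape[0]):
            dx, dy = field_.deflections_um[t, p]
            fx, fy = field_.forces_nn[t, p]
            pillar_rows.append(
                (p, t, nodes[p, 0], nodes[p, 1], dx, dy,
                 float(np.hypot(fx, fy)))
            )
    pillar_table = pd.DataFrame(
        pillar_rows,
        columns=["pillar_id", "frame", "x_um", "y_um", "dx_um", "dy_um", "force_nN"],
    )

    # FRET ratio per frame, per-FA values
    fa_rows = []
    for t, frame_segments in enumerate(segments):
        rmap = fret.process_fret_frame(
            stack.channel("ecfp")[t],
            stack.channel("ypet")[t],
            stack.channel("fret")[t],
            fret.BleedThroughConstants(cfg.alpha, cfg.beta),
        )
        for seg in frame_segments:
            mask = np.zeros(rmap.ratio.shape, bool)
            mask[seg.pixels[:, 0], seg.pixels[:, 1]] = True
            ratio = fret.fa_ratio(rmap, mask)
            pid = traction.assign_fa_to_pillar(np.asarray(seg.centroid_um), field_)
            force = (
                float(np.hypot(*field_.forces_nn[t, pid])) if pid is not None else np.nan
            )
            fa_rows.append(
                (t, t * dt, seg.label, seg.centroid_um[0], seg.centroid_um[1],
                 seg.area_um2, seg.mean_brightness, seg.size_index,
                 ratio, pid if pid is not None else -1, force)
            )
    fa_table = pd.DataFrame(
        fa_rows,
        columns=["frame", "time_s", "label", "x_um", "y_um", "area_um2",
                 "mean_brightness", "size_index", "fak_ratio", "pillar_id",
                 "force_nN"],
    )

    tracks = tracking.track_fas(segments, cfg.max_disp_um, cfg.min_track_frames)
    log["tracks_retained"] = len(tracks)

    trace_rows = []
    for tr in tracks:
        for seg in tr.segments:
            sel = fa_table[(fa_table["frame"] == seg.frame) & (fa_table["label"] == seg.label)]
            if len(sel) != 1:
                continue
            row = sel.iloc[0]
            trace_rows.append(
                ("cell00", f"track{tr.track_id:03d}", seg.frame, seg.frame * dt,
                 row["force_nN"], row["fak_ratio"], row["area_um2"])
            )
    trace_table = pd.DataFrame(trace_rows, columns=dynamics.TRACE_COLUMNS)
    return StackAnalysis(
        fa_table=fa_table,
        pillar_table=pillar_table,
        tracks=tracks,
        trace_table=trace_table,
        config_hash=cfg.digest(),
        log=log,
    )


def analyze_traces(
    traces: pd.DataFrame,
    frame_interval_s: float,
    config: PipelineConfig | None = None,
    pairs: tuple[str, ...] = ("force:fak", "fak:area", "force:area"),
) -> dict:
    """Dynamics stage on a trace table: z-scores, rates, per-pair ensemble
    lags, per-FA periods, and the force-trend classification."""
    cfg = config or PipelineConfig()
    dt = frame_interval_s
    df = dynamics.zscore_by_cell(traces)
    df = dynamics.add_rates(df, dt)
    df = dynamics.zscore_by_cell(
        df, metrics=[f"rate_{m}" for m in dynamics.METRICS]
    )
    out: dict = {"frame_interval_s": dt, "config_hash": cfg.digest()}
    out["lags"] = {}
    for pair in pairs:
        try:
            out["lags"][pair] = dynamics.ensemble_lag_summary(df, pair, dt, cfg.max_lag_s)
        except ValueError as err:
            out["lags"][pair] = {"error": str(err)}

    periods = []
    for (_, _), g in df.groupby(["cell_id", "fa_id"], sort=False):
        series = g.sort_values("frame")["z_rate_force_nN"].to_numpy()
        try:
            p = dynamics.autocorr_period(series, dt, max_lag_s=min(600.0, (len(series) // 2) * dt))
        except ValueError:
            p = None
        periods.append(p)
    found = [p for p in periods if p is not None]
    out["period"] = {
        "n_fas": len(periods),
        "n_with_period": len(found),
        "median_period_s": float(np.median(found)) if found else None,
    }

    classes = dynamics.classify_tracks(df, dt, cfg.slope_window_s, cfg.slope_min_nn_per_min)
    out["force_classes"] = classes["force_class"].value_counts().to_dict()
    out["proportion_increasing"] = dynamics.proportion_increasing(classes)
    out["_tables"] = {"traces": df, "classes": classes}
    return out
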