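"""Synthetic multichannel time-lapse stacks of a cell on a micropillar array.

Renders four channels — YPet (acceptor, used for FA segmentation), ECFP
(donor), FRET (sensitized emission) and pillar tops — for a configurable
set of focal adhesions sitting on pillars inside an elliptical cell.

Channel synthesis inverts the processing chain so pipeline correctness is
testable as an exact round trip: each FA is a smoothed disk profile whose
ECFP amplitude and *true* donor/cFRET ratio fix the corrected-FRET
amplitude, and the rendered FRET channel is

    I_FRET = cFRET_true + alpha * I_ECFP + beta * I_YPet ,

so inverting the bleed-through equation with the same constants recovers
the configured ratio exactly.  Loaded pillar tops are displaced by the
beam-equation deflection delta = F L^3 / (3 E I) of their ground-truth
force; exponential photobleaching and Poisson-Gaussian camera noise are
applied last.  All randomness flows through the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ..fret import DEFAULT_ALPHA, DEFAULT_BETA
from ..traction import PillarSpec, force_to_deflection

CHANNELS = ("ypet", "ecfp", "fret", "pillars")

#: Whole-FA donor/cFRET ratios: ~1.4 in control cells, falling to ~0.8
#: under FAK inhibition.
RATIO_PRESETS = {"control": 1.4, "fak_inhibited": 0.8}


@dataclass(frozen=True)
class SyntheticFA:
    """One rendered focal adhesion: position (um), area (um^2), traction
    force vector (nN), true donor/cFRET ratio and a brightness factor."""

    x_um: float
    y_um: float
    area_um2: float = 2.0
    force_nN: tuple[float, float] = (0.0, 0.0)
    true_ratio: float = 1.4
    brightness: float = 1.0


@dataclass(frozen=True)
class StackGenConfig:
    """Configuration for :func:`generate_stack`.

    ``shape`` is (T, Y, X) pixels; intensities are arbitrary camera units.
    ``bleach_rate`` is the fractional intensity loss per frame;
    ``poisson_gain`` (camera units per photon; 0 disables shot noise) and
    ``read_noise_sd`` define the noise model.  Background levels are
    strictly positive so ratio maps never divide by ~0 in noise-free
    fixtures.
    """

    shape: tuple[int, int, int] = (1, 256, 256)
    pixel_size_um: float = 0.2
    frame_interval_s: float = 10.0
    pillar_spec: PillarSpec = PillarSpec(
        radius_um=1.0, height_um=8.0, youngs_modulus_pa=2e6, pitch_um=4.0
    )
    fas: tuple[SyntheticFA, ...] = ()
    cell_center_um: tuple[float, float] = (25.6, 25.6)
    cell_axes_um: tuple[float, float] = (18.0, 12.0)
    bleach_rate: float = 0.0
    poisson_gain: float = 0.0
    read_noise_sd: float = 0.0
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    background: dict = field(
        default_factory=lambda: {"ypet": 12.0, "ecfp": 10.0, "fret": 15.0, "pillars": 8.0}
    )
    amp_ecfp: float = 600.0
    amp_ypet: float = 800.0
    amp_pillar: float = 600.0
    psf_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        t, ny, nx = self.shape
        if min(t, ny, nx) < 1:
            raise ValueError("shape must be positive")
        if not 0 <= self.bleach_rate < 1:
            raise ValueError("bleach_rate must be in [0, 1)")
        footprint = 2 * self.pillar_spec.radius_um
        if self.pillar_spec.pitch_um <= footprint:
            raise ValueError("pillar pitch must exceed the pillar footprint")
        fx = nx * self.pixel_size_um
        fy = ny * self.pixel_size_um
        for fa in self.fas:
            if not (0 < fa.x_um < fx and 0 < fa.y_um < fy):
                raise ValueError(f"FA at ({fa.x_um}, {fa.y_um}) um lies outside the image")
            if not 0 < fa.area_um2 < fx * fy:
                raise ValueError("FA area must be within (0, field area)")


@dataclass
class StackGroundTruth:
    """Generator-side truth for one rendered stack."""

    lattice_origin_um: np.ndarray
    pitch_um: float
    node_index: np.ndarray  # (P, 2) int
    node_positions_um: np.ndarray  # (P, 2) undeformed
    deflections_um: np.ndarray  # (P, 2)
    forces_nN: np.ndarray  # (P, 2)
    fa_pillar: np.ndarray  # (F,) index into nodes, -1 if unassigned
    fa_centers_um: np.ndarray  # (F, 2) rendered centre (displaced pillar top)
    fa_true_ratio: np.ndarray  # (F,)
    fa_label_stack: np.ndarray  # (T, Y, X) int, 0 = background
    inside_cell: np.ndarray  # (P,) bool

    def to_jsonable(self) -> dict:
        return {
            "lattice_origin_um": self.lattice_origin_um.tolist(),
            "pitch_um": self.pitch_um,
            "node_index": self.node_index.tolist(),
            "node_positions_um": self.node_positions_um.tolist(),
            "deflections_um": self.deflections_um.tolist(),
            "forces_nN": self.forces_nN.tolist(),
            "fa_pillar": self.fa_pillar.tolist(),
            "fa_centers_um": self.fa_centers_um.tolist(),
            "fa_true_ratio": self.fa_true_ratio.tolist(),
            "inside_cell": self.inside_cell.tolist(),
        }


@dataclass
class ImageStack:
    """Multichannel time-lapse with physical metadata.

    ``data`` has axes (T, C, Y, X) with channels ordered as
    ``("ypet", "ecfp", "fret", "pillars")``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channels: tuple[str, ...] = CHANNELS

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


def _disk_profile(ny: int, nx: int, cx_px: float, cy_px: float,
                  radius_px: float, psf_sigma_px: float) -> np.ndarray:
    """Unit-amplitude plaque profile: hard disk convolved with the PSF."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    disk = ((xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= radius_px**2).astype(float)
    if psf_sigma_px > 0:
        disk = gaussian_filter(disk, psf_sigma_px)
    return disk


def _gaussian_spot(ny: int, nx: int, cx_px: float, cy_px: float,
                   sigma_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.exp(-(((xx - cx_px) ** 2 + (yy - cy_px) ** 2) / (2 * sigma_px**2)))


def generate_stack(config: StackGenConfig) -> tuple[ImageStack, StackGroundTruth]:
    """Render a four-channel stack and its ground truth."""
    t_frames, ny, nx = config.shape
    px = config.pixel_size_um
    spec = config.pillar_spec
    rng = np.random.default_rng(config.seed)

    # --- reference pillar lattice covering the field ---
    pitch = spec.pitch_um
    origin = np.array([pitch / 2, pitch / 2])
    n_i = int((nx * px - origin[0]) // pitch) + 1
    n_j = int((ny * px - origin[1]) // pitch) + 1
    jj, ii = np.mgrid[0:n_j, 0:n_i]
    node_index = np.column_stack([ii.ravel(), jj.ravel()])
    nodes = origin + node_index * pitch  # (P, 2) in um
    margin = 2 * spec.radius_um
    keep = (
        (nodes[:, 0] > margin) & (nodes[:, 0] < nx * px - margin)
        & (nodes[:, 1] > margin) & (nodes[:, 1] < ny * px - margin)
    )
    node_index, nodes = node_index[keep], nodes[keep]

    # --- assign each FA to its nearest pillar; that pillar carries its force
    forces = np.zeros_like(nodes)
    fa_pillar = np.full(len(config.fas), -1, dtype=int)
    for k, fa in enumerate(config.fas):
        d = np.linalg.norm(nodes - [fa.x_um, fa.y_um], axis=1)
        j = int(np.argmin(d))
        if d[j] <= pitch / 2:
            fa_pillar[k] = j
            forces[j] += np.asarray(fa.force_nN)
    deflections = force_to_deflection(forces, spec)
    tops = nodes + deflections  # displaced pillar tops

    cx, cy = config.cell_center_um
    ax, ay = config.cell_axes_um
    inside = ((nodes[:, 0] - cx) / ax) ** 2 + ((nodes[:, 1] - cy) / ay) ** 2 <= 1.0

    # --- static single-frame scene per channel ---
    sigma_pillar_px = 0.5 * spec.radius_um / px
    scene = {name: np.full((ny, nx), config.background[name]) for name in CHANNELS}
    for top in tops:
        scene["pillars"] += config.amp_pillar * _gaussian_spot(
            ny, nx, top[0] / px, top[1] / px, sigma_pillar_px
        )

    label = np.zeros((ny, nx), dtype=np.int32)
    fa_centers = np.zeros((len(config.fas), 2))
    fa_ratio = np.zeros(len(config.fas))
    for k, fa in enumerate(config.fas):
        center = tops[fa_pillar[k]] if fa_pillar[k] >= 0 else np.array([fa.x_um, fa.y_um])
        fa_centers[k] = center
        fa_ratio[k] = fa.true_ratio
        r_px = np.sqrt(fa.area_um2 / np.pi) / px
        cx_px, cy_px = center[0] / px, center[1] / px
        profile = _disk_profile(ny, nx, cx_px, cy_px, r_px, config.psf_sigma_px)
        a_e = config.amp_ecfp * fa.brightness
        a_y = config.amp_ypet * fa.brightness
        a_cfret = a_e / fa.true_ratio
        scene["ecfp"] += a_e * profile
        scene["ypet"] += a_y * profile
        scene["fret"] += (a_cfret + config.alpha * a_e + config.beta * a_y) * profile
        yy, xx = np.mgrid[0:ny, 0:nx]
        label[((xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= r_px**2)] = k + 1

    # --- time axis: bleaching then camera noise ---
    data = np.empty((t_frames, len(CHANNELS), ny, nx))
    for t in range(t_frames):
        fade = (1.0 - config.bleach_rate) ** t
        for c, name in enumerate(CHANNELS):
            img = scene[name] * fade
            if config.poisson_gain > 0:
                img = rng.poisson(img / config.poisson_gain) * config.poisson_gain
            if config.read_noise_sd > 0:
                img = img + rng.normal(0, config.read_noise_sd, img.shape)
            data[t, c] = np.clip(img, 0, None)

    stack = ImageStack(
        data=data, pixel_size_um=px, frame_interval_s=config.frame_interval_s
    )
    truth = StackGroundTruth(
        lattice_origin_um=origin,
        pitch_um=pitch,
        node_index=node_index,
        node_positions_um=nodes,
        deflections_um=deflections,
        forces_nN=forces,
        fa_pillar=fa_pillar,
        fa_centers_um=fa_centers,
        fa_true_ratio=fa_ratio,
        fa_label_stack=np.broadcast_to(label, (t_frames, ny, nx)).copy(),
        inside_cell=inside,
    )
    return stack, truth


def stack_preset(
    name: str,
    n_fas: int = 10,
    seed: int = 0,
    noise: bool = False,
    bleach_rate: float = 0.0,
    force_range_nN: tuple[float, float] = (1.0, 6.0),
    **overrides,
) -> StackGenConfig:
    """Stack configs for the control / FAK-inhibited imaging conditions.

    Places ``n_fas`` FAs on distinct pillars inside the cell ellipse, each
    pulling toward the cell centre with a force drawn uniformly from
    ``force_range_nN``; the preset fixes the true donor/cFRET ratio.
    """
    if name not in RATIO_PRESETS:
        raise KeyError(f"unknown stack preset {name!r}; choose from {sorted(RATIO_PRESETS)}")
    ratio = RATIO_PRESETS[name]
    base = StackGenConfig(seed=seed, bleach_rate=bleach_rate, **overrides)
    rng = np.random.default_rng(seed)
    pitch = base.pillar_spec.pitch_um
    origin = np.array([pitch / 2, pitch / 2])
    cx, cy = base.cell_center_um
    ax, ay = base.cell_axes_um
    _, ny, nx = base.shape
    fx, fy = nx * base.pixel_size_um, ny * base.pixel_size_um
    margin = 3 * base.pillar_spec.radius_um

    candidates = []
    for i in range(int(fx // pitch) + 1):
        for j in range(int(fy // pitch) + 1):
            p = origin + np.array([i, j]) * pitch
            if not (margin < p[0] < fx - margin and margin < p[1] < fy - margin):
                continue
            if ((p[0] - cx) / (0.8 * ax)) ** 2 + ((p[1] - cy) / (0.8 * ay)) ** 2 <= 1.0:
                candidates.append(p)
    if len(candidates) < n_fas:
        raise ValueError(f"cell ellipse only covers {len(candidates)} pillars, need {n_fas}")
    chosen = rng.choice(len(candidates), size=n_fas, replace=False)
    fas = []
    for idx in chosen:
        p = candidates[idx]
        radial = np.array([cx, cy]) - p
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 0 else np.array([1.0, 0.0])
        mag = rng.uniform(*force_range_nN)
        fas.append(
            SyntheticFA(
                x_um=float(p[0]), y_um=float(p[1]),
                area_um2=float(rng.uniform(1.5, 4.0)),
                force_nN=tuple(mag * direction),
                true_ratio=ratio,
                brightness=float(rng.uniform(0.8, 1.2)),
            )
        )
    cfg = replace(base, fas=tuple(fas))
    if noise:
        cfg = replace(cfg, poisson_gain=1.0, read_noise_sd=2.0)
    return cfg
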