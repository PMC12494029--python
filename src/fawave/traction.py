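"""Micropillar traction-force extraction.

Cells on a micropillar array detector (mPAD) bend elastomer posts; each
post tip behaves as a cantilever, so its in-plane deflection reports the
local traction force through Euler-Bernoulli beam bending,

    F = 3 E I delta / L**3,        I = pi r**4 / 4,

with E the Young's modulus of the elastomer, r the post radius, L the post
height and delta the tip deflection.  This module detects pillar tops in a
fluorescence channel, fits the undeformed reference lattice from pillars
outside the cell (presumed unloaded), and converts deflections to forces.

Coordinates are 0-based pixel indices with the pixel-center convention,
x rightward / y downward; physical coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class PillarSpec:
    """Geometry and stiffness of one cylindrical micropillar.

    Parameters
    ----------
    radius_um, height_um, pitch_um : float
        Post radius, post height and lattice pitch in micrometres.
    youngs_modulus_pa : float
        Young's modulus of the post elastomer in pascal.
    """

    radius_um: float
    height_um: float
    youngs_modulus_pa: float
    pitch_um: float

    def __post_init__(self) -> None:
        for name in ("radius_um", "height_um", "youngs_modulus_pa", "pitch_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PillarSpec.{name} must be > 0")

    @property
    def second_moment_m4(self) -> float:
        """Second moment of area I = pi r^4 / 4 of the circular section, m^4."""
        return np.pi * (self.radius_um * 1e-6) ** 4 / 4.0

    @property
    def spring_constant_nn_per_um(self) -> float:
        """Cantilever tip stiffness k = 3 E I / L^3, in nN/um."""
        L = self.height_um * 1e-6
        k_si = 3.0 * self.youngs_modulus_pa * self.second_moment_m4 / L**3  # N/m
        return k_si * 1e9 * 1e-6  # N/m -> nN/um


# Placeholder geometric presets: the effective substrate stiffnesses are the
# experimentally relevant quantity; radius/height here are nominal values for
# synthetic work, not measured dimensions.
PILLAR_PRESETS: dict[str, PillarSpec] = {
    "soft_5kPa": PillarSpec(radius_um=1.0, height_um=11.0, youngs_modulus_pa=2e6, pitch_um=4.0),
    "stiff_14kPa": PillarSpec(radius_um=1.0, height_um=8.0, youngs_modulus_pa=2e6, pitch_um=4.0),
}


def deflection_to_force(delta_um: np.ndarray, spec: PillarSpec) -> np.ndarray:
    """Convert tip deflection vectors (um) to force vectors (nN).

    F = 3 E I delta / L^3; the force is parallel to the deflection and
    linear in its magnitude.  Accepts a single (2,) vector or an (N, 2)
    array; scalars are treated as magnitudes.
    """
    delta = np.asarray(delta_um, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("deflection must be finite")
    return spec.spring_constant_nn_per_um * delta


def force_to_deflection(force_nn: np.ndarray, spec: PillarSpec) -> np.ndarray:
    """Inverse of :func:`deflection_to_force`: force (nN) to deflection (um)."""
    force = np.asarray(force_nn, dtype=float)
    return force / spec.spring_constant_nn_per_um


def detect_pillar_centroids(
    frame: np.ndarray,
    spec: PillarSpec,
    pixel_size_um: float,
) -> np.ndarray:
    """Detect sub-pixel pillar-top centroids in one pillar-channel frame.

    The frame is smoothed at the pillar scale, thresholded (Otsu), and each
    connected bright component yields one intensity-weighted centroid.
    Detections closer than ``pitch/2`` are merged (intensity-weighted mean).

    Returns an (N, 2) array of (x, y) positions in micrometres.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2D frame")
    sigma_px = max(1.0, 0.5 * spec.radius_um / pixel_size_um)
    smooth = ndimage.gaussian_filter(img, sigma_px)
    if smooth.max() <= smooth.min():
        raise RuntimeError(
            "no pillar tops detected: frame is constant "
            "(wrong channel, or wrong detection scale?)"
        )
    mask = smooth > threshold_otsu(smooth)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise RuntimeError(
            "no pillar tops detected (wrong channel, or wrong detection scale?)"
        )
    # Intensity-weighted centroids; background-subtract inside each blob so
    # a constant offset does not bias the weighting.
    base = float(np.median(img[~mask])) if (~mask).any() else 0.0
    weights = np.clip(img - base, 0, None)
    cy, cx = [], []
    for com in ndimage.center_of_mass(weights, labels, range(1, n + 1)):
        cy.append(com[0])
        cx.append(com[1])
    pts = np.column_stack([cx, cy]) * pixel_size_um

    # Merge duplicates closer than pitch/2.
    merged: list[np.ndarray] = []
    used = np.zeros(len(pts), bool)
    for i in range(len(pts)):
        if used[i]:
            continue
        d = np.linalg.norm(pts - pts[i], axis=1)
        group = (d < spec.pitch_um / 2) & ~used
        used |= group
        merged.append(pts[group].mean(axis=0))
    return np.asarray(merged)


@dataclass
class ReferenceLattice:
    """Least-squares 2D Bravais lattice: origin + two basis vectors (um)."""

    origin_um: np.ndarray
    basis_um: np.ndarray  # (2, 2), rows are the two lattice vectors

    def node_position(self, ij: np.ndarray) -> np.ndarray:
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        return self.origin_um + ij @ self.basis_um

    def nearest_node(self, pts_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest integer node index and residual vector for each point."""
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        ij = np.rint((pts - self.origin_um) @ np.linalg.inv(self.basis_um)).astype(int)
        res = pts - self.node_position(ij)
        return ij, res


def _initial_basis(centroids: np.ndarray) -> np.ndarray:
    """Initial lattice basis from the shortest nearest-neighbour directions."""
    diffs = centroids[None, :, :] - centroids[:, None, :]
    dist = np.linalg.norm(diffs, axis=-1)
    np.fill_diagonal(dist, np.inf)
    # Shortest inter-pillar distance ~ pitch; collect all difference vectors
    # near that length and cluster them by direction (mod pi).
    d0 = dist.min()
    sel = (dist < 1.3 * d0) & (dist > 0)
    vecs = diffs[sel]
    if len(vecs) < 2:
        raise RuntimeError("could not identify two lattice directions")
    # Directions are defined mod pi (a lattice vector and its negation are
    # the same axis): cluster on the doubled angle, which removes the sign
    # ambiguity, then split at the largest circular gap.
    a2 = np.mod(2 * np.arctan2(vecs[:, 1], vecs[:, 0]), 2 * np.pi)
    order = np.argsort(a2)
    a2s = a2[order]
    gaps = np.diff(np.concatenate([a2s, [a2s[0] + 2 * np.pi]]))
    if gaps.max() < 0.3:
        raise RuntimeError("could not identify two lattice directions")
    cut = int(np.argmax(gaps))
    rolled = np.roll(order, -(cut + 1))  # start just past the largest gap
    # second split inside the remaining arc
    a2r = np.mod(a2[rolled] - a2[rolled[0]], 2 * np.pi)
    gaps2 = np.diff(a2r)
    split = int(np.argmax(gaps2)) + 1 if len(a2r) > 1 else 1
    basis = []
    for cluster in (rolled[:split], rolled[split:]):
        if len(cluster) == 0:
            raise RuntimeError("could not identify two lattice directions")
        c = np.mean(np.cos(a2[cluster]))
        s = np.mean(np.sin(a2[cluster]))
        theta = 0.5 * np.arctan2(s, c)
        length = np.linalg.norm(vecs[cluster], axis=1).mean()
        basis.append(length * np.array([np.cos(theta), np.sin(theta)]))
    return np.vstack(basis)


def fit_reference_grid(
    centroids_um: np.ndarray,
    anchor_mask: np.ndarray | None = None,
    *,
    pitch_um: float | None = None,
) -> ReferenceLattice:
    """Fit the undeformed reference lattice from anchor (unloaded) pillars.

    Parameters
    ----------
    centroids_um : (N, 2) array
        Observed pillar centroids in micrometres.
    anchor_mask : (N,) bool array, optional
        Pillars presumed unloaded (outside the cell).  Default: all.
    pitch_um : float, optional
        If given, used to validate the fitted basis length and the anchor
        residuals (mean residual must be below pitch/4).

    Returns a :class:`ReferenceLattice` whose origin and basis minimise the
    squared anchor residuals.  The fit is translation- and rotation-
    equivariant because it depends on the centroids alone.
    """
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    anchors = pts if anchor_mask is None else pts[np.asarray(anchor_mask, bool)]
    if len(anchors) < 6:
        raise ValueError(
            f"need >= 6 anchor pillars to fit the reference lattice, got {len(anchors)}"
        )
    basis = _initial_basis(anchors)
    origin = anchors[0].copy()
    for _ in range(3):  # index, then linear least squares; converges fast
        ij = np.rint((anchors - origin) @ np.linalg.inv(basis))
        A = np.column_stack([np.ones(len(anchors)), ij])  # origin, b1, b2
        sol, *_ = np.linalg.lstsq(A, anchors, rcond=None)
        origin, basis = sol[0], sol[1:]
    lattice = ReferenceLattice(origin_um=origin, basis_um=basis)
    _, res = lattice.nearest_node(anchors)
    mean_res = float(np.linalg.norm(res, axis=1).mean())
    if pitch_um is not None and mean_res > pitch_um / 4:
        raise RuntimeError(
            f"reference-lattice fit failed: mean anchor residual {mean_res:.3f} um "
            f"exceeds pitch/4 = {pitch_um / 4:.3f} um"
        )
    return lattice


@dataclass
class PillarField:
    """Per-frame pillar observations referenced to a fitted lattice.

    ``node_index`` maps each tracked pillar to its integer lattice node;
    deflection is observed centroid minus reference node position, and the
    force is the beam-equation image of the deflection.
    """

    lattice: ReferenceLattice
    spec: PillarSpec
    node_index: np.ndarray  # (P, 2) int
    centroids_um: np.ndarray  # (T, P, 2)
    deflections_um: np.ndarray = field(init=False)
    forces_nn: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ref = self.lattice.node_position(self.node_index)  # (P, 2)
        self.deflections_um = self.centroids_um - ref[None, :, :]
        self.forces_nn = deflection_to_force(self.deflections_um, self.spec)

    @property
    def node_positions_um(self) -> np.ndarray:
        return self.lattice.node_position(self.node_index)

    def loaded(self, threshold_um: float = 0.05) -> np.ndarray:
        """Boolean (T, P): pillars whose deflection exceeds ``threshold_um``."""
        return np.linalg.norm(self.deflections_um, axis=-1) > threshold_um


def build_pillar_field(
    frames_centroids_um: list[np.ndarray],
    lattice: ReferenceLattice,
    spec: PillarSpec,
) -> PillarField:
    """Assemble a :class:`PillarField` from per-frame centroid detections.

    Centroids are assigned to their nearest lattice node (within pitch/2);
    a pillar enters the field only if observed in every frame.
    """
    per_frame: list[dict[tuple[int, int], np.ndarray]] = []
    for pts in frames_centroids_um:
        ij, res = lattice.nearest_node(pts)
        d = np.linalg.norm(res, axis=1)
        frame_map: dict[tuple[int, int], np.ndarray] = {}
        for k in range(len(pts)):
            if d[k] <= spec.pitch_um / 2:
                frame_map[tuple(ij[k])] = pts[k]
        per_frame.append(frame_map)
    common = set(per_frame[0])
    for fm in per_frame[1:]:
        common &= set(fm)
    nodes = sorted(common)
    if not nodes:
        raise RuntimeError("no pillar persisted across all frames")
    node_index = np.asarray(nodes, dtype=int)
    cents = np.stack(
        [np.asarray([fm[n] for n in nodes]) for fm in per_frame], axis=0
    )
    return PillarField(lattice=lattice, spec=spec, node_index=node_index, centroids_um=cents)


def assign_fa_to_pillar(fa_centroid_um: np.ndarray, pillar_field: PillarField) -> int | None:
    """Assign an FA centroid to the nearest pillar node within pitch/2.

    Returns the pillar's row index in ``pillar_field.node_index``, or None
    if no node lies within pitch/2.  Equidistant candidates tie-break to the
    lowest row index (deterministic).
    """
    nodes = pillar_field.node_positions_um
    d = np.linalg.norm(nodes - np.asarray(fa_centroid_um, dtype=float), axis=1)
    # round to suppress float noise so exact midpoints tie-break by index
    d = np.round(d, 9)
    best = int(np.argmin(d))
    if d[best] > pillar_field.spec.pitch_um / 2:
        return None
    return best
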