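"""Beam-equation forces, pillar detection, and reference-lattice fitting."""

import numpy as np
import pytest

from fawave.synthetic import SyntheticFA, StackGenConfig, generate_stack
from fawave.traction import (
    PillarSpec,
    assign_fa_to_pillar,
    build_pillar_field,
    deflection_to_force,
    detect_pillar_centroids,
    fit_reference_grid,
    force_to_deflection,
)


class TestDeflectionToForce:
    def test_hand_evaluated_case(self, default_spec):
        # I = pi/4 * (1e-6)^4 m^4; F = 3*E*I*delta/L^3 = 9.203e-9 N for
        # r = 1 um, L = 8 um, E = 2 MPa, delta = 1 um
        f = deflection_to_force(np.array([1.0, 0.0]), default_spec)
        assert np.hypot(*f) == pytest.approx(9.203, abs=0.005)

    def test_zero_and_linearity(self, default_spec):
        assert np.all(deflection_to_force(np.zeros(2), default_spec) == 0)
        d = np.array([0.3, -0.4])
        f1 = deflection_to_force(d, default_spec)
        f2 = deflection_to_force(2 * d, default_spec)
        np.testing.assert_allclose(f2, 2 * f1)
        # force parallel to deflection
        assert f1[0] * d[1] - f1[1] * d[0] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_inverse(self, default_spec):
        d = np.array([[0.1, 0.2], [-0.5, 0.05]])
        np.testing.assert_allclose(
            force_to_deflection(deflection_to_force(d, default_spec), default_spec), d
        )

    def test_rejects_nonfinite(self, default_spec):
        with pytest.raises(ValueError):
            deflection_to_force(np.array([np.nan, 0.0]), default_spec)

    def test_spec_validates_geometry(self):
        with pytest.raises(ValueError):
            PillarSpec(radius_um=-1, height_um=8, youngs_modulus_pa=2e6, pitch_um=4)


def _bare_lattice_stack(seed=0, fas=(), **kw):
    cfg = StackGenConfig(shape=(1, 128, 128), fas=tuple(fas),
                         cell_center_um=(12.8, 12.8), cell_axes_um=(8.0, 6.0),
                         seed=seed, **kw)
    return cfg, *generate_stack(cfg)


class TestDetection:
    def test_undeflected_lattice_centroids_subpixel(self, default_spec):
        cfg, stack, truth = _bare_lattice_stack()
        cents = detect_pillar_centroids(stack.channel("pillars")[0], default_spec,
                                        cfg.pixel_size_um)
        assert len(cents) == len(truth.node_positions_um)
        d = np.linalg.norm(
            cents[:, None] - truth.node_positions_um[None], axis=-1
        ).min(axis=1)
        assert d.max() < 0.05 * cfg.pixel_size_um  # within 0.05 px

    def test_displaced_pillar_detected_at_displacement(self, default_spec):
        fa = SyntheticFA(x_um=14.0, y_um=14.0, force_nN=(9.203, 0.0))  # 1 um deflection
        cfg, stack, truth = _bare_lattice_stack(fas=[fa])
        cents = detect_pillar_centroids(stack.channel("pillars")[0], default_spec,
                                        cfg.pixel_size_um)
        loaded = truth.node_positions_um[truth.fa_pillar[0]]
        top = loaded + truth.deflections_um[truth.fa_pillar[0]]
        assert np.linalg.norm(truth.deflections_um[truth.fa_pillar[0]]) == pytest.approx(1.0, abs=1e-3)
        d = np.linalg.norm(cents - top, axis=1).min()
        assert d < 0.05

    def test_blank_frame_raises(self, default_spec):
        with pytest.raises(RuntimeError, match="wrong channel"):
            detect_pillar_centroids(np.zeros((64, 64)), default_spec, 0.2)


class TestReferenceGrid:
    def test_perfect_lattice_recovers_pitch(self):
        jj, ii = np.mgrid[0:5, 0:5]
        pts = np.column_stack([ii.ravel() * 4.0 + 2, jj.ravel() * 4.0 + 2])
        lat = fit_reference_grid(pts, pitch_um=4.0)
        lengths = sorted(np.linalg.norm(lat.basis_um, axis=1))
        assert lengths == pytest.approx([4.0, 4.0], abs=1e-9)
        _, res = lat.nearest_node(pts)
        assert np.linalg.norm(res, axis=1).max() < 1e-9

    def test_interior_deflections_recovered_with_border_anchors(self, default_spec):
        fas = [SyntheticFA(x_um=x, y_um=y, force_nN=f) for (x, y), f in
               [((10, 10), (3.0, 0.0)), ((14, 14), (0.0, -2.0)), ((10, 14), (1.5, 1.5))]]
        cfg, stack, truth = _bare_lattice_stack(fas=fas)
        cents = detect_pillar_centroids(stack.channel("pillars")[0], default_spec,
                                        cfg.pixel_size_um)
        fa_xy = truth.fa_centers_um
        d = np.linalg.norm(cents[:, None] - fa_xy[None], axis=-1).min(axis=1)
        lat = fit_reference_grid(cents, d > 4.0, pitch_um=4.0)
        field = build_pillar_field([cents], lat, default_spec)
        # every truth deflection appears in the recovered field
        for p, true_d in enumerate(truth.deflections_um):
            if np.linalg.norm(true_d) < 1e-6:
                continue
            node = truth.node_positions_um[p]
            k = np.linalg.norm(field.node_positions_um - node, axis=1).argmin()
            np.testing.assert_allclose(
                field.deflections_um[0, k], true_d, atol=0.02
            )

    def test_too_few_anchors_raise(self):
        pts = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [8, 0]], float)
        with pytest.raises(ValueError, match=">= 6 anchor"):
            fit_reference_grid(pts, pitch_um=4.0)

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(3)
        jj, ii = np.mgrid[0:6, 0:6]
        pts = np.column_stack([ii.ravel() * 4.0, jj.ravel() * 4.0])
        pts += rng.normal(0, 0.01, pts.shape)
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([7.1, -3.2])
        lat1 = fit_reference_grid(pts, pitch_um=4.0)
        lat2 = fit_reference_grid(pts @ rot.T + shift, pitch_um=4.0)
        # residuals of transformed points against transformed fit are identical
        _, res1 = lat1.nearest_node(pts)
        _, res2 = lat2.nearest_node(pts @ rot.T + shift)
        np.testing.assert_allclose(
            np.sort(np.linalg.norm(res1, axis=1)),
            np.sort(np.linalg.norm(res2, axis=1)),
            atol=1e-8,
        )


class TestAssignment:
    @pytest.fixture()
    def field(self, default_spec):
        jj, ii = np.mgrid[0:4, 0:4]
        pts = np.column_stack([ii.ravel() * 4.0, jj.ravel() * 4.0])
        lat = fit_reference_grid(pts, pitch_um=4.0)
        return build_pillar_field([pts], lat, default_spec)

    def test_fa_at_node(self, field):
        k = assign_fa_to_pillar(field.node_positions_um[5], field)
        assert k == 5

    def test_equidistant_ties_to_lower_index(self, field):
        a, b = field.node_positions_um[0], field.node_positions_um[1]
        mid = (a + b) / 2
        assert assign_fa_to_pillar(mid, field) == 0

    def test_far_fa_unassigned(self, field):
        far = field.node_positions_um.max(axis=0) + np.array([10.0, 10.0])
        assert assign_fa_to_pillar(far, field) is None


class TestStackGroundTruthInvariants:
    def test_beam_equation_exact_in_ground_truth(self, control_stack, default_spec):
        _, _, truth = control_stack
        k = default_spec.spring_constant_nn_per_um
        np.testing.assert_allclose(
            truth.forces_nN, k * truth.deflections_um, rtol=1e-12
        )

    def test_stack_generation_deterministic(self):
        from fawave.synthetic import stack_preset

        cfg = stack_preset("control", n_fas=5, seed=9, noise=True)
        s1, _ = generate_stack(cfg)
        s2, _ = generate_stack(cfg)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_fa_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside the image"):
            StackGenConfig(shape=(1, 64, 64), fas=(SyntheticFA(x_um=50.0, y_um=5.0),))
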