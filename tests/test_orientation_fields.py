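"""Quadratic-differential line fields, grids, frames and tensors."""

import numpy as np
import pytest

from ridgesim import (AngleGrid, HomogeneousField, PiecewiseField,
                      SampledField, SingularField, SingularPoint,
                      composite_orientation, core_orientation,
                      delta_orientation, fill_missing_orientations, frame_at,
                      grid_lookup, tensor_at)
from ridgesim.orientation_fields import FieldDomainError, SingularPointError


def ang_diff(a, b):
    """Distance between line angles (mod pi)."""
    d = np.mod(a - b, np.pi)
    return np.minimum(d, np.pi - d)


class TestSingularOrientations:
    Z = (0.5, 0.5)

    def test_delta_on_positive_x_axis(self):
        assert delta_orientation(np.array([0.9, 0.5]), self.Z) == pytest.approx(0.0)

    def test_delta_on_positive_y_axis(self):
        # arg = pi/2 -> -pi/4 mod pi = 3pi/4
        assert delta_orientation(np.array([0.5, 0.9]), self.Z) == pytest.approx(
            3 * np.pi / 4)

    def test_core_on_positive_y_axis(self):
        assert core_orientation(np.array([0.5, 0.9]), self.Z) == pytest.approx(
            np.pi / 4)

    def test_evaluation_at_singularity_raises(self):
        with pytest.raises(SingularPointError):
            delta_orientation(np.array(self.Z), self.Z)

    @pytest.mark.parametrize("kind", ["delta", "core"])
    def test_matches_solution_curve_tangents(self, kind):
        """The field angle must equal the tangent direction of the closed-form
        solution curves z(r) = (r + z0^{3/2})^{2/3} (delta) and
        z(r) = (r + z0^{1/2})^2 (core), traced by finite differences."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            z0 = rng.uniform(0.05, 0.4) * np.exp(1j * rng.uniform(-2.9, 2.9))
            r = rng.uniform(0.0, 0.3)
            h = 1e-7
            if kind == "delta":
                curve = lambda t: (t + z0 ** 1.5) ** (2.0 / 3.0)
            else:
                curve = lambda t: (t + z0 ** 0.5) ** 2
            z = curve(r)
            dz = curve(r + h) - curve(r - h)
            tangent = np.angle(dz) % np.pi
            x = np.array([z.real, z.imag])
            fn = delta_orientation if kind == "delta" else core_orientation
            worst = max(worst, float(ang_diff(fn(x, (0.0, 0.0)), tangent)))
        assert worst < 1e-6

    def test_delta_has_three_straight_ridges(self):
        """Rays where the field is parallel to the ray itself: -arg/2 = arg
        mod pi gives arg in {0, 2pi/3, -2pi/3} — three arms at equal angles."""
        arms = []
        for a in np.linspace(-np.pi, np.pi, 3600, endpoint=False):
            x = np.array(self.Z) + 0.3 * np.array([np.cos(a), np.sin(a)])
            if ang_diff(delta_orientation(x, self.Z), a % np.pi) < 1e-3:
                arms.append(a)
        arms = np.array(arms)
        clusters = np.nonzero(np.diff(np.concatenate([[-10], arms])) > 0.1)[0]
        assert len(clusters) == 3
        assert np.allclose(np.diff(np.sort(arms[clusters])), 2 * np.pi / 3,
                           atol=0.01)

    def test_core_has_single_straight_ridge(self):
        """arg/2 = arg mod pi holds only for arg = 0: one line ends at the core."""
        arms = []
        for a in np.linspace(-np.pi, np.pi, 3600, endpoint=False):
            x = np.array(self.Z) + 0.3 * np.array([np.cos(a), np.sin(a)])
            if ang_diff(core_orientation(x, self.Z), a % np.pi) < 1e-3:
                arms.append(a)
        arms = np.array(arms)
        clusters = np.nonzero(np.diff(np.concatenate([[-10], arms])) > 0.1)[0]
        assert len(clusters) == 1


class TestCompositeOrientation:
    def test_reduces_to_single_delta(self, rng):
        zeta = (0.3, 0.4)
        pts = rng.random((50, 2))
        composite = composite_orientation(pts, [SingularPoint(zeta, "delta")])
        np.testing.assert_allclose(composite, delta_orientation(pts, zeta))

    def test_reduces_to_single_core(self, rng):
        zeta = (0.6, 0.2)
        pts = rng.random((50, 2))
        composite = composite_orientation(pts, [SingularPoint(zeta, "core")])
        np.testing.assert_allclose(composite, core_orientation(pts, zeta))

    def test_smooth_away_from_singularities(self):
        """Finite-difference gradient of the doubled-angle embedding stays
        bounded on a disc well separated from both singular points."""
        pts_def = [SingularPoint((0.3, 0.6), "core"),
                   SingularPoint((0.7, 0.35), "delta")]
        h = 1e-5
        for center in [(0.1, 0.1), (0.9, 0.9), (0.5, 0.95)]:
            for dx, dy in [(h, 0.0), (0.0, h)]:
                a1 = composite_orientation(np.array(center), pts_def)
                a2 = composite_orientation(np.array(center) + [dx, dy], pts_def)
                grad = ang_diff(a1, a2) / h
                assert grad < 20.0  # bounded; 1/(2 min-distance) scale


class TestFrameAndTensor:
    def test_homogeneous_vertical(self):
        f = HomogeneousField(np.pi / 2, chi=0.3)
        s, l = frame_at(f, np.array([0.2, 0.7]))
        np.testing.assert_allclose(s, [0.0, 1.0], atol=1e-15)
        np.testing.assert_allclose(l, [-1.0, 0.0], atol=1e-15)

    def test_orthonormality_all_representations(self, rng):
        grid = AngleGrid(rng.uniform(0, np.pi, (32, 32)))
        fields = [
            HomogeneousField(0.7),
            SingularField([SingularPoint((0.5, 0.5), "delta")]),
            PiecewiseField([((0.0, 0.5, 0.0, 1.0), 0.3)], fallback=1.2),
            SampledField(grid),
        ]
        pts = rng.random((1000, 2))
        for f in fields:
            s, l = frame_at(f, pts)
            np.testing.assert_allclose((s * s).sum(1), 1.0, atol=1e-12)
            np.testing.assert_allclose((l * l).sum(1), 1.0, atol=1e-12)
            np.testing.assert_allclose((s * l).sum(1), 0.0, atol=1e-12)

    def test_tensor_matches_canonical_matrix(self):
        # s = (0,1), l = (1,0) gives T = [[1,0],[0,chi]]
        f = HomogeneousField(np.pi / 2, chi=0.37)
        T = tensor_at(f, np.array([0.5, 0.5]))
        np.testing.assert_allclose(T, [[1.0, 0.0], [0.0, 0.37]], atol=1e-15)

    def test_tensor_eigenstructure(self, rng):
        f = SingularField([SingularPoint((0.4, 0.4), "core")], chi=0.2)
        pts = rng.random((100, 2))
        T = tensor_at(f, pts)
        np.testing.assert_allclose(np.trace(T, axis1=-2, axis2=-1), 1.2,
                                   atol=1e-12)
        w = np.linalg.eigvalsh(T)
        np.testing.assert_allclose(w[:, 0], 0.2, atol=1e-12)
        np.testing.assert_allclose(w[:, 1], 1.0, atol=1e-12)

    def test_chi_one_gives_identity(self):
        f = HomogeneousField(1.1, chi=1.0)
        T = tensor_at(f, np.array([0.1, 0.9]))
        np.testing.assert_allclose(T, np.eye(2), atol=1e-14)


class TestGridLookup:
    def test_constant_grid_both_modes(self, rng):
        grid = AngleGrid(np.full((16, 16), 0.8))
        pts = rng.random((64, 2))
        for mode in ("nearest", "bilinear"):
            np.testing.assert_allclose(grid_lookup(grid, pts, mode), 0.8,
                                       atol=1e-12)

    def test_cell_center_identity(self):
        rng = np.random.default_rng(3)
        grid = AngleGrid(rng.uniform(0, np.pi, (16, 16)))
        i, j = 5, 11
        x = np.array([(i + 0.5) / 16, (j + 0.5) / 16])
        for mode in ("nearest", "bilinear"):
            assert grid_lookup(grid, x, mode) == pytest.approx(
                grid.angles[i, j], abs=1e-12)

    def test_wraparound_averaging_across_pi(self):
        """Angles 0.01 and pi-0.01 average to ~0 (mod pi), not pi/2."""
        angles = np.full((16, 16), 0.01)
        angles[8:, :] = np.pi - 0.01
        grid = AngleGrid(angles)
        x = np.array([0.5, 0.5])  # midpoint between cells 7 and 8
        got = grid_lookup(grid, x, "bilinear")
        assert ang_diff(got, 0.0) < 1e-6

    def test_recovers_analytic_delta_field(self):
        from ridgesim import make_angle_map
        grid = make_angle_map("single_delta", resolution=256)
        rng = np.random.default_rng(11)
        pts = 0.02 + 0.96 * rng.random((500, 2))  # interior: the analytic
        # field is not periodic, so lookups that wrap the seam are excluded
        far = np.linalg.norm(pts - 0.5, axis=1) > 0.1
        pts = pts[far]
        est = grid_lookup(grid, pts, "bilinear")
        ref = delta_orientation(pts, (0.5, 0.5))
        assert ang_diff(est, ref).max() < 0.01

    def test_masked_nearest_falls_back_to_valid(self):
        angles = np.zeros((16, 16))
        angles[0, 0] = 1.0
        mask = np.zeros((16, 16), dtype=bool)
        mask[0, 0] = True
        grid = AngleGrid(angles, mask)
        assert grid_lookup(grid, np.array([0.9, 0.9]), "nearest") == 1.0


class TestFillMissing:
    def test_fully_valid_identity(self, rng):
        grid = AngleGrid(rng.uniform(0, np.pi, (16, 16)))
        filled = fill_missing_orientations(grid)
        np.testing.assert_array_equal(filled.angles, grid.angles)

    def test_constant_hole_fill(self):
        angles = np.full((20, 20), 0.6)
        mask = np.ones((20, 20), dtype=bool)
        mask[8:12, 8:12] = False
        filled = fill_missing_orientations(AngleGrid(angles, mask))
        np.testing.assert_allclose(filled.angles, 0.6, atol=1e-10)
        assert filled.valid.all()

    def test_single_valid_cell_floods_grid(self):
        angles = np.zeros((16, 16))
        angles[7, 3] = 1.3
        mask = np.zeros((16, 16), dtype=bool)
        mask[7, 3] = True
        filled = fill_missing_orientations(AngleGrid(angles, mask))
        np.testing.assert_allclose(filled.angles, 1.3, atol=1e-8)

    def test_empty_mask_rejected(self):
        with pytest.raises(FieldDomainError):
            fill_missing_orientations(
                AngleGrid(np.zeros((16, 16)), np.zeros((16, 16), dtype=bool)))

    def test_valid_cells_untouched(self, rng):
        angles = rng.uniform(0, np.pi, (16, 16))
        mask = rng.random((16, 16)) > 0.4
        mask[0, 0] = True
        filled = fill_missing_orientations(AngleGrid(angles, mask))
        np.testing.assert_array_equal(filled.angles[mask], angles[mask])


def test_sign_invariance_of_downstream_dynamics(rng):
    """Flipping s -> -s at arbitrary sites leaves forces, tensors and
    trajectories bit-for-bit unchanged (the field is a line field)."""
    from ridgesim import (ParticleState, SimConfig, integrate, make_preset,
                          tensor_at)

    class FlippedFrameField(HomogeneousField):
        """Same line field but with s negated at randomly chosen queries."""

        def __init__(self, base, flips):
            super().__init__(base.theta0, base.chi)
            self._flips = flips

        def angle_at(self, x):
            theta = super().angle_at(x)
            # adding pi flips the returned frame to (-s, -l); downstream
            # quantities are quadratic in the frame and must not change
            return theta + np.pi * self._flips(np.atleast_2d(x))

    base = HomogeneousField(0.9, chi=0.2)
    flipped = FlippedFrameField(base, lambda x: (x[..., 0] * 997 % 2 > 1))
    model = make_preset("kc-reparam", cutoff_radius=0.5)
    init = ParticleState(rng.random((40, 2)))
    cfg = SimConfig(dt=0.2, n_steps=20)
    _, fin_a = integrate(init, base, model, cfg)
    _, fin_b = integrate(init, flipped, model, cfg)
    np.testing.assert_array_equal(fin_a.positions, fin_b.positions)
    x = rng.random((20, 2))
    np.testing.assert_allclose(tensor_at(base, x), tensor_at(flipped, x),
                               atol=1e-15)
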