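"""Contour geometry, line-integral drives and interface evolution."""

import numpy as np
import pytest

import neuralfield as nf
from neuralfield.field2d import Grid2D, extract_contours, simulate_amari_2d
from neuralfield.interface2d import (
    Contour,
    ContourHistory,
    DomainSpec,
    InterfaceDegeneracyError,
    TopologyChangeEvent,
    contour_normals,
    evolve_interface,
    grad_psi_line,
    hausdorff_distance,
    normal_velocity_dirichlet,
    normal_velocity_free,
    psi_area,
    psi_line,
    psi_line_at_vertices,
    step_contour,
    winding_C,
    z_from_history,
)
from neuralfield.kernels import DoGKernel, TopHatKernel

from conftest import CURVES, sample_closed_curve


class TestContourGeometry:
    def test_too_few_or_duplicate_vertices_rejected(self):
        with pytest.raises(ValueError):
            Contour(np.random.default_rng(0).random((10, 2)))
        v = Contour.circle(1.0, 32).vertices.copy()
        v[5] = v[4]
        with pytest.raises(ValueError):
            Contour(v)

    def test_circle_normals_point_outward(self):
        c = Contour.circle(2.0, 128)
        n = contour_normals(c)
        assert np.allclose(n[0], [1.0, 0.0], atol=1e-12)
        assert np.abs(np.linalg.norm(n, axis=1) - 1.0).max() < 1e-12
        # outward means aligned with the radial direction everywhere
        radial = c.vertices / np.linalg.norm(c.vertices, axis=1, keepdims=True)
        assert np.all(np.sum(n * radial, axis=1) > 0.99)

    def test_reversing_orientation_flips_normals(self):
        c = Contour.circle(2.0, 64)
        c_rev = Contour(c.vertices[::-1], orient_ccw=False)
        assert np.allclose(
            contour_normals(c), -contour_normals(c_rev)[::-1], atol=1e-12
        )

    def test_ccw_is_enforced_by_default(self):
        c = Contour(Contour.circle(1.0, 64).vertices[::-1])
        assert c.area > 0

    def test_resampling_preserves_area(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 2 + 0.3 * np.cos(4 * th)
        c = Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        c2 = c.resampled(300)
        h = c.perimeter / 200
        assert abs(c2.area - c.area) < h**2 * 10


class TestWinding:
    def test_interior_exterior_and_on_contour(self):
        c = Contour.circle(1.5, 64)
        assert winding_C(np.array([0.0, 0.0]), c) == 1.0
        assert winding_C(np.array([3.0, 0.0]), c) == 0.0
        assert winding_C(c.vertices[10], c) == 0.5


class TestPsiLine:
    def test_far_field_vanishes(self, planar_kernel):
        c = Contour.circle(1.0, 64)
        assert abs(psi_line(np.array([40.0, 0.0]), c, planar_kernel)) < 1e-12

    def test_non_integrable_kernel_rejected(self):
        c = Contour.circle(1.0, 64)
        with pytest.raises(TypeError):
            psi_line(
                np.array([0.0, 0.0]), c,
                TopHatKernel(w_plus=1, w_minus=-0.5, sigma=1),
            )

    def test_circle_centre_matches_area_integral(self, planar_kernel):
        c = sample_closed_curve(CURVES["circle"], 512)
        cf = sample_closed_curve(CURVES["circle"], 4096)
        pl = psi_line(np.array([0.0, 0.0]), c, planar_kernel)
        pa = psi_area(np.array([0.0, 0.0]), cf, planar_kernel, gauss_order=10)
        assert pl == pytest.approx(pa, abs=1e-6)

    def test_on_contour_ellipse_matches_area_integral(self, planar_kernel):
        c = sample_closed_curve(CURVES["ellipse"], 512)
        cf = sample_closed_curve(CURVES["ellipse"], 2048)
        pt = c.vertices[100]
        pl = psi_line(pt, c, planar_kernel)  # C = 1/2 at a vertex
        pa = psi_area(pt, cf, planar_kernel, gauss_order=10)
        assert pl == pytest.approx(pa, abs=1e-5)

    @pytest.mark.parametrize("shape", ["circle", "ellipse", "star"])
    def test_oracle_equivalence_inside_outside_on(self, planar_kernel, shape):
        """Line-integral psi equals the area integral everywhere (1e-5)."""
        c = sample_closed_curve(CURVES[shape], 512)
        cf = sample_closed_curve(CURVES[shape], 2048)
        rng = np.random.default_rng(7)
        pts_in, pts_out = [], []
        lo = np.abs(cf.vertices).max()
        while len(pts_in) < 4 or len(pts_out) < 4:
            p = rng.uniform(-1.6 * lo, 1.6 * lo, size=2)
            d = np.abs(np.linalg.norm(cf.vertices - p, axis=1)).min()
            if d < 0.15:  # stay clear of the near-singular band
                continue
            (pts_in if winding_C(p, cf) == 1.0 else pts_out).append(p)
        pts_on = [c.vertices[17], c.vertices[301]]
        for p in [*pts_in[:4], *pts_out[:4], *pts_on]:
            pl = psi_line(p, c, planar_kernel)
            pa = psi_area(p, cf, planar_kernel, gauss_order=10)
            assert pl == pytest.approx(pa, abs=1e-5), (shape, p)

    def test_convergence_is_at_least_second_order(self, planar_kernel):
        """Doubling the vertex count shrinks the psi error by >= 4x."""
        cf = sample_closed_curve(CURVES["star"], 4096)
        pt = np.array([1.5, 0.2])
        ref = psi_area(pt, cf, planar_kernel, gauss_order=10)
        errs = []
        for n in (128, 256):
            c = sample_closed_curve(CURVES["star"], n)
            errs.append(abs(psi_line(pt, c, planar_kernel) - ref))
        assert errs[0] / errs[1] >= 4.0

    def test_vertex_batch_agrees_with_single_point(self, planar_kernel):
        c = sample_closed_curve(CURVES["star"], 256)
        batch = psi_line_at_vertices(c, planar_kernel)
        for i in (0, 57, 200):
            assert batch[i] == pytest.approx(
                psi_line(c.vertices[i], c, planar_kernel), abs=1e-12
            )


class TestPsiArea:
    def test_constant_kernel_gives_scaled_polygon_area(self):
        k = TopHatKernel(w_plus=0.8, w_minus=-1e-9, sigma=50.0)
        c = sample_closed_curve(CURVES["star"], 512)
        val = psi_area(np.array([0.5, -0.2]), c, k)
        assert val == pytest.approx(0.8 * c.area, rel=1e-6)

    def test_matches_radial_drive_on_a_circle(self, planar_kernel):
        c = Contour.circle(2.0, 1024)
        for r in (0.0, 1.2, 3.1):
            pa = psi_area(np.array([r, 0.0]), c, planar_kernel, gauss_order=10)
            pr = float(nf.psi_radial(np.array(r), 2.0, planar_kernel))
            assert pa == pytest.approx(pr, abs=1e-5)


class TestGradPsi:
    def test_symmetry_at_circle_centre(self, planar_kernel):
        c = Contour.circle(2.0, 256)
        g = grad_psi_line(np.array([0.0, 0.0]), c, planar_kernel)
        assert np.abs(g).max() < 1e-10

    def test_matches_finite_difference_of_area_integral(self, planar_kernel):
        c = sample_closed_curve(CURVES["ellipse"], 1024)
        h = 1e-5
        for pt in (np.array([1.1, 0.4]), np.array([5.0, 2.5])):
            g = grad_psi_line(pt, c, planar_kernel)
            fd = np.array(
                [
                    (
                        psi_area(pt + np.array([h, 0]), c, planar_kernel, 10)
                        - psi_area(pt - np.array([h, 0]), c, planar_kernel, 10)
                    )
                    / (2 * h),
                    (
                        psi_area(pt + np.array([0, h]), c, planar_kernel, 10)
                        - psi_area(pt - np.array([0, h]), c, planar_kernel, 10)
                    )
                    / (2 * h),
                ]
            )
            assert np.abs(g - fd).max() < 1e-5

    def test_linear_in_kernel_amplitude(self):
        k1 = DoGKernel(a1=3.55, a2=3.0, b1=2.4, b2=3.2, c=10.0)
        k2 = DoGKernel(a1=7.10, a2=6.0, b1=2.4, b2=3.2, c=10.0)
        c = Contour.circle(2.0, 128)
        pt = np.array([1.0, 0.7])
        assert np.allclose(
            2.0 * grad_psi_line(pt, c, k1), grad_psi_line(pt, c, k2)
        )


class TestZFromHistory:
    def test_initial_time_returns_z0(self, planar_kernel):
        c = Contour.circle(1.0, 64)
        z0 = lambda pts: np.column_stack([pts[:, 0] * 0 + 1.0, pts[:, 1]])
        hist = ContourHistory(z0)
        hist.append(0.0, c)
        out = z_from_history(np.array([[0.3, 0.4]]), hist, planar_kernel, 0.0)
        assert np.allclose(out, [[1.0, 0.4]])

    def test_stationary_history_converges_to_grad_psi(self, planar_kernel):
        c = Contour.circle(2.0, 128)
        hist = ContourHistory(lambda pts: np.zeros_like(np.atleast_2d(pts)))
        for t in np.arange(0, 30.0 + 0.005, 0.01):
            hist.append(t, c)
        pt = np.array([1.0, 0.3])
        z = z_from_history(pt, hist, planar_kernel, 30.0)
        assert np.abs(z - grad_psi_line(pt, c, planar_kernel)).max() < 1e-8

    def test_time_beyond_history_rejected(self, planar_kernel):
        hist = ContourHistory(lambda pts: np.zeros_like(np.atleast_2d(pts)))
        hist.append(0.0, Contour.circle(1.0, 64))
        with pytest.raises(ValueError):
            z_from_history(np.array([0.0, 0.0]), hist, planar_kernel, 1.0)


class TestNormalVelocity:
    def test_stationary_spot_is_a_fixed_point_free(self, planar_kernel):
        kap = 0.1
        br = nf.solve_spot_radius(planar_kernel, kap, "plane")[1]
        c = nf.contour_from_polar(
            lambda th: br.radius * np.ones_like(th), 256
        )
        hist = ContourHistory(lambda pts: grad_psi_line(np.atleast_2d(pts), c, planar_kernel))
        hist.append(0.0, c)
        cn = normal_velocity_free(c, hist, planar_kernel, kap, 0.0)
        assert np.abs(cn).max() < 1e-6

    def test_stationary_disc_spot_is_a_fixed_point_dirichlet(self, planar_kernel):
        kap = 0.05
        D = 5 * np.pi
        br = nf.solve_spot_radius(planar_kernel, kap, "disc", D=D, u_bc=0.0)[1]
        c = nf.contour_from_polar(lambda th: br.radius * np.ones_like(th), 256)
        dom = DomainSpec(shape="disc", D=D, bc_mode="dirichlet", u_bc=0.0)
        hist = ContourHistory(
            lambda pts: grad_psi_line(np.atleast_2d(pts), c, planar_kernel)
        )
        hist.append(0.0, c)
        cn = normal_velocity_dirichlet(c, hist, planar_kernel, kap, dom, 0.0)
        assert np.abs(cn).max() < 1e-6

    def test_expansion_has_positive_normal_speed(self, planar_kernel):
        # tiny threshold, suprathreshold drive everywhere on a small circle,
        # with u rising inward => z points inward, c_n > 0 means growth
        c = Contour.circle(0.5, 64)
        hist = ContourHistory(
            lambda pts: -0.2 * np.atleast_2d(pts)
            / np.linalg.norm(np.atleast_2d(pts), axis=1, keepdims=True)
        )
        hist.append(0.0, c)
        cn = normal_velocity_free(c, hist, planar_kernel, 1e-4, 0.0)
        assert np.all(cn > 0)

    def test_degenerate_gradient_raises_with_vertex_info(self, planar_kernel):
        c = Contour.circle(0.5, 64)
        hist = ContourHistory(lambda pts: np.zeros_like(np.atleast_2d(pts)) )
        hist.append(0.0, c)
        with pytest.raises(InterfaceDegeneracyError, match="vertex"):
            normal_velocity_free(c, hist, planar_kernel, 1e-4, 0.0)

    def test_dirichlet_far_from_boundary_matches_free_rule(self, planar_kernel):
        c = Contour.circle(1.5, 128)
        hist = ContourHistory(
            lambda pts: grad_psi_line(np.atleast_2d(pts), c, planar_kernel)
        )
        hist.append(0.0, c)
        kap = 0.07
        free = normal_velocity_free(c, hist, planar_kernel, kap, 0.0)
        dom = DomainSpec(shape="rectangle", L=60.0, bc_mode="dirichlet", u_bc=0.0)
        clamped = normal_velocity_dirichlet(c, hist, planar_kernel, kap, dom, 0.0)
        assert np.abs(free - clamped).max() < 1e-6


class TestStepContour:
    def test_zero_velocity_is_identity(self):
        c = Contour.circle(1.0, 64)
        c2 = step_contour(c, None, np.zeros(64), 0.01)
        assert hausdorff_distance(c, c2) < 1e-12

    def test_uniform_speed_inflates_a_circle(self):
        c = Contour.circle(2.0, 256)
        c2 = step_contour(c, None, np.full(256, 0.5), 0.01)
        radii = np.hypot(*c2.vertices.T)
        assert np.abs(radii - 2.005).max() < 1e-8

    def test_self_intersection_halts_with_contour_attached(self):
        c = Contour.circle(1.0, 64)
        th = np.arctan2(c.vertices[:, 1], c.vertices[:, 0])
        vel = -1.3 * np.abs(np.cos(th))  # pinch left and right arcs through
        with pytest.raises(TopologyChangeEvent) as exc:
            step_contour(c, None, vel, 1.0)
        assert exc.value.contour is not None

    def test_history_is_appended(self, planar_kernel):
        c = Contour.circle(1.0, 64)
        hist = ContourHistory(lambda pts: np.zeros_like(np.atleast_2d(pts)))
        hist.append(0.0, c)
        step_contour(c, hist, np.zeros(64), 0.01)
        assert len(hist) == 2 and hist.times[-1] == pytest.approx(0.01)


class TestEvolution:
    def test_z_consistent_with_grid_simulation(self, planar_kernel):
        """Memory-convolution z matches the grid z along the interface."""
        kap = 0.05
        grid = Grid2D(4 * np.pi, 128)
        seed = nf.make_perturbed_spot(R=2.0, m=4, eps=0.1, kappa=kap, amp=kap)
        from neuralfield.field2d import simulate_gradient_2d

        hz = simulate_gradient_2d(
            lambda X, Y: seed.gradient(X, Y), planar_kernel, kap, 0.0,
            grid, T=2.0, dt=0.01,
        )
        c0 = seed.contour(128)
        hist, _ = evolve_interface(
            c0, planar_kernel, kap, seed.gradient, T=2.0, dt=0.01
        )
        pts = hist.contours[-1].vertices
        z_int = z_from_history(pts, hist, planar_kernel, 2.0)
        from scipy.ndimage import map_coordinates

        iy = (pts[:, 1] + grid.L) / grid.h
        ix = (pts[:, 0] + grid.L) / grid.h
        z_grid = np.column_stack(
            [
                map_coordinates(hz.z1[-1], [iy, ix], order=3),
                map_coordinates(hz.z2[-1], [iy, ix], order=3),
            ]
        )
        assert np.abs(z_int - z_grid).max() < 5 * grid.h**2 * 3

    def test_free_interface_tracks_field_simulation(self, labyrinth_tracking):
        """Scaled-down labyrinth seed: contour engine vs full field at T=3."""
        assert labyrinth_tracking["hausdorff"] <= 2 * labyrinth_tracking["grid_h"]
        # the spread is monotone for this seed
        assert np.all(np.diff(labyrinth_tracking["diags"]["area"]) > -1e-9)

    def test_dirichlet_interface_tracks_field_simulation(self, dirichlet_tracking):
        """Clamped rectangle: contour engine vs gradient simulator at T=3."""
        assert dirichlet_tracking["hausdorff"] <= 2 * dirichlet_tracking["grid_h"]

    def test_oversized_time_step_rejected(self, planar_kernel):
        c = Contour.circle(1.0, 64)
        with pytest.raises(ValueError):
            evolve_interface(
                c, planar_kernel, 0.05,
                lambda pts: np.zeros_like(np.atleast_2d(pts)), T=1.0, dt=0.1,
            )
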