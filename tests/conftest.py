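import numpy as np
import pytest

from neuralfield.interface2d import Contour
from neuralfield.kernels import DoGKernel


@pytest.fixture(scope="session")
def bump_kernel():
    """Mexican-hat kernel used for the 1D bump bifurcation study."""
    return DoGKernel(a1=14.0, a2=13.0, b1=24.0, b2=150.0, c=5.0)


@pytest.fixture(scope="session")
def planar_kernel():
    """Mexican-hat kernel used for the 2D labyrinth / spot studies."""
    return DoGKernel(a1=3.55, a2=3.0, b1=2.4, b2=3.2, c=10.0)


def sample_closed_curve(par, n, dense=65536):
    """Uniform-arclength polygonal sampling of a parametric closed curve.

    Returns vertices exactly on the curve; using the same dense
    parametrisation for a coarse and a fine sampling makes every coarse
    vertex an exact fine vertex (n_fine a multiple of n_coarse).
    """
    thd = np.linspace(0.0, 2.0 * np.pi, dense + 1)
    pts = par(thd)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    th = np.interp(np.linspace(0.0, s[-1], n, endpoint=False), s, thd)
    return Contour(par(th))


@pytest.fixture(scope="session")
def labyrinth_tracking(planar_kernel):
    """Scaled-down spreading-labyrinth run: interface engine vs full field.

    Returns the final contours of both descriptions at T=3, the grid
    spacing and the per-step interface diagnostics.
    """
    import neuralfield as nf
    from neuralfield.field2d import Grid2D, extract_contours, simulate_amari_2d
    from neuralfield.interface2d import evolve_interface, hausdorff_distance

    kap = 0.03
    grid = Grid2D(4 * np.pi, 128)
    seed = nf.make_perturbed_spot(R=2.0, m=6, eps=0.1, kappa=kap)
    hf = simulate_amari_2d(
        seed.field, planar_kernel, kap, grid, T=3.0, dt=0.01, sample_every=100
    )
    (cf,) = extract_contours(hf.u[-1], grid, kap)
    c0 = seed.contour(128)
    h = c0.perimeter / 128
    hist, diags = evolve_interface(
        c0, planar_kernel, kap, seed.gradient, T=3.0, dt=0.01,
        h_bounds=(0.5 * h, 1.6 * h),
    )
    return {
        "hausdorff": hausdorff_distance(hist.contours[-1], cf),
        "grid_h": grid.h,
        "diags": diags,
        "hist": hist,
        "field_contour": cf,
        "kernel_kappa": kap,
    }


@pytest.fixture(scope="session")
def dirichlet_tracking(planar_kernel):
    """Clamped-rectangle run: interface engine vs gradient simulator at T=3."""
    import neuralfield as nf
    from neuralfield.field2d import Grid2D, extract_contours, simulate_gradient_2d
    from neuralfield.interface2d import (
        DomainSpec,
        evolve_interface,
        hausdorff_distance,
    )

    kap = 0.05
    Lbox = 2.5 * np.pi
    grid = Grid2D(Lbox, 128)
    seed = nf.make_perturbed_spot(R=2.0, m=6, eps=0.1, kappa=kap)
    hf = simulate_gradient_2d(
        lambda X, Y: seed.gradient(X, Y), planar_kernel, kap, 0.0,
        grid, T=3.0, dt=0.01, sample_every=100,
    )
    (cf,) = extract_contours(hf.u[-1], grid, kap)
    c0 = seed.contour(128)
    h = c0.perimeter / 128
    dom = DomainSpec(
        shape="rectangle", L=Lbox, bc_mode="dirichlet", u_bc=0.0,
        zeta_policy="left_edge",
    )
    hist, _ = evolve_interface(
        c0, planar_kernel, kap, seed.gradient, T=3.0, dt=0.01,
        domain=dom, h_bounds=(0.5 * h, 1.6 * h),
    )
    return {
        "hausdorff": hausdorff_distance(hist.contours[-1], cf),
        "grid_h": grid.h,
    }


@pytest.fixture(scope="session")
def mode_sign_observations(planar_kernel):
    """Azimuthal-mode growth observed in the full model vs Evans prediction.

    Runs the grid simulator from spot profiles with a cos(m theta) edge
    modulation for m in {0, 2, 3} on both plane branches and records
    (lambda_m, observed_growth) pairs.
    """
    import neuralfield as nf
    from neuralfield.field2d import Grid2D, extract_contours, simulate_amari_2d
    from scipy.ndimage import map_coordinates

    def mode_amp(u, grid, R, m):
        rs = np.linspace(max(R - 1.5, 0.2), R + 1.5, 32)
        th = np.arange(256) * 2 * np.pi / 256
        Rm, Tm = np.meshgrid(rs, th, indexing="ij")
        ix = (Rm * np.cos(Tm) + grid.L) / grid.h
        iy = (Rm * np.sin(Tm) + grid.L) / grid.h
        vals = map_coordinates(u, [iy, ix], order=3)
        return np.abs(np.fft.rfft(vals, axis=1)[:, m]).sum()

    kap = 0.06
    narrow, wide = nf.solve_spot_radius(planar_kernel, kap, "plane")
    eps = 0.07
    results = []

    grid = Grid2D(3 * np.pi, 192)
    X, Y = grid.mesh()
    r, th = np.hypot(X, Y), np.arctan2(Y, X)
    for m in (2, 3):
        u0 = nf.spot_profile(
            wide, (r / (1 + eps * np.cos(m * th))).ravel()
        ).reshape(r.shape)
        hist = simulate_amari_2d(
            u0, planar_kernel, kap, grid, T=12.0, dt=0.02, sample_every=200
        )
        amps = [mode_amp(u, grid, wide.radius, m) for u in hist.u]
        results.append(
            {"branch": "wide", "m": m, "lam": wide.eigenvalues[m],
             "grew": amps[-1] > 1.5 * amps[0]}
        )
    # m = 0 on the wide branch: uniform dilation relaxes back
    u0 = nf.spot_profile(wide, (r / (1 + eps)).ravel()).reshape(r.shape)
    hist = simulate_amari_2d(
        u0, planar_kernel, kap, grid, T=12.0, dt=0.02, sample_every=300
    )
    radii = []
    for u in (hist.u[0], hist.u[-1]):
        (c,) = extract_contours(u, grid, kap)
        radii.append(np.hypot(*c.vertices.T).mean())
    results.append(
        {"branch": "wide", "m": 0, "lam": wide.eigenvalues[0],
         "grew": abs(radii[1] - wide.radius) > abs(radii[0] - wide.radius)}
    )
    # m = 0 on the narrow branch: uniform dilation runs away
    grid2 = Grid2D(2 * np.pi, 128)
    r2 = np.hypot(*grid2.mesh())
    u0 = nf.spot_profile(narrow, (r2 / (1 + eps)).ravel()).reshape(r2.shape)
    hist = simulate_amari_2d(
        u0, planar_kernel, kap, grid2, T=6.0, dt=0.02, sample_every=150
    )
    areas = [float(np.mean(u > kap)) for u in hist.u]
    results.append(
        {"branch": "narrow", "m": 0, "lam": narrow.eigenvalues[0],
         "grew": areas[-1] > 3 * areas[0]}
    )
    return results


CURVES = {
    "circle": lambda th: np.column_stack([3 * np.cos(th), 3 * np.sin(th)]),
    "ellipse": lambda th: np.column_stack([6 * np.cos(th), 3 * np.sin(th)]),
    "star": lambda th: np.column_stack(
        [
            3 * (1 + 0.2 * np.cos(5 * th)) * np.cos(th),
            3 * (1 + 0.2 * np.cos(5 * th)) * np.sin(th),
        ]
    ),
}
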