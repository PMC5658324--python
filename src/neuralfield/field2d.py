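"""Full space-time simulation of planar Amari fields (the ground truth).

Two formulations are integrated on a square grid ``[-L, L]^2``:

* the classical scalar model ``u_t = -u + w * H[u - kappa]`` (no boundary
  condition; the domain is treated as compactly supported and the
  convolution is computed spectrally with zero padding), and
* the gradient reformulation ``z_t = -z + (grad w) * H[u - kappa]`` with
  ``z = grad u``, where ``u`` is rebuilt each step by a line integral of
  ``z`` from a boundary anchor — row-wise from the left edge on a
  rectangle (so ``u(-L, y) = u_BC`` exactly) or radially inward from the
  rim of a disc.  This is how a Dirichlet boundary value enters the
  dynamics.

The simulator doubles as the oracle for the contour-only interface
engine: :func:`extract_contours` pulls the ``kappa``-level set out of a
snapshot with sub-pixel (marching squares) accuracy for direct
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

from .interface2d import Contour, DomainSpec
from .kernels import RadialKernel

__all__ = [
    "Grid2D",
    "FieldHistory",
    "simulate_amari_2d",
    "simulate_gradient_2d",
    "reconstruct_u",
    "extract_contours",
    "discrete_curl",
    "save_fields_h5",
]


@dataclass(frozen=True)
class Grid2D:
    """Uniform square grid on ``[-L, L]^2`` including the boundary nodes."""

    L: float
    n: int

    def __post_init__(self):
        if self.n < 16:
            raise ValueError("grid needs at least 16 points per axis")
        if self.L <= 0:
            raise ValueError("half-width L must be positive")

    @property
    def h(self) -> float:
        return 2.0 * self.L / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(-self.L, self.L, self.n)

    def mesh(self):
        """``(X, Y)`` with array layout ``[iy, ix]``."""
        return np.meshgrid(self.x, self.x, indexing="xy")


@dataclass
class FieldHistory:
    """Sampled trajectory of ``u`` (and optionally ``z``) on a grid."""

    grid: Grid2D
    times: list = field(default_factory=list)
    u: list = field(default_factory=list)
    z1: list = field(default_factory=list)
    z2: list = field(default_factory=list)

    def append(self, t, u, z1=None, z2=None):
        self.times.append(float(t))
        self.u.append(np.asarray(u).copy())
        if z1 is not None:
            self.z1.append(np.asarray(z1).copy())
            self.z2.append(np.asarray(z2).copy())


def _padded_kernel_fft(kernel, grid, pad_factor=2.0, func=None):
    """FFT of the kernel (or a derived field) on the zero-padded grid."""
    n, h = grid.n, grid.h
    N = int(2 ** np.ceil(np.log2(max(int(n * pad_factor), n + 16))))
    idx = np.fft.fftfreq(N, d=1.0 / N)  # 0, 1, ..., -1 ordering
    off = idx * h
    X, Y = np.meshgrid(off, off, indexing="xy")
    R = np.hypot(X, Y)
    if func is None:
        k_arr = kernel.evaluate(R)
    else:
        k_arr = func(X, Y, R)
    # wrap-around check: the kernel should have decayed at the padding edge
    r_edge = (N // 2) * h
    tail = float(np.abs(kernel.evaluate(r_edge)))
    if tail > 1e-8 * max(np.abs(k_arr).max(), 1e-300):
        import warnings

        warnings.warn(
            "kernel support reaches the padded box edge; spectral "
            "convolution may wrap around",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.fft.rfft2(k_arr), N


def _heaviside(u, kappa):
    """Pointwise firing indicator with the midpoint convention H(0)=1/2."""
    return np.where(u > kappa, 1.0, np.where(u == kappa, 0.5, 0.0))


def simulate_amari_2d(
    u0,
    kernel: RadialKernel,
    kappa: float,
    grid: Grid2D,
    T: float,
    dt: float = 0.05,
    sample_every: int = 10,
) -> FieldHistory:
    """Evolve the classical scalar model by exponential Euler.

    The convolution ``w * H[u - kappa]`` is computed spectrally with zero
    padding to at least twice the box, which suppresses wrap-around for
    kernels that decay within the domain.  ``u0`` may be an array on the
    grid or a callable ``u0(X, Y)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    X, Y = grid.mesh()
    u = u0(X, Y) if callable(u0) else np.asarray(u0, dtype=float).copy()
    what, N = _padded_kernel_fft(kernel, grid)
    n, h = grid.n, grid.h
    ed, g = np.exp(-dt), -np.expm1(-dt)
    hist = FieldHistory(grid)
    hist.append(0.0, u)
    n_steps = int(round(T / dt))
    for k in range(n_steps):
        Hpad = np.zeros((N, N))
        Hpad[:n, :n] = _heaviside(u, kappa)
        conv = np.fft.irfft2(np.fft.rfft2(Hpad) * what, s=(N, N))[:n, :n] * h * h
        u = ed * u + g * conv
        if (k + 1) % sample_every == 0 or k == n_steps - 1:
            hist.append((k + 1) * dt, u)
    return hist


def reconstruct_u(
    z1: np.ndarray,
    z2: np.ndarray,
    u_bc: float,
    grid: Grid2D,
    path_policy: Literal["axis_from_left", "radial"] = "axis_from_left",
    disc_radius: float | None = None,
) -> np.ndarray:
    """Rebuild ``u`` from its gradient by a cumulative line integral.

    ``axis_from_left`` integrates ``z1`` row-wise from the left edge, so
    the left edge is clamped to ``u_BC`` exactly.  ``radial`` integrates
    ``z . rhat`` inward from the rim of the disc of ``disc_radius`` (grid
    values are sampled along each ray by bilinear interpolation); points
    outside the disc are set to ``u_BC``.
    """
    h = grid.h
    if path_policy == "axis_from_left":
        integ = np.zeros_like(z1)
        integ[:, 1:] = np.cumsum((z1[:, 1:] + z1[:, :-1]) * 0.5 * h, axis=1)
        return u_bc + integ
    if path_policy != "radial":
        raise ValueError(f"unknown path policy {path_policy!r}")
    D = disc_radius if disc_radius is not None else grid.L
    X, Y = grid.mesh()
    R = np.hypot(X, Y)
    inside = R <= D
    m = int(np.ceil(2 * D / h)) + 2
    s = np.linspace(0.0, 1.0, m)  # fraction of the way from rim to point
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy = np.where(R > 0, X / R, 1.0), np.where(R > 0, Y / R, 0.0)
    # sample points along each ray: from (D * rhat) to the target point
    rad = D + s[:, None] * (R.ravel()[None, :] - D)
    px = rad * ux.ravel()[None, :]
    py = rad * uy.ravel()[None, :]
    ix = (px + grid.L) / h
    iy = (py + grid.L) / h
    zr1 = map_coordinates(z1, [iy, ix], order=1, mode="nearest")
    zr2 = map_coordinates(z2, [iy, ix], order=1, mode="nearest")
    integrand = zr1 * ux.ravel()[None, :] + zr2 * uy.ravel()[None, :]
    seg = np.diff(rad, axis=0)
    vals = u_bc + np.sum(
        (integrand[1:] + integrand[:-1]) * 0.5 * seg, axis=0
    )
    u = np.full_like(z1, u_bc)
    u.ravel()[inside.ravel()] = vals[inside.ravel()]
    return u


def discrete_curl(z1, z2, h) -> np.ndarray:
    """Interior central-difference curl ``dz2/dx - dz1/dy``."""
    dz2dx = (z2[1:-1, 2:] - z2[1:-1, :-2]) / (2 * h)
    dz1dy = (z1[2:, 1:-1] - z1[:-2, 1:-1]) / (2 * h)
    return dz2dx - dz1dy


def simulate_gradient_2d(
    z0,
    kernel: RadialKernel,
    kappa: float,
    u_bc: float,
    grid: Grid2D,
    T: float,
    dt: float = 0.05,
    domain: DomainSpec | None = None,
    sample_every: int = 10,
    curl_tol: float | None = None,
    store_z: bool = True,
) -> FieldHistory:
    """Evolve the gradient formulation with Dirichlet clamping.

    ``z0`` is either a pair of arrays ``(z1, z2)`` or a callable
    ``z0(X, Y) -> (z1, z2)`` and must be discretely curl-free.  Each step
    convolves the firing indicator with the two components of ``grad w``
    spectrally, advances ``z`` by exponential Euler, and rebuilds ``u``
    from ``z`` (row-wise from the left edge on a rectangle, radially on a
    disc) before the next Heaviside evaluation.  On a disc the firing
    indicator is forced to zero outside the disc.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    X, Y = grid.mesh()
    if callable(z0):
        z1, z2 = z0(X, Y)
        z1, z2 = np.asarray(z1, dtype=float).copy(), np.asarray(z2, dtype=float).copy()
    else:
        z1, z2 = (np.asarray(z, dtype=float).copy() for z in z0)
    h = grid.h
    if curl_tol is None:
        curl_tol = 50.0 * h
    c0 = np.abs(discrete_curl(z1, z2, h)).max()
    if c0 > curl_tol:
        raise ValueError(
            f"initial z is not curl-free: max |curl z| = {c0:.3g} > {curl_tol:.3g}"
        )

    disc = domain is not None and domain.shape == "disc"
    if disc:
        mask = np.hypot(X, Y) <= domain.D
        policy, D = "radial", domain.D
    else:
        mask = None
        policy, D = "axis_from_left", None

    def dw(comp):
        def f(XX, YY, RR):
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(RR > 0, (XX if comp == 0 else YY) / RR, 0.0)
            return np.where(RR > 0, kernel.derivative(RR) * unit, 0.0)

        return f

    gx_hat, N = _padded_kernel_fft(kernel, grid, func=dw(0))
    gy_hat, _ = _padded_kernel_fft(kernel, grid, func=dw(1))
    n = grid.n
    ed, g = np.exp(-dt), -np.expm1(-dt)

    u = reconstruct_u(z1, z2, u_bc, grid, policy, D)
    hist = FieldHistory(grid)
    hist.append(0.0, u, *((z1, z2) if store_z else (None, None)))
    n_steps = int(round(T / dt))
    for k in range(n_steps):
        Hk = _heaviside(u, kappa)
        if disc:
            Hk = np.where(mask, Hk, 0.0)
        Hpad = np.zeros((N, N))
        Hpad[:n, :n] = Hk
        Hhat = np.fft.rfft2(Hpad)
        f1 = np.fft.irfft2(Hhat * gx_hat, s=(N, N))[:n, :n] * h * h
        f2 = np.fft.irfft2(Hhat * gy_hat, s=(N, N))[:n, :n] * h * h
        z1 = ed * z1 + g * f1
        z2 = ed * z2 + g * f2
        u = reconstruct_u(z1, z2, u_bc, grid, policy, D)
        if (k + 1) % sample_every == 0 or k == n_steps - 1:
            hist.append(
                (k + 1) * dt, u, *((z1, z2) if store_z else (None, None))
            )
    return hist


def boundary_residual(u: np.ndarray, u_bc: float, grid: Grid2D) -> float:
    """Diagnostic: max |u - u_BC| over the rectangle boundary nodes."""
    edges = np.concatenate([u[0, :], u[-1, :], u[:, 0], u[:, -1]])
    return float(np.abs(edges - u_bc).max())


def extract_contours(
    u: np.ndarray,
    grid: Grid2D,
    kappa: float,
    return_open: bool = False,
):
    """Closed ``kappa``-level contours of a snapshot, CCW around ``u > kappa``.

    Marching squares with linear interpolation (sub-pixel accuracy).
    Open contours touching the domain edge are excluded from the closed
    list; pass ``return_open=True`` to get them as raw vertex arrays in a
    second return value.
    """
    raw = measure.find_contours(u, kappa)
    closed, open_ = [], []
    for arr in raw:
        pts = np.column_stack(
            [-grid.L + arr[:, 1] * grid.h, -grid.L + arr[:, 0] * grid.h]
        )
        if np.allclose(arr[0], arr[-1]) and len(arr) >= 17:
            closed.append(Contour(pts))
        else:
            open_.append(pts)
    if return_open:
        return closed, open_
    return closed


def save_fields_h5(path, hist: FieldHistory) -> None:
    """Write a trajectory to HDF5: groups ``/u``, ``/z1``, ``/z2``."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["L"] = hist.grid.L
        f.attrs["n"] = hist.grid.n
        f.create_dataset("t", data=np.asarray(hist.times))
        f.create_dataset("u", data=np.stack(hist.u))
        if hist.z1:
            f.create_dataset("z1", data=np.stack(hist.z1))
            f.create_dataset("z2", data=np.stack(hist.z2))
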