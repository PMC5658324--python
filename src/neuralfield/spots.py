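"""Circularly symmetric spots: existence, geometry and azimuthal stability.

A *spot* is a stationary active disc of radius ``R`` (centred at the
origin) of the planar Amari model, either on the free plane or inside a
disc domain of radius ``D`` whose rim is clamped to ``u_BC``.  Setting
the interface normal velocity to zero gives the implicit radius equation

.. math::
   \\kappa = u_{BC} + \\psi(R) - \\psi(D),

(the ``u_BC`` and ``psi(D)`` terms are absent on the plane) where
``psi(r)`` is the drive at radius ``r`` from the active disc.  For a
difference of Gaussians ``psi`` is an angular quadrature; for piece-wise
constant kernels it reduces to circle-overlap ("lens") areas computed in
closed form by :func:`A_plus`.

Linear stability against azimuthal perturbations ``cos(m theta)`` of the
spot edge comes from an Evans-function argument: the eigenvalue of mode
``m`` is

.. math::
   \\lambda_m = -1 + \\frac{R}{|q'(R)|}\\Big[J_m(R, R) - J_m(R, D)\\Big],

with ``J_m(R, r) = \\oint cos(m\\theta)\\,w(\\sqrt{r^2 + R^2 -
2 r R\\cos\\theta})\\,d\\theta`` and ``q`` the radial spot profile.  On
the plane the ``D`` term is dropped and translation symmetry forces
``lambda_1 = 0``; a Dirichlet rim breaks that symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .kernels import (
    DoGKernel,
    PwcMexicanHatKernel,
    RadialKernel,
    TopHatKernel,
)

__all__ = [
    "SpotBranch",
    "psi_radial",
    "A_plus",
    "solve_spot_radius",
    "spot_profile",
    "q_prime_at_R",
    "angular_weight_integral",
    "spot_spectrum",
]

STABILITY_TOL = 1e-10


@dataclass
class SpotBranch:
    """A steady spot: radius, threshold, domain and azimuthal spectrum."""

    radius: float
    kappa: float
    domain: Literal["plane", "disc"]
    D: float = np.inf
    u_bc: float = 0.0
    kernel: RadialKernel | None = None
    eigenvalues: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    stable: bool = False
    residual: float = np.nan


def _C_indicator(r, R):
    return np.where(r < R, 1.0, np.where(r == R, 0.5, 0.0))


def psi_radial(r, R: float, kernel: RadialKernel, n_theta: int = 2048):
    """Drive ``psi(r)`` at radius ``r`` from an active disc of radius ``R``.

    Difference of Gaussians: angular (midpoint) quadrature of the ring
    representation plus the ``K C`` winding term, with ``C = 1/2`` exactly
    on the spot edge so ``psi`` is continuous there.  Piece-wise constant
    kernels: exact circle-overlap areas.  Vectorises over ``r``.
    """
    if R <= 0:
        raise ValueError("spot radius must be positive")
    r = np.asarray(r, dtype=float)
    if isinstance(kernel, TopHatKernel):
        return (kernel.w_plus - kernel.w_minus) * A_plus(
            r, R, kernel.sigma
        ) + kernel.w_minus * np.pi * R**2
    if isinstance(kernel, PwcMexicanHatKernel):
        return (kernel.w_plus - kernel.w_minus) * A_plus(
            r, R, kernel.sigma1
        ) + kernel.w_minus * A_plus(r, R, kernel.sigma2)
    if not isinstance(kernel, DoGKernel):
        raise TypeError("unsupported kernel family for psi_radial")
    # midpoint nodes keep the integrable 1/Q^2 structure at r = R away
    # from the quadrature points
    theta = (np.arange(n_theta) + 0.5) * (2.0 * np.pi / n_theta)
    ct = np.cos(theta)
    rr = r[..., None] if r.ndim else r[None]
    Q2 = R**2 + rr**2 - 2.0 * R * rr * ct
    out = 0.0
    for a, b, sgn in (
        (kernel.a1, kernel.b1, 1.0),
        (kernel.a2, kernel.b2, -1.0),
    ):
        # ring integrand; the sign pairs with *outward* edge normals
        # (checked against direct area quadrature of the kernel)
        rho = (b / 2.0) * np.sum(
            np.exp(-Q2 / b) / Q2 * R * (rr * ct - R), axis=-1
        ) * (2.0 * np.pi / n_theta)
        out = out + sgn * a / np.sqrt(kernel.c * np.pi * b) * rho
    out = out + kernel.total_mass() * _C_indicator(r, R)
    return out if r.ndim else float(out[0] if np.ndim(out) else out)


def A_plus(r, R: float, sigma: float):
    """Overlap area of disc(0, R) and disc(center at distance r, sigma).

    Closed-form lens geometry: zero for disjoint discs
    (``r >= R + sigma``), the full smaller disc under containment
    (``r <= |R - sigma|``), otherwise the two circular-segment areas
    ``A(rho, phi) = rho^2 (phi - sin phi)/2`` with opening angles from
    the law of cosines.  Continuous across all three regimes and
    symmetric under swapping the two radii.
    """
    r = np.asarray(r, dtype=float)
    if R <= 0 or sigma <= 0 or np.any(r < 0):
        raise ValueError("A_plus needs non-negative r and positive radii")
    out = np.zeros_like(r)
    small = min(R, sigma)
    contained = r <= abs(R - sigma)
    out[contained] = np.pi * small**2
    lens = (~contained) & (r < R + sigma)
    if np.any(lens):
        rl = r[lens]
        with np.errstate(invalid="ignore"):
            phi0 = 2.0 * np.arccos(
                np.clip((R**2 - sigma**2 + rl**2) / (2.0 * R * rl), -1, 1)
            )
            phi1 = 2.0 * np.arccos(
                np.clip((sigma**2 - R**2 + rl**2) / (2.0 * sigma * rl), -1, 1)
            )
        out[lens] = (
            R**2 * (phi0 - np.sin(phi0)) + sigma**2 * (phi1 - np.sin(phi1))
        ) / 2.0
    return out if np.ndim(r) else float(out)


def _radius_residual(R, kernel, kappa, dom, D, u_bc):
    psi_R = psi_radial(np.array(R), R, kernel)
    if dom == "plane":
        return kappa - float(psi_R)
    psi_D = psi_radial(np.array(D), R, kernel)
    return kappa - u_bc - float(psi_R) + float(psi_D)


def _residual_scan(Rs, kernel, kappa, dom, D, u_bc, n_theta=2048):
    """Vectorised residual over a batch of candidate radii (scan stage)."""
    if not isinstance(kernel, DoGKernel):
        return np.array(
            [_radius_residual(R, kernel, kappa, dom, D, u_bc) for R in Rs]
        )
    theta = (np.arange(n_theta) + 0.5) * (2.0 * np.pi / n_theta)
    ct = np.cos(theta)
    Rs = np.asarray(Rs, dtype=float)[:, None]

    def psi_at(r_eval, C):
        Q2 = Rs**2 + r_eval**2 - 2.0 * Rs * r_eval * ct[None, :]
        out = 0.0
        for a, b, sgn in (
            (kernel.a1, kernel.b1, 1.0),
            (kernel.a2, kernel.b2, -1.0),
        ):
            rho = (b / 2.0) * np.sum(
                np.exp(-Q2 / b) / Q2 * Rs * (r_eval * ct[None, :] - Rs),
                axis=1,
            ) * (2.0 * np.pi / n_theta)
            out = out + sgn * a / np.sqrt(kernel.c * np.pi * b) * rho
        return out + kernel.total_mass() * C

    psi_R = psi_at(Rs, 0.5)
    if dom == "plane":
        return kappa - psi_R
    psi_D = psi_at(np.full_like(Rs, D), 0.0)
    return kappa - u_bc - psi_R + psi_D


def solve_spot_radius(
    kernel: RadialKernel,
    kappa: float,
    domain: Literal["plane", "disc"] = "plane",
    D: float = np.inf,
    u_bc: float = 0.0,
    r_max: float | None = None,
    n_scan: int = 2000,
    eps: float = 1e-3,
    m_max: int = 8,
) -> list[SpotBranch]:
    """All steady spot radii at threshold ``kappa`` (scan plus bisection).

    On a disc the candidate radii live in ``(eps, D - eps)``; on the
    plane in ``(eps, r_max)``.  Each root is polished to 1e-12 and
    returned as a :class:`SpotBranch` carrying its azimuthal spectrum for
    modes ``m = 0..m_max``.
    """
    if domain == "disc" and not np.isfinite(D):
        raise ValueError("disc domain needs a finite radius D")
    hi = (D - eps) if domain == "disc" else (r_max or 20.0)
    Rs = np.linspace(eps, hi, n_scan)
    res = _residual_scan(Rs, kernel, kappa, domain, D, u_bc)
    roots = []
    for i in range(len(Rs) - 1):
        if res[i] == 0.0:
            roots.append(Rs[i])
        elif res[i] * res[i + 1] < 0:
            roots.append(
                brentq(
                    _radius_residual,
                    Rs[i],
                    Rs[i + 1],
                    args=(kernel, kappa, domain, D, u_bc),
                    xtol=1e-12,
                    rtol=8.9e-16,
                )
            )
    merged = []
    for r0 in sorted(roots):
        if not merged or abs(r0 - merged[-1]) > 1e-8:
            merged.append(r0)
    branches = []
    for R in merged:
        br = SpotBranch(
            radius=R,
            kappa=kappa,
            domain=domain,
            D=D,
            u_bc=u_bc,
            kernel=kernel,
            residual=abs(
                _radius_residual(R, kernel, kappa, domain, D, u_bc)
            ),
        )
        spot_spectrum(br, kernel, m_max=m_max)
        branches.append(br)
    return branches


def spot_profile(branch: SpotBranch, r) -> np.ndarray:
    """Radial profile ``q(r)`` of a solved spot (``q(R) = kappa``)."""
    psi_r = psi_radial(np.asarray(r, dtype=float), branch.radius, branch.kernel)
    if branch.domain == "plane":
        return psi_r
    psi_D = psi_radial(np.array(branch.D), branch.radius, branch.kernel)
    return branch.u_bc + psi_r - float(psi_D)


def q_prime_at_R(branch: SpotBranch, kernel: RadialKernel | None = None) -> float:
    """Radial slope of the profile at the spot edge, ``q'(R)``.

    Top hat: closed form ``sigma (w_- - w_+) sqrt(4R^2 - sigma^2) / R``
    (valid for ``sigma < 2R``).  Other kernels use the gradient
    line-integral identity ``grad psi(x) = -oint n(s) w(|x-gamma(s)|) ds``
    evaluated on the spot edge, which collapses to
    ``q'(R) = -R J_1(R, R)`` with ``J_1`` the ``m = 1`` angular weight
    integral — a smooth periodic quadrature, free of the near-edge
    resolution problems a finite difference of ``psi`` would have.  (The
    top-hat closed form is exactly this identity evaluated analytically.)
    """
    kernel = kernel or branch.kernel
    R = branch.radius
    if isinstance(kernel, TopHatKernel):
        s = kernel.sigma
        if s >= 2.0 * R:
            raise ValueError(
                "top-hat q'(R) formula requires sigma < 2R (kernel ring "
                "wider than the spot)"
            )
        return s * (kernel.w_minus - kernel.w_plus) * np.sqrt(4 * R**2 - s**2) / R
    return -R * angular_weight_integral(1, R, R, kernel, n_theta=4096)


def angular_weight_integral(
    m: int,
    R: float,
    r_eval: float,
    kernel: RadialKernel,
    n_theta: int = 1024,
) -> float:
    """``J_m = oint cos(m theta) w(sqrt(r^2 + R^2 - 2 r R cos theta)) dtheta``.

    Smooth kernels use the periodic trapezoid (``n_theta`` nodes).  For a
    top hat evaluated on the spot edge (``r_eval = R``) the integral is
    closed form: the excitatory arc subtends ``theta* = 2 asin(sigma/2R)``
    so ``J_m = 2 (w_+ - w_-) sin(m theta*)/m`` for ``m >= 1`` and
    ``J_0 = 2 (w_+ - w_-) theta* + 2 pi w_-`` (the constant inhibitory
    background survives only at ``m = 0`` and cancels between the two
    evaluation radii of the disc spectrum).
    """
    if m < 0:
        raise ValueError("mode number m must be non-negative")
    if R <= 0:
        raise ValueError("R must be positive")
    if isinstance(kernel, TopHatKernel) and np.isclose(r_eval, R):
        s = kernel.sigma
        if s > 2.0 * R:
            raise ValueError(
                "no root theta*: top-hat reach sigma exceeds the spot "
                "diameter"
            )
        theta_star = 2.0 * np.arcsin(s / (2.0 * R))
        if m == 0:
            return 2.0 * (kernel.w_plus - kernel.w_minus) * theta_star + (
                2.0 * np.pi * kernel.w_minus
            )
        return (
            2.0 * (kernel.w_plus - kernel.w_minus) / m
        ) * np.sin(m * theta_star)
    # midpoint rule: robust for piece-wise constant kernels as well
    theta = (np.arange(n_theta) + 0.5) * (2.0 * np.pi / n_theta)
    dist = np.sqrt(
        np.maximum(r_eval**2 + R**2 - 2.0 * r_eval * R * np.cos(theta), 0.0)
    )
    return float(
        np.sum(np.cos(m * theta) * kernel.evaluate(dist))
        * (2.0 * np.pi / n_theta)
    )


def spot_spectrum(
    branch: SpotBranch,
    kernel: RadialKernel | None = None,
    m_max: int = 8,
) -> np.ndarray:
    """Azimuthal eigenvalues ``lambda_0 .. lambda_m_max`` of a spot.

    The Evans function of mode ``m`` is affine in ``lambda``, so each
    eigenvalue is explicit.  ``stable`` requires every computed
    ``lambda_m < 0`` (tolerance 1e-10); on the plane the ``m = 1``
    translation mode is exactly zero and exempted.
    """
    kernel = kernel or branch.kernel
    R = branch.radius
    qp = q_prime_at_R(branch, kernel)
    if abs(qp) < 1e-14:
        raise ValueError("q'(R) = 0: degenerate spot spectrum")
    lams = np.empty(m_max + 1)
    for m in range(m_max + 1):
        J_RR = angular_weight_integral(m, R, R, kernel)
        J_RD = (
            angular_weight_integral(m, R, branch.D, kernel)
            if branch.domain == "disc"
            else 0.0
        )
        lams[m] = -1.0 + (R / abs(qp)) * (J_RR - J_RD)
    branch.eigenvalues = lams
    considered = np.ones(m_max + 1, dtype=bool)
    if branch.domain == "plane" and m_max >= 1:
        considered[1] = False  # translation mode, exactly zero
    branch.stable = bool(np.all(lams[considered] < STABILITY_TOL))
    return lams
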