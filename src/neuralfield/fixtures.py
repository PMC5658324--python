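"""Programmatic initial conditions: spots, perturbed spots, labyrinth seeds.

All experiments start from synthetic data built here — there is no
external input.  The standard seed for azimuthal-instability runs is a
spot of radius ``R`` whose edge is modulated as
``r(theta) = R (1 + eps cos(m theta))``, realised either as a polygonal
contour (for the interface engine) or as a smoothed-indicator field with
an analytic gradient (for the grid simulators).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .interface2d import Contour

__all__ = [
    "PerturbedSpotSeed",
    "make_perturbed_spot",
    "contour_from_polar",
]


def contour_from_polar(
    r_func: Callable[[np.ndarray], np.ndarray],
    n: int = 256,
    uniform_arclength: bool = True,
    dense_factor: int = 32,
) -> Contour:
    """Sample a polar curve ``r(theta)`` into a closed contour.

    With ``uniform_arclength`` the ``n`` vertices are placed at equal
    arc-length intervals (computed on a dense auxiliary sampling), which
    keeps the periodic-trapezoid line integrals high-order; every vertex
    lies exactly on the curve.
    """
    if not uniform_arclength:
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    else:
        thd = np.linspace(0.0, 2.0 * np.pi, dense_factor * n + 1)
        rd = r_func(thd)
        pts = np.column_stack([rd * np.cos(thd), rd * np.sin(thd)])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        th = np.interp(np.linspace(0.0, s[-1], n, endpoint=False), s, thd)
    r = r_func(th)
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@dataclass
class PerturbedSpotSeed:
    """A spot seed: contour plus matching smoothed field and gradient.

    The field is ``u0 = kappa + amp * tanh((R f(theta) - r)/delta)`` with
    ``f(theta) = 1 + eps cos(m theta)``: its ``kappa``-level set is
    exactly the perturbed circle, the activity saturates to
    ``kappa + amp`` inside and ``kappa - amp`` far outside, and the
    gradient is analytic (what the gradient-formulation simulators and
    the interface engine both consume).
    """

    R: float
    m: int
    eps: float
    kappa: float
    amp: float
    delta: float

    def _f(self, theta):
        return 1.0 + self.eps * np.cos(self.m * theta)

    def radius_at(self, theta):
        return self.R * self._f(theta)

    def contour(self, n: int = 256) -> Contour:
        return contour_from_polar(self.radius_at, n)

    def field(self, X, Y) -> np.ndarray:
        r = np.hypot(X, Y)
        theta = np.arctan2(Y, X)
        return self.kappa + self.amp * np.tanh(
            (self.radius_at(theta) - r) / self.delta
        )

    def gradient(self, X, Y=None):
        """``grad u0``; accepts ``(X, Y)`` arrays or an ``(n, 2)`` stack."""
        if Y is None:
            pts = np.atleast_2d(np.asarray(X, dtype=float))
            gx, gy = self.gradient(pts[:, 0], pts[:, 1])
            return np.column_stack([gx, gy])
        r = np.hypot(X, Y)
        theta = np.arctan2(Y, X)
        arg = (self.radius_at(theta) - r) / self.delta
        pref = self.amp / (self.delta * np.cosh(np.clip(arg, -300, 300)) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_r = np.where(r > 0, 1.0 / r, 0.0)
        fp = -self.eps * self.m * np.sin(self.m * theta)
        gx = pref * (self.R * fp * (-Y * inv_r**2) - X * inv_r)
        gy = pref * (self.R * fp * (X * inv_r**2) - Y * inv_r)
        # the tanh is saturated at the origin, so the gradient vanishes
        gx = np.where(r > 0, gx, 0.0)
        gy = np.where(r > 0, gy, 0.0)
        return gx, gy

    @property
    def enclosed_area(self) -> float:
        """Exact area inside the perturbed edge, ``pi R^2 (1 + eps^2/2)``."""
        if self.m == 0:
            return np.pi * (self.R * (1.0 + self.eps)) ** 2
        return np.pi * self.R**2 * (1.0 + self.eps**2 / 2.0)


def make_perturbed_spot(
    R: float,
    m: int,
    eps: float,
    kappa: float = 0.05,
    amp: float | None = None,
    delta: float | None = None,
) -> PerturbedSpotSeed:
    """Standard azimuthal-instability seed (contour and/or field).

    ``eps`` is the relative edge modulation and must be below 1;
    ``delta`` is the indicator smoothing width (default ``R/6``) and
    ``amp`` the activity contrast (default ``2 kappa``, so the far field
    sits at ``-kappa``, below threshold).
    """
    if eps >= 1.0:
        raise ValueError("relative perturbation eps must be < 1")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if R <= 0:
        raise ValueError("spot radius must be positive")
    return PerturbedSpotSeed(
        R=R,
        m=int(m),
        eps=eps,
        kappa=kappa,
        amp=amp if amp is not None else 2.0 * kappa,
        delta=delta if delta is not None else R / 6.0,
    )
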