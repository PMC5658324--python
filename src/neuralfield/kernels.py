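"""Radially symmetric synaptic connectivity kernels.

Every construction in this package — bump widths, interface velocities,
spot spectra — is built from a radial weight function ``w(r)`` describing
how strongly tissue at distance ``r`` excites (or inhibits) a given point.
Three families are supported:

* ``DoGKernel`` — difference of Gaussians (smooth Mexican hat),

  .. math::
     w(r) = \\frac{1}{\\sqrt{c\\pi}}\\Big[\\frac{a_1}{\\sqrt{b_1}}
     e^{-r^2/b_1} - \\frac{a_2}{\\sqrt{b_2}} e^{-r^2/b_2}\\Big],

* ``TopHatKernel`` — constant excitation ``w_+`` out to radius ``sigma``
  and constant inhibition ``w_-`` beyond (not integrable on the plane),
* ``PwcMexicanHatKernel`` — piece-wise constant Mexican hat: ``w_+`` for
  ``r <= sigma1``, ``w_-`` for ``sigma1 < r <= sigma2``, zero beyond.

Besides the pointwise value each kernel exposes the derived quantities the
interface machinery needs: the radial derivative ``dw/dr``, the planar
total mass :math:`\\mathcal{K} = \\int_{\\mathbb{R}^2} w`, the ring
potential

.. math:: \\varphi(r) = \\frac{1}{r}\\int_\\infty^r x\\,w(x)\\,dx

that converts area integrals of ``w`` into contour line integrals, and the
cumulative radial moment :math:`W(r) = \\int_0^r x\\,w(x)\\,dx` used by the
polygon area-integral quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = [
    "RadialKernel",
    "DoGKernel",
    "TopHatKernel",
    "PwcMexicanHatKernel",
    "kernel_from_dict",
]

_SQRT_PI = np.sqrt(np.pi)


class UnsupportedKernelError(TypeError):
    """Requested quantity is undefined for this kernel family."""


def _check_nonnegative_r(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial argument r must be non-negative")
    return r


class RadialKernel:
    """Abstract radially symmetric connectivity kernel ``w(r)``."""

    family: str = ""

    #: True when w is absolutely integrable on the plane, so that the
    #: total mass and ring potential exist.
    integrable: bool = False

    def __call__(self, r):
        return self.evaluate(r)

    def evaluate(self, r):
        raise NotImplementedError

    def derivative(self, r):
        """Radial derivative ``dw/dr``; errors at jump radii."""
        raise NotImplementedError

    def ring_potential(self, r):
        """phi(r), defined for integrable smooth kernels only."""
        raise UnsupportedKernelError(
            f"ring potential is not available for {self.family!r} kernels"
        )

    def total_mass(self) -> float:
        raise UnsupportedKernelError(
            f"total mass diverges / is unsupported for {self.family!r} kernels"
        )

    def cumulative_moment(self, r):
        """W(r) = integral_0^r x w(x) dx (finite for every family)."""
        raise NotImplementedError

    def integral_1d(self, x):
        """Odd antiderivative ``Psi(x) = integral_0^x w(|t|) dt``.

        Lets 1D synaptic drives over an interval be written as
        ``Psi(x - x1) - Psi(x - x2)`` in closed form.
        """
        raise NotImplementedError

    def jump_radii(self) -> tuple[float, ...]:
        """Radii where w is discontinuous (empty for smooth kernels)."""
        return ()

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        raise NotImplementedError


@dataclass(frozen=True)
class DoGKernel(RadialKernel):
    """Difference-of-Gaussians (smooth Mexican hat) kernel.

    Parameters
    ----------
    a1, a2 : amplitudes of the excitatory / inhibitory Gaussians.
    b1, b2 : squared length scales (must be positive).
    c : positive overall normalisation constant.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    c: float

    family = "dog"
    integrable = True

    def __post_init__(self):
        for name in ("b1", "b2", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def _norm(self) -> float:
        return 1.0 / np.sqrt(self.c * np.pi)

    def evaluate(self, r):
        r = _check_nonnegative_r(r)
        return self._norm * (
            self.a1 / np.sqrt(self.b1) * np.exp(-(r**2) / self.b1)
            - self.a2 / np.sqrt(self.b2) * np.exp(-(r**2) / self.b2)
        )

    def derivative(self, r):
        r = np.asarray(r, dtype=float)
        return self._norm * (
            self.a1 / np.sqrt(self.b1) * (-2.0 * r / self.b1) * np.exp(-(r**2) / self.b1)
            - self.a2 / np.sqrt(self.b2) * (-2.0 * r / self.b2) * np.exp(-(r**2) / self.b2)
        )

    def ring_potential(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("ring potential phi(r) requires r > 0")
        pref = 1.0 / (2.0 * r * np.sqrt(self.c * np.pi))
        return pref * (
            self.a2 * np.sqrt(self.b2) * np.exp(-(r**2) / self.b2)
            - self.a1 * np.sqrt(self.b1) * np.exp(-(r**2) / self.b1)
        )

    def total_mass(self) -> float:
        return np.sqrt(np.pi / self.c) * (
            self.a1 * np.sqrt(self.b1) - self.a2 * np.sqrt(self.b2)
        )

    def cumulative_moment(self, r):
        r = _check_nonnegative_r(r)
        return (
            self.a1 * np.sqrt(self.b1) * (1.0 - np.exp(-(r**2) / self.b1))
            - self.a2 * np.sqrt(self.b2) * (1.0 - np.exp(-(r**2) / self.b2))
        ) / (2.0 * np.sqrt(self.c * np.pi))

    def integral_1d(self, x):
        from scipy.special import erf

        x = np.asarray(x, dtype=float)
        return (
            self.a1 * erf(x / np.sqrt(self.b1))
            - self.a2 * erf(x / np.sqrt(self.b2))
        ) / (2.0 * np.sqrt(self.c))

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": "dog",
            "a1": self.a1,
            "a2": self.a2,
            "b1": self.b1,
            "b2": self.b2,
            "c": self.c,
        }


def _at_jump(r, radii, rtol=1e-12, atol=1e-12):
    r = np.asarray(r, dtype=float)
    hit = np.zeros(r.shape, dtype=bool)
    for rj in radii:
        hit |= np.isclose(r, rj, rtol=rtol, atol=atol)
    return hit


@dataclass(frozen=True)
class TopHatKernel(RadialKernel):
    """Top-hat kernel: ``w_+`` for ``r <= sigma``, ``w_-`` otherwise.

    The inhibitory plateau does not decay, so the total mass and the ring
    potential are undefined; area integrals over bounded regions remain
    available through :meth:`cumulative_moment`.
    """

    w_plus: float
    w_minus: float
    sigma: float

    family = "tophat"
    integrable = False

    def __post_init__(self):
        if self.w_plus <= 0:
            raise ValueError("w_plus must be positive")
        if self.w_minus >= 0:
            raise ValueError("w_minus must be negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def evaluate(self, r):
        r = _check_nonnegative_r(r)
        return np.where(r <= self.sigma, self.w_plus, self.w_minus)

    def derivative(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(_at_jump(r, self.jump_radii())):
            raise ValueError(
                "derivative requested at a jump radius of a piece-wise "
                "constant kernel (distributional)"
            )
        return np.zeros_like(r)

    def cumulative_moment(self, r):
        r = _check_nonnegative_r(r)
        inner = self.w_plus * np.minimum(r, self.sigma) ** 2 / 2.0
        outer = self.w_minus * np.maximum(r**2 - self.sigma**2, 0.0) / 2.0
        return inner + outer

    def integral_1d(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        val = self.w_plus * np.minimum(ax, self.sigma) + self.w_minus * np.maximum(
            ax - self.sigma, 0.0
        )
        return np.sign(x) * val

    def jump_radii(self) -> tuple[float, ...]:
        return (self.sigma,)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": "tophat",
            "w_plus": self.w_plus,
            "w_minus": self.w_minus,
            "sigma": self.sigma,
        }


@dataclass(frozen=True)
class PwcMexicanHatKernel(RadialKernel):
    """Piece-wise constant Mexican hat with compact support.

    ``w_+`` on ``r <= sigma1``, ``w_-`` on ``sigma1 < r <= sigma2`` and zero
    beyond, with ``0 < sigma1 < sigma2``.
    """

    w_plus: float
    w_minus: float
    sigma1: float
    sigma2: float

    family = "pwc_mexican_hat"
    integrable = True

    def __post_init__(self):
        if self.w_plus <= 0:
            raise ValueError("w_plus must be positive")
        if self.w_minus >= 0:
            raise ValueError("w_minus must be negative")
        if not (0 < self.sigma1 < self.sigma2):
            raise ValueError("need 0 < sigma1 < sigma2")

    def evaluate(self, r):
        r = _check_nonnegative_r(r)
        return np.where(
            r <= self.sigma1,
            self.w_plus,
            np.where(r <= self.sigma2, self.w_minus, 0.0),
        )

    def derivative(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(_at_jump(r, self.jump_radii())):
            raise ValueError(
                "derivative requested at a jump radius of a piece-wise "
                "constant kernel (distributional)"
            )
        return np.zeros_like(r)

    def total_mass(self) -> float:
        return np.pi * (
            self.w_plus * self.sigma1**2
            + self.w_minus * (self.sigma2**2 - self.sigma1**2)
        )

    def cumulative_moment(self, r):
        r = _check_nonnegative_r(r)
        inner = self.w_plus * np.minimum(r, self.sigma1) ** 2 / 2.0
        mid = (
            self.w_minus
            * (np.clip(r, self.sigma1, self.sigma2) ** 2 - self.sigma1**2)
            / 2.0
        )
        return inner + mid

    def integral_1d(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        val = self.w_plus * np.minimum(ax, self.sigma1) + self.w_minus * (
            np.clip(ax, self.sigma1, self.sigma2) - self.sigma1
        )
        return np.sign(x) * val

    def jump_radii(self) -> tuple[float, ...]:
        return (self.sigma1, self.sigma2)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": "pwc_mexican_hat",
            "w_plus": self.w_plus,
            "w_minus": self.w_minus,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
        }


_FAMILIES = {
    "dog": DoGKernel,
    "tophat": TopHatKernel,
    "pwc_mexican_hat": PwcMexicanHatKernel,
}


def kernel_from_dict(d: dict[str, Any]) -> RadialKernel:
    """Rebuild a kernel from its :meth:`RadialKernel.to_dict` mapping."""
    d = dict(d)
    family = d.pop("family", None)
    if family not in _FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}")
    return _FAMILIES[family](**{k: float(v) for k, v in d.items()})
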