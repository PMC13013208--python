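"""Pointwise model ingredients of the non-local migration model.

The flux of the non-local interaction is a product of four factors,
``u * p(u) * omega * A{u}``: the density itself, a volume-filling (packing)
function, a mobility coefficient, and the non-local interaction average.
This module holds everything pointwise — the packing forms, logistic
proliferation, the interaction kernel with its normalisation, and the
sensing response ``g`` — while the discrete non-local operator lives in
:mod:`growdom.nonlocal_op`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PackingKind",
    "KernelShape",
    "PackingForm",
    "KernelSpec",
    "ModelParams",
    "packing",
    "proliferation",
    "kernel_value",
    "g",
    "mu_from_unnormalized",
    "mu_to_unnormalized",
]


class PackingKind(str, enum.Enum):
    NONE = "none"            # p(u) = 1, i.e. P = +inf
    LINEAR = "linear"        # p(u) = 1 - u/P (may go negative)
    CLIPPED = "clipped"      # p(u) = max(0, 1 - u/P)


class KernelShape(str, enum.Enum):
    TOP_HAT = "tophat"


@dataclass(frozen=True)
class PackingForm:
    """Volume-filling function ``p(u)`` limiting flux in crowded regions."""

    form: PackingKind = PackingKind.CLIPPED
    P: float = float("nan")  # limiting packing density; ignored for NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", PackingKind(self.form))
        if self.form is not PackingKind.NONE and not self.P > 0:
            raise ValueError(f"limiting packing density P must be positive, got {self.P}")

    def __call__(self, u):
        return packing(u, self)


@dataclass(frozen=True)
class KernelSpec:
    """Interaction kernel ``Omega(|r|) = mu * Omega_tilde(|r|/xi) / xi``.

    ``xi`` is the sensing radius, ``mu`` the signed interaction strength
    (``mu > 0`` attracting, ``mu < 0`` repelling).  The normalised shape
    ``Omega_tilde >= 0`` satisfies ``int_0^xi Omega_tilde(r/xi) dr = xi``,
    so the one-sided kernel integral equals ``mu`` for every shape.
    """

    xi: float
    mu: float
    shape: KernelShape = KernelShape.TOP_HAT

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", KernelShape(self.shape))
        if not self.xi > 0:
            raise ValueError(f"sensing radius xi must be positive, got {self.xi}")
        self._check_normalization()

    def shape_value(self, s):
        """Normalised shape ``Omega_tilde(s)`` for ``s = |r|/xi >= 0``."""
        s = np.asarray(s, dtype=float)
        if self.shape is KernelShape.TOP_HAT:
            out = np.where(s <= 1.0, 1.0, 0.0)
        else:  # pragma: no cover - extension point
            raise NotImplementedError(self.shape)
        return out if out.ndim else float(out)

    def _check_normalization(self) -> None:
        # int_0^xi Omega_tilde(r/xi) dr = xi  must hold for any shape added here
        val, _ = quad(lambda r: self.shape_value(r / self.xi), 0.0, self.xi, limit=200)
        if abs(val - self.xi) > 1e-10 * self.xi:
            raise ValueError(
                f"kernel shape violates normalization: got {val}, expected {self.xi}"
            )

    def __call__(self, r_abs):
        return kernel_value(r_abs, self)

    def rescaled(self, L: float) -> "KernelSpec":
        """Kernel on the unit reference domain: sensing radius ``xi/L``."""
        return KernelSpec(xi=self.xi / L, mu=self.mu, shape=self.shape)


@dataclass(frozen=True)
class ModelParams:
    """All constitutive constants of the single-species model.

    D       diffusion coefficient (length^2/time)
    omega   mobility coefficient of the non-local flux (> 0; the sign of the
            interaction lives in ``kernel.mu``)
    rho     logistic proliferation rate (1/time)
    U       carrying capacity (density)
    """

    D: float
    omega: float
    rho: float
    U: float
    packing: PackingForm = field(default_factory=lambda: PackingForm(PackingKind.NONE))
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec(xi=0.1, mu=0.0))

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be non-negative")
        if self.omega < 0:
            raise ValueError("mobility omega must be non-negative")
        if self.rho < 0:
            raise ValueError("proliferation rate rho must be non-negative")
        if not self.U > 0:
            raise ValueError("carrying capacity U must be positive")


# -- pointwise functions --------------------------------------------------


def packing(u, form: PackingForm):
    """Evaluate the packing function ``p(u)``.

    Negative ``u`` is permitted (it can arise transiently in high-order
    schemes); the linear form may return negative values for ``u > P``.
    """
    u = np.asarray(u, dtype=float)
    if form.form is PackingKind.NONE:
        out = np.ones_like(u)
    elif form.form is PackingKind.LINEAR:
        out = 1.0 - u / form.P
    else:
        out = np.maximum(0.0, 1.0 - u / form.P)
    return out if out.ndim else float(out)


def proliferation(u, params: ModelParams):
    """Logistic source ``rho u (1 - u/U)``; exactly zero when ``rho = 0``."""
    if params.rho == 0.0:
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        return out if out.ndim else 0.0
    u = np.asarray(u, dtype=float)
    out = params.rho * u * (1.0 - u / params.U)
    return out if out.ndim else float(out)


def kernel_value(r_abs, spec: KernelSpec):
    """Kernel ``Omega(|r|) = mu Omega_tilde(|r|/xi)/xi`` at distance ``|r|``."""
    r_abs = np.asarray(r_abs, dtype=float)
    if np.any(r_abs < 0):
        raise ValueError("kernel argument is a distance and must be >= 0")
    out = spec.mu * np.asarray(spec.shape_value(r_abs / spec.xi)) / spec.xi
    return out if out.ndim else float(out)


def g(u):
    """Sensing response: how density at the interaction point acts back.

    Kept as an explicit (identity) extension point; volume-filling variants
    of the sensing response plug in here.
    """
    return u


def mu_from_unnormalized(mu_unnormalized: float, xi: float) -> float:
    """Convert an interaction strength stated in the older *unnormalised*
    kernel convention into the normalised convention used here.

    Part of the non-local literature omits the ``1/xi`` kernel
    normalisation; models agree when the unnormalised strength equals
    ``2 xi mu`` with ``mu`` and ``xi`` as defined here.  Hence
    ``mu = mu_unnormalized / (2 xi)``.
    """
    return mu_unnormalized / (2.0 * xi)


def mu_to_unnormalized(mu: float, xi: float) -> float:
    """Inverse of :func:`mu_from_unnormalized`: ``2 xi mu``."""
    return 2.0 * xi * mu
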