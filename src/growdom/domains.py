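"""Time-dependent 1-D spatial domains under spatially homogeneous growth.

A moving interval ``Omega_t = (l(t), l(t) + L(t))`` is described by a growth
law for its length ``L(t)`` together with a placement rule for its left end
``l(t)``.  Two placements are supported:

* ``Type L`` — left end pinned at the origin, ``l(t) = 0``;
* ``Type S`` — symmetric about the origin, ``l(t) = -L(t)/2``.

Spatially homogeneous domain change means the velocity gradient
``d v / d x = r(t) = Ldot(t)/L(t)`` is independent of ``x``, so the whole
domain stretches uniformly and material points move with ``v(t, x) = r(t) x``
for either placement.  Under this assumption the moving interval maps onto a
fixed unit reference interval by ``xhat = (x - l(t)) / L(t)``, on which the
transformed PDE is actually solved.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthKind",
    "Placement",
    "GrowthLaw",
    "DomainSpec",
]


class GrowthKind(str, enum.Enum):
    FIXED = "fixed"
    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"


class Placement(str, enum.Enum):
    TYPE_L = "L"
    TYPE_S = "S"


@dataclass(frozen=True)
class GrowthLaw:
    """Length law ``L(t)`` of a uniformly stretching 1-D domain.

    Parameters
    ----------
    kind
        One of ``fixed``, ``linear``, ``exponential``, ``logistic``.
    L0
        Initial length ``L(t0) > 0`` (length units).
    alpha
        Growth-rate parameter (1/time).  ``alpha < 0`` (shrinkage) is
        permitted as long as the length stays positive on the time interval
        of interest; ignored for ``fixed``.
    K
        Limiting length of the logistic law (length units); the length
        satisfies the logistic ODE ``Ldot = alpha L (1 - L/K)``.
    """

    kind: GrowthKind = GrowthKind.FIXED
    L0: float = 1.0
    alpha: float = 0.0
    K: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GrowthKind(self.kind))
        if not self.L0 > 0:
            raise ValueError(f"initial length L0 must be positive, got {self.L0}")
        if self.kind is GrowthKind.LOGISTIC and not self.K > 0:
            raise ValueError(f"logistic limiting length K must be positive, got {self.K}")

    def length(self, t, t0: float = 0.0):
        """Domain length ``L(t)``; ``t`` may be a scalar or array."""
        dt = np.asarray(t, dtype=float) - t0
        if self.kind is GrowthKind.FIXED:
            L = self.L0 * np.ones_like(dt)
        elif self.kind is GrowthKind.LINEAR:
            L = self.L0 * (1.0 + self.alpha * dt)
        elif self.kind is GrowthKind.EXPONENTIAL:
            L = self.L0 * np.exp(self.alpha * dt)
        else:  # logistic
            e = np.exp(self.alpha * dt)
            L = self.K * self.L0 * e / (self.K + self.L0 * (e - 1.0))
        if np.any(L <= 0):
            raise ValueError(f"growth law yields non-positive length at t={t}")
        return L if np.ndim(t) else float(L)

    def length_rate(self, t, t0: float = 0.0):
        """Time derivative ``Ldot(t)`` of the length."""
        dt = np.asarray(t, dtype=float) - t0
        if self.kind is GrowthKind.FIXED:
            r = np.zeros_like(dt)
        elif self.kind is GrowthKind.LINEAR:
            r = self.alpha * self.L0 * np.ones_like(dt)
        elif self.kind is GrowthKind.EXPONENTIAL:
            r = self.alpha * self.L0 * np.exp(self.alpha * dt)
        else:  # logistic: Ldot = alpha L (1 - L/K)
            L = self.length(t, t0)
            r = self.alpha * np.asarray(L) * (1.0 - np.asarray(L) / self.K)
        return r if np.ndim(t) else float(r)

    def dilution_rate(self, t, t0: float = 0.0):
        """Relative stretching rate ``r(t) = Ldot(t)/L(t)`` (1/time).

        For homogeneous domain change this is the velocity gradient
        ``d v / d x`` and, with a minus sign, the rate at which domain
        growth dilutes any conserved density.
        """
        return self.length_rate(t, t0) / self.length(t, t0)


@dataclass(frozen=True)
class DomainSpec:
    """A moving interval: growth law, placement and time horizon."""

    growth: GrowthLaw
    placement: Placement = Placement.TYPE_L
    t0: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "placement", Placement(self.placement))
        if not self.T > self.t0:
            raise ValueError(f"need T > t0, got t0={self.t0}, T={self.T}")
        # fail early on laws that collapse within the horizon
        if self.growth.kind is GrowthKind.LINEAR and self.growth.alpha < 0:
            if 1.0 + self.growth.alpha * (self.T - self.t0) <= 0:
                raise ValueError("linear shrinkage reaches zero length before T")

    # -- geometry ---------------------------------------------------------

    def length(self, t):
        return self.growth.length(t, self.t0)

    def length_rate(self, t):
        return self.growth.length_rate(t, self.t0)

    def dilution_rate(self, t):
        return self.growth.dilution_rate(t, self.t0)

    def left_end(self, t):
        """Left end point ``l(t)``: 0 for Type L, ``-L(t)/2`` for Type S."""
        if self.placement is Placement.TYPE_L:
            return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
        return -0.5 * self.length(t)

    def left_end_rate(self, t):
        if self.placement is Placement.TYPE_L:
            return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
        return -0.5 * self.length_rate(t)

    def velocity(self, t, x):
        """Material velocity ``v(t, x) = (Ldot/L) x`` of homogeneous stretching.

        ``x`` must lie inside the closed domain at time ``t``.
        """
        self._check_inside(t, x)
        return self.dilution_rate(t) * np.asarray(x, dtype=float) if np.ndim(x) \
            else self.dilution_rate(t) * float(x)

    # -- reference-domain transform --------------------------------------

    def to_reference(self, t, x):
        """Map a physical position to the reference coordinate.

        Type L maps onto [0, 1] via ``(x - l)/L``; Type S maps onto
        [-1/2, 1/2] via ``x/L``.
        """
        self._check_inside(t, x)
        if self.placement is Placement.TYPE_L:
            return (np.asarray(x, dtype=float) - self.left_end(t)) / self.length(t)
        return np.asarray(x, dtype=float) / self.length(t)

    def from_reference(self, t, xhat):
        """Inverse of :meth:`to_reference`."""
        xhat = np.asarray(xhat, dtype=float)
        lo, hi = (0.0, 1.0) if self.placement is Placement.TYPE_L else (-0.5, 0.5)
        if np.any(xhat < lo - 1e-12) or np.any(xhat > hi + 1e-12):
            raise ValueError(f"reference position outside [{lo}, {hi}]")
        if self.placement is Placement.TYPE_L:
            out = self.left_end(t) + xhat * self.length(t)
        else:
            out = xhat * self.length(t)
        return out if out.ndim else float(out)

    # internal convention: one periodic grid on [0, 1) serves both placements
    def to_internal(self, t, x):
        """Physical position -> internal reference coordinate in [0, 1]."""
        return (np.asarray(x, dtype=float) - self.left_end(t)) / self.length(t)

    def from_internal(self, t, s):
        """Internal reference coordinate in [0, 1] -> physical position."""
        return self.left_end(t) + np.asarray(s, dtype=float) * self.length(t)

    # -- trajectories -----------------------------------------------------

    def back_trajectory(self, t, x):
        """Initial position of the material point that sits at ``x`` at time ``t``.

        Homogeneous stretching preserves the relative position inside the
        domain, giving the closed form ``l(t0) + (x - l(t)) L(t0)/L(t)``.
        For an exponentially growing Type S domain this reduces to the
        growth-discounting factor ``x * exp(-alpha (t - t0))``.
        """
        x = np.asarray(x, dtype=float)
        out = self.left_end(self.t0) + (x - self.left_end(t)) * (
            self.length(self.t0) / self.length(t)
        )
        return out if out.ndim else float(out)

    def forward_trajectory(self, t, x0):
        """Position at time ``t`` of the material point starting at ``x0``."""
        x0 = np.asarray(x0, dtype=float)
        out = self.left_end(t) + (x0 - self.left_end(self.t0)) * (
            self.length(t) / self.length(self.t0)
        )
        return out if out.ndim else float(out)

    # -- helpers ----------------------------------------------------------

    def _check_inside(self, t, x) -> None:
        l = self.left_end(t)
        L = self.length(t)
        x = np.asarray(x, dtype=float)
        tol = 1e-12 * max(1.0, float(np.max(L)))
        if np.any(x < l - tol) or np.any(x > l + L + tol):
            raise ValueError(
                f"position {x} outside domain [{l}, {l + L}] at t={t}"
            )
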