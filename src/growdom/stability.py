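"""Fourier-type linear stability of the aggregation model on a fixed domain.

Linearising the model about a spatially homogeneous state ``u_bar`` on a
fixed periodic domain of length ``L`` (no proliferation, no domain motion)
gives, for a perturbation ``exp(i q x + lambda t)`` with admissible wave
numbers ``q_k = 2 pi k / L``, the dispersion relation for the top-hat
kernel

    lambda(q) = -D q^2 + 2 omega Phi(u_bar) mu (1 - cos(q xi)) / xi .

``Phi`` is the linearised prefactor of the non-local flux.  Since the
non-local average of a constant state vanishes, only the term
``u_bar p(u_bar) * delta A`` survives the linearisation of the implemented
model, i.e. ``Phi = u_bar p(u_bar)`` (``with_packing``).  The variant
``Phi = u_bar`` (``without_packing``) is also provided: it corresponds to
linearising the model without a volume-filling factor, and it is the
package's designated variant for the aggregation case study's reference
threshold and dominant wave numbers; see the methods note for the
discussion.  A positive ``lambda`` at some integer mode signals
pattern formation; the smallest ``mu`` with a non-negative mode is the
instability threshold ``mu_min(L)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .model import KernelShape, ModelParams, packing

__all__ = [
    "PrefactorVariant",
    "DispersionSpec",
    "growth_rate",
    "mu_min",
    "dominant_mode",
    "dispersion_table",
]

#: modes with 1 - cos(q xi) at or below this are resonant (kernel-blind)
RESONANCE_TOL = 1e-14


class PrefactorVariant(str, enum.Enum):
    WITH_PACKING = "with_packing"
    WITHOUT_PACKING = "without_packing"


@dataclass(frozen=True)
class DispersionSpec:
    """A linear-stability query about ``u_bar`` on a fixed domain of length L."""

    L: float
    u_bar: float
    params: ModelParams
    prefactor_variant: PrefactorVariant = PrefactorVariant.WITHOUT_PACKING
    k_max: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prefactor_variant", PrefactorVariant(self.prefactor_variant)
        )
        if not self.L > 0:
            raise ValueError("domain length L must be positive")
        if self.u_bar < 0:
            raise ValueError("homogeneous state u_bar must be non-negative")
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        if self.params.kernel.shape is not KernelShape.TOP_HAT:
            raise NotImplementedError(self.params.kernel.shape)

    @property
    def phi(self) -> float:
        """Linearised flux prefactor ``Phi(u_bar)``."""
        if self.prefactor_variant is PrefactorVariant.WITH_PACKING:
            return self.u_bar * packing(self.u_bar, self.params.packing)
        return self.u_bar

    def wave_number(self, k) -> np.ndarray:
        return 2.0 * np.pi * np.asarray(k) / self.L


def growth_rate(spec: DispersionSpec, k, mu: float | None = None):
    """Growth rate ``lambda(q_k)`` of integer mode(s) ``k >= 1``.

    ``mu`` defaults to the kernel strength in ``spec.params``.
    """
    k = np.asarray(k)
    if np.any(k < 1) or not np.issubdtype(k.dtype, np.integer):
        raise ValueError("mode index k must be a positive integer")
    if mu is None:
        mu = spec.params.kernel.mu
    p = spec.params
    q = spec.wave_number(k)
    lam = (-p.D * q**2
           + 2.0 * p.omega * spec.phi * mu * (1.0 - np.cos(q * p.kernel.xi))
           / p.kernel.xi)
    return lam if lam.ndim else float(lam)


def mu_min(spec: DispersionSpec) -> float:
    """Instability threshold: smallest ``mu > 0`` destabilising some mode.

    Per mode the threshold is ``mu*(q) = D q^2 xi / (2 omega Phi (1-cos(q xi)))``;
    the minimum over ``k = 1..k_max`` is returned.  Resonant modes (where
    the odd top-hat kernel is blind, ``1 - cos(q xi) ~ 0``) are skipped.
    For the top-hat kernel the minimiser is ``k = 1``.
    """
    p = spec.params
    if not (p.D > 0 and spec.u_bar > 0 and p.omega > 0 and spec.phi > 0):
        raise ValueError("mu_min requires D > 0, u_bar > 0, omega > 0, Phi > 0")
    k = np.arange(1, spec.k_max + 1)
    q = spec.wave_number(k)
    denom = 1.0 - np.cos(q * p.kernel.xi)
    ok = denom > RESONANCE_TOL
    if not np.any(ok):
        raise ValueError("all modes up to k_max are resonant for this kernel")
    thresholds = p.D * q[ok]**2 * p.kernel.xi / (2.0 * p.omega * spec.phi * denom[ok])
    return float(np.min(thresholds))


def dominant_mode(spec: DispersionSpec, mu: float | None = None) -> int | None:
    """Integer mode maximising ``lambda(q_k)``; ``None`` if all are damped.

    Ties are broken toward the smaller mode index.
    """
    if mu is None:
        mu = spec.params.kernel.mu
    if mu == 0.0:
        return None
    k = np.arange(1, spec.k_max + 1)
    lam = growth_rate(spec, k, mu)
    if np.max(lam) <= 0.0:
        return None
    return int(k[np.argmax(lam)])  # argmax takes the first, i.e. smallest k


def dispersion_table(spec: DispersionSpec, mu: float | None = None):
    """(k, q_k, lambda) arrays for ``k = 1..k_max``, e.g. for CSV output."""
    k = np.arange(1, spec.k_max + 1)
    return k, spec.wave_number(k), growth_rate(spec, k, mu)
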