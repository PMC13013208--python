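"""Method-of-lines right-hand side of the transformed model.

On the unit reference domain with homogeneous domain change the model reads

    d uhat / dt = -(1/L) d/dxhat ( -(D/L) d uhat/dxhat
                                   + uhat p(uhat) omega A{uhat} )
                  + rho uhat (1 - uhat/U)  -  (Ldot/L) uhat ,

with periodic boundary conditions.  The spatial discretization is a
finite-volume scheme on the uniform reference grid: central differences
for the diffusive flux and an upwind scheme (first order, or van-Leer
limited linear reconstruction) for the non-local advective flux.  The
dilution term ``-(Ldot/L) uhat`` is applied pointwise, which keeps the
semi-discrete mass identity exact:

    d/dt [ L h sum_j uhat_j ] = L h sum_j rho uhat_j (1 - uhat_j / U) .
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .domains import DomainSpec
from .model import ModelParams, packing, proliferation
from .nonlocal_op import NonlocalWeights, ReferenceGrid, apply_nonlocal, build_weights

__all__ = [
    "Limiter",
    "PackingEval",
    "SchemeConfig",
    "SemiDiscreteState",
    "diffusive_interface_flux",
    "advective_interface_flux",
    "RhsAssembler",
]

#: relative change in L beyond which cached weights are rebuilt
WEIGHT_CACHE_RTOL = 1e-14


class Limiter(str, enum.Enum):
    NONE_FIRST_ORDER = "none_first_order"
    VAN_LEER = "van_leer"


class PackingEval(str, enum.Enum):
    UPWIND_WITH_STATE = "upwind_with_state"
    DOWNWIND = "downwind"


@dataclass(frozen=True)
class SchemeConfig:
    limiter: Limiter = Limiter.VAN_LEER
    packing_eval: PackingEval = PackingEval.UPWIND_WITH_STATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "limiter", Limiter(self.limiter))
        object.__setattr__(self, "packing_eval", PackingEval(self.packing_eval))


@dataclass
class SemiDiscreteState:
    """Snapshot of the semi-discrete solution: time and cell averages."""

    t: float
    u_hat: np.ndarray

    def __post_init__(self) -> None:
        self.u_hat = np.asarray(self.u_hat, dtype=float)
        if not np.all(np.isfinite(self.u_hat)):
            raise ValueError("state contains non-finite entries")


def diffusive_interface_flux(u_hat: np.ndarray, grid: ReferenceGrid,
                             D: float, L: float) -> np.ndarray:
    """Central diffusive flux ``-(D/L) (u_{j+1} - u_j)/h`` at interface j."""
    if D == 0.0:
        return np.zeros(grid.N)
    du = np.roll(u_hat, -1) - u_hat
    return -(D / L) * du / grid.h


def _van_leer_slopes(n: np.ndarray) -> np.ndarray:
    """Limited slopes (per cell, in units of one cell) of the advected field."""
    dl = n - np.roll(n, 1)   # n_j - n_{j-1}
    dr = np.roll(n, -1) - n  # n_{j+1} - n_j
    prod = dl * dr
    denom = dl + dr
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where((prod > 0.0) & (denom != 0.0), 2.0 * prod / denom, 0.0)
    return s


def advective_interface_flux(u_hat: np.ndarray, a: np.ndarray,
                             params: ModelParams,
                             scheme: SchemeConfig = SchemeConfig()) -> np.ndarray:
    """Upwind non-local advective flux ``u p(u) a`` at the interfaces.

    ``a`` is the advective velocity factor ``omega * A{uhat}`` evaluated at
    the interfaces.  The advected quantity is ``n(u) = u p(u)``; with the
    van-Leer limiter it is reconstructed linearly within the upwind cell.
    The flux is exactly zero wherever ``a`` vanishes.
    """
    a = np.asarray(a, dtype=float)
    if scheme.packing_eval is PackingEval.UPWIND_WITH_STATE:
        n = u_hat * packing(u_hat, params.packing)
        if scheme.limiter is Limiter.VAN_LEER:
            s = _van_leer_slopes(n)
            n_left = n + 0.5 * s             # value at right face of cell j
            n_right = np.roll(n, -1) - 0.5 * np.roll(s, -1)  # left face of cell j+1
        else:
            n_left = n
            n_right = np.roll(n, -1)
    else:  # DOWNWIND: p evaluated at the cell the flux points into
        p = packing(u_hat, params.packing)
        n_left = u_hat * np.roll(p, -1)
        n_right = np.roll(u_hat, -1) * p
        # limiter not defined for the split evaluation; first order only

    return np.where(a > 0.0, a * n_left, a * n_right)


class RhsAssembler:
    """Assembles ``d uhat / dt`` for a given domain, parameters and grid.

    The circulant non-local weights are cached and rebuilt whenever the
    domain length at the requested stage time has changed by more than a
    relative ``1e-14`` — on a time-dependent domain the rescaled sensing
    radius ``xi/L(t)`` makes the weights time-dependent.
    """

    def __init__(self, domain: DomainSpec, params: ModelParams,
                 grid: ReferenceGrid, scheme: SchemeConfig = SchemeConfig(),
                 *, use_fft: bool | None = None) -> None:
        self.domain = domain
        self.params = params
        self.grid = grid
        self.scheme = scheme
        self.use_fft = use_fft
        self._cached_L: float | None = None
        self._weights: NonlocalWeights | None = None
        self.n_weight_rebuilds = 0

    def weights_for(self, L: float) -> NonlocalWeights:
        if (self._weights is None or self._cached_L is None
                or abs(L - self._cached_L) > WEIGHT_CACHE_RTOL * self._cached_L):
            self._weights = build_weights(self.grid, self.params.kernel, L)
            self._cached_L = L
            self.n_weight_rebuilds += 1
        return self._weights

    def interface_flux(self, t: float, u_hat: np.ndarray) -> np.ndarray:
        """Total flux (diffusive + non-local advective) at all interfaces."""
        L = self.domain.length(t)
        flux = diffusive_interface_flux(u_hat, self.grid, self.params.D, L)
        if self.params.omega != 0.0 and self.params.kernel.mu != 0.0:
            w = self.weights_for(L)
            a = self.params.omega * apply_nonlocal(w, u_hat, use_fft=self.use_fft)
            flux = flux + advective_interface_flux(u_hat, a, self.params, self.scheme)
        return flux

    def __call__(self, t: float, u_hat: np.ndarray) -> np.ndarray:
        u_hat = np.asarray(u_hat, dtype=float)
        L = self.domain.length(t)
        # rejected trial steps of adaptive solvers may probe huge states;
        # let inf/nan propagate silently so the controller can back off
        with np.errstate(over="ignore", invalid="ignore"):
            F = self.interface_flux(t, u_hat)
            div = (F - np.roll(F, 1)) / (L * self.grid.h)
            out = -div + proliferation(u_hat, self.params)
            r = self.domain.dilution_rate(t)
            if r != 0.0:
                out = out - r * u_hat
        return out

    def rhs(self, state: SemiDiscreteState) -> np.ndarray:
        return self(state.t, state.u_hat)
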