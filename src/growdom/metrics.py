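"""Post-processing of simulated trajectories.

Total cell mass, invading-front detection at the half-carrying-capacity
threshold, growth-discounted front positions, and cluster counting for
aggregation patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainSpec, Placement
from .nonlocal_op import ReferenceGrid
from .rhs import SemiDiscreteState

__all__ = [
    "FrontRecord",
    "total_mass",
    "front_position",
    "discounted_front",
    "front_record",
    "count_clusters",
]


@dataclass(frozen=True)
class FrontRecord:
    """Invading-front position at one time, raw and growth-discounted."""

    t: float
    front_x: float | None
    front_x_discounted: float | None


def total_mass(state: SemiDiscreteState, domain: DomainSpec,
               grid: ReferenceGrid) -> float:
    """Total mass ``m(t) = int_domain u dx = L(t) * h * sum_j uhat_j``.

    The cell-average sum is the exact integral of the finite-volume
    reconstruction — no additional quadrature is involved.
    """
    L = domain.length(state.t)
    return float(L * grid.h * np.sum(state.u_hat))


def front_position(state: SemiDiscreteState, domain: DomainSpec,
                   grid: ReferenceGrid, U: float) -> float | None:
    """Position of the right-moving invading front, or ``None``.

    The front is the x-value where the right-moving part of the profile
    crosses the threshold ``U/2``: scanning cell centres from the right
    domain end leftward, the first sign change of ``u - U/2`` is located
    and linearly interpolated in physical coordinates.  For a symmetric
    (Type S) domain only ``x > 0`` is searched.  Returns ``None`` when the
    density never reaches the threshold.
    """
    thr = 0.5 * U
    if not thr > 0:
        raise ValueError("threshold U/2 must be positive")
    u = state.u_hat
    if float(np.max(u)) < thr:
        return None
    x = np.asarray(domain.from_internal(state.t, grid.centers), dtype=float)
    if domain.placement is Placement.TYPE_S:
        sel = x > 0.0
        x, u = x[sel], u[sel]
    d = u - thr
    # rightmost adjacent pair with a sign change (or exact hit)
    for j in range(len(d) - 1, 0, -1):
        if d[j] == 0.0:
            return float(x[j])
        if d[j] * d[j - 1] < 0.0:
            w = d[j - 1] / (d[j - 1] - d[j])
            return float(x[j - 1] + w * (x[j] - x[j - 1]))
    if d[0] == 0.0:
        return float(x[0])
    return None


def discounted_front(t: float, front_x: float | None,
                     domain: DomainSpec) -> float | None:
    """Pull a front position back along the growth trajectories to ``t0``.

    For exponential growth this is ``x * exp(-alpha (t - t0))``; in general
    it is the back-trajectory of the moving domain.  ``None`` propagates.
    """
    if front_x is None:
        return None
    return float(domain.back_trajectory(t, front_x))


def front_record(state: SemiDiscreteState, domain: DomainSpec,
                 grid: ReferenceGrid, U: float) -> FrontRecord:
    fx = front_position(state, domain, grid, U)
    return FrontRecord(t=state.t, front_x=fx,
                       front_x_discounted=discounted_front(state.t, fx, domain))


def count_clusters(state: SemiDiscreteState, grid: ReferenceGrid,
                   threshold: float, min_width: int = 3) -> int:
    """Number of clusters: maximal periodic runs of cells above ``threshold``
    of length at least ``min_width`` cells."""
    if not threshold > 0:
        raise ValueError("cluster threshold must be positive")
    above = state.u_hat > threshold
    n = grid.N
    if above.all():
        return 1
    if not above.any():
        return 0
    # rotate so the sequence starts just after a below-threshold cell,
    # making runs contiguous (no wrap-around split)
    start = int(np.argmin(above))
    rolled = np.roll(above, -start)
    run_starts = np.flatnonzero(np.diff(np.concatenate(([0], rolled.astype(int)))) == 1)
    run_ends = np.flatnonzero(np.diff(np.concatenate((rolled.astype(int), [0]))) == -1)
    lengths = run_ends - run_starts + 1
    return int(np.sum(lengths >= min_width))
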