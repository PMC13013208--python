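"""Experiment configuration, seeded initial conditions, time integration
and the packaged case studies.

The method-of-lines ODE system is integrated with an adaptive solver from
:func:`scipy.integrate.solve_ivp` at strict tolerances (default
``rtol = atol = 1e-7``).  Two families of experiments ship with the
package:

* ``aggregation`` — a self-attracting (``mu > 0``), non-proliferating
  population on a Type L domain of initial length 2, starting from a
  perturbed homogeneous state at a third of the packing density; domain
  growth slows aggregation and selects the number of emerging clusters.
* ``nc`` — neural-crest-style invasion under contact inhibition of
  locomotion, modelled as non-local repulsion (``mu < 0``) with logistic
  proliferation, on a Type S domain of initial length 11 (lengths in mm,
  times in hours), starting from a plated cluster of cells around the
  origin.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .domains import DomainSpec, GrowthKind, GrowthLaw, Placement
from .metrics import count_clusters, front_record, total_mass
from .model import KernelSpec, ModelParams, PackingForm, PackingKind
from .nonlocal_op import ReferenceGrid
from .rhs import RhsAssembler, SchemeConfig, SemiDiscreteState

__all__ = [
    "ICKind",
    "InitialConditionSpec",
    "SolverOptions",
    "SimulationConfig",
    "TrajectoryOutput",
    "initial_state",
    "simulate",
    "case_config",
    "run_case_study",
    "CASE_STUDIES",
]

#: abort when the solution grows by this factor over the initial maximum
BLOWUP_FACTOR = 1e6


class ICKind(str, enum.Enum):
    PERTURBED_CONSTANT = "perturbed_constant"
    INDICATOR = "indicator"
    TABLE = "table"


@dataclass(frozen=True)
class InitialConditionSpec:
    """Seeded initial profile on the initial physical domain.

    ``perturbed_constant``: ``u0 = mean + amplitude * eps(x)`` with i.i.d.
    per-cell noise ``eps ~ Uniform(-1, 1)`` drawn from the run seed.
    ``indicator``: ``u0 = U0`` for ``|x| <= x0`` (Type S), else 0; cells cut
    by the edge receive the exactly covered fraction of ``U0``.
    ``table``: conservative cell averages of the piecewise-linear
    interpolant through user-supplied ``(position, density)`` pairs.
    """

    kind: ICKind = ICKind.PERTURBED_CONSTANT
    mean: float = 0.0
    amplitude: float = 0.0
    U0: float = 0.0
    x0: float = 0.0
    table: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ICKind(self.kind))
        if self.kind is ICKind.PERTURBED_CONSTANT and self.amplitude < 0:
            raise ValueError("perturbation amplitude must be non-negative")


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-7
    atol: float = 1e-7
    method: str = "DOP853"
    max_step: float = float("inf")

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("solver tolerances must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    domain: DomainSpec
    model: ModelParams
    N: int
    ic: InitialConditionSpec
    solver: SolverOptions = field(default_factory=SolverOptions)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    output_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.output_times)
        if not ts:
            ts = (self.domain.t0, self.domain.T)
        if abs(ts[0] - self.domain.t0) > 1e-12:
            ts = (self.domain.t0,) + ts
        if abs(ts[-1] - self.domain.T) > 1e-12:
            ts = ts + (self.domain.T,)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("output_times must be strictly increasing")
        if ts[0] < self.domain.t0 - 1e-12 or ts[-1] > self.domain.T + 1e-12:
            raise ValueError("output_times must lie within [t0, T]")
        object.__setattr__(self, "output_times", ts)

    @property
    def grid(self) -> ReferenceGrid:
        return ReferenceGrid(self.N)


@dataclass
class TrajectoryOutput:
    """Time-stamped solution snapshots plus geometry and run metadata."""

    times: np.ndarray                  # (n_out,)
    states: np.ndarray                 # (n_out, N) cell averages of uhat
    lengths: np.ndarray                # L(t) at output times
    left_ends: np.ndarray              # l(t) at output times
    config: SimulationConfig
    solver_stats: dict

    def state_at(self, i: int) -> SemiDiscreteState:
        return SemiDiscreteState(t=float(self.times[i]), u_hat=self.states[i])

    # -- file output ------------------------------------------------------

    def write_snapshots(self, path: str | Path) -> None:
        """CSV with header ``t,x_hat,x,u``, one block per output time."""
        grid = self.config.grid
        dom = self.config.domain
        with open(path, "w") as f:
            f.write("t,x_hat,x,u\n")
            for i, t in enumerate(self.times):
                xhat = dom.to_reference(t, dom.from_internal(t, grid.centers))
                x = dom.from_internal(t, grid.centers)
                for xh, xx, uu in zip(xhat, x, self.states[i]):
                    f.write(f"{t:.12g},{xh:.12g},{xx:.12g},{uu:.12g}\n")

    def write_metrics(self, path: str | Path, *, cluster_threshold: float | None = None,
                      cluster_min_width: int = 3) -> None:
        """CSV ``t,L,mass,max_u,front_x,front_x_discounted,n_clusters``."""
        grid = self.config.grid
        dom = self.config.domain
        U = self.config.model.U
        with open(path, "w") as f:
            f.write("t,L,mass,max_u,front_x,front_x_discounted,n_clusters\n")
            for i, t in enumerate(self.times):
                st = self.state_at(i)
                m = total_mass(st, dom, grid)
                rec = front_record(st, dom, grid, U)
                fx = "" if rec.front_x is None else f"{rec.front_x:.12g}"
                fd = ("" if rec.front_x_discounted is None
                      else f"{rec.front_x_discounted:.12g}")
                if cluster_threshold is not None:
                    nc = str(count_clusters(st, grid, cluster_threshold,
                                            cluster_min_width))
                else:
                    nc = ""
                f.write(f"{t:.12g},{self.lengths[i]:.12g},{m:.12g},"
                        f"{np.max(st.u_hat):.12g},{fx},{fd},{nc}\n")

    def write_metadata(self, path: str | Path) -> None:
        meta = {
            "config": _config_to_jsonable(self.config),
            "solver_stats": self.solver_stats,
        }
        with open(path, "w") as f:
            json.dump(meta, f, indent=2, default=str)


# -- initial conditions ---------------------------------------------------


def initial_state(config: SimulationConfig,
                  grid: ReferenceGrid | None = None) -> SemiDiscreteState:
    """Cell averages of the initial profile at ``t0`` from the run seed."""
    grid = grid or config.grid
    dom, ic = config.domain, config.ic
    t0 = dom.t0
    if ic.kind is ICKind.PERTURBED_CONSTANT:
        rng = np.random.default_rng(config.seed)
        eps = rng.uniform(-1.0, 1.0, size=grid.N)
        u0 = ic.mean + ic.amplitude * eps
    elif ic.kind is ICKind.INDICATOR:
        if dom.placement is Placement.TYPE_S and not 0 < ic.x0 < dom.length(t0) / 2:
            raise ValueError("indicator half-width x0 must satisfy 0 < x0 < L0/2")
        # exact covered fraction of [c - x0, c + x0] per cell, c = domain centre
        L0, l0 = dom.length(t0), dom.left_end(t0)
        edges_phys = l0 + np.arange(grid.N + 1) * grid.h * L0
        centre = 0.0 if dom.placement is Placement.TYPE_S else l0 + L0 / 2
        lo, hi = centre - ic.x0, centre + ic.x0
        covered = (np.minimum(edges_phys[1:], hi)
                   - np.maximum(edges_phys[:-1], lo)).clip(min=0.0)
        u0 = ic.U0 * covered / (grid.h * L0)
    else:  # TABLE
        u0 = _cell_averages_from_table(ic.table, dom, grid)
    return SemiDiscreteState(t=t0, u_hat=np.asarray(u0, dtype=float))


def _cell_averages_from_table(table, dom: DomainSpec,
                              grid: ReferenceGrid) -> np.ndarray:
    """Exact cell averages of the piecewise-linear interpolant (conservative)."""
    if len(table) < 2:
        raise ValueError("table initial condition needs at least two points")
    pts = np.asarray(sorted(table), dtype=float)
    xs, ys = pts[:, 0], pts[:, 1]
    t0 = dom.t0
    l0, L0 = dom.left_end(t0), dom.length(t0)
    edges = l0 + np.arange(grid.N + 1) * grid.h * L0
    if xs[0] > edges[0] + 1e-12 or xs[-1] < edges[-1] - 1e-12:
        raise ValueError("table does not cover the initial domain")
    # exact antiderivative of the piecewise-linear interpolant at the edges
    seg_int = 0.5 * (ys[1:] + ys[:-1]) * np.diff(xs)
    cum = np.concatenate(([0.0], np.cumsum(seg_int)))

    def antideriv(x):
        i = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, len(xs) - 2)
        dx = x - xs[i]
        slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
        return cum[i] + ys[i] * dx + 0.5 * slope * dx**2

    F = antideriv(edges)
    return np.diff(F) / (grid.h * L0)


# -- time integration -----------------------------------------------------


def simulate(config: SimulationConfig) -> TrajectoryOutput:
    """Integrate the semi-discrete model over ``[t0, T]``.

    The rescaled sensing radius must stay resolvable for the whole run
    (checked up front at the extremal domain lengths); blow-up beyond
    ``1e6`` times the initial maximum aborts the integration.
    """
    grid = config.grid
    dom = config.domain
    assembler = RhsAssembler(dom, config.model, grid, config.scheme)
    # admissibility over the full horizon: weights must build at both extremes
    if config.model.omega != 0.0 and config.model.kernel.mu != 0.0:
        for t_check in (dom.t0, dom.T):
            assembler.weights_for(dom.length(t_check))

    state0 = initial_state(config, grid)
    u0 = state0.u_hat
    cap = BLOWUP_FACTOR * max(1e-300, float(np.max(np.abs(u0))))

    def blowup(t, u):
        return cap - float(np.max(np.abs(u)))

    blowup.terminal = True

    sol = solve_ivp(
        assembler, (dom.t0, dom.T), u0,
        method=config.solver.method,
        rtol=config.solver.rtol, atol=config.solver.atol,
        max_step=config.solver.max_step,
        t_eval=np.asarray(config.output_times),
        events=blowup,
        dense_output=False,
    )
    if sol.status == 1:
        t_reached = float(sol.t_events[0][0]) if len(sol.t_events[0]) else float("nan")
        raise RuntimeError(
            f"solution blow-up detected at t = {t_reached:.6g} "
            f"(|u| exceeded {BLOWUP_FACTOR:g} x initial maximum)"
        )
    if not sol.success:
        t_reached = float(sol.t[-1]) if len(sol.t) else dom.t0
        raise RuntimeError(
            f"time integration failed at t = {t_reached:.6g}: {sol.message}"
        )

    times = sol.t
    states = sol.y.T.copy()
    stats = {
        "nfev": int(sol.nfev),
        "n_weight_rebuilds": assembler.n_weight_rebuilds,
        "method": config.solver.method,
        "rtol": config.solver.rtol,
        "atol": config.solver.atol,
        "message": str(sol.message),
    }
    return TrajectoryOutput(
        times=times,
        states=states,
        lengths=np.asarray([dom.length(t) for t in times]),
        left_ends=np.asarray([dom.left_end(t) for t in times]),
        config=config,
        solver_stats=stats,
    )


# -- packaged case studies ------------------------------------------------

CASE_STUDIES = (
    "aggregation_fixed",
    "aggregation_growing",
    "nc_fixed",
    "nc_growing",
)


def case_config(name: str, *, alpha: float | None = None, mu: float | None = None,
                P: float | None = None, N: int | None = None, seed: int = 0,
                rtol: float | None = None, atol: float | None = None,
                T: float | None = None, method: str | None = None,
                output_every: float | None = None) -> SimulationConfig:
    """Build the configuration of one packaged case study, with overrides.

    ``P=inf`` (or ``P <= 0``) selects the no-packing variant ``p == 1``.
    """
    if name not in CASE_STUDIES:
        raise ValueError(f"unknown case study {name!r}; choose from {CASE_STUDIES}")
    is_agg = name.startswith("aggregation")
    growing_default = 0.1 if is_agg else 0.007
    alpha = (growing_default if name.endswith("growing") else 0.0) if alpha is None else alpha

    if is_agg:
        T = 10.0 if T is None else T
        mu = (1.2 if name.endswith("growing") else 0.8) if mu is None else mu
        P = 0.8 if P is None else P
        N = 1500 if N is None else N
        out_dt = 0.25 if output_every is None else output_every
        dom = DomainSpec(
            growth=GrowthLaw(kind=GrowthKind.EXPONENTIAL, L0=2.0, alpha=alpha),
            placement=Placement.TYPE_L, t0=0.0, T=T,
        )
        params = ModelParams(
            D=1e-3, omega=1.0, rho=0.0, U=1.0,
            packing=_packing_from_P(P),
            kernel=KernelSpec(xi=0.4, mu=mu),
        )
        ic = InitialConditionSpec(kind=ICKind.PERTURBED_CONSTANT,
                                  mean=P / 3 if np.isfinite(P) and P > 0 else 0.8 / 3,
                                  amplitude=1e-3)
    else:
        T = 240.0 if T is None else T
        mu = -1e-3 if mu is None else mu
        P = 1e4 if P is None else P
        N = 2**14 if N is None else N
        out_dt = 24.0 if output_every is None else output_every
        dom = DomainSpec(
            growth=GrowthLaw(kind=GrowthKind.EXPONENTIAL, L0=11.0, alpha=alpha),
            placement=Placement.TYPE_S, t0=0.0, T=T,
        )
        params = ModelParams(
            D=3.6e-4, omega=1.0, rho=0.07, U=1e3,
            packing=_packing_from_P(P),
            kernel=KernelSpec(xi=0.01, mu=mu),
        )
        ic = InitialConditionSpec(kind=ICKind.INDICATOR, U0=1e3, x0=0.05)

    n_out = int(round((T - dom.t0) / out_dt))
    times = tuple(dom.t0 + out_dt * i for i in range(n_out + 1))
    if times[-1] < T:
        times = times + (T,)
    solver = SolverOptions(
        rtol=1e-7 if rtol is None else rtol,
        atol=1e-7 if atol is None else atol,
        method="DOP853" if method is None else method,
    )
    return SimulationConfig(domain=dom, model=params, N=N, ic=ic,
                            solver=solver, output_times=times, seed=seed)


def _packing_from_P(P: float) -> PackingForm:
    if not np.isfinite(P) or P <= 0:
        return PackingForm(PackingKind.NONE)
    return PackingForm(PackingKind.CLIPPED, P=P)


def run_case_study(name: str, out_dir: str | Path | None = None,
                   **overrides) -> TrajectoryOutput:
    """Run one packaged case study and optionally write its output files."""
    config = case_config(name, **overrides)
    traj = simulate(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        thr = None
        if name.startswith("aggregation"):
            P = config.model.packing.P
            thr = P / 2 if np.isfinite(P) else None
        traj.write_snapshots(out / f"{name}_snapshots.csv")
        traj.write_metrics(out / f"{name}_metrics.csv", cluster_threshold=thr)
        traj.write_metadata(out / f"{name}_run.json")
    return traj


# -- config (de)serialisation --------------------------------------------


def _config_to_jsonable(config: SimulationConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, enum.Enum):
            return obj.value
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (YAML/JSON file)."""
    d = raw["domain"]
    growth = d.get("growth", {})
    dom = DomainSpec(
        growth=GrowthLaw(
            kind=growth.get("kind", "fixed"),
            L0=float(growth.get("L0", 1.0)),
            alpha=float(growth.get("alpha", 0.0)),
            K=float(growth.get("K", float("nan"))),
        ),
        placement=d.get("placement", "L"),
        t0=float(d.get("t0", 0.0)),
        T=float(d["T"]),
    )
    m = raw["model"]
    pk = m.get("packing", {"form": "none"})
    kn = m["kernel"]
    params = ModelParams(
        D=float(m["D"]), omega=float(m["omega"]),
        rho=float(m.get("rho", 0.0)), U=float(m.get("U", 1.0)),
        packing=PackingForm(pk.get("form", "none"), P=float(pk.get("P", float("nan")))),
        kernel=KernelSpec(xi=float(kn["xi"]), mu=float(kn["mu"]),
                          shape=kn.get("shape", "tophat")),
    )
    ic_raw = raw["ic"]
    ic = InitialConditionSpec(
        kind=ic_raw.get("kind", "perturbed_constant"),
        mean=float(ic_raw.get("mean", 0.0)),
        amplitude=float(ic_raw.get("amplitude", 0.0)),
        U0=float(ic_raw.get("U0", 0.0)),
        x0=float(ic_raw.get("x0", 0.0)),
        table=tuple((float(a), float(b)) for a, b in ic_raw.get("table", ())),
    )
    sv = raw.get("solver", {})
    solver = SolverOptions(
        rtol=float(sv.get("rtol", 1e-7)), atol=float(sv.get("atol", 1e-7)),
        method=sv.get("method", "DOP853"),
        max_step=float(sv.get("max_step", float("inf"))),
    )
    sc = raw.get("scheme", {})
    scheme = SchemeConfig(limiter=sc.get("limiter", "van_leer"),
                          packing_eval=sc.get("packing_eval", "upwind_with_state"))
    return SimulationConfig(
        domain=dom, model=params, N=int(raw["grid"]["N"]), ic=ic,
        solver=solver, scheme=scheme,
        output_times=tuple(float(t) for t in raw.get("output_times", ())),
        seed=int(raw.get("seed", 0)),
    )
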