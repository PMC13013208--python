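# Methods

## Model

`growdom` simulates a single cell population with density `u(t, x)` on a
time-dependent interval `Omega_t = (l(t), l(t) + L(t))` with periodic
boundary conditions:

    du/dt = -d/dx ( u v  -  D du/dx  +  u p(u) omega A{u} )  +  rho u (1 - u/U) .

The three fluxes are advection by the domain-change velocity `v`, Fickian
diffusion with coefficient `D`, and a non-local interaction flux.  The
non-local average

    A{u}(x) = int_{-xi}^{xi} sign(r) * Omega(|r|; xi, mu) * g(u(x + r)) dr

converts the density within the sensing radius `xi` into a directed
velocity: attracting for `mu > 0` (cell–cell adhesion), repelling for
`mu < 0` (contact inhibition of locomotion).  The kernel is normalised so
that its one-sided integral equals `mu` for any shape; the only shape
currently implemented is the top hat `Omega = mu/xi` on `[0, xi]`.  The
sensing response `g` is the identity, routed through one call site as an
extension point for volume-filling variants.  The packing (volume-filling)
function `p(u)` throttles the flux in crowded regions; available forms are
`p = 1`, the linear `1 - u/P`, and the clipped `max(0, 1 - u/P)` used in
all shipped case studies.

### Moving domain and reference transform

Only *spatially homogeneous* domain change is supported: the velocity
gradient `dv/dx = r(t) = Ldot/L` is independent of `x`, so `v = r(t) x`
for both supported placements (Type L, left end pinned at 0; Type S,
symmetric about 0).  Length laws: fixed, linear `L0 (1 + alpha (t - t0))`,
exponential `L0 exp(alpha (t - t0))`, and logistic (the solution of
`Ldot = alpha L (1 - L/K)`).  Shrinking domains (`alpha < 0`) are allowed
as long as `L` stays positive on the horizon; a linear law that collapses
before `T` is rejected at configuration time.

The change of variables `xhat = (x - l(t)) / L(t)` maps the problem to the
fixed unit interval, where the equation becomes

    duhat/dt = -(1/L) d/dxhat ( -(D/L) duhat/dxhat + uhat p(uhat) omega Ahat{uhat} )
               + rho uhat (1 - uhat/U)  -  (Ldot/L) uhat ,

picking up the dilution source `-(Ldot/L) uhat` and a *time-dependent*
rescaled sensing radius `xihat(t) = xi / L(t)` inside the transformed
non-local term.  Internally one periodic grid on `[0, 1)` serves both
placements (Type S is shifted by +1/2); all user-facing coordinates are
reported in the placement's own convention.  Material trajectories have
the closed form `x(t; x0) = l(t) + (x0 - l(t0)) L(t)/L(t0)`, which for
exponential Type S growth reduces to the discount factor
`x0(t, x) = x exp(-alpha (t - t0))` used by the front metrics.

## Discretization

Finite volumes on a uniform periodic reference grid of `N` cells of width
`h = 1/N`; cell `j` is `[jh, (j+1)h)` and interface `j` separates cells
`j` and `j+1`.  The method of lines ODE system is closed by:

* **Diffusion** — central difference `-(D/L)(u_{j+1} - u_j)/h`, second
  order.
* **Non-local term** — the integral against the piecewise-constant
  reconstruction is evaluated *exactly* for the top-hat kernel: at each
  interface it is a signed sum over the `m = floor(xihat/h)` fully covered
  cells per side plus the fraction `theta = xihat/h - m` of one partial
  cell.  The partial cell contributes the plain fraction `theta` of its
  average (midpoint-exact for piecewise-constant data); no sub-cell
  reconstruction is attempted.  The sum is a circulant matrix–vector
  product: the first column is rebuilt in O(N) whenever `L` changes by
  more than a relative 1e-14 (every right-hand-side evaluation on a
  growing domain), and the product is an O(N log N) real FFT.  A direct
  O(N·m) summation ships alongside as the oracle and the default path for
  `N < 64`.  A coverage ratio `xihat/h` within 1e-9 of an integer is
  snapped to it so that exactly aligned radii have `theta = 0`.
  Admissibility is enforced, not warned: `xihat < h` ("sensing radius
  unresolved by grid") and `2 xihat >= 1` ("sensing region wraps domain")
  raise errors, checked up front for the whole time horizon.
* **Non-local advection** — upwinding on the advected quantity
  `n(u) = u p(u)` with the interface velocity `a = omega * Ahat`.  Default
  is van-Leer-limited linear reconstruction of `n` in the upwind cell;
  `none_first_order` selects plain upwind sampling.  The alternative
  `packing_eval = "downwind"` evaluates `p` at the receiving cell
  (blocking inflow into saturated regions) and is first-order only.  The
  flux is exactly zero where `a = 0`.
* **Dilution** — applied pointwise, never folded into a flux.  This makes
  the semi-discrete mass identity exact:
  `d/dt [L h sum_j u_j] = L h sum_j rho u_j (1 - u_j/U)`, i.e. exact mass
  conservation for `rho = 0` up to time-integration error.

Spatial accuracy (verified by grid-doubling tests): order 2 for
diffusion-dominated problems, about 1.5–2 for advection-dominated smooth
profiles with the van Leer limiter, 1 with first-order upwinding.

## Time integration

The MOL system is integrated with an adaptive explicit Runge–Kutta method
(`scipy.integrate.solve_ivp`, DOP853 by default) at `rtol = atol = 1e-7`.
At the shipped resolutions the problems are advection/diffusion-CFL
limited rather than severely stiff, so a high-order explicit method with
automatic step control is efficient and keeps the right-hand side the
only model-specific code; any adaptive integrator passing the
tolerance-halving and grid-refinement checks is acceptable, and the
method is a configuration field.  Blow-up (`max|u|` exceeding 1e6 times
its initial value) terminates the run with a diagnostic.  Rerunning a
configuration with the same seed reproduces trajectories bitwise.

## Linear stability

For the aggregation model about a homogeneous state `u_bar` on a *fixed*
periodic domain of length `L`, perturbations `exp(i q x + lambda t)` with
`q_k = 2 pi k / L` obey, for the top-hat kernel,

    lambda(q) = -D q^2 + 2 omega Phi mu (1 - cos(q xi)) / xi .

Two choices of the linearised flux prefactor `Phi` are implemented behind
a flag.  Linearising the implemented model (flux `u p(u) omega A`) gives
`Phi = u_bar p(u_bar)` (`with_packing`); the centered-difference Jacobian
of the semi-discrete right-hand side matches this variant to better than
1% on the first ten modes.  The variant `Phi = u_bar`
(`without_packing`) corresponds to linearising without the volume-filling
factor; it is the package default for the aggregation threshold/mode
tables because it is the variant that reproduces the reference values for
that case study (threshold 0.011 at `L = 2`; dominant modes 3 and 6 at
`L = 2 e^0.3` and `2 e^0.8` with `mu = 1.2`, where `with_packing` gives
0.0161 and 5).  Both variants are always computable and reported; neither
is hidden.  Per-mode thresholds `mu*(q) = D q^2 xi / (2 omega Phi
(1 - cos(q xi)))` skip resonant modes with `1 - cos(q xi) <= 1e-14`; for
the top hat the minimum sits at `k = 1`.  The dominant wave number is the
integer argmax of `lambda(q_k)`, ties broken toward smaller `k`, `None`
if every mode is damped.

## Case studies and the seeded initial conditions

* **Aggregation** (`aggregation_fixed`, `aggregation_growing`): Type L,
  `L0 = 2`, `T = 10`, `D = 1e-3`, `omega = 1`, clipped packing with
  `P = 0.8`, `xi = 0.4`, no proliferation, `N = 1500`, snapshots every
  0.25 time units.  Growth rate `alpha = 0.1` for the growing variant
  (final length ≈ 5.44); interaction strength defaults 0.8 (fixed) and
  1.2 (growing).  Initial condition: `P/3` plus i.i.d. per-cell noise,
  uniform on `(-amplitude, amplitude)` with `amplitude = 1e-3`, drawn
  from the run seed.  Per-cell noise is a declared reading of a
  "uniformly distributed spatial perturbation"; a band-limited random
  field is the other reading, and the choice shifts the pattern-onset
  time (per-cell noise seeds each Fourier mode at ~1e-5, so visible
  aggregation starts about one time unit later than with mode-amplitude
  1e-3 noise).
* **Neural-crest invasion** (`nc_fixed`, `nc_growing`): Type S,
  `L0 = 11` mm, `T = 240` h, `D = 3.6e-4`, `omega = 1`, clipped packing
  with `P = 1e4`, `xi = 0.01`, `mu = -1e-3` (repulsion), `rho = 0.07`,
  `U = 1e3`, indicator initial condition of height `U` on `|x| <= 0.05`
  (exact cell averages, partially covered edge cells included), snapshots
  every 24 h.  `alpha = 0.007` for the growing variant (final length
  ≈ 59).  Default grid `N = 2^14` ≈ 15 cells per sensing radius at the
  final length; the test suite exercises these runs at `N = 2^13`, the
  coarsest power of two that resolves `xi/L(T)`, where front positions
  agree with finer grids to within one coarse cell (grid-doubling test).

The front metric scans cell centres from the right domain end leftward
(Type S: only `x > 0`) for the first crossing of `U/2` and interpolates
linearly; `None` is returned while the density is everywhere below the
threshold.  Cluster counting reports maximal periodic runs of cells above
a threshold (default `P/2`) of at least `min_width = 3` cells, which
suppresses single-cell noise while counting the plateau-shaped aggregates
of the attraction model.

## What the synthetic experiments do and do not show

All inputs are generated (no external data): the perturbed-homogeneous
and indicator initial states are idealisations, the noise is spatially
white, parameters are the dimensionless/benchmark values of the two case
studies.  Passing tests therefore demonstrate correctness of the
numerics and reproduction of the benchmark behaviours — not biological
calibration.  Known limitations:

* Spatially heterogeneous domain change (x-dependent velocity gradient),
  velocities defined by their own PDE, and dimensions above one are out
  of scope; the weight structure would lose circulancy.
* Stability analysis is for fixed domains only; on growing domains it is
  used in a frozen-domain sense.
* In the growing aggregation run the three-cluster pattern (onset
  t ≈ 5–7, plateau at `P`) is robust across seeds, but the later
  transition to six clusters is not: inter-cluster troughs drain to
  ~1e-3·P before the cluster spacing exceeds the sensing diameter, so
  at the stated noise amplitude only some seeds grow a fourth cluster by
  `t = 10`.  The corresponding pattern-sequence tests document this gap.
* The limiter and reconstruction details of upwind FV schemes for
  non-local taxis-like fluxes vary between implementations; exact curve
  shapes at cluster edges are scheme-dependent even when the integral
  metrics (mass, thresholds, front positions) are converged.
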