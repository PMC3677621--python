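# Methods

## Model

`seirvax` implements a four-compartment SEIR epidemic model in which the
latent class transmits, and susceptibles are vaccinated with a partially
effective vaccine.  In absolute counts, with inflow `b`, outflow `d`,
disease-induced mortality `α`, recovery `γ`, progression `ε`, vaccination
rate `a` and vaccine efficacy `σ`:

    S' = bN − F(S, E, I) − (σa + d) S
    E' = F(S, E, I) − (d + ε) E
    I' = εE − (α + γ + d) I
    R' = σa S + γI − dR

where the incidence splits into unvaccinated and vaccinated-but-unprotected
contributions,

    F = βS(1 − a)(I + qE)/N + βaS(1 − σ)(I + qE)/N = βS(1 − σa)(I + qE)/N,

and `q` is the relative infectiousness of the latent class.  Because the two
vaccination parameters enter only through the product `σa`, the `Parameters`
type carries `sigma_a` as its primary field; `sigma`, `a` and `d` are needed
only by the absolute system.

Normalising by the (non-constant) population size `N` (which obeys
`N' = (b − d)N − αI`) gives the reduced system in proportions `(s, e, i)`:

    s' = b − βs(1 − σa)(i + qe) − (σa + b)s + αsi
    e' = βs(1 − σa)(i + qe) − (b + ε)e + αei
    i' = εe − (α + γ + b)i + αi²

studied on the simplex `T = {s, e, i ≥ 0, s + e + i ≤ 1}`.  The reduced
right-hand side is evaluated exactly as written everywhere — feasibility is a
flag on states, never an enforcement, so that solvers can explore and
infeasible fixed points can be represented.  All rates are "per unit time";
the toolkit is unit-agnostic.

## Thresholds

    R01 = β(1 − σa)(q(α + γ + b) + ε) / [(b + ε)(α + b + γ)]
    R0  = R01 · b/(σa + b)

`R0 < 1` gives local stability of the disease-free equilibrium
`P0 = (b/(σa + b), 0, 0)`; `R01 ≤ 1` upgrades this to global stability via a
linear Lyapunov function (below).  `R01 ≥ R0` always, with equality only
without vaccination.

### The endemic-existence quantity Δ

The published closed form for Δ is internally inconsistent, and the package
therefore exposes three readings.

Setting the three reduced equations to zero and eliminating `e` and `s`
leaves a scalar residual in `i` whose denominator-cleared form is
`f(i) − g(i)` with

    f(i)  = f1(i) · (b + ε − αi)(α + γ + b − αi)
    f1(i) = −(αqβ(1−σa)/ε) i² + (β(1−σa)(ε + q(α+γ+b))/ε − α) i + (σa + b)
    g(i)  = bβ(1−σa) [q(α + γ + b) + ε − αq i].

(The published `f1` flips the signs of the `(σa + b)` and `αi` terms, a
propagation of a sign error in its equilibrium relations; the version above
follows from the equations of the model directly, and its roots reproduce the
benchmark endemic point to printed precision.)

* `delta_ratio` (authoritative) — the intersection ratio of the two curves at
  `i = 0`: `g(0)/f(0)`, which algebraically equals `R0`.  For `b ≥ α` one can
  show `f(1) > g(1)` always (see below), so by the intermediate value theorem
  a feasible endemic root exists in `(0, 1)` precisely when `g(0) > f(0)`,
  i.e. when `delta_ratio > 1`.  This is the quantity used in all theorem
  checks.
* `delta_endpoint` (diagnostic) — the endpoint ratio `f(1)/g(1)` suggested by
  the published identity `f(1) = Δ·g(1)`.  It cannot serve as an existence
  threshold: with `b ≥ α` every term of `f1(1)` is nonnegative and

      f(1)/g(1) ≥ [β(1−σa)(ε + q(γ+b))/ε] (b + ε − α)(γ + b) / [bβ(1−σa)(ε + q(γ+b))]
                ≥ ε(γ + b)/(εb) = (γ + b)/b > 1,

  so it exceeds 1 unconditionally in the theorem's own regime.
* `delta_printed` (diagnostic) — the published closed form, read with
  `γ/b + 1` as its second factor.  The flattened `γb + 1` reading evaluates
  to ≈ 0.996 for the benchmark rates, contradicting the endemic point that
  demonstrably exists there, so the `γ/b + 1` reading is used.

For the benchmark rates: `delta_ratio = 9.9798…` (= R0),
`delta_endpoint = 278.18`, `delta_printed = 299.86`.

### Theorem hypothesis sets

`check_theorems` evaluates, with strict inequalities and `delta_ratio` for Δ:
local disease-free stability (`R0 < 1`), global disease-free stability
(`R01 ≤ 1`), endemic existence/uniqueness (`b ≥ α` and `Δ > 1`), and endemic
global stability (`b ≥ α`, `Δ > 1`, `R01 > 1`, `α < min{σa, b, ε}`).
Boundary cases (e.g. `R01 = 1`) report a theorem as not applying.

## Equilibria

The disease-free point is returned in closed form.  Endemic candidates come
from the scalar reduction

    e(i) = i(α + γ + b − αi)/ε
    s(i) = e(i)(b + ε − αi) / [β(1−σa)(i + q e(i))]
    h(i) = e(i)(b + ε − αi) + s(i)(σa + b − αi) − b

with `h(i) = 0` iff `(s(i), e(i), i)` is an equilibrium.  `q` is kept general
throughout.  Root-finding scans a uniform grid (default 10⁴ points) for sign
changes and refines each bracket with Brent's method to `|Δi| < 1e-14`; this
is robust against the near-flat residual produced by small rates.  Every
candidate is validated against the full vector field (max-norm < 1e-9),
which removes the spurious sign changes at the pole of `s(i)` where
`i + q e(i) = 0`.

`solve_endemic` returns only roots whose full state lies in `T`: in the
below-replacement regime `b < α` the scalar equation can have roots in
`(0, 1)` whose back-substituted `s` exceeds 1 (or `e` does), which are not
endemic states.  Those branch points remain visible through
`find_all_equilibria`, which censuses an arbitrary finite `i`-interval and
flags records outside `T` as infeasible.  Several *feasible* roots — which
would contradict the uniqueness theorem — raise an error listing them all
rather than returning an arbitrary one.

Local stability is read off the Jacobian spectrum with tolerance 1e-9 on the
largest real part; "marginal" is an explicit third outcome.

For the benchmark parameter set the census over `i ∈ (0, 30)` finds, besides
the disease-free point and the feasible endemic point, three infeasible
branch points (i ≈ 2.503, 25.005, 26.505, with negative `e` or `s + e + i` far
above 1).  The benchmark study's third reported fixed point
(0.0000083926, 0.025, 24.7973) does not satisfy the equilibrium equations
under any component ordering tried; it is represented nowhere and used for
nothing.

## Stability certificates

Both certificates are finite-horizon numerical diagnostics of the
inequalities underlying the analytical arguments — not proofs.

**Lyapunov.**  `L = (α + γ + b)e + β(1−σa)i` with orbital derivative
evaluated through the vector field.  Differentiating the model gives

    L' = β(1−σa) i [(α+γ+b)(s − 1) + αi] + e(α+γ+b)[qβ(1−σa)s − (b+ε) + αi] + εβ(1−σa)e.

On `T`, `(α+γ+b)(1−s) ≥ (α+γ+b)(e+i)` bounds the `i`-bracket by
`−β(1−σa)(α+γ+b) ei`, and provided `β(1−σa) ≥ α` that slack absorbs the
`+αei` term of the `e`-bracket, yielding

    L' ≤ e(α+γ+b)(b+ε)(R01 − 1).

The proviso matters: the published derivation carries the `αi` term with the
wrong sign and claims the bound unconditionally, but for sampled parameter
sets with `β(1−σa) < α` (disease mortality dominating transmission) `L`
genuinely increases along stretches of trajectory even with `R01 < 1`.  The
descent and convergence tests therefore sample within the validity regime
`β(1−σa) ≥ α`, and the docstrings state the condition.

**Lozinskii (Li–Muldowney).**  Along interior trajectories the Lozinskii
measure of the weighted second additive compound of the Jacobian is bounded
by `sup(g1, g2)` with

    g1 = e'/e − β(1−σa)(i + qe) − (σa + b) + 2αi
    g2 = e'/e + 2αi − b − min{σa, ε}.

Since `i ≤ 1` on `T`, `g1 ≤ e'/e − (σa + b − 2α)` and
`g2 ≤ e'/e − (b + min{σa, ε} − 2α)`, so the implemented margin is

    m = min{σa + b − 2α,  b + min{σa, ε} − 2α},

positive under the endemic-side conditions.  The published margin uses `max`,
for which the pointwise bound fails whenever the two margins differ; the
`max` value is still reported (`margin_printed`) for transparency.  The
asymptotic time-average statement is checked only in finite-horizon form,

    (1/t)∫ sup(g1, g2) ds + m ≤ (1/t)∫ (e'/e) ds,

with both integrals evaluated by the same trapezoid rule so that the
pointwise bound implies the discrete inequality at any sampling density.
Samples with `e ≤ 1e-12` or `i ≤ 0` are rejected (domain error), never
regularized.

## Simulation and oscillation detection

Integration uses adaptive RK45 (`scipy.integrate.solve_ivp`) with
`rtol = 1e-8`, `atol = 1e-10` by default; the benchmark rates span 1e-5 to
5e-2 — wasteful for fixed steps but not stiff, and LSODA is available via
`method=`.  States are never projected onto `T`; excursions beyond 1e-6 are
logged as warnings.

Oscillations in `i(t)` are classified by peak analysis
(`scipy.signal.find_peaks`): peaks must exceed the trajectory mean by a
prominence fraction (default 1% of the `i` range); with ≥ 3 peaks the ratio
of last to first peak amplitude about the mean decides "sustained"
(within [0.9, 1.1]) versus "damped" (< 0.9); anything else, including growing
ripples and pure numerical noise near an equilibrium, is "none".  These
thresholds are tool conventions — the benchmark study states no quantitative
criterion.  The detector is validated on synthetic signals of known period
(recovered within 2%) rather than against the study's figures, whose initial
conditions and horizon are not stated; `run_reference_scenario` therefore
requires the horizon and initial state as arguments.

For the benchmark set the endemic point's leading eigenvalues are
−5.28e-5 ± 6.98e-4 i: a stable spiral with period ≈ 9.0e3 and decay time
≈ 1.9e4 time units.  Trajectories from generic starts show a large outbreak
followed by damped ringing into the endemic point — consistent with
transient, not sustained, oscillation.

## Random parameter sampling

Property suites draw rates log-uniformly on [1e-5, 1] (the span of the
benchmark rates) and `q` uniformly on [0, 1], with named constraints
(`R01<1`, `R01>1`, `b>=alpha`, `theorem4`) enforced by rejection sampling
capped at 1e5 draws; all draws are pure functions of the seed.

## Problem sizes and numerical defaults

Default endemic grid 10⁴ points (2×10⁴ for the census), Brent refinement to
1e-14; stability tolerance 1e-9; equilibrium residual tolerance 1e-9
(max-norm of the vector field); certificate slack 1e-9 pointwise and 1e-6 on
time averages.  The test suites use 300 parameter sets for the
threshold–eigenvalue sign check, 200 for endemic uniqueness, 20 trajectories
for Lyapunov descent, 50 matrices for the compound-eigenvalue oracle, and 5
endemic-side sets (10 interior starts for attractor convergence), with
integration horizons scaled as `50/min(b + ε, σa + b)` on the disease-free
side (the `s`-component relaxes at rate `σa + b`, so shorter horizons would
test nothing) and `40/|Re λ_max|` on the endemic side.

## What the synthetic benchmark does and does not show

The benchmark scenario and the sampled parameter sets exercise the model's
mathematical structure: thresholds, equilibrium geometry, spectra and
certificate inequalities.  They do not emulate features of real epidemic
data — seasonality, reporting noise, time-varying contact rates, age
structure, demographic stochasticity — so passing tests validate the
implementation of this model, not the model's fit to any real outbreak.

## Known limitations

* Certificates are trajectory diagnostics; they cannot establish global
  stability, only corroborate or refute it numerically.
* The below-replacement regime `b < α` can fold the endemic branch
  (multiple infeasible roots); the census handles it, but no stability
  theory is claimed there.
* No bifurcation tracking, age structure, stochastic variants or
  time-varying parameters.
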