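# Methods

## Model and assumptions

The state is a triple of dimensionless population densities: prey `X`,
predator type I `Y`, predator type II `Z`. Each species has logistic
growth/death/self-limitation; the predators additionally gain (and the prey
loses) from bilinear predation `XY`, `XZ` and from the cubic mating-period
terms `XY²`, `XZ²`, which model a male-female pair of the same predator
species feeding jointly on one prey. The two predator species never
interact directly — the Jacobian entries coupling `Y` and `Z` are
identically zero — and the model is symmetric under exchanging the two
predator species together with their rates, a property the test suite
checks. All rates are nonnegative; construction rejects anything else.

**Positivity.** Each equation has the form `w' = w·g(X,Y,Z)`, so
`w(t) = w(0)·exp(∫g)` keeps nonnegative initial data nonnegative.

**Boundedness.** Adding the three equations cancels all interaction terms
and yields `(X+Y+Z)' = (β₁−β₂)X − β₃X² + (β₈−β₉)Y − β₁₀Y² + (β₁₁−β₁₂)Z −
β₁₃Z²`, which with `γ₁ = max(β₁−β₂, β₈−β₉, β₁₁−β₁₂)` and
`γ₂ = min(β₃, β₁₀, β₁₃)` gives an asymptotic bound `γ₁/γ₂` per component.
`boundedness_certificate` reports γ₁, γ₂ and the bound and is marked
applicable only when growth strictly exceeds death for all three species
and γ₂ > 0; for γ₂ = 0 the bound is NaN and no division is performed.
The Monte-Carlo check asserts the bound asymptotically (over t ∈ [50, 100],
with +0.1 slack), not as an invariant region at all times, because a
trajectory starting inside the box can transiently overshoot it.

## Equilibria and stability

The axial equilibria are `P₁ = (0, (β₈−β₉)/β₁₀, (β₁₁−β₁₂)/β₁₃)`,
`P₂ = (0, 0, (β₁₁−β₁₂)/β₁₃)`, `P₃ = (0, (β₈−β₉)/β₁₀, 0)`,
`P₄ = ((β₁−β₂)/β₃, 0, 0)`, plus the trivial point. A point is admissible
when all coordinates are finite and nonnegative; a point whose defining
self-limitation rate is zero is omitted with a logged notice rather than an
exception. The interior (coexistence) equilibrium is deliberately not
computed — in the regimes of interest it has negative coordinates — and its
exclusion is logged.

**Local stability** is certified numerically: eigenvalues of the analytic
Jacobian, "stable" iff every real part is below `−tol` with
`tol = 1e−9`; real parts within `±tol` give the verdict "inconclusive"
so the non-hyperbolic boundary is never misclassified. The closed-form
local-stability condition sets for P₂, P₃, P₄ are implemented as
`local_stability_conditions`; at each of these points the Jacobian is triangular
up to a decoupled block, so the conditions are exactly "all diagonal
entries nonpositive" and the tests verify the one-way implication
conditions ⇒ negative spectrum on seeded random draws. No closed-form
condition is encoded for P₁ — the compound-fraction inequality for that
point does not reduce to an unambiguous expression — so
`local_stability_conditions("P1", ·)` returns `None` (indeterminate) and P₁
is certified by eigenvalues alone.

**Global stability** uses the Volterra-type Lyapunov function
`V = Σ_w (w − w* − w*ln(w/w*))`, with the limiting summand `V_w = w` for
components whose reference coordinate is zero (consistent with the
closed-form derivatives below). V is zero exactly at the reference point
and positive elsewhere by convexity. For each axial point the closed form
of `dV/dt` is obtained from the chain rule `∇V·F` after substituting the
equilibrium identities (e.g. `β₈ = β₉ + β₁₀Y₁*` at P₁); the P₃ form is
derived directly from the identity implied by `F₂ = 0` and keeps the
`−β₁₀(Y₃*−Y)²` term that a naive simplification drops. Every closed form is tested against the numeric
`∇V·F` at hundreds of random states to 1e−9 relative. The premise sets
under which `dV/dt ≤ 0` on the whole positive orthant are in
`global_stability_conditions`; the P₄ set reads `β₁ ≥ β₂` (the positivity
requirement for `X₄* = (β₁−β₂)/β₃`) and requires all four predation rates
to vanish.

## The MsDTM solver

The differential transform of `u` about `tᵢ` is `U(k) = (1/k!)·dᵏu/dtᵏ`,
so `u(t) = Σ U(k)(t−tᵢ)ᵏ`. Sums transform to sums, constants scale,
products transform to the Cauchy convolution `Σₚ U(p)V(k−p)`, the cubic
terms to a nested double convolution, and `u'` to `(k+1)U(k+1)` — giving a
recurrence that generates all coefficients from the initial state (the
`k!/(k+1)!` factor is simplified to `1/(k+1)`). A single expansion is only
locally convergent, so the driver splits `[0, T]` into subdomains of width
`h`, restarts the expansion from each left endpoint, and evaluates the
degree-`N` polynomials (Horner, highest coefficient first, to bound
round-off growth) at the subdomain width. Dense output between endpoints
is available by evaluating the stored segment polynomial; the default
output grid is the endpoints.

Convolution index semantics: coefficient lists are polynomials, so indices
beyond the stored length read as zero and any `k ≥ 0` is defined; the
solver recurrences themselves never index past `N`.

**Defaults.** `h = 0.01` (the scenario value for the built-in cases) and
`N = 10`. The iteration count is not prescribed anywhere; at `h = 0.01`
the degree-10 one-step error for this smooth system is below the round-off
floor, which is why the measured MsDTM-vs-RK4 discrepancy sits at ~1e−13
and why the error-vs-N curve flattens after N ≈ 8: the monotonicity test
requires strict decrease only while the error is above 1e−12.

**Clamping.** Solver outputs may dip to −1e−9 below zero by round-off;
recorded states are clamped to 0 at that tolerance for reporting, while
stepping always uses the raw values, so a genuine positivity bug larger
than round-off is never masked.

## Reference oracle

A classical fixed-step RK4 integrator over the same right-hand side,
implemented independently of the DTM recurrences (and itself cross-checked
against scipy's adaptive integrator and against the exact exponential on a
decoupled linear problem, where it shows the expected ~16× error reduction
per step halving). Tight references use step 1e−4, ten- to hundred-fold
finer than the solver under test, so reference error is negligible at the
tested tolerances. `trajectory_distance` is the max over shared sample
times of the ∞-norm state difference; nested grids are compared on the
times they share, and a trajectory carrying dense segments can be evaluated
on the other's grid.

## Parameter sampler

Property tests and the Monte-Carlo sweeps draw each rate uniformly on
[0, 1] (the range spanned by the built-in presets) and rejection-sample the
named premise set, capped at 1e5 attempts. Two numerical-robustness choices
fixed in advance: strict inequalities are enforced with a margin of 1e−3
(so that implied eigenvalues are bounded away from the marginal band), and
rates required to be nonzero must clear 0.02 (keeping γ₁/γ₂ and the
equilibrium coordinates O(10) so the fixed-step sweeps stay well resolved).
Equality constraints (the vanishing predation rates of the P₄ premise set)
are imposed by construction, not rejection. All draws are deterministic in
the seed.

## Scope of the synthetic scenarios

The built-in cases and the sampler define what the tests exercise: smooth,
bounded, nonstiff dynamics with rates in [0, 1] and densities O(1)–O(10).
Passing tests show the solver and the analytic certificates are correct for
this model class; they say nothing about stiff regimes (vanishing
self-limitation with large interaction rates), measurement noise,
demographic stochasticity, or spatial structure, none of which the model
includes. Cases 1 and 3 are intentionally identical parameter sets; both
presets are kept verbatim rather than "corrected".
Whether case 4 is a true limit cycle or a slowly damped oscillation is not
established: the oscillation check asserts at least two strict prey maxima
on [0, 100], not exact periodicity.

## Problem sizes

The cross-validation runs use T = 50 with RK4 at step 1e−4 (5×10⁵ steps);
the convergence studies use T = 10; the positivity/boundedness sweep
integrates 200 random systems to T = 100 at step 0.01 with a vectorized
ensemble integrator; the stability sweeps use 100 draws per condition set
and 500–1000 random states per draw. These sizes make the full suite run
in about a minute while leaving every measured margin several orders of
magnitude wide.
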