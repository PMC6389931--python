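# Methods

## Model and standing assumptions

The package analyses a planar autonomous ODE for a mosaic ecosystem: forest
fraction f ∈ [0, 1) and forest-preferring population fraction x ∈ [0, 1],

    df/dt = w(f) f (1 − f) − ν f − h (1 − 2x),
    dx/dt = s x (1 − x) [ r (1 − f)^m − q f^n ],
    w(f)  = c / (1 + e^{−k f/(1−f) + b}).

Assumptions inherited from the model structure: the landscape is well mixed
(no space), the population is large (deterministic imitation dynamics), and
the human feedback acts instantaneously at magnitude h. The lines x = 0 and
x = 1 are invariant; f = 1 is a singular limit of w (the argument f/(1−f)
diverges), so all routines guard f ≤ 1 − 1e−9 and integration terminates
with a domain-exit flag if an orbit reaches f = 1 or crosses f = 0 (strong
deforestation, −J < 0, can push f through 0; the region f < 0 is
unphysical and is treated as leaving the domain, not as an error of the
integrator).

Parameters (defaults): b = 11 (switch offset), c = 1 /yr (max recruitment),
k (switch steepness, main bifurcation parameter), ν /yr (natural
forest→grassland conversion, second bifurcation parameter), s = 10 /yr
(social learning rate), h = 2 /yr (human influence), r = q = 1 and
m = n = 1 (perceived-value gains and exponents, giving u(f) = 1 − 2f).
The time unit is nominally one year; nothing in the numerics depends on
that choice — reading it as a decade rescales ν, s, h, c uniformly and
makes the baseline rates more conservative ecologically.

## Equilibria and one-parameter continuation

With the symmetric preference (u(1/2) = 0) the interior equilibrium family
is f* = 1/2, x* = 1/2 + (ν/2 − w(1/2)/4)/(2h), valid while x* ∈ (0, 1); the
closed form is used as an oracle, while branches are traced by
pseudo-arclength continuation (tangent from the bordered Jacobian, Newton
corrector at tolerance 1e−6, initial arclength step 0.01–0.05 with halving
on failure and a 0.1–0.15 ceiling). The Jacobian of the family has trace
τ = w′(1/2)/4 − ν and determinant Δ = 4hs·x*(1 − x*) > 0: the interior
equilibrium is never a saddle and can only destabilise through a Hopf
bifurcation. Eigenvalues with |Re λ| < 1e−9 are flagged "marginal" rather
than forced into stable/unstable, since Hopf points live exactly there.
Boundary equilibria on the invariant lines are found by a 10⁴-point sign
scan plus bisection; they are reported but excluded from the regime map.

## Hopf points and the first Lyapunov coefficient

Hopf candidates are sign changes of the eigenvalue real part (equivalently
the trace, when Δ > 0) along a branch, refined by bisection to
|trace| < 1e−9. On the interior family the trace-zero condition has the
closed form ν_H(k) = c k e^{b−k}/(1 + e^{b−k})², which was re-derived from
the analytic Jacobian and is verified against eigenvalue-based detection in
the test suite (agreement to 1e−6). At a Hopf point ω = √Δ; on the interior
family ω = 2√(hs·x*(1 − x*)).

Criticality uses the planar normal-form reduction in complex coordinates:
with A q = iω q, Aᵀ p = −iω p, ⟨p, q⟩ = 1, and the analytic multilinear
forms B, C of the vector field,

    g20 = ⟨p, B(q, q)⟩,  g11 = ⟨p, B(q, q̄)⟩,  g21 = ⟨p, C(q, q, q̄)⟩,
    l1 = Re(i g20 g11 + ω g21) / (2ω²).

In the plane the whole phase space is the centre manifold, so no manifold
correction terms arise. Only the sign and zero of l1 are meaningful — the
magnitude depends on eigenvector scaling — and the package guarantees only
those. All derivative tensors are hand-coded closed forms (third-order
accuracy is what decides the l1 sign near its zeros); central finite
differences and a sympy evaluation serve as independent oracles in tests,
and the classic rotation-form 1/16-formula is a second, independent route
checked against the reduction on random cubic fields.

Bautin (generalized Hopf) points are zeros of l1 along the one-parameter
Hopf curve, bracketed on a 200-point scan of each flank of the locus peak
and refined by Brent's method to |Δk| ≈ 1e−13, leaving an l1 residual below
1e−8. A noteworthy structural fact (proved numerically and used as a test):
the low-k zero of l1 is independent of c, because c rescales the locus and
the equilibrium feedback balance coherently.

## Limit cycles, Floquet multipliers, folds

Periodic orbits are solved by single shooting: unknowns (y₀, T), residuals
φ_T(y₀) − y₀ together with the anchored phase condition
F(y_a)·(y₀ − y_a) = 0. The corrector is a damped Newton iteration with
residual backtracking, a period guard (0.05 T₀ < T < 20 T₀), and anchor
re-selection when the phase plane through a crude seed misses the orbit.
Multiple-segment shooting was considered and rejected: the monodromy of
every traced cycle stays O(1) (nontrivial multiplier within [0.2, 1.6]),
so splitting the period adds cost without conditioning benefit in this
system. Integration uses DOP853 at absolute/relative tolerance 1e−10;
discretisation convergence is asserted as tolerance-halving invariance of
the period (< 1e−6 relative).

The monodromy matrix comes from the variational equations integrated over
one period. For a planar autonomous system the multipliers are {1, det M},
and det M = exp ∮ tr J dt (Abel/Liouville, asserted in tests to 1e−6); the
cycle is stable iff |det M| < 1. Cycles are seeded from Hopf points on the
eigenplane with the normal-form radius estimate √|τ/(2 l1)| and a ladder of
fallback radii, on the parameter side chosen from sign(l1)·sign(dτ/dλ).

Branches of cycles are continued by pseudo-arclength in (y₀, T, λ) with a
frozen-Jacobian corrector (plain flows per iteration; the shooting Jacobian
is refreshed on slow convergence). Folds of cycles (LPC) are parameter
tangent reversals, refined by Newton on the extended system with the fold
condition log det M = 0 appended (finite-difference Jacobian, refreshed
whenever convergence is not fast). A branch terminates with a labelled
reason: amplitude → 0 at a known Hopf endpoint (with step clamping through
the shrinking neck, so the branch does not thread the zero-amplitude gap
and retrace itself), period → ∞, parameter range exhausted, or corrector
failure.

## Two-parameter structure and the regime map

The Hopf locus is sampled from its closed form and annotated with l1
(refined near sign changes). Each LPC locus is continued in ν by re-solving
the extended fold system with secant predictors; near its termination the
fold amplitude obeys amp² ∝ remaining distance, which drives the step
control, and the endpoint is extrapolated to the amp → 0 limit. The
endpoints recover the Bautin points to ~1e−4 in (k, ν), comfortably inside
the 1e−3 assertion used in tests.

`classify_regime` assembles the attractor inventory at a point: trace sign
of the interior equilibrium (unstable ⇒ region II, by Poincaré–Bendixson
with the bounded trapping region), and for stable equilibria a fresh
one-parameter cycle analysis at that ν — continue the cycle branch outward
from the flanking subcritical Hopf point to its first fold; region III is
the strip between the fold and the Hopf point. Points within 1e−3 of a
bounding curve are labelled "boundary". `build_regime_map` assembles the
curve-based partition and a verification grid. Region I's emptiness of
cycles is checked operationally by multi-seed shooting searches
(`search_cycles`), which in regions II/III find the known cycles and in
region I find none.

## Shift experiments

A shift protocol applies, at t_p = 100 yr, either a state kick or a
parameter step, after settling on the pre-perturbation attractor
(steady-state: amplitude varying < 1e−4 over a 100-yr block, horizon
2000 yr). Classification:

* state kick — catastrophic iff the settled post-kick amplitude exceeds
  5× the pre-kick amplitude, with a 0.05 floor on the denominator so that
  numerically-zero equilibrium amplitudes do not inflate the ratio;
* parameter step — the step is re-traced quasi-statically (16 settled
  sub-steps); the shift is smooth iff no consecutive pair of attractor
  amplitudes jumps by that same threshold. A plain post/pre ratio would
  brand any supercritical onset of oscillation "catastrophic", which is
  exactly the transition that is smooth: the amplitude grows continuously
  from zero along the path.

The threshold (ratio 5, floor 0.05, 16 sub-steps) is a package choice: the
catastrophic jumps in this model change the amplitude by a factor ≫ 10
while the largest quasi-static increments near a supercritical Hopf stay
below 2× the floor, so the classification is insensitive to the exact
values (halving the integrator tolerances does not change it).

## Synthetic benchmarks

Both fixtures are rotationally symmetric planar fields with radial part
r′ = A(r²) r and unit angular speed, sharing the derivative-tensor
interface of the model so the whole pipeline runs on them unchanged:

* Hopf normal form, A = μ ± ρ: Hopf at μ = 0 with l1 sign = cubic sign,
  stable-cycle radius √μ and period 2π/ω for the supercritical sign;
* Bautin unfolding, A = β₁ + β₂ρ − ρ²: Hopf line β₁ = 0, Bautin point at
  the origin, cycle radii r² = (β₂ ± √(β₂² + 4β₁))/2, fold of cycles at
  β₁ = −β₂²/4 with radius² = β₂/2.

These are exact closed forms; the pipeline recovers the fold at −β₂²/4 to
1e−8 and the Bautin point to < 1e−10, which validates each numerical stage
independently of the ecosystem model. What the fixtures do not emulate:
non-symmetric cycles, sharp-switch stiffness, domain boundaries — those are
exercised by the model tests themselves.

## Numerical choices and reference-value precision

Newton tolerance 1e−6 (absolute and relative) everywhere a corrector runs;
cycle closure 1e−8; trace refinement 1e−9; LPC multiplier tolerance 1e−3;
l1 degeneracy threshold 1e−8. H1 always denotes the smaller-k Hopf point.
Reported bifurcation coordinates carry full precision plus a 4-significant-
figure "printed" field in all JSON writers.

The reference coordinates this package is compared against are reported to
3–4 significant figures by a continuation tool whose printed points carry
mesh-level error of up to ~0.5% in k: the same low-k Bautin point appears
as 9.946 in one regime and 9.94 in another, while the zero of l1 in k is
exactly c-independent (here 9.9398, with the simulation-level weak-focus
test agreeing). Tests therefore compare printed coordinates at 0.6%
relative tolerance and assert digit-level agreement where the print
verifies; all exact invariants are held to 1e−6 or tighter.

## Known limitations

* The l1 magnitude is not normalised across parameterisations; only signs
  and zeros are contractual.
* Cycle continuation assumes the branch stays in the f < 1 − 1e−9 domain;
  branches that would graze the singular limit terminate early with a
  diagnostic rather than switching charts.
* `classify_regime` trusts Poincaré–Bendixson for region II rather than
  constructing the trapping region explicitly.
* No fold continuation for equilibria (none exists on the interior family,
  Δ > 0), and no Bogdanov–Takens/cusp machinery.
* The shift-experiment classifier is calibrated for this model's attractor
  geometry; systems with nearly-equal competing amplitudes would need a
  different criterion.
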