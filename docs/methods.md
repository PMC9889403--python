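# Methods

## Model and assumptions

The circuit couples three two-state elements in series — receptor, monomeric
GTPase (mG) and heterotrimeric GTPase (tG) — through the GEF/GAP enzymes
that catalyze their activation and deactivation, plus two negative feedback
arms from tGEF and active tG onto the mGTPase's GAP.  Pools are conserved,
so each switch is described by its fractional activation (a number in
[0, 1]); GEF and GAP levels are concentrations with first-order production
and decay.  tGAP is held at a constant concentration (the circuit contains
no regulation of it, so it carries no differential equation).  Basal
(constitutive) production is present only for mGAP, whose production term is
where the feedback enters; all other production terms require their upstream
regulator.

Two kinetic closures are supported for the regulatory function f: linear
mass action, f(x) = x, and the activating Hill form
f_act(x) = xⁿ/(Kⁿ + xⁿ).  One (K, n) pair is shared by every Hill term,
including the stimulus term f(S): the saturable-enzyme argument applies to
each reaction alike, and per-reaction constants would add un-constrained
parameters.  Per-reaction overrides can be emulated by rescaling the
corresponding rate constants.  No amplitude parameter multiplies f_act: it
saturates at 1, so amplitude differences are absorbed into the k_on's.

The feedback crosstalk F(tGEF, tG*) is 0 (feedback deleted),
f(tGEF)·f(tG*) (AND gate) or f(tGEF) + f(tG*) (OR gate); with the two
kinetics this yields six model variants.  Setting k_feedback = 0 reduces
either gate to the no-feedback model identically, and the code routes
k_feedback = 0 evaluations through the no-feedback path so the degeneracy is
exact rather than approximate.

## Steady states

Three routes are implemented and continuously cross-checked:

1. **Closed forms** (no feedback).  Setting the right-hand sides to zero
   collapses the cascade to Michaelian maps:
   mG* = X/(X + a) and tG* = h₂(mG*), with X = R*_ss (mass action) or
   F₁(R*_ss) = f_act(k_mGEF·f_act(R*_ss)) (Hill), a = a_M =
   mGAP_ss·(k_off^mGEF k_off^mG)/(k_on^mGEF k_on^mG) or its Hill analogue
   a_H = (k_off^mG/k_on^mG)·f_act(mGAP_ss).  Note the k_off/k_on
   orientation of these composites: it follows directly from dividing the
   activation balance by k_on, and is what the ODE cross-checks confirm.

2. **Scalar fixed point** (all variants).  With feedback, mGAP_ss depends on
   mG*_ss through the gate, giving y = X/(X + c_eff + h(y)) for y = mG*_ss,
   where h collects the feedback-dependent deactivation.  Since h is
   nondecreasing in y, g(y) = y·(X + c_eff + h(y)) − X is strictly
   increasing on [0, 1] with g(0) ≤ 0 ≤ g(1): the steady state is unique
   and is found by Brent's method at machine tolerance (xtol 1e-15).  The
   remaining variables are reconstructed from y by the same algebra.  A
   bracket failure (possible only for degenerate deactivation) raises an
   explicit error rather than returning a clipped value.

3. **Stiff ODE integration** (reference).  BDF with the analytic 6×6
   Jacobian, rtol 1e-10 / atol 1e-12, from the all-zero initial state, in
   geometric time chunks (10², 10⁴, 10⁶, 10⁸).  The run exits early once
   the *implied state correction* |rhs_i / J_ii| falls below
   1e-9·(1 + |y_i|) per component — dividing the residual by the diagonal
   damping matters because a small residual on a slowly decaying mode
   (k_off ~ 10⁻²) can hide a large remaining state error.  Non-convergence
   by t = 10⁸ is an error carrying the residual, never a silent clip.

The fixed point is the production route (it is exact and ~100× faster); the
ODE route is the cross-check used in tests, where the two agree to well
under 1e-6 per component across random parameter sets of all six variants.

Activation levels (the S → ∞ normalization constants) are evaluated
analytically by running the fixed point at the receptor's maximal activation
(1 under mass action, k_on^R/(k_on^R + k_off^R) under Hill) rather than at
the top of the finite dose grid.

## Distance metric

The metric is computed on the normalized-receptor axis u: the area between
the piecewise-linear curve v(u) and the diagonal, with intervals containing
a sign change of v − u split at the interior crossing so the absolute value
is integrated exactly for the interpolant.  Doses where u is flat carry zero
weight, matching the du/dS weighting of the dose-space definition.  Because
the dose grid is finite, the quadrature is closed with the analytic
endpoint (u, v) = (1, 1); both normalized curves approach 1, so the omitted
tail is bounded by that final trapezoid.  A second, independent quadrature —
trapezoid in S of |v − u| · du/dS with the analytic receptor derivative —
is exposed for cross-checking; the two converge together at first order or
better under grid refinement and agree below 1e-6 on dense grids
(~16 000 points over S ∈ [10⁻⁶, 10⁶]).

Degenerate models whose activation level is zero cannot be normalized and
are rejected (experiment drivers log and skip such parameter sets).

## Feedback-strength derivatives

For mass action the implicit-function derivative of the normalized response
is closed-form:

(1/y)·∂y/∂k_fb = −(1/k_fb) / [ (y/h)·∂h/∂y + ((c+h)/h)/(1−y) ],

evaluated at y = mG*_ss(S) and at y_max, whose difference (times y/y_max)
gives ∂(y/y_max)/∂k_fb.  The formula is singular at k_fb = 0, where the
model is the no-feedback one and finite differences apply.  The metric's
derivative d D/dk_fb is obtained by differentiating under the integral
(valid under mass action, where v ≥ u pointwise so the absolute value is
inert); for Hill kinetics only the central finite difference of the full
metric is offered (relative step 1e-4), since the Hill-side analysis yields
sign information rather than a closed derivative.

## Parameter generation and sweeps

Defaults: every rate constant and tGAP equal to 1 and no feedback, making
the mass-action composites a_M = b_M = 1 and the mGTPase activation level
exactly 1/2 — a neutral midpoint of the activation range.  Hill defaults
K = 0.5 (half-max at the midpoint of a fractional argument) and n = 1.5,
with n = 3 as the steeper comparison case.

Sampled spaces are log-uniform, seeded, and follow the analysis's
conventions: {k_on^mG, k_on^tG, k_on^mGAP} under mass action, expanded with
k_on^R under Hill kinetics (where the receptor's own saturation level
moves).  Rate constants range over [10⁻², 10¹] except k_on^mGAP
([10⁻², 1]) and k_feedback ([0, 10^2.6]); sweep grids are log-spaced with
{0} prepended for the feedback strength (the zero point is evaluated through
the degenerate no-feedback path).  Default space size is 500 parameter sets
per experiment (the acceptance script uses 200 per space to keep a full
from-scratch rerun to a few minutes; sizes are config-driven).

Trend classification uses an anchor walk: a new segment is recorded only
when the value moves more than 1% (relative) away from the last anchor, so
sub-tolerance wiggle is flat, cumulative drift is not, and appending
sub-tolerance values never changes the label.  At most one sign change is
interpreted (increasing / decreasing / dec-then-inc / inc-then-dec); two or
more filtered sign changes flag the series as ambiguous instead of forcing a
label.  Regime windows are operational choices: "high" activation ≥ 0.8,
"low" ≤ 0.2 for presets; the Hill regime map compares the decreasing-trend
share in the extreme bands (activation ≥ 0.7 or < 0.1) against the
intermediate band, restricted to sweeps whose metric moves at all (at very
low activation many sweeps are flat at the 1% tolerance).

The AND/OR comparison holds the mGTPase activation level fixed: matching
the saturating mGAP level requires k_fb^AND·h₁(y_max)·h₂(y_max) =
k_fb^OR·(h₁(y_max)+h₂(y_max)), which is used as initial guess and
cross-check for a bracketed root on the activation mismatch (agreement to
1e-8 or better; in practice machine precision, since matching the gate drive
at y_max makes both fixed-point equations identical there).  Pair proximity
to the diagonal is summarized by the mean perpendicular distance
|D_AND − D_OR|/√2 relative to the mean metric of the pairs, with 10% as the
default "almost identical" threshold.

## What the generator does and does not emulate

The synthetic parameter spaces reproduce the structure of the published
analysis — log-spaced sweeps over stated ranges, seeded random spaces,
activation-regime conditioning — not any fitted biology: rate constants are
not calibrated to measured Arf1/Gi kinetics, there is no cell-to-cell
variability, no stochasticity, and no basal production for the GTPases.
Passing tests therefore establish the model's internal design principles
(ordering, regime maps, gate equivalence) over these parameter ranges, not
quantitative predictions for any particular cell system.  The exact
per-figure parameter values of the original study are not available in its
text, so figure-level comparisons are qualitative by construction and all
defaults are config-overridable.

## Numerical choices and limitations

* brentq tolerances: xtol 1e-15, rtol ~9e-16 (machine); dose grid default
  60 log-spaced points on [10⁻⁵, 10³].
* The fixed-point reduction assumes the steady state is unique, which holds
  for this model family because h is nondecreasing in y; should a modified
  h ever produce multiple roots, the bracketed solver surfaces the
  discrepancy against the ODE route rather than choosing silently.
* Stability of the steady state is not analysed (no eigenvalue/bifurcation
  machinery); transient dynamics and adaptation are out of scope.
* Fractional states can acquire O(solver-tolerance) negative excursions
  during integration; the right-hand side clips its inputs at zero, and
  invariance tests allow 1e-7 slack.
* Hill coefficients n < 1 make f_act's derivative singular at 0; the
  Jacobian handles n ≥ 1, which covers all shipped configurations.
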