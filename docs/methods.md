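# Methods

## Model

Each gene product is a first-order birth–death process whose synthesis rate
switches between two levels according to a thresholded ("digital") view of its
regulator:

    dY/dt = β₀ + (β₁ − β₀)·θ(t) − α·Y,        θ(t) ∈ {0, 1}

with β₀ the basal and β₁ the induced synthesis rate (concentration/hour) and
α > 0 the degradation rate (1/hour). `θ` is 1 while the regulating
concentration is strictly above the activation threshold K (or strictly below
it, for a repressive sense). `β₁ > β₀` makes the edge activating, `β₁ < β₀`
inhibiting; repression can equivalently be written on the thresholding side
(`sense: active_below`), which is how the incoherent-loop repressor arm is
configured. A value exactly at a threshold counts as *not* above; this
measure-zero convention is stated once and used everywhere.

Supported wiring is strictly feed-forward (the input oscillation is given,
not generated; cyclic edge sets are rejected):

* **direct**: X→Y
* **two-step**: X→Y→Z
* **feed-forward loops**: X→Y, X→Z, Y→Z with the two conditions on Z combined
  by an AND or OR gate. With three signed edges there are eight loop types; we
  number them by the published convention — types 1–4 are the coherent loops
  C1–C4 (type 1 = all activators), types 5–8 the incoherent loops I1–I4
  (type 5 = the classic activator/activator/repressor pulse generator). A
  declared type is validated against the signs derived from edge senses and
  rate orderings; CFFL-1 (type 1) and IFFL-1 (type 5) are the worked
  prototypes, the others arise by flipping senses/orderings.

## Input signals

Periodic inputs are built from a unit-interval shape passing through a short
anchor list, interpolated with a **monotone shape-preserving piecewise cubic**
(PCHIP), then stretched to a period T (hours) and repeated. The three
canonical shapes (left-skewed, symmetric, right-skewed) share the duty
structure *above 0.1 for 75% and above 0.75 for 25% of each cycle*, with
anchors sitting exactly on those thresholds, so shape comparisons isolate the
temporal profile from total activation time. The interpolant family is a
package design choice: an unconstrained cubic spline through the same anchors
overshoots the normalized range and creates spurious crossings, destroying the
75/25 structure the anchors encode; PCHIP is monotone between anchors, so it
adds no crossings and stays inside [0, 1]. Step stimuli and ideal square
waves (for exercising the closed forms) are provided alongside.

Crossing times are located by bracketing on the (monotone) anchor intervals
and refining with Brent's method at essentially machine precision
(xtol 1e-15); anchors lying exactly on a threshold *are* the crossing points.
Event times feed closed-form propagation, so sloppy roots would leak into
every downstream statistic.

## Event-driven solution

Between events the ODE is linear with constant coefficients, so the exact
solution on each interval is a single exponential toward the local equilibrium
β/α. A trajectory is a chain of such segments glued continuously at events
(`PiecewiseExpTrajectory`); extrema sit at segment junctions (each segment is
monotone), integrals are closed-form per segment (never quadrature), and the
trajectory's own threshold crossings solve one logarithm per segment. Gate
algebra (AND/OR) operates directly on switch times — no sampling; coincident
events are merged (tie tolerance 1e-12 h) and zero-length segments elided.

## Stationary regime

Under a periodic drive the one-period return map is affine,
`y(T) = F·y(0) + B` with `F = e^{−αT} < 1`, composed segment by segment; the
periodic attractor is its fixed point `y* = B/(1 − F)`, computed in closed
form rather than by burn-in. The cascade is feed-forward, so each stage's
drive is periodic once its upstream is stationary and the whole stationary
response is assembled stage by stage.

Closed forms derived from the two-exponential self-consistency conditions and
cross-validated against the numerical oracle before being relied on
(equilibria y₀ = β₀/α, y₁ = β₁/α; duty f; dimensionless period τ = αT):

* **Mean**: ⟨Y⟩ = (1−f)·y₀ + f·y₁ — the duty-weighted average of the two
  equilibria; equal to the exact cycle integral over T and independent of
  period and shape at fixed duty.
* **Extrema** (single drive pulse per cycle):

      y_max = [y₁(1 − e^{−fτ}) + y₀(1 − e^{−(1−f)τ})e^{−fτ}] / (1 − e^{−τ})
      y_min = y₀ + (y_max − y₀)·e^{−(1−f)τ}

  y_max increases and y_min decreases with τ; both → ⟨Y⟩ as τ → 0 and → y₁,
  y₀ as τ → ∞. They depend on the input only through its digitized drive, so
  equal-duty shapes give identical extrema.
* **Onset delay** to a downstream threshold K from a start value y_s toward
  asymptote a: δ = ln[(y_s − a)/(K − a)]/α, valid when K lies strictly
  between y_s and a (a threshold at or beyond the asymptote is never reached
  and raises a distinct "never crosses" signal).
* **Downstream duty**: with y_min < K < y_max and a single crossing per
  cycle,

      f_out = f + (δ_off − δ_on)/T,
      δ_on = ln[(y₁ − y_min)/(y₁ − K)]/α,   δ_off = ln[(y_max − y₀)/(K − y₀)]/α,

  (roles mirrored for an inhibitor stage). Either logarithm can be positive
  or negative, so the downstream gene can be active longer or shorter than
  the intermediate's own drive. Saturation: f_out = 1 when K ≤ y_min, 0 when
  K ≥ y_max. Drives with multiple pulses per cycle are fully supported by the
  event-driven path; the closed forms check applicability explicitly and
  refuse otherwise.

## Numerical oracle

`oscimotif.oracle` integrates the same models with `scipy.solve_ivp` (DOP853,
rtol 1e-10 / atol 1e-12 — tight enough that disagreement indicates a logic
bug, not integrator error), restarting at every synthesis-rate discontinuity.
Input-threshold crossing times come from the signal's exact crossing
structure; discontinuities at *intermediate*-gene crossings are supplied by
the caller rather than detected adaptively inside the integrator (stepping
across a jump silently degrades order). The right-hand side still evaluates
the step functions truthfully from the current state, and `cross_validate`
additionally checks that the numerically integrated intermediate sits on its
threshold at each supplied instant, so a wrong event time cannot pass
silently. The Hill variant replaces each step with
h(x) = xⁿ/(xⁿ + Kⁿ) (1 − h for repressive senses; AND = product,
OR = inclusion–exclusion), with the half-activation equated to the edge
threshold so the step model is recovered exactly in the large-n limit.

## Regime classification

For an FFL with single-crossing drive the qualitative period response is
fixed by two orderings — the direct-branch input threshold K_xz versus the
indirect-branch input threshold K_xy, and the intermediate threshold K_yz
versus the intermediate mean ⟨Y⟩ (period-invariant, hence so is the label):

| case | input thresholds | intermediate threshold |
|------|------------------|------------------------|
| A    | K_xy < K_xz      | K_yz < ⟨Y⟩             |
| B    | K_xy < K_xz      | K_yz > ⟨Y⟩             |
| C    | K_xy > K_xz      | K_yz < ⟨Y⟩             |
| D    | K_xy > K_xz      | K_yz > ⟨Y⟩             |

Exact ties are reported as `boundary` rather than silently forced into a
class. Because ⟨Y⟩ depends on the input duty, classification takes the input
signal alongside the motif config. Whether additional gate-threshold
magnitude effects can shift the case boundaries beyond these two orderings is
left open; boundary configurations are therefore never auto-assigned.

## Canonical scenario set

Figure-level parameter values are not prescribed anywhere, so the shipped
configs (`oscimotif/examples/`, regenerable via `generate_fixtures()`) are
representative choices satisfying each scenario's defining *ordering*
constraints, with normalized kinetics: β₀ = 0, β₁ = 1 conc/h, α = 1/h for
every gene, input thresholds at the canonical 0.1/0.75 levels (duty 75%/25%),
symmetric shape and T = 1 h unless the scenario says otherwise. Assertions on
these scenarios are about directions, limits and saturation values, not curve
heights. Default sweep grids are log-spaced over dimensionless periods
10⁻¹–10², covering both extrema limits. The whole pipeline is deterministic —
there is no random number generation in the core, and repeated runs produce
byte-identical CSV/JSON.

Problem sizes: oracle cross-validation runs on
{direct, two-step, CFFL-1 AND/OR, IFFL-1 AND/OR} × 3 shapes × periods
{0.5, 1, 3} h over ~4-period horizons on ~1500-point grids; long-run oracle
averages discard a 25-lifetime transient and average over 200 cycles. These
sizes leave integrator error well below every comparison tolerance.

## Known limitations and subtleties

* **Monotone two-step switching has a boundary zone.** When the downstream
  threshold lies between the intermediate's equilibrium midpoint
  (y₀ + y₁)/2 and its mean ⟨Y⟩, the two delay logarithms change sign with
  the period and mean-Z is genuinely non-monotone in period (a shallow dip
  before approaching the duty-limited plateau); the familiar monotone
  on/off switching statements hold for thresholds clearly separated from
  that zone, which is how the canonical scenarios are placed.
* The synthetic inputs are noiseless, perfectly periodic and normalized to
  [0, 1]; real transcription-factor traces have amplitude drift, stochastic
  bursting and cycle-to-cycle variability, none of which is modelled. Passing
  tests certify the deterministic threshold-kinetics model, not the behaviour
  of noisy cellular signals.
* Gates are idealized instantaneous boolean (or, in the Hill variant,
  multiplicative) combinations; promoter-level kinetics, cooperativity beyond
  a single Hill exponent, and transcription/translation delays are out of
  scope, as are feedback topologies and stochastic (Gillespie) simulation.
* Step-function switching makes the response insensitive to the regulator's
  values away from the threshold; the Hill oracle quantifies how quickly the
  smooth model approaches this idealization (relative sup-norm deviation on
  the canonical direct scenario falls monotonically with the exponent).
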