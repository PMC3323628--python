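# Methods

## Model

The transcriptional machinery of a promoter regulated by N transcription
factors (TFs) and RNA polymerase (RNAP) is treated as an equilibrium system
with 2^(N+1) mutually exclusive occupancy states: any subset S of TFs bound,
with or without RNAP (flag sigma).  Each state carries a statistical weight

    W(S, sigma) = x_P^sigma * prod_{i in S} x_i
                  * prod_{i<j in S} omega_ij
                  * [ prod_{i in S} w_i * prod_{i<j in S} omega3_ij ]^sigma

built from dimensionless relative concentrations x = c/K (concentration over
dissociation constant) and three families of cooperativity factors:

* `w_i` — two-body TF–RNAP coupling.  An activator lowers the RNAP binding
  energy, so its shift is negative and its factor exceeds 1.
* `omega_ij` — TF–TF coupling, present whenever both TFs are bound,
  regardless of RNAP.
* `omega3_ij` — three-body TF–TF–RNAP coupling (DNA looping, assembly of an
  activation complex), active only when both TFs *and* RNAP are bound.

Factors and free-energy shifts are related by `factor = exp(-dE/(R T))`.
The direction of this map is a convention we fix explicitly: activating
shifts are negative and map to factors > 1.  Defaults: T = 298.15 K,
R = 1.98720425864083e-3 kcal/(mol K) or 8.31446261815324 J/(mol K) selected
by the unit tag.  Only pairwise TF–TF and pairwise-with-RNAP interactions
are represented; interaction terms among triples of TFs (without RNAP) are
not part of the model.

State probabilities are weights over the partition sum; the model's central
output is the RNAP occupancy

    p = V_on / (V_on + V_off),

with V_on/V_off the summed weights of RNAP-bound/-free states.  The
transcription rate is taken proportional to p; the proportionality constant
carries the units of the readout and is never estimated.  Because the rate
is linear in p, fold changes of rates and of occupancies coincide.

For two activators A and B the sums are

    V_on  = x_P (1 + x_A w_A + x_B w_B + x_A x_B w_A w_B omega_AB omega3)
    V_off = 1 + x_A + x_B + x_A x_B omega_AB.

## Synergy measure

Dual stimulation is compared against the sum of the single stimulations:

    D = p(x_A, x_B) - p(x_A, 0) - p(0, x_B),

greater-than-additive (GTA) for D > 0, less-than-additive (LTA) for D < 0.
D is computed from raw occupancies without basal subtraction: the
zero-dose value D(0,0) = -p_basal < 0 is part of the model's content (at
vanishing TF doses the response is always LTA), and the double-binding-site
analysis compares against *twice* the single-site activity, not against
baseline-subtracted activity.  The basal-added convention (D + p(0,0)) is
available behind a flag but is not the default.  Classification uses an
additive band of 1e-9 (absolute, probability units) around zero.

### Exact sign statistic

Writing u, v for the single-stimulation on/off odds (u = V_on/V_off with
only A dosed, etc.) and S for the dual-stimulation odds, clearing the three
denominators of D gives

    sign(D) = sign( S (1 - u v) - u - v - 2 u v ).

This identity is exact for all parameter values and is the root of every
closed-form boundary below.  The public `synergy_sign_statistic` restricts
itself to the neutral-omega case (omega_AB = omega3 = 1, where S = u v/x_P
and the statistic is quadratic in the odds) because that is the regime in
which it is used for classification; calls outside it are rejected.

### Limits and boundaries

All saturation statements are evaluated analytically from the limit
expressions (u -> x_P w_A, S -> x_P w_A w_B omega3 — the TF–TF factor
omega_AB cancels in the joint limit), never by plugging huge doses into the
occupancy; numeric cross-checks in the tests use dose 1e9 with the
log-space weight path.  The derived boundaries:

* **Equal activators, neutral omegas, saturation.**  D changes sign at
  x_P*(w) = (w - 2)/w^2: zero at w = 2, single interior maximum 1/8 at
  w = 4, decaying to zero.  Below the curve, saturated stimulation is GTA;
  above, LTA.  Since the curve never exceeds 1/8, and the quadratic
  statistic is negative whenever x_P >= 1/2 regardless of doses and
  two-body factors, a promoter with RNAP above half its dissociation
  constant can never be GTA without three-body interactions.  The same
  curve re-parameterised by the energy shift g = ln w gives the re-entrant
  LTA -> GTA -> LTA sequence as activator strength grows at fixed
  x_P in (0, 1/8).
* **Strong activation, low RNAP.**  The statistic reduces to
  h = omega3 w_A w_B - w_A - w_B, zero on the hyperbola
  w_B = w_A/(omega3 w_A - 1) with asymptotes at 1/omega3.  For omega3 = 1
  this is w_B = w_A/(w_A - 1) (diagonal crossing at w = 2, asymptote
  w_B -> 1).  Since sup over the activator domain w_A, w_B > 1 of
  (1/w_A + 1/w_B) is 2, the infimum three-body factor that makes h positive
  for *every* pair of activators is exactly 2 — the universal three-body
  threshold.  It is computed by bisection of the positivity predicate over
  a 200-point log grid of factor pairs in (1, 100] (grid floor 1 + 1e-4,
  bisection tolerance 1e-4), reproducing 2 to better than 1e-3.

### Regime classification

`classify_regime` matches a promoter to the tabulated cases in the fixed
priority order 1, 2, 3, 4, 7b, 7a, 6, 5b, 5a so overlapping preconditions
resolve deterministically.  The >> / << conditions of the analysis are
implemented with documented numeric thresholds, adjustable per call:
strong activation x_i w_i >= 100, low RNAP x_P <= 0.01, low TF dose
x_i <= 0.01, weak activation products x_i w_i <= 1.  The "weak activators"
case (closed conditions not printed in the main analysis) uses a sufficient
condition derived here: since S <= x_P w_A w_B omega3 term by term and
G <= S - u - v, we get G <= x_P (w_A w_B omega3 - 2), so
w_A w_B omega3 <= 2 forces D < 0 at every dose and every omega_AB.
Classification is defined for activators only (w >= 1); the core math
accepts w < 1 but repressor-specific classification is out of scope.
The thresholds assume factors of ordinary magnitude; e.g. the low-dose case
can be escaped by astronomically large omega3 at doses just below the 0.01
threshold, which the classifier does not second-guess.

## Double-binding-site dose responses

Two identical sites for one activator species are the two-activator model
with x_A = x_B = x, w_A = w_B = w.  The reference is a one-site promoter
with the *same* x_P and w, occupancy
p_SS = x_P (1 + x w)/(x_P (1 + x w) + 1 + x), and the dose-resolved synergy
is D(x) = p_DS(x) - 2 p_SS(x); the Chi–Carey ratio p_DS/(2 p_SS) crosses 1
exactly where D crosses 0.

With neutral omegas the critical doses are closed-form: the single-site
odds u(x) = x_P(1 + w x)/(1 + x) must enter the window (u-, u+),
u+- = (1 -+ sqrt(1 - 8 x_P))/2, and each attained edge maps to the dose
x_c = (u_c - x_P)/(x_P w - u_c).  This yields the pattern trichotomy:

* no window (x_P >= 1/8) or window never reached — LTA at every dose;
* saturated odds stop inside the window (x_P < (w-2)/w^2) — one crossover;
* saturated odds pass beyond the window — re-entrant (-, +, - with two
  crossovers), the regime in which the Chi–Carey ratio rises above 1,
  peaks once, then decays monotonically below 1.

With a pure three-body interaction (w = 1, omega_tf = 1) the crossover is
the positive root of a quadratic: it exists iff omega3 (1 - x_P) > 2, at
x* = (m + sqrt(m(m + omega3 - c)))/(omega3 - c) with c = 2/(1 - x_P),
m = c - 1.  The existence line in the (omega3, x_P) plane is
x_P* = 1 - 2/omega3, approaching the asymptote x_P = 1 as omega3 grows; at
or above x_P = 1 no crossover exists at any interaction strength.

The closed forms are the implementation; the numeric path (sign-change
bracketing on 400 log-spaced doses in [1e-6, 1e6], Brent refinement to
1e-12 in log-dose) serves as the independent oracle in the tests, with
1e-8 agreement required, and as the solver for general omega factors and
for unequal-site promoters (distinct near/far w values routed through the
general two-activator model with a shared dose).  Roots outside
[1e-6, 1e6] are invisible to the numeric path; the closed forms have no
such restriction.

## Fold-change estimation

Saturation fold changes F = p_stim/p_basal of the forward model are
F = w (1 + x_P)/(1 + x_P w) per single condition and the same form in
W3 = w_A w_B omega3 for the dual condition.  Exact mode inverts these at a
known x_P (invertible while F < (1 + x_P)/x_P).  The default low-RNAP mode
uses the x_P -> 0 limits w_A = F_A, w_B = F_B, omega3 = F_AB/(F_A F_B); the
TF–TF factor cancels at joint saturation, so omega_AB and omega3 are not
separately identifiable from three saturation fold changes (recorded in the
output).  The low-RNAP estimates carry the model's first-order bias: the
recovered omega3 equals
omega3 (1 + x_P w_A)(1 + x_P w_B)/((1 + x_P)(1 + x_P W3)), i.e. a relative
error ~ x_P W3 for strong promoters.  At x_P = 1e-6 this is negligible for
W3 up to ~1e3 and reaches percents at W3 ~ 1e4; the relevant smallness
condition for "low polymerase" is x_P W3 << 1, not x_P << 1 alone.

The synergy-domain contour D(x_A, x_B) = 0 is traced by radial root
finding along rays from the origin (log-bracketed, Brent-refined until
|D| < 1e-9, innermost crossing kept); rays without a crossing are skipped
and an empty contour is reported, not raised.  Axes can be rescaled to the
dose inducing a stated fraction (e.g. 80%) of each single-stimulation
saturation activity; the rescaling dose solves a linear equation in x and
is exact.  Occupancy (not baseline-subtracted activity) defines the
saturation fraction.

## Synthetic fixtures

The fixture generator emulates reporter-assay readouts: per promoter it
draws truth parameters log-uniformly (w_A, w_B in [1, 50], omega3 in
[0.5, 20]), computes the three noiseless saturation fold changes from the
forward model at x_P = 1e-6, and multiplies by lognormal noise
(sd 0.1 on the log scale by default), keeping the truth columns.  It is the
only randomness in the package, driven by a single explicit seed recorded
in the manifest; identical seeds reproduce byte-identical tables.  What the
fixtures do *not* emulate: dose-response curves away from saturation,
additive (background) noise, basal drift between conditions, or any
disagreement between occupancy and readout — passing recovery tests
therefore demonstrate correctness of the inversion arithmetic under the
model's own assumptions, not robustness to real-assay systematics.

## Numerical choices

* Weights accumulate in log space with one log-sum-exp normalisation;
  probabilities stay finite for doses/factors up to ~1e12.  Zero doses give
  -inf log weights (weight 0) without special-casing; the empty state's
  weight is identically 1, so the partition sum never vanishes.
* State ordering is RNAP-free block then RNAP-bound block, TF subsets in
  binary counting order; a stored permutation maps the two-TF case onto the
  conventional (empty; P; A; B; PA; PB; AB; PAB) display order.
* Bisection brackets: x_P in (1e-12, 1) and w in (1 + 1e-9, 1e6) where a
  root is hunted; boundary ties classify as `additive`.
* Problem sizes: the high-RNAP ceiling search uses 50-point log grids per
  axis over x_A, x_B in [1e-3, 1e3] and w_A, w_B in [1, 1e3] (vectorised,
  ~6.3e6 parameter points per RNAP concentration, 40 RNAP values); random-
  draw invariants use 1000 draws.  These sizes resolve every boundary in
  question to well under one grid cell while keeping the full suite fast.

## Known limitations

* Equilibrium only: no kinetic ODE or stochastic binding dynamics.
* No boundary surfaces for more than two TFs; the general state space
  handles any N, but the closed-form analysis is two-activator.
* Regime classification is a threshold-based match of asymptotic cases; a
  promoter between regimes returns `unclassified` rather than a guess.
* The numeric dose-root finder is limited to doses in [1e-6, 1e6].
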