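# Methods

## Model

Each of the four components (CRH, ACTH, cortisol, activated GR) relaxes
toward a logistic steady-state function of its net regulatory input:

    dX_i/dt = ts_i (F_i − X_i),  F_i = 1/(1 + e^(−σ W_i)),
    W_i = R_i0 + Σ_j R_ij X_j.

Activities are dimensionless and confined to (0, 1) at steady state, so
the unit cube is forward-invariant and all attractors live inside it. The
wiring is fixed (8 regulatory edges): the stress signal SS enters CRH only
(`RCRH_SS`); CRH → ACTH → COR → GR is the forward cascade; GR ⊣ CRH and
GR ⊣ ACTH close the negative feedback; CRH → CRH and GR → GR are the two
positive feedbacks. A one-dimensional self-activation `x = F(b + Rx)` is
bistable exactly when σR > 4 and the effective background b sits inside a
window whose width grows with R; at the default gain σ = 10, order-one
weights straddle that threshold, which is what makes the heterogeneous
population interesting.

Time is in arbitrary units; with `ts = 1` a component relaxes on ~1 time
unit, and all protocol windows (burn-in to 20, pulse [20, 30), scan
treatment [40, 50), targeted treatment [60, 70), horizon 100) are long
relative to it.

## Basal parameter set and population

The shipped basal set (`data/basal_default.yaml`, version 1) was
calibrated once, by hand followed by a small random search, against four
requirements and then frozen: (i) the basal individual itself is a stable
control — it recovers its cortisol baseline after the pulse and is not
oscillatory; (ii) under 10-fold uniform sampling and the strong pulse all
three phenotypes occur (≈ 82% control, ≈ 3% low, ≈ 15% high at n = 2,000);
(iii) the low-cortisol state is mechanistically a latched GR positive
feedback and the high-cortisol state a latched CRH positive feedback, so
the treatment analysis has a discoverable ground truth; (iv) the control
fraction stays above one half. `RACTH_0 = 0` is a modeling statement —
ACTH is driven purely by CRH and GR — and the sampler holds a zero basal
parameter at zero (degenerate range, warned once).

Heterogeneity: every parameter is drawn independently and uniformly on
`[|basal|/10, |basal|·10]` on the linear scale (not log-uniform), with the
basal sign re-applied so inhibitions never become activations. Draws use
counter-based substreams keyed by individual index, so individual *i* is
identical for any population size and the population is reproducible from
one seed.

The pulse amplitude default is 2.0. The direct input to CRH during the
pulse is `RCRH_SS · amplitude`, and with `RCRH_SS` sampled up to 10 the
response saturates: amplitudes 1.5–3 change the phenotype fractions by
under one percentage point, while the disorder fraction falls steeply
below ~1 (this is the dose–response the trend test probes).

## Numerical integration

The stress signal and treatment overlays are piecewise constant, so every
run is split at their breakpoints into segments on which the ODE is smooth
and autonomous. Each segment is integrated with an embedded
Dormand–Prince 4(5) pair (adaptive steps, atol 1e−9, rtol 1e−7, PI-free
step control with factor clamped to [0.2, 5]), compiled with numba for
population-scale throughput; output points (default spacing dt_out = 0.1)
are forced integration stops, so sampled values carry full step accuracy
rather than interpolation error. The kernel is verified in the test suite
against the closed-form exponential relaxation (all weights zero, 1e−6
absolute) and against scipy's `solve_ivp` at tighter tolerances along a
stressed trajectory (agreement ≈ 1e−9). Failure modes (step underflow,
non-finite states) raise an `IntegrationError` carrying the individual's
parameters; cohort runs exclude such individuals with a logged warning.
A treatment may transiently flip a weight's sign; relaxation rates,
however, are clamped at zero since a negative rate is unphysical and
produces divergent artifacts.

## Fixed points and oscillations

`find_fixed_points` solves X = F(W(X)) by damped Newton iteration (with
backtracking on the residual) seeded from a `grid_n^4` lattice plus a
Picard pre-pass (60 plain iterations of the map) that lands extra seeds on
the attracting roots even when σ·weights are extreme. Roots are kept when
the residual is below 1e−9, deduplicated within 1e−6 (∞-norm), and
classified stable/unstable by the eigenvalues of the analytic Jacobian
`diag(ts)(diag(σF(1−F))R − I)`. Brouwer's theorem guarantees at least one
root, so an empty result raises rather than returning silently.

Sustained oscillations (the negative feedback supports limit cycles) are
flagged when the cortisol peak-to-peak amplitude over the final 20% of a
run exceeds 0.01; all phenotype and outcome decisions use windowed time
averages (last 25% of the burn-in and of the horizon), so oscillatory
individuals are classified by their cycle means rather than excluded.

A note on monotonicity: steady-state cortisol is *not* globally monotone
in the ACTH→cortisol weight under the full wiring — the GR-mediated
negative feedback can overcompensate a stronger drive. The monotone-gain
property holds (and is tested) on the cooperative reduction with the GR
repressions removed, where monotone-systems theory guarantees it.

## Phenotypes and treatments

Baseline cortisol is the time average over the last quarter of the
stress-free burn-in; post-stress cortisol over the last quarter of the
horizon. The classification tolerance is 0.05 activity units — small
against typical attractor separation at σ = 10 but large against
integrator error and residual burn-in drift (≤ 5e−3). Treatments are
additive changes of one raw parameter value inside a half-open window,
fully withdrawn afterwards; "effective" means the final-window cortisol
re-enters the baseline band (the treatment window itself precedes the
averaging window and never enters the decision). The random scan draws
the target uniformly among all 16 parameters, the direction uniformly,
and the magnitude uniformly on (0, 10].

## ML analysis

The phenotype tree is a scikit-learn CART (Gini, max depth 4, min leaf 5)
over the 16 parameters plus the 4 post-stress component averages, with
classes downsampled to equal size beforehand. The treatment analysis uses
a random forest built as a bagging ensemble of depth-unlimited CARTs with
`sqrt(16) = 4` features considered per split (500 trees), which exposes
each tree's bootstrap sample through public API; importance is the mean
out-of-bag accuracy drop over 10 independent permutations of each feature
per tree, floored at zero and scaled so the maximum reads 100. Classes
are reweighted inversely to frequency during fitting because effective
treatments are the minority (~5%). Ranking ties break lexicographically.
The direction tree is the same CART (balanced class weights) over the
signed-delta table; the effective-majority side of a target's shallowest
split gives the treatment direction, and the protocol magnitude is the
|threshold| × 1.5 safety factor (capped at 10) — thresholds estimate the
boundary of the effective region, and the overshoot buys robustness to
their estimation error. When the top two importances are within 10 points,
both protocols are emitted; a runner-up whose direction the tree cannot
determine is skipped with a warning rather than guessed.

## Scales used by the tests and the acceptance script

The test battery uses a shared 20,000-individual cohort (≈ 660 low- and
≈ 3,000 high-cortisol patients) with the per-patient treatment count
chosen to give ≈ 5,000 scan records per class, 10 forest seeds per class
for ranking stability, 20 seeded replicates at n = 5,000 for the
planted-signal check, and 2,000 individuals per amplitude for the
stress-dose trend. The acceptance script uses 3 replicate populations of
5,000 for the recovery fraction and a 4,000-individual population for the
scan behind the importance normalization. These sizes are the package's
own choices for routine runs; all of them can be raised through the run
configuration.

## What the generator does and does not emulate

The virtual population emulates parametric heterogeneity of a fixed
network topology under a single standardized stress episode. It does not
emulate measurement noise, intra-individual parameter drift, circadian or
ultradian forcing, multi-episode stress histories, or pharmacokinetics of
an actual drug; passing tests therefore demonstrate that the
model-plus-ML loop recovers planted mechanisms and ranks true targets
under these idealized conditions, not that the specific parameter values
transfer to clinical cortisol data.

## Known limitations

* Phenotype fractions depend on the basal calibration; the low-cortisol
  class is intrinsically the rarest (its latch requires an indirect,
  bounded kick through cortisol, unlike the directly driven CRH latch).
* The direction tree's threshold is a coarse dose estimate; per-patient
  dose optimization is out of scope.
* Cohort-level efficacy of designed protocols is reported as a fraction
  cured with a fixed dose; combination treatments and schedules beyond a
  single rectangular window are not modelled.
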