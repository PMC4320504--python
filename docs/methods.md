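# Methods

## Model

The post-exercise recovery of finger-skin temperature is modelled as a
supervised homeostatic negative-feedback loop with two hierarchical
units. The *executor* is a first-order, unitary-gain plant (the skin
thermal compartment) in series with an integral controller (the active
vasodilatory drive); the *supervisor* decides when the loop closes. In
deviation coordinates — temperature minus the post-exercise value `y0`,
with the controller reference `r = T − y0` where `T` is the basal
(pre-exercise) mean —

- open loop, `t < LT`:  `dy/dt = a (d − y)`, `y(0) = 0`, closed form
  `y(t) = d (1 − e^{−a t})`;
- closed loop, `t ≥ LT`:  `dy/dt = a (m + d − y)`, `dm/dt = K (r − y)`,
  with `y` continuous across the switch and the integrator reset,
  `m(LT) = 0`.

The disturbance `d` models passive heat exchange with the room and
drives the plant in both regimes; the supervisor only gates the
controller. For `a > 0, K > 0` both closed-loop eigenvalues
(`λ² + aλ + aK = 0`) have negative real part and the integral action
gives zero steady-state error (`y → r`). Negative `K` makes the loop
unstable; such parameters are admitted (the estimation search box allows
`K ≥ −5`) because real recoveries occasionally look locally divergent
over a 5-minute window, and the population table assigns them
non-negligible probability.

All dynamics run in deviation coordinates; absolute temperatures appear
only at I/O. The choice reconciles the zero-initial-condition analysis
with `y0` being the measured post-exercise temperature, and makes `d` a
deviation-scale quantity consistent with the population table's
magnitudes.

**Units.** Time is in samples (1 sample = 10 s at 0.1 Hz); `a` and `K`
are per-sample rates. This is the only unit convention under which the
search-space bound `LT ≤ 22` and the tabulated parameter magnitudes are
compatible with a 30-sample recovery window.

**Solver.** The closed-loop system is linear time-invariant, so the
production solver is exact: analytic eigendecomposition of the 2×2
system matrix (complex arithmetic handles the oscillatory case), with a
matrix-exponential propagation fallback when the eigenvalue gap is below
1e−7 (critically damped boundary, `a ≈ 4K`). `LT` is continuous, not
grid-aligned: the closed-loop phase starts from the open-loop closed
form evaluated exactly at `LT`, avoiding a one-sample quantisation floor
on lag estimates. Numeric ODE integration appears only in test oracles
(independent fixed-step RK4 and `solve_ivp` routes).

## Estimation

Per curve, three stages over `(LT, a, d, K)` with `T` and `r` fixed
measured inputs:

1. **Graphical initialisation.** `LT0` = index of the undershoot
   minimum, or, for monotone curves, the sample preceding the largest
   positive second difference (the re-warming slope break); if neither
   exists the lag clips to its upper bound. `a0` = reciprocal of the
   time after `LT0` at which the curve first covers 63.2% of the gap to
   its final value (mean of the last 3 samples). The whole-loop gain
   estimate (final value over `r`) maps onto the controller gain as
   `K0 = gain × a0` because the plant is unitary-gain. `d0` = the
   pre-switch extremum (open-loop asymptote estimate). Everything clips
   into the search box; a flat curve falls back to the box centre with a
   warning.
2. **Simplex refinement.** Nelder–Mead on the mean-squared cost with a
   quadratic out-of-box penalty (weight 1e3), max 500 iterations,
   `xatol 1e−4` / `fatol 1e−10` (loose on purpose — the next stage
   polishes). The incumbent is clipped and never returned worse than
   the clipped initial guess.
3. **Bounded nonlinear least squares.** Trust-region reflective on the
   residual vector scaled by `1/√NE` (so the optimized quantity equals
   the mean-squared cost), `xtol 1e−8`, `ftol 1e−10`, max 200
   iterations. The reported fit is the better of the NLS and simplex
   points, making the cost monotone along the whole chain.

The cost is the mean squared misfit in °C² (the normalisation makes the
exclusion rule length-independent): fits with cost strictly above 1
(≈1 °C RMS) are excluded from statistics; cost exactly 1 is retained.

**Identifiability.** `d` is well identified only when the open-loop
phase is visible (`LT` of a few samples or more): once the loop closes,
integral action absorbs any constant input into the steady state, so for
`LT < 1` sample the data constrain `d` only through a short transient.
Expect heavy-tailed `d` errors on small-`LT` curves; this is a property
of the model class, not of the optimizer.

## Preprocessing

Exports are CSVs with a `time_s` column plus one column per ROI,
covering 9 baseline + 30 recovery samples (the 2-minute exercise gap is
not recorded). Smoothing is a centred moving average of span 5 with
shrinking symmetric edge windows (windows of 1, 3, 5 at offsets 0, 1,
≥2), applied to the full trace before segmentation so boundary samples
share windows. `T` is the baseline time-average, `y0` the first recovery
sample (no extrapolation into the unrecorded gap), `r = T − y0`.

Samples outside a 15–42 °C plausibility window are treated as sensor
dropouts: masked with a warning and linearly interpolated when they make
up at most 10% of the series. A *sustained* excursion (> 10% of samples)
is retained untouched instead — it is a property of the curve (e.g. a
locally unstable recovery), not a sensor fault, and the cost-based
exclusion downstream is the right judge of it.

Note that filtering the data while fitting the unfiltered model is a
(slightly) biased estimator: the moving average smears the switch kink,
which mostly affects fast-pole regimes. The pipeline keeps the
filter-then-fit order because that is the procedure being modelled; the
estimator-quality tests therefore characterise the estimator on
unfiltered deviation curves.

## Synthetic cohorts

The generator emulates the study design so every downstream stage is
testable without any recording: 11 patients + 9 controls × 14 ROIs = 280
curves (154/126 per group). Per (group, ROI), the four parameters are
drawn from normal distributions with the packaged population means/SDs,
truncated to the search box by resampling (≤100 draws, then clip) —
normality is the minimal assumption given only means and SDs, and
truncation enforces physicality since several SDs exceed their means.
Per subject, `T ~ N(30 °C, 1²)` and `r ~ N(0.8 °C, 0.3²)` truncated
positive — magnitudes chosen as typical hand-dorsum values, configurable.
Measurement noise is iid Gaussian with SD 0.04 °C, the thermal camera's
stated temperature resolution, added to baseline and recovery alike.
All randomness flows from one seed through a spawned `SeedSequence`
tree; identical seeds give byte-identical exports.

What the generator does *not* emulate: inter-ROI correlation within a
hand (ROIs are independent draws), drift or autocorrelated sensor noise,
motion artefacts, and any within-subject coupling between `T`, `r` and
the model parameters. Passing tests therefore demonstrate correctness of
the computational chain and its behaviour under the assumed data model,
not performance on real recordings.

A consequence of the truncated-normal population worth knowing: the
tabulated SDs put roughly 20–35% probability on `K < 0` in several ROIs,
so a sizeable minority of synthetic curves are locally unstable and can
leave the plausible temperature range; they are generated faithfully and
almost always removed by the cost exclusion (typically ~30 of 280
curves, the same order as the 25 exclusions the original analysis
reports).

## Statistics and classification

Shapiro–Wilk for normality screening (3 ≤ n ≤ 5000). Group comparisons
use the Wilcoxon–Mann–Whitney rank-sum of the patient group with midrank
ties: for `min(n1, n2) < 10` the exact two-sided p is computed by
dynamic programming over doubled midranks (exact under ties) and no z is
reported; otherwise a tie-corrected normal approximation supplies z.
α = 0.05, two-sided, no multiplicity correction (matching the analysis
being reproduced). Per-region classification is a binary logistic
regression of diagnosis on `(LT, a, d, K)` with intercept; perfect
separation — common at 20 records per ROI with 4 predictors — is
detected and flagged rather than silently diverging. The ROC operating
point maximises Youden's J with ties broken toward higher sensitivity,
then toward the higher threshold; records at exactly the cutoff are
predicted positive. The confusion matrix is row-normalised per original
group, in-sample.

## Test design choices

- Oracle-equivalence and steady-state sweeps sample the search box
  restricted to its stable subset `K ≥ 0` (the steady-state sweep also
  bounds `a, K ≥ 0.05` so the slow eigenvalue, `≈ min(a/2, K)`, mixes
  within the 20×-extended window). On unstable draws trajectories reach
  ~1e56, where absolute-error assertions are meaningless.
- The brute-force RK4 oracle refines its step to
  `min(dt/100, 0.01/ω)`, `ω = max(a, √(aK))`, keeping the *oracle's*
  accumulated phase error comfortably below the 1e−5 comparison band
  even for the fastest admissible dynamics (`ω ≈ 55` per sample).
- Problem sizes: recovery tests use the protocol's 30-sample window;
  estimator sweeps use 50–200 replicates; the cohort discrimination
  property uses 20 seeded full cohorts.

## Known limitations

- The pooled-cohort discrimination property (significant group
  difference in `d` and/or `K` in ≥80% of seeded replicates) is at the
  edge of what the assumed population supports: measured on the *true*
  generating parameters it holds in exactly 16/20 seeds, and end-to-end
  (fit + exclusion) in 14/20. The gap is driven by the weak
  identifiability of `d` at small `LT`, the per-curve uncertainty of the
  measured `y0`, and the exclusion rule trimming extreme-`K` curves.
- No uncertainty quantification on fitted parameters (no bootstrap CIs),
  no multi-start optimisation beyond the single graphical init, and no
  cross-validated classification (in-sample, as in the analysis being
  reproduced).
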