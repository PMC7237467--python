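# Methods

## The task

Eight binary decision units share one screen. Each unit `i` owns a hidden
movement direction `mu_i`; the eight directions are a rotated wind rose
(equiangular spacing `pi/4`, one uniform rotation in `[0, pi/4)`, randomly
permuted over units) redrawn every *batch* of ten *trials*. Within a trial
the group steers a cursor from a random start to a target placed exactly
840 px away (both rejected into the inner 80% of a 1980 x 1080 px display).
At every discrete time point each active unit contributes a 10 px step along
its direction; the cursor moves by the vector sum. A trial ends when the
cursor comes within `target_radius` of the target (default 30 px — the
radius is not part of the published task description; it only controls trial
termination) or after `max_steps_per_trial` (default 2000) steps, in which
case the trial is flagged as aborted. Learning state persists across the
trials of a batch and is reset between batches. Coordinates are mathematical
(x right, y up); angles are `atan2` values wrapped to `[0, 2*pi)`.

Simulated sessions are also rendered as millisecond event logs in the format
of the original recordings (press timestamps per player, cursor trajectory
samples, batch and trial marks), with one step per 130 ms and a 3 s pause
between trials, so that the discretization pipeline below round-trips the
simulator's internal matrices exactly.

## Time discretization

Recorded logs are binned with the *adaptive bin width*: the minimum over
players of that player's minimum inter-press interval. This is the largest
width that provably never places two presses of the same player in one bin
(two points in a half-open bin of width `w` differ by less than `w`). Events
in one bin count as simultaneous; the trajectory is forward-filled at bin
starts. Analysis records are binned per trial (anchored at the trial start)
so inter-trial pauses never produce rows.

## The shared decision pipeline

Each unit, at each time point:

1. observes the on-screen target-difference angle `psi` through Gaussian
   angular noise of variance `beta3` (rad^2), giving its private `phi`;
2. encodes `phi` by tile coding: `m = 45` tilings of `n = 8` tiles, exactly
   one active tile per tiling, flat layout tiling-major. The 45 tilings
   jointly partition the circle into 360 cells of width `pi/180`; the
   encoding is constant on each cell (and is precomputed per cell). The
   circular mean of the 45 active tile centers equals the cell center, which
   is why the feature-conditional angle density is uniform on that cell with
   height `nm/(2*pi)`;
3. maps the features to a scalar activation `g` (model specific, below);
4. presses with probability `(1-q) * (eps/2 + (1-eps) * sigma(g))`, where
   `sigma(x) = atan(gain*x)/pi + 1/2`, `q = 0.1939` forces idleness as a
   refractory surrogate (resampled independently per unit and step), and
   `eps = max(beta2, 0.85^c)` decays with the unit's spike count `c`. The
   published decay is written `e^(-rho c)` with `rho = log 0.85 < 0`, which
   would grow; we implement the evidently intended decay and expose the base;
5. if it pressed, absorbs the outcome with probability `beta1`
   (inattention), updating its model parameters.

Units never see another unit's action: their only inputs are the shared
angle and the realized group displacement.

**Displacement observation.** A unit keeps the running vector sum of the
group displacements over its own active steps and, on each accepted update,
feeds the *angle of that running average* into its belief. We also
implemented the alternative in which each active step contributes the angle
of that step's own group displacement; it is markedly less stable (on some
seeds the group never coordinates and session success collapses toward
chance) and matches the published group statistics worse, so the averaged
form is the default and only behavior. Zero net displacement contributes
nothing.

## The four models

**Bayes.** Belief over the unit's hidden direction: sufficient statistics
`(R0, Phi, c)` — resultant length, resultant direction (undefined while
`R0 = 0`), observation count — updated by vector-adding unit vectors of
observed angles. The posterior over direction `nu` and concentration `kappa`
is `p(nu, kappa) ∝ exp(kappa R0 cos(Phi - nu)) / I0(kappa)^c`. The flat
prior over `kappa` is improper; we truncate `kappa` to a 50-point
logarithmic grid on (1e-2, 500], which both makes it proper and resolves
the `pi/180` tile width. Numerically we use the exact factorization
`p(kappa) ∝ I0(R0 kappa)/I0(kappa)^c` (direction marginalized analytically)
with `nu | kappa ~ vonMises(Phi, kappa R0)`. Bessel functions are evaluated
through the exponentially scaled `I0` (`scipy.special.ive`), which is the
uniformly accurate form of the large-argument asymptotic regularization and
never overflows. The activation is the expected utility of pressing,
`U(1, phi, nu) = pi/2 - d_C(phi, nu)` (circular distance), integrated over
the posterior and over the feature-conditional angle density: the direction
mixture is tabulated on a 360-point grid, convolved with the distance kernel
by FFT, and averaged over a 16-point midpoint quadrature across the
feature cell; the profile is cached per belief state. A tenfold grid
refinement changes the result by less than 1e-2 (tested). The uninformed
belief gives exactly zero by symmetry. `U(0, ., .) = 0`, so `g` is the
expected gain of pressing over idling.

**Thompson.** Same belief; the activation is a single posterior sample of
the utility: draw `kappa` from the grid weights, `nu ~ vonMises(Phi,
kappa R0)` exactly, `phi` uniform on the feature cell. This is an unbiased
one-sample estimator of the Bayes activation (tested against the quadrature
within Monte-Carlo error).

**SARSA(lambda).** Linear state-action values over the tile-coded features,
two actions (idle block stacked before the press block). Reward
`r = sign(d_t - d_{t+1})` of the realized group step. Updates follow the
published order literally: replacing-trace update, TD update with the next
state-action value, trace decay by `gamma*lambda`. Units update only on
steps where they pressed; the trace and the pending bootstrap transition are
episodic (reset at trial boundaries; terminal transitions drop the bootstrap
term) while the weights persist across the batch. Because 45 features are
active at once, one update moves `Q` by `45*alpha*delta`; learning rates of
order `0.1` oscillate, and the calibrated value is `alpha = 0.035`
(effectively `alpha/m`-scaled, the standard tile-coding practice).

**Perceptron.** `g = w . f + b`, trained only on pressed steps by the
binary signal `T` (did the group step reduce the distance?). The published
update `w <- w + alpha (T-1) w`, `b <- b + alpha (T-1) b` is multiplicative
and, with the stated zero initialization, never leaves the origin; it is
retained under `variant="as_printed"` (and its degeneracy is unit-tested),
but the default is the feature-based punitive rule `w <- w + alpha (T-1) f`,
`b <- b + alpha (T-1)`, which punishes the active features after failed
presses and satisfies the same "no update when label and training signal
coincide" property. The dynamics are exactly invariant under
`(alpha, gain) -> (c*alpha, gain/c)`, so only the product is a real degree
of freedom.

## Cooperation statistics

All statistics operate on the binned action matrix `A` (N x 8), cursor
positions before/after each step, and per-row targets. The Heaviside
comparisons are strict (`H(x) = 1` iff `x > 0`): with threshold
`delta = 0`, "success" means the distance strictly decreased; ties (no
movement) are failures, which reproduces the 50% chance level of an
unlearned group.

* **Success rate**: fraction of *decision* time points (rows with at least
  one press) whose distance drop exceeds `delta`. The printed formula
  averages over all rows, but the accompanying text restricts to rows where
  at least one player responded; we follow the text. The threshold sweep
  expresses `delta` as a fraction of display size (width by default,
  diagonal available — the normalization is not defined in the source).
* **Pairwise success** `S_ij`: same numerator restricted to rows where both
  `i` and `j` pressed, divided by the count of such rows; undefined (NaN)
  for pairs that never co-activate.
* **Correct response rate** `R_i`: fraction of `i`'s presses for which a
  lone 10 px step along `mu_i` would have strictly reduced the distance.
* **Event synchronization** `ES_ij`: counts of near-coincident spikes
  within `tau_kl` = half the minimum of the four surrounding inter-spike
  intervals (missing boundary intervals enter the minimum as +inf),
  normalized by `sqrt(m_i m_j)`; equal times count 1/2 in each direction.
  Implemented with a windowed `searchsorted` scan, tested against a literal
  double-loop oracle. `ES` is 1 for identical trains and 0 for trains far
  apart.
* **Action-time correlation** `C_ij`: the product-moment formula on the
  binary activity columns; on binary data Pearson and Spearman coincide
  (phi coefficient, unit-tested), so the printed formula implements the
  stated Spearman correlation. Constant columns give NaN.
* **Cooperation measure** `zeta`: sample covariance (divisor 27) over the
  28 strict-upper-triangle pairs between the correlation and pairwise-
  success matrices. Because the direction assignment is batch-local, the
  per-batch matrices are re-ordered by direction rank and *averaged across
  batches*, and `zeta` is the covariance of the averaged matrices — the
  matrices the group-level figures show. Computing `zeta` per batch and
  averaging instead inflates the value several-fold, because the
  within-batch sampling noise of `C` and `S` is itself positively
  correlated; that variant is reported as `zeta_per_batch`. Note the
  averaged-matrix `zeta` decreases with the number of batches averaged (the
  noise-covariance term scales as 1/n_batches), so it is only comparable at
  matched protocol sizes.
* **Synchronization by distance**: mean `ES` bucketed by the signed
  circular distance between the pair's true directions (multiples of
  `pi/4`; +-pi share one bucket). Cooperative groups show a U-shape with
  the minimum at +-pi.

Undefined statistics propagate as NaN and are reported (never silently 0);
`zeta` raises with the offending pairs listed if any of the 28 entries is
undefined.

## Learning statistics

The stimulus of a press is the *noiseless* on-screen target-difference
angle at that time point (an analysis-side quantity; the unit's private
noisy angle is not observable to an analyst).

* **STA / STV**: circular mean and `1 - resultant length` of the
  spike-conditioned angles, tracked over ordinal spike number. A vanishing
  resultant leaves the STA undefined (NaN). The STV is the dimensionless
  circular variance in [0, 1]; the source labels it rad^2. Note the running
  (cumulative) STV of a simulated unit starts near zero — its first spikes
  usually fall within a single trial and share one stimulus angle — and
  converges from below to the ensemble circular variance of its receptive
  field; small asymptotic values, not a monotone decline, are the signature
  of sharp tuning here.
* **Learning duration** `T*`: smallest spike ordinal from which the running
  STA stays within `pi/2` of the true direction for every later spike;
  censored if never. Undefined STA values count as outside.
* **Learning-curve fit**: least squares of `F(k) = 1 - exp(-r k)` to the
  empirical fraction of durations `<= k`. Censored unit-batches are
  excluded from the curve (a CDF with asymptote 1 is only consistent with
  observed durations) but their count is reported; the "fraction learned
  within 50 spikes" uses the same uncensored denominator. Degenerate
  all-equal data put `r` at the optimizer boundary and are flagged.
* **Population-vector decoding**: with unit axes `e_i` at the whole-batch
  STAs, `v_pop = sum_i <v, e_i> e_i`. For exactly equiangular axes this is
  a tight frame (`v_pop = 4 v`), so the angular error vanishes — a
  machine-precision test. The decoding error is the mean circular distance
  between the decoded and true angles over the batch's time points; a
  zero-length population vector contributes `pi/2` (chance). Batches where
  some unit never pressed are skipped and counted.

## Calibration

The hyperparameters that the original study fitted per model are not
published. The package ships a coarse grid-search harness
(`neurongame.calibration.grid_search`) that simulates reduced sessions and
scores candidates by distance to the published model-level statistics, and
a frozen profile (`data/calibration.yaml`, v3) produced with it:

| parameter | Bayes/Thompson | SARSA(lambda) | perceptron |
|---|---|---|---|
| `beta1` (update prob.) | 0.35 | 0.9 | 0.9 |
| `beta2` (exploration floor) | 0.01 | 0.05 | 0.05 |
| `beta3` (noise var., rad^2) | 0.05 | 0.01 | 0.1 |
| `gain` | 20 | 20 | 5 |
| model-specific | — | `alpha=0.035, gamma=0.9, lambda=0.5` | `alpha=0.007` |

`q = 0.1939`, `epsilon_base = 0.85`, `n = 8`, `m = 45` are fixed study
conditions, not calibration knobs. The low `beta1` for the belief models
keeps posterior concentration growing slowly, which preserves Thompson
exploration longer and strengthens the covariance structure behind `zeta`.

## Synthetic fixtures

`FixtureSpec`/`generate_fixture` emulate the millisecond recording format
without any behavioral model: each player is a direction-tuned point
process (von Mises-shaped rate, peak 2 spikes/s, floor 0.3 spikes/s,
width 1.0 rad by default; `tuning_width=None` gives the untuned null),
presses displace the cursor by 10 px at their own jittered timestamps, and
the trajectory is sampled at every tick and press so the adaptive binning
attributes each displacement to the bin of the press that caused it. Tuned
fixtures exercise every analysis path (positive `zeta`, U-shaped
synchronization profile); untuned ones sit at the null. The fixtures
emulate the *format and first-order tuning statistics* of real recordings,
not learning: their rates are stationary within a batch, so passing
fixture-based tests says nothing about adaptation dynamics, and nothing
about heterogeneous skill across players, which real groups show.

## What the simulations do and do not establish

The simulated groups are homogeneous (eight copies of one average unit), so
they lack the good/average/bad player spread of real groups. Two group
statistics sit systematically away from the published human-fitted model
values in our re-implementation and are documented rather than forced: the
belief-model individual correct-response rate saturates near 67% (once the
group coordinates, a unit's displacement observations reflect the group's
heading rather than its own direction — the restoring force toward the true
direction is only the unit's own one-in-several-steps share — leaving a
residual direction bias of ~0.5 rad), and the SARSA group's cooperation
measure stays below ~0.001 under the averaged-matrix convention (its
correlation amplitudes are weak, as the source itself notes). All other
model-level statistics reproduce within the stated tolerances at the
standard protocol (40 batches x 10 trials, >= 5 seeds; 10 batches and 3
seeds for the quadrature Bayes units, whose activation integral makes full
sessions ~6x costlier).

## Problem sizes and determinism

Default sessions are 40 batches x 10 trials; a full calibrated session
simulates ~36k (Thompson) to ~550k (perceptron, the slowest learner)
discrete time points and runs in seconds to half a minute. All randomness
flows from one master seed through fixed `spawn_key` streams: geometry and
engine draws on one stream, each unit on its own, fixtures on a third, so
adding a unit never perturbs the others' draws and identical seeds give
byte-identical logs.
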