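# neurongame

Simulation and analysis of **group coordination by neuron-like binary
decision units**. Eight players — humans in the original experiment,
simulated units here — each control one button whose press displaces a
shared cursor by a small step in a hidden, player-specific direction; the
group must jointly steer the cursor into targets, learning each player's
role purely from the shared visual feedback. Each player thus behaves like
a neuron emitting a spike train, and the group like a tiny population code:
the cursor moves along the population vector of the active units.

The package is for computational neuroscientists and group-behavior
researchers who want to (a) simulate such groups under four behavioral
models and (b) quantify cooperation and learning in either simulated or
recorded millisecond event logs.

## What it implements

**Environment.** Trials steer the cursor over a fixed 840 px start-target
distance on a 1980 x 1080 px display (10 px unit steps, vector-sum group
displacement); ten trials form a batch sharing one random equiangular
("rotated wind rose") direction assignment; learning resets between
batches. Recorded logs are discretized with an adaptive bin width — the
smallest inter-press interval of any single player — guaranteeing no player
is active twice at one discrete time point.

**Models.** Four unit models share one decision pipeline (noisy angle
observation, tile-coded features with n=8 tiles x m=45 tilings, arctan
soft activation, spike-count-decaying exploration, forced-idle probability
q=19.39%, update probability beta1):

* *Bayes* — von Mises belief `p(nu,kappa) ∝ exp(kappa R0 cos(Phi-nu)) / I0(kappa)^c`
  over the unit's own direction; activation = expected utility
  `E[pi/2 - d_C(phi, nu)]` by numerical quadrature;
* *Thompson* — same belief, activation = one posterior sample of the utility;
* *SARSA(lambda)* — linear two-action values on the tile code, replacing
  eligibility traces, reward `sign(d_t - d_{t+1})`;
* *perceptron* — punitive single-layer rule driven by the binary
  did-it-get-closer signal.

**Metrics.** Group success rate (fraction of decision time points whose
step reduced target distance by more than a threshold), counterfactual
individual correct-response rates, event synchronization of spike-train
pairs, action-time (phi) correlations, the scalar cooperation measure
`zeta` (covariance between pair correlations and pair success
probabilities over the 28 pairs), spike-triggered average/variance,
learning durations with cumulative-exponential fits, and population-vector
decoding error. See `docs/methods.md` for the precise definitions and
numerical choices.

## A worked example

```bash
python examples/run_simulation.py
```

```
simulated 4 batches, 2932 group decisions
group success rate:        0.898
mean correct response:     0.689
synergy gap (group-indiv): +0.209
cooperation measure zeta:  0.0058
```

A Thompson-sampling group of eight units played four batches of ten trials.
89.8% of the time points with at least one press moved the cursor strictly
closer to the target, while only 68.9% of individual presses would have
helped had that unit acted alone — the +0.21 gap is the synergy of pooling
eight noisy decisions. The positive `zeta` says that the pairs of units
pressing together are also the pairs whose joint steps tend to succeed,
i.e. the group coordinates rather than merely coincides. (Short runs like
this one fluctuate by a few points between seeds; `zeta` in particular
shrinks as more batches are averaged — see `docs/methods.md`.)

The other example scripts show the recording-format pipeline
(`analyze_fixture_log.py`), the learning statistics
(`learning_progress.py`) and the belief machinery (`belief_machinery.py`).

A thin CLI wraps the same functions:

```bash
neurongame simulate --model thompson --seed 1 --out runs/thom1
neurongame analyze metrics --in runs/thom1 --out thom1.json
neurongame analyze learning --in runs/thom1 --out thom1_learning.json
neurongame report runs/thom1 --out report/
neurongame fixture --out events.jsonl --seed 3
```

Hyperparameters that the original study fitted per model are not published;
the package ships a calibration profile (`src/neurongame/data/calibration.yaml`)
produced by its own grid-search harness (`neurongame calibrate`).

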