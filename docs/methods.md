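# Methods

## Signal model and task

At walk, a dog's pelvis rolls laterally with each support phase. A single
IMU fixed over the second sacral vertebra measures this as the gyroscope
roll angle, in degrees, sampled at 100 Hz. The package addresses a binary
screen: label 0 = sound, label 1 = unilateral supporting-hindlimb lameness.
The working assumption is that a lame dog unloads the painful limb, so the
lean toward that side has reduced amplitude, while a sound dog's roll trace
is symmetric about zero up to noise. Side identity is not modeled: the
classifier detects asymmetry, not which limb causes it.

## Synthetic cohorts

No public recordings exist for this task, so the simulator is a first-class
component, not a test fixture. One trial is

    base(t) = A sin(2π f t + φ)
    lame:     negative half-cycles of base scaled by r ∈ (0, 1]
    trace(t) = base(t) + ε(t) + a(t)

with `ε ~ N(0, σ²)` i.i.d. per sample and `a(t)` an artifact: with
probability ρ per sample, a draw from Uniform(−M, M), else zero. Defaults
(`GaitSimParams`): stride frequency f = 1.5 Hz, amplitude A = 10° (≈20°
peak-to-peak), noise σ = 1°, artifact rate ρ = 0.01, artifact magnitude
M = 15°, 400 samples at 100 Hz. The default lame condition is r = 0.6, a
clearly but not grotesquely lame gait (a 40% amplitude deficit on one side).

Cohorts draw each dog's frequency and amplitude with ±10% uniform jitter so
subjects are mutually distinguishable and subject-level splitting is
actually exercised; each dog contributes several trials (three by default,
matching field practice). Randomness is hierarchical
(cohort seed → per-dog stream → per-trial stream), so appending dogs to a
cohort leaves earlier dogs' data untouched.

What the simulator deliberately omits: temporal (duty-cycle) asymmetry,
stride-to-stride variability, drift and soft-tissue oscillation, pitch/yaw
coupling, forelimb and bilateral lameness. Passing tests therefore show
that the pipeline recovers *amplitude* asymmetry under noise and artifacts
at realistic sample sizes — not that it generalizes to clinical recordings.

## Cleaning: percentile band filter

Per trial, only samples whose value lies inside the central percentile band
survive, in their original order; defaults keep the 10th–90th band, i.e.
the inner ~80% of the empirical distribution, which removes head-shake
spikes without touching the gait oscillation.

Percentile convention: nearest-rank order statistics, no interpolation.
`percentile(v, q)` returns the ⌈q/100·n⌉-th smallest value. The band's
*lower* cutoff mirrors the upper one — counted from the maximum, which
lands on the ⌊low/100·n⌋+1-th smallest value — so the two tails are trimmed
symmetrically and exactly ~(high−low)% of tie-free data survives. Bounds
are inclusive, so a constant trace passes through unchanged. With
`low < high` the retained set is provably non-empty; the degenerate-result
error path is defensive only.

Percentile trimming is *not* idempotent: a second application trims a
further ~20% of the already-trimmed values. This is inherent to rank-based
cutoffs on continuous data, and the filter is applied exactly once per
trial.

## Windowing

Cleaned traces are cut to the model's fixed sequence length (250 samples =
2.5 s at 100 Hz, several stride cycles). A trace shorter than the window is
padded with leading zeros into a single window — the pad reads as "the dog
stood still before the recording" and precedes the data so the recurrent
state ends on real gait. Longer traces yield ⌊(L−W)/stride⌋+1 windows at
offsets 0, stride, 2·stride, …; the default stride equals the window length
(non-overlapping), and overlap is configurable to augment small cohorts.
No mask channel marks the padding; the pad value 0 is in-band.

## Classifier

A stacked LSTM: one scalar input per time step (roll in degrees), 2 layers
of 256 units by default, final hidden state of the top layer → one fully
connected unit → sigmoid → `p(lame)`. The engine (forward, backpropagation
through time, Adam, global-norm gradient clipping) is written directly in
NumPy (float32); per-step recurrences are looped while input projections
and weight-gradient contractions are batched over all timesteps into single
BLAS calls, which keeps the 2×256 configuration trainable in seconds per
epoch on one CPU core.

Numerical and design choices, all package decisions where the underlying
recipe is silent:

* **Initialization.** Uniform(−k, k) with fan-in scaling: k = 1/√d for
  input-to-hidden weights (d = input dimension) and k = 1/√H for recurrent
  weights and the head; forget-gate biases start at 1. Fan-in scaling on
  the first layer is essential: its input is a single scalar, and scaling
  its weights by 1/√H instead leaves the hidden dynamics nearly insensitive
  to the input at H = 256, where training then stalls indefinitely on the
  constant-output plateau (p ≡ 0.5, MSE ≈ 0.25).
* **Dropout placement.** Inverted dropout on the sequence passed between
  LSTM layers only, masks i.i.d. per element and timestep, active only in
  training. The final hidden state is *not* dropped before the head:
  corrupting the head's only input at batch size 3 injects enough gradient
  noise that plateau escape becomes unreliable. This matches the dropout
  semantics of mainstream LSTM implementations.
* **Head.** A single linear unit; the binary decision needs only one
  sigmoid probability, with 0 = sound and 1 = lame.
* **Loss.** MSE between sigmoid output and the 0/1 label (the recipe's
  choice), not cross-entropy.
* **Tie rule.** `classify(p, t)` returns lame when p ≥ t: in a screening
  tool the threshold tie favors sensitivity.
* **Checkpoints.** A single `.npz` holding every weight array plus the
  model (and optionally preprocessing) configuration as embedded JSON;
  loading reproduces predictions bit-identically and validates shapes
  against the stored configuration.

## Training and evaluation

`TrainConfig` defaults document the reference recipe: learning rate 0.1
(the recipe's stated value), 200 epochs, batch size 3, global gradient-norm
clip 1.0, validation fraction 0.2. In practice Adam at 0.1 on this loss
diverges more often than it converges — the recipe itself warns that high
rates diverge — so every convergence-critical path in this package
(the pipeline default, the CLI default, the acceptance script) uses 0.01;
the faithful value remains available by configuration.

Each epoch shuffles windows (seeded), iterates batches, backpropagates,
clips the global gradient norm, and applies Adam. Non-finite losses abort
with the failing epoch. Early stopping — patience 20 on validation loss
with a 10⁻⁴ minimum improvement, best-weights restore — is an addition
beyond the reference recipe; pass `early_stopping_patience=None` for the
faithful fixed-epoch schedule.

Splits are at the dog level: `round(fraction × n_dogs)` dogs (clamped to
[1, n−1]) form the validation set, stratified by label via largest-remainder
apportionment when both classes are present. No dog ever contributes
windows to both partitions. With 15 dogs and fraction 0.2 this yields the
12-train / 3-validation design. A dog's diagnosis is the mean of its window
probabilities (the recipe never specifies how trials combine; the mean is
the package's choice), and reports carry window-level accuracy, dog-level
accuracy, and dog-level confusion counts, since with three validation dogs
the dog-level accuracy is quantized to thirds.

## Problem sizes in the test suite

The signal-recovery checks train the full 2×256 configuration on balanced
40-dog cohorts (3 trials × 400 samples, asymmetry 0.6, noise 1°, artifacts
1%) across five independent cohort seeds, with early-stopping patience 8
inside the 200-epoch budget; the permuted-label null control reuses the
same conditions over two permutation seeds. Smaller configurations (1×8 to
1×16 units, 6–16 dogs) exercise memorization, determinism, and the CLI.
These sizes are the package's choice of a desk-scale experiment that still
separates signal from null cleanly.

## Known limitations

* The asymmetry model is a plausible reconstruction; no quantitative
  characterization of real lame-dog roll traces was available to fit it.
* Only amplitude asymmetry is modeled and detected; temporal asymmetry,
  forelimb and bilateral lameness are out of scope.
* The percentile cut is per-trial; a cohort-level cut would behave
  differently on trials with unusual overall amplitude.
* Lameness is not graded or lateralized — the output is a probability of
  "some unilateral hindlimb asymmetry".
* MSE on a sigmoid output has weak gradients near saturated predictions;
  the chosen initialization and learning rate mitigate but do not remove
  this.
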