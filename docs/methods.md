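# Methods

## The scientific problem

The package models how time-continuous motor behavior in a visually rich,
fast task can be predicted from the internal features of a deep Q-network
(DQN).  The original study setting is human players of arcade games whose
screens, key presses and rewards are recorded at 45 Hz; that dataset is not
public, and the published agents need days of GPU training.  This package
therefore rebuilds the complete analysis at desk scale on fully synthetic
data: a toy game supplies the video, numpy Q-networks supply the features,
and a stochastic "responder" with known ground-truth structure supplies the
key-press trains.  Every stage is the same two-step design as the original
analysis — (1) a DQN maps video to per-action Q-values, (2) a logistic
encoding model maps Q-values to responses — so the pipeline's statistical
properties (parameter recovery, smoothing trade-off, architecture ordering,
training-score coupling) can be verified against oracles and known
generators.

## The toy environment (MiniCatch)

A ball drops one row per frame from the top of a 12x12 grid; the player
slides a 3-pixel paddle along the bottom row (actions: no-op, left, right).
A catch scores +1, a miss costs one of 3 lives, and the ball respawns at a
seeded-random top column; an episode ends at 0 lives, and sessions of a
fixed frame count contain many episodes.  Frames are grayscale (background
0, paddle 128, ball 255).  The geometry was chosen so the induced MDP is
small enough for exact solution while the rendered video still exercises the
whole preprocessing chain.  Sessions default to 20,000 frames at a nominal
45 Hz, matching the session structure of the original recordings; the
studies and tests use 2,000-frame sessions and 7 sessions per synthetic
subject, a problem size chosen so the complete pipeline runs in minutes on
one CPU while every fold retains ~1,950 usable time steps.

## The synthetic responder

At each time step of a (base-rate) Q-series, the responder samples one
action from

    softmax(beta * z(Q) + noop_bias * e_noop),

where z(.) is a z-score across actions (making beta scale-free, mirroring
the encoding model's standardization), then repeats the previous action with
probability `hold_prob`, and finally delays the emitted one-hot series by
`lag` frames (zeros fill the gap — a causal motor delay).  Defaults:

| parameter | default | rationale |
|---|---|---|
| beta | 2.0 | decisions follow the Q-drive but stay noisy; cross-validated r lands in the 0.3–0.8 range rather than at ceiling |
| lag | 4 frames (~89 ms) | the pipeline's asymmetric alignment trims (below) shift responses 4 frames relative to predictors, i.e. they compensate exactly this delay |
| hold_prob | 0.85 | geometric key-hold durations with mean ~6.7 frames (~150 ms), producing the autocorrelation real key presses have |
| noop_bias | 0.5 | a preference for doing nothing, emulating the reported human no-op tendency |

What the generator does **not** emulate: visual processing noise, fatigue or
learning within a session, anticipatory (negative-lag) responses, and
combined key chords (the response binarizer supports splitting labels such
as `fire-right`, but MiniCatch has single-key actions).  Passing tests
therefore show that the pipeline recovers structure *of this kind*; they do
not certify recovery on real human data.

## The agent ladder

Three variants share a convolutional torso (default: 32/8x8/4, 64/4x4/2,
64/3x3/1 filters with ReLU, fully connected 512, for 84x84 inputs; the
`mini` preset used throughout the studies is one 8-filter 3x3 conv and a
64-unit layer on 12x12 inputs — both satisfy identical contracts):

* **baseline** — feed-forward, vanilla Q-learning;
* **dueling_double** — separate value/advantage streams combined as
  `Q_a = V + (A_a - mean(A))`, trained with double Q-learning and 3-step
  bootstrap targets.  This rung stands for the distributed prioritized-replay
  agent of the original ladder *by its architectural and learning deltas
  only*; the actor/learner systems machinery contributes throughput, not
  model class, and is deliberately dropped;
* **recurrent** — an LSTM after the fully connected layer, receiving the
  last reward, terminal flag and previous-action one-hot as auxiliary
  inputs, with linear dueling heads on the hidden state.  During feature
  extraction the action vector is fixed to zeros so the agent's own choices
  cannot leak into the features.

Training is classic DQN: epsilon-greedy (epsilon = 0.05), uniform replay,
Huber loss, Adam at lr 2.5e-4, gamma 0.99, batch 32, reward clipping to
[-1, 1], target-network sync every 200 updates.  Agents act through a
frame-skip-4 wrapper whose observation is the pixelwise max of the last two
frames of each group — the same statistic the feature extractor computes —
so training and extraction see identical inputs.  The recurrent variant
trains on length-8 windows sampled from stored episodes with zero initial
hidden state (a standard truncated-BPTT simplification).  The networks are
plain numpy with hand-written backward passes (verified against numerical
differentiation in development); this keeps the package dependency-light and
bit-reproducible.

Conventions the source design left open and that are configurable here:
replay capacity (20,000 transitions), target-sync cadence (200 updates), and
the clipping range [-1, 1].

## Feature extraction

Per session: (1) pairwise-max temporal downsampling — output frame k is the
elementwise max of input frames 4k+2 and 4k+3 (0-based), taking 45 Hz video
to 11.25 Hz; (2) bilinear resize to the network input size, clipped to
[0, 255] (skimage, order 1; the resize dialect is configurable because the
original models used two different backends); (3) FIFO stacking to depth 4,
the first three stacks padded by repeating the earliest frame (keeping the
session head instead of discarding it); (4) one forward pass per stack.
Stacks advance at the preprocessed rate with stride 1.  Recurrent
checkpoints thread hidden state across the whole session with downsampled
reward/terminal auxiliary inputs; `ablate_memory=True` zeroes the hidden
state before every step, which is bit-identical to evaluating each stack
statelessly — the memory-ablation contract used to probe temporal context.

## The encoding model

Per session at the base rate: Q-values are upsampled x4 (row repetition),
z-scored across actions per time step (sample sd, n-1; constant rows map to
zeros so early checkpoints remain usable), and aligned with the responses by
dropping the first 12 and last 3 predictor rows and the first 16 response
rows, then truncating to the common length.  (The stated trims leave a
one-row mismatch — 19,985 vs 19,984 on a 20,000-frame session; common-length
truncation is the repair adopted here.)  Both series are then smoothed with
the same truncated Gaussian kernel: sigma_samples = FWHM x rate / (2 sqrt(2
ln 2)), truncated at 4 sigma and renormalized; the convolution is the
full-length discrete sum, center-cropped back to the input length so
predictors and targets stay aligned.  z-scoring precedes smoothing (order
configurable).

The design matrix is the smoothed z-scored Q columns with the no-op column
replaced by a constant 1 (the no-op indicator is near-complementary to the
other actions, so it is the natural baseline column).  One logistic model
per action is fit by Newton/IRLS maximizing the Bernoulli log-likelihood —
valid for fractional targets in [0, 1], which the smoothed response series
are, read as response probabilities — with an L2 ridge of 1e-4 on the
non-constant columns to stabilize collinear Q predictors.  Fits always use
the smoothed target; evaluation under 7-fold leave-one-session-out
cross-validation scores Pearson r against either the smoothed
(`target_mode="smoothed"`) or the raw binary (`"unsmoothed"`) held-out
series.  Degenerate folds (constant training or held-out target, e.g. an
action never pressed) are flagged and excluded from aggregation; actions
used in fewer than a configurable fraction of sessions can be excluded
outright.  Aggregation averages folds, then actions, then subjects, with an
optional mean over the last k checkpoints of a training run.

## Statistics

Per-subject mean correlations are Fisher-z transformed before parametric
tests; "chance" is z = 0 in a two-sided one-sample t-test (the source design
does not state its chance baseline or sidedness; these are the package's
choices).  The variant comparison is a one-way repeated-measures ANOVA
(hand-computed sums of squares, cross-checked against pingouin in the test
suite) with Greenhouse-Geisser epsilon from the double-centered condition
covariance and the corrected p evaluated at (eps df1, eps df2); post hocs
are paired t-tests with Bonferroni adjustment p_adj = min(1, m p).  The
checkpoint summary correlation r_DQN uses raw scores and raw mean r, no
z-transform.  The FFT diagnostic returns a one-sided amplitude spectrum
scaled so that the sum of squared amplitudes equals the series energy.

## Numerical and degenerate-input choices

* argmax tie-breaks: lowest index (determinism).
* Constant Q rows z-score to zeros rather than erroring.
* Kernels with sub-sample sigma collapse to the identity kernel [1].
* Even-length kernels crop floor((n-1)/2) samples from the head.
* Logistic fits cap at 100 Newton iterations and raise a named
  convergence error with diagnostics; IRLS weights are floored at 1e-10.
* Value iteration rejects gamma >= 1 (no contraction).
* Non-finite training loss aborts with a named divergence error.
* Training episodes are truncated (not terminated) at 2,000 env frames, and
  evaluation episodes at 240 env frames, to bound runtimes on agents that
  rarely miss.

## Study designs wired into the acceptance script

* **Q-learning correctness** — the mini network trained on rendered tabular
  MDPs (single-frame input, gamma 0.5) must land within 0.05 sup-norm of
  exact value iteration.
* **End-to-end recovery** — responses sampled from a trained checkpoint's
  own Q-series (beta 2, no lag, no hold); matched cross-validated r is
  compared with the identical pipeline run on phase-randomized surrogate
  predictors (same power spectrum, scrambled timing), 10 seeds.
* **Smoothing sweep** — FWHM grid {0.09, 0.26, 0.79, 1.57} s, default
  responder, 10 seeds.  Expected shape: smoothed-target accuracy rises with
  kernel width over the first three points; raw-target accuracy peaks at an
  interior width — the information-loss vs temporal-resolution trade-off.
* **Temporal context** — responders driven by a recurrent network's
  memoryful Q-series (history dependence beyond any frame stack) are fit
  with recurrent vs feed-forward features, matched random initializations,
  10 seeds.  This isolates the architectural effect of memory; it does not
  require either agent to be trained.
* **Checkpoint curve** — one dueling+double training run (60,000 env frames,
  11 checkpoints, 50 evaluation episodes each); responses driven by the
  final checkpoint; the correlation between the score curve and accuracy
  curve summarizes how gaming competence and predictive power co-develop.
  Even the frames-0 checkpoint predicts above zero: random convolutional
  features already carry stimulus information.

## Known limitations

* MiniCatch's optimal policy is simple; absolute accuracy numbers are not
  comparable to the original study's, only the qualitative properties are.
* The recurrent rung trains with zero start-state truncated BPTT and no
  prioritized replay, value rescaling or V-trace; it represents the
  recurrent model class, not a faithful re-implementation of any published
  training system.
* The responder's hold/lag dynamics are stationary; slow drifts in human
  responsiveness are out of scope.
* Smoothing is non-causal (symmetric kernel), matching the offline analysis
  setting, not a real-time filter.
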