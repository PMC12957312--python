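# Methods

## The analysis problem

A subject learns a sequence of visuomotor mapping tasks: in each task,
two (or more) visual stimuli map onto two motor decisions (up/down).
Task roles are A, B, C (new stimulus pairs), Revisit-A (task A's
stimuli again) and Reverse-A (task A's stimuli with the mapping
inverted). The question is geometric: which parts of the population
code are *reused* across tasks, and how are the reusable (decision)
and task-specific (stimulus) codes arranged relative to each other?

The pipeline answers this with four linked analyses on a session
tensor X ∈ ℝ^(M×N×T) of spike counts (M trials, N units, T = 100 bins
of 10 ms covering the one-second epoch before the go cue):
demixed subspace decomposition, cross-task manifold-reuse correlation,
the stimulus–decision principal angle with a label-shuffle null, and
frozen-decoder generalization; plus the behavioral statistics that
relate neural reuse to learning speed.

## Preprocessing

Single-trial counts are smoothed with a unit-area Gaussian kernel
(σ = 50 ms, i.e. 5 bins at 10 ms). Edges are handled by reflection
(half-sample symmetric), which keeps a constant series constant and
preserves the total mass of each series to 1e−9; no convention is
canonical here, and reflection avoids attenuating the epoch's ends.
Condition averages are taken over all trials in each
(stimulus, decision) cell — cells must be non-empty, and unequal
counts are averaged as-is rather than padded to a common trial count,
since padding semantics would be arbitrary.

## Demixed decomposition

The centered condition-averaged tensor is marginalized factorially:

    X_ave = x_t + x_ts + x_td + x_tsd

(condition-independent, stimulus, decision, stimulus–decision
interaction). For balanced designs these terms are mutually orthogonal
and their variances add to the total — both properties are tested
exactly.

Components are extracted per marginalization. The encoding axes are
the orthonormal eigenvectors q of the term's covariance C_m; the
decoding axis of each component is the ridge-regression readout of
that component's trajectory from the full data,
d = (C_tot + λI)⁻¹ C_m q, i.e. the encoder pushed through the
regularized total-covariance whitener — this is what suppresses other
factors' variance in the projection. λ defaults to 1e−6·tr(C_tot);
λ = 0 on rank-deficient data raises with a pointer to the ridge.
Components from all four factors are pooled, ranked by explained
variance (the eigenvalue as a fraction of total variance, so a
complete pool sums to one on balanced data) and truncated to p = 20.
How the original budget of 20 was split across factors is not
documented anywhere we could follow; global variance ranking is this
package's declared convention. Decision-component signs are fixed so
the 'up' trajectory has positive mean, making trajectories comparable
across fits.

**Denoising.** Condition averaging leaves a broadband noise floor
spread over all N units. The eigenvectors of C_m are tilted by the
*sum* of these near-threshold noise directions, which biases 1-D
subspace estimates (the planted-0° recovery error was ~9° at any
physiological firing rate before denoising, because the tilt magnitude
is set by the number of noise dimensions as much as by their size).
The fit therefore first projects the condition-averaged data onto the
leading principal axes of the total covariance — by default the
components above 1% of total variance, capped at 16 to match the
latent dimensionality used for decoding. This is the standard
denoise-then-demix ordering for population analyses; an integer fixes
the dimension and `None` disables it (used by the exactness tests).

## Manifold reuse

Demixing is fit on task A alone, giving W_A. Other tasks' activity is
projected through W_A's top-variance decision component without any
refitting. For each decision class c, ρ(S_A^c, S_j^c) is the Pearson
correlation over time; reuse is the mean over the two classes. The
statistic is scale- and offset-invariant, so it measures trajectory
*shape* reuse, not amplitude. Only the single top decision component
is used by default (a multi-component variant exists but is off by
default). Ordinary least squares relates reuse to trials-to-criterion
across sessions (slope, R² against the intercept-only model, two-sided
slope p).

## Subspace angle and null

From a fitted decomposition, components are selected by explained
variance: eligible components must exceed 1% of total variance; the
stimulus subspace takes eligible components in descending order until
they cover ≥70% of the stimulus subspace's variance, while the
decision subspace takes all eligible components (it is low-dimensional
to begin with). Selected encoder columns are re-orthonormalized (QR)
into bases U_d and U_s, and the reported angle is

    θ = arccos(σ_max(U_dᵀ U_s)),

the *smallest* principal angle. The full principal-angle spectrum is
returned alongside because the commonly used numerical routine for
"the" subspace angle returns the largest one; exposing the spectrum
lets either convention be reproduced.

The null distribution permutes the stimulus labels and the decision
labels independently across trials (10 repeats by default), rerunning
the entire fit → select → angle pipeline per repeat; permutations that
empty a condition cell are resampled and logged, keeping the repeat
count fixed. Observed-vs-null group comparisons use the
Watson–Williams test.

## Decoders

Single-trial smoothed activity is reduced to 16-dimensional latent
trajectories by projecting onto the top principal axes of the
trial-concatenated data; the fitted projection is reused verbatim for
held-out tasks of the same session. This linear extraction fills the
M×16×T contract that a sequential variational autoencoder would
provide in a GPU setting; downstream analyses depend only on the
contract.

The classifier is a two-layer temporal CNN:

    H1 = maxpool(relu(conv(X, W1) + b1))
    H2 = maxpool(relu(conv(H1, W2) + b2))
    Y  = softmax(FC(dropout(H2, 0.5)))

with 8 filters per layer, kernel 3, stride 1, padding 1. The pooling
width (2, the smallest nontrivial choice, keeping T = 100 cleanly
divisible) and the training schedule (minibatch SGD, learning rate
0.05, batch 32, up to 200 epochs with early stop on a training-loss
plateau) are this package's choices; the analyses that depend on the
decoder operate in separability regimes insensitive to them. Dropout
uses the inverted convention (scaling at train time), so evaluation is
a plain forward pass. Training uses a stratified 80/20 split or
stratified k-fold (k = 10; plain shuffled folds when k exceeds the
smallest class, e.g. leave-one-out on toy sets). Frozen evaluation is
forward-only and asserts a parameter hash before/after. Chance levels
are 1/2 for decisions and 1/S for stimuli (0.17 at six categories).

## Behavioral statistics

Task acquisition is the earliest trial t ≥ 15 whose trailing 15-trial
window has mean accuracy ≥ 0.9 — read strictly, so 14/15 correct
passes and 13/15 does not. Unacquired tasks fall back to the total
trial count (normalized trials-to-criterion = 1.0). Window alignment
(trailing) is a convention choice. Reaction time is touch − go-cue per
trial; trials with missing or inverted events are excluded with a
warning. Hedges' g applies J = 1 − 3/(4·df − 1) to the pooled-SD
standardized difference (or to the paired difference). η² and Cohen's
f come from one-way-ANOVA sums of squares.

The Watson–Williams F uses the standard two-sample form with the
1 + 3/(8κ̂) concentration correction, κ̂ estimated from the mean
resultant length by the usual piecewise approximation; a resultant
length below 0.45 logs a warning (the test's assumptions are strained
there). Angles are treated as circular data on their native scale —
no doubling of the [0°, 90°] range — matching the test as named; the
implementation is validated against a 10,000-draw permutation oracle
whose statistic (the sum of within-group resultant lengths) is
monotone in F.

## Synthetic sessions

The generator builds a latent space in canonical coordinates — one
condition-independent axis (drive 0.4 + 0.6·ramp), one decision axis,
and per-task stimulus-contrast directions — then maps it to unit space
through a scaled orthonormal loading matrix (conformal, so all planted
angles survive exactly).

- **Angle:** the first stimulus contrast is cos θ·d + sin θ·d⊥, so the
  smallest principal angle between the stimulus span and the decision
  axis equals the target exactly (verified to 1e−6 in `GroundTruth`).
- **Reuse:** the decision time course is a half-cosine ramp r(t) for
  task A and ρ·r + √(1−ρ²)·g for the other same-mapping tasks, with g
  a smooth profile orthogonalized against r over time and
  variance-matched — so the Pearson correlation between trajectories
  equals ρ exactly before noise. Rotating the decision *axis* instead
  cannot produce intermediate ρ: the reuse statistic correlates over
  time and is scale-invariant, so a rotated axis only rescales the
  projected trajectory. Reverse-A carries the sign-flipped course
  (−ρ·r − …), modelling persistence of the old stimulus-keyed signal
  after the mapping inverts; its reuse is −ρ.
- **Stimuli:** orthonormal zero-sum contrasts assign each stimulus a
  direction; each task draws its own stimulus directions by default
  (stimulus representations are task-specific), with a shared-axes
  switch for controls. Stimulus time course is a Gaussian bump
  (center 0.35 s, width 0.12 s).
- **Rates and spikes:** rate = softplus(β₀ + gain·(loading·z)) with β₀
  set so the baseline is 12 spikes/s, per-unit loading scale 6
  spikes/s per latent unit (modulations of roughly ±10–20 Hz on the
  baseline — ordinary for premotor preparatory activity), and Poisson
  counts per 10-ms bin. Softplus guarantees nonnegative rates; at this
  baseline it is effectively linear, so the planted geometry is not
  distorted by rectification (strong modulation on a low baseline
  does distort it — a real property of firing rates, and the reason
  the baseline is not set lower).
- **Design:** balanced — every (task, stimulus, decision) cell gets
  the same trial count (50 by default, 60 units), sidestepping the
  padding ambiguity of max-trial tensors. Event times (grip, stimulus
  on, go, release, touch) are ordered and carry exponential-ish
  reaction times.

Behavioral sequences are independent Bernoulli draws whose success
probability rises as a saturating exponential from a start accuracy
(0.5 = naive) to an asymptote (0.95), rate 0.05/trial.

**What the generator does not emulate:** trial-to-trial rate
correlations beyond Poisson, non-stationarity within a session,
error-trial dynamics, kinematic confounds, unit-count drift, or any
nonlinear embedding of the latents. Passing recovery tests therefore
shows the *pipeline* is correct and well-calibrated at realistic
signal-to-noise, not that real recordings satisfy the model.

## Problem sizes and numerical choices

The validation suite runs sessions of 60 units × 50 trials per
condition × 100 bins (the regime the recovery claims are stated for),
with 5 seeds per planted angle and 10-shuffle nulls; unit tests use
40-unit, 15-trial sessions. Tolerances: exact linear-algebra
identities at 1e−10–1e−6; recovery at ±5° (angle) and ±0.15 (reuse);
stochastic decoder checks at 99% binomial confidence bounds.
Degenerate inputs (single-factor tensors, empty condition cells,
constant trajectories, zero pooled variance, rank-deficient
covariances at λ = 0) raise informative errors rather than returning
NaN. Ties in eigenvalue ranking are broken by LAPACK's deterministic
ordering; component signs are fixed only for decision components,
other factors' signs are arbitrary (tests compare up to sign).

## Known limitations

- The reuse statistic uses one decision component; distributed
  decision codes would be under-read.
- The angle is estimated between *selected* bases, so the >1% / ≥70%
  rules influence it; very weak stimulus signals can leave a 1-D
  stimulus basis and a noisier angle.
- The CNN is small and CPU-trained; it is adequate for the
  separability regimes analyzed, not a general-purpose decoder.
- Unbalanced sessions are accepted but the orthogonality of
  marginalized terms (and hence exact variance bookkeeping) holds only
  for balanced designs.
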