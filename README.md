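# popgeom

Population-geometry analysis of multi-task visuomotor learning.

When an animal learns a series of stimulus–response mapping tasks
(task A, then B, then C, then a revisit of A, then A with the mapping
reversed), premotor-cortex populations can reuse the low-dimensional
dynamics that encode the *decision* while re-representing each task's
*stimuli* along fresh directions. `popgeom` implements the analysis
pipeline that quantifies this organization, together with a synthetic
spiking-population generator whose geometry is planted exactly — so
every stage can be validated against known ground truth without any
restricted-access recordings.

## What it computes

Given a session tensor **X** ∈ ℝ^(M×N×T) (trials × units × 10-ms bins)
with per-trial task, stimulus and decision labels:

- **Demixed decomposition.** Condition-averaged activity
  X_ave ∈ ℝ^(N×S×D×T) is marginalized into
  x_t + x_ts + x_td + x_tsd (condition-independent, stimulus, decision,
  interaction). Per-factor components (encoder q, decoder
  (C_tot + λI)⁻¹C_m q) are pooled, ranked by explained variance and
  truncated to p = 20, giving a projection matrix W ∈ ℝ^(N×p) with a
  factor label per column.
- **Manifold reuse.** Task B/C/Revisit-A/Reverse-A activity is
  projected through task A's W; reuse is the Pearson correlation over
  time between the two tasks' top-decision-component trajectories,
  ρ(S_i^c, S_j^c) = cov(S_i^c, S_j^c)/σ_i^c σ_j^c, averaged over the
  up/down classes. Linear regression relates reuse to
  trials-to-criterion.
- **Subspace angle.** Components explaining >1% variance (stimulus:
  accumulated to ≥70% of the subspace) form orthonormal bases U_d, U_s;
  the reported angle is θ = arccos(σ_max(U_dᵀU_s)), the smallest
  principal angle, compared against a 10-repeat null in which stimulus
  and decision labels are permuted independently across trials
  (Watson–Williams test for the group comparison).
- **Decoder generalization.** Trials are reduced to 16-dimensional
  latent trajectories and classified by a two-layer temporal CNN
  (8 filters, kernel 3, ReLU, max-pool, dropout 0.5, softmax;
  80/20 split or stratified 10-fold CV). Frozen decoders evaluated on
  held-out tasks measure which representations transfer.
- **Behavioral metrics.** Trials-to-criterion (accuracy ≥90% within a
  trailing 15-trial window, normalized by session length), reaction
  times, Hedges' g (with the J = 1 − 3/(4·df−1) correction), Cohen's f
  and η² from one-way-ANOVA sums of squares.

The generator (`popgeom.simulate`) plants both headline quantities
exactly: the stimulus–decision angle (via a controlled cosine in the
latent construction) and the cross-task reuse correlation (via
temporal mixing of the shared decision profile), with softplus rates
and Poisson spiking on top.

## Worked example

```python
from popgeom import (SimConfig, make_session, fit_demix,
                     select_components, subspace_angle, shuffle_null)
import numpy as np

session, truth = make_session(SimConfig(target_angle_deg=80.0, seed=7))
result = fit_demix(session, tasks="A", p=20)
theta = subspace_angle(select_components(result, "decision"),
                       select_components(result, "stimulus"))
null = shuffle_null(session, tasks="A", n_shuffles=10, seed=0)
print(theta, np.mean(null.null_deg))
```

prints

```
81.5 51.0
```

— the recovered stimulus–decision angle (81.5°, planted at 80°) sits
far above the label-shuffle null mean (51.0°): stimulus and decision
coding are near-orthogonal, and detectably so against chance. The
scripts in `examples/` walk through each capability (simulation,
demixing and angles, manifold reuse, decoder generalization,
behavioral statistics, and the CLI pipeline) with printed output and a
line on what the numbers mean.

A thin CLI chains the pipeline on HDF5 session containers:

```bash
popgeom simulate --seed 1 --out session.h5
popgeom geometry --in session.h5 --seed 1 --out geometry.csv
popgeom report -g geometry.csv --out summary.csv
```

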