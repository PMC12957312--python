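"""Cross-task reuse of decision manifolds, and its link to learning.

Task B, Revisit-A and Reverse-A are projected through the projection
matrix fitted on task A alone; the Pearson correlation between
decision-component trajectories (averaged over up/down) measures how
much of task A's decision manifold each task reuses.  Higher reuse
predicts faster learning, which we illustrate with simulated learning
curves regressed on reuse.
"""

import numpy as np

from popgeom import (BehaviorSimConfig, SimConfig, decision_manifolds,
                     fit_demix, make_behavior_sequence, make_session,
                     manifold_reuse, regress_reuse_vs_learning,
                     trials_to_criterion)

session, _ = make_session(SimConfig(reuse_rho=0.9, seed=3))
result_a = fit_demix(session, tasks="A")

print("manifold reuse relative to task A:")
reuse = {}
for task in ("B", "Revisit-A", "Reverse-A"):
    pair = decision_manifolds(session, result_a, "A", task)
    reuse[task] = manifold_reuse(pair)
    print(f"  {task:10s} rho = {reuse[task]:+.2f}")

# emulate the reuse -> learning-speed relationship: higher reuse gives a
# faster-saturating learning curve, then regress trials-to-criterion on rho
rng = np.random.default_rng(0)
xs, ys = [], []
for rho, rate in [(0.95, 0.10), (0.8, 0.06), (0.5, 0.03), (-0.8, 0.008)]:
    for rep in range(5):
        seq = make_behavior_sequence(BehaviorSimConfig(
            n_trials=300, start_accuracy=0.5, asymptote_accuracy=0.97,
            learning_rate=rate, seed=int(rng.integers(1 << 30))))
        lr = trials_to_criterion(seq)
        xs.append(rho + rng.normal(0, 0.03))
        ys.append(lr.criterion_trial or lr.n_session_trials)
slope, intercept, r2, p = regress_reuse_vs_learning(xs, ys)
print(f"\ntrials-to-criterion vs reuse: slope {slope:.0f} trials/unit rho, "
      f"R^2 = {r2:.2f}, p = {p:.2g}")
# The negative slope says sessions that reuse the decision manifold more
# reach the 90%/15-trial criterion in fewer trials.
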