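"""Demix task-A activity and measure the stimulus-decision angle.

Condition-averaged activity is split into condition-independent,
stimulus, decision and interaction terms; demixed components define
the decision and stimulus-related subspaces, whose smallest principal
angle is compared against a 10-repeat label-shuffle null.
"""

import numpy as np

from popgeom import (SimConfig, fit_demix, make_session, select_components,
                     shuffle_null, subspace_angle)

session, truth = make_session(SimConfig(target_angle_deg=80.0, seed=7))

result = fit_demix(session, tasks="A", p=20)
print("top components (factor, % total variance):")
for fac, ev in list(zip(result.factor_of_component,
                        result.explained_variance_ratio))[:6]:
    print(f"  {fac:12s} {100 * ev:5.1f}%")

u_dec = select_components(result, "decision")
u_stim = select_components(result, "stimulus")
theta, spectrum = subspace_angle(u_dec, u_stim, return_spectrum=True)
print(f"\nsmallest principal angle: {theta:.1f} deg "
      f"(planted {truth.realized_angle_deg:.1f} deg)")

null = shuffle_null(session, tasks="A", n_shuffles=10, seed=0)
print(f"label-shuffle null: mean {np.mean(null.null_deg):.1f} deg, "
      f"range [{min(null.null_deg):.1f}, {max(null.null_deg):.1f}]")
# An observed angle well above the null mean indicates genuinely
# near-orthogonal stimulus and decision coding, not a sampling artifact.
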