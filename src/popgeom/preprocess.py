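"""Smoothing and condition averaging of spike-count tensors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .simulate import SessionData

__all__ = ["CondTensor", "smooth_rates", "condition_average"]


@dataclass
class CondTensor:
    """Condition-averaged activity, units × stimuli × decisions × time.

    ``stimuli`` and ``decisions`` hold the label of each axis position;
    ``condition_counts`` the trials averaged into each (S, D) cell.
    """

    values: np.ndarray
    stimuli: list[str]
    decisions: list[str]
    condition_counts: np.ndarray

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


def smooth_rates(spike_counts: np.ndarray, sigma_ms: float = 50.0,
                 bin_ms: float = 10.0) -> np.ndarray:
    """Gaussian-smooth each unit's time series with a unit-area kernel.

    ``sigma_ms`` is the kernel width in milliseconds (σ = sigma_ms/bin_ms
    bins); edges are handled by reflection so a constant series stays
    constant and total mass per series is preserved.  Accepts any array
    whose last axis is time.
    """
    if sigma_ms <= 0:
        raise ValueError(f"sigma_ms must be positive, got {sigma_ms}")
    x = np.asarray(spike_counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty spike-count tensor")
    return gaussian_filter1d(x, sigma=sigma_ms / bin_ms, axis=-1, mode="reflect")


def condition_average(session: SessionData, tasks=None, sigma_ms: float = 50.0,
                      smooth: bool = True) -> CondTensor:
    """Average smoothed single-trial activity within each (stimulus,
    decision) cell of the selected tasks.

    Cells are the cross product of the stimulus labels present and the
    decision labels present; every cell must contain at least one trial.
    """
    if tasks is not None:
        session = session.task_subset(tasks)
    if session.n_trials == 0:
        raise ValueError("no trials in the requested task subset")
    x = smooth_rates(session.spike_counts, sigma_ms=sigma_ms,
                     bin_ms=session.bin_ms) if smooth else \
        np.asarray(session.spike_counts, dtype=float)

    stimuli = sorted(set(session.stimulus_label))
    decisions = sorted(set(session.decision_label))
    n, t = session.n_units, session.n_bins
    values = np.empty((n, len(stimuli), len(decisions), t))
    counts = np.zeros((len(stimuli), len(decisions)), dtype=np.int64)
    for i, s in enumerate(stimuli):
        for j, d in enumerate(decisions):
            mask = (session.stimulus_label == s) & (session.decision_label == d)
            counts[i, j] = int(mask.sum())
            if counts[i, j] == 0:
                raise ValueError(
                    f"empty condition cell: stimulus={s!r}, decision={d!r}")
            values[:, i, j, :] = x[mask].mean(axis=0).reshape(n, t)
    return CondTensor(values=values, stimuli=stimuli, decisions=decisions,
                      condition_counts=counts)
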