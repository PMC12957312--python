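"""Subspace geometry: manifold reuse, basis selection, principal angles,
and the label-shuffle null distribution.

The two headline statistics are (i) the manifold-reuse correlation —
the Pearson correlation over time, averaged over decision classes,
between two tasks' trajectories on the top decision component — and
(ii) the smallest principal angle between the decision and
stimulus-related subspaces, θ = arccos(σ_max(U_dᵀ U_s)), compared
against a null built by independently permuting stimulus and decision
labels across trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .demix import DemixResult, fit_demix, project
from .preprocess import condition_average
from .simulate import SessionData

__all__ = [
    "ManifoldPair",
    "SubspaceBasis",
    "AngleNull",
    "manifold_reuse",
    "decision_manifolds",
    "select_components",
    "subspace_angle",
    "shuffle_null",
]

log = logging.getLogger(__name__)


@dataclass
class ManifoldPair:
    """Per-decision-class trajectories of two tasks on a shared decision
    component: arrays of shape (classes, time) with a common class order."""

    S_i: np.ndarray
    S_j: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        if self.S_i.shape != self.S_j.shape:
            raise ValueError("trajectory arrays must have identical shape")
        if self.S_i.shape[0] != len(self.classes):
            raise ValueError("class labels must match the first axis")


@dataclass
class SubspaceBasis:
    """Orthonormal basis U (units × k) for a factor's subspace."""

    U: np.ndarray
    factor: str
    variance_kept: float

    @property
    def k(self) -> int:
        return self.U.shape[1]


@dataclass
class AngleNull:
    observed_deg: float
    null_deg: list[float]
    seed: int
    observed_spectrum_deg: np.ndarray = field(default=None)


def manifold_reuse(pair: ManifoldPair) -> float:
    """Mean over decision classes of the Pearson correlation, over time,
    between the two tasks' decision-component trajectories."""
    if pair.S_i.shape[1] < 3:
        raise ValueError("trajectories need >= 3 time points")
    rhos = []
    for c in range(pair.S_i.shape[0]):
        a = pair.S_i[c] - pair.S_i[c].mean()
        b = pair.S_j[c] - pair.S_j[c].mean()
        va, vb = float(a @ a), float(b @ b)
        if va == 0.0 or vb == 0.0:
            raise ValueError(
                f"zero-variance trajectory for class {pair.classes[c]!r}; "
                "correlation undefined")
        rhos.append(float(a @ b) / np.sqrt(va * vb))
    return float(np.mean(rhos))


def decision_manifolds(session: SessionData, result: DemixResult,
                       task_i: str, task_j: str,
                       sigma_ms: float = 50.0) -> ManifoldPair:
    """Build the reuse pair for two tasks: each task's condition-averaged
    activity projected onto the top-variance decision component of
    ``result`` (typically fitted on task A only), averaged over stimuli
    within each decision class."""
    dec_idx = result.components_of("decision")
    if dec_idx.size == 0:
        raise ValueError("fit has no decision components")
    top = dec_idx[0]  # components are globally variance-ordered
    trajs = []
    for task in (task_i, task_j):
        cond = condition_average(session, tasks=task, sigma_ms=sigma_ms)
        y = np.einsum("n,nsdt->sdt", result.W[:, top], cond.values)
        trajs.append(y.mean(axis=0))  # decisions × time
        classes = cond.decisions
    return ManifoldPair(S_i=trajs[0], S_j=trajs[1], classes=classes)


def select_components(result: DemixResult, factor: str,
                      min_var: float = 0.01,
                      cum_var: float = 0.70) -> SubspaceBasis:
    """Select a factor's components by explained variance and return the
    orthonormalized encoder span.

    A component is eligible if it explains more than ``min_var`` of the
    total variance.  Stimulus factor: eligible components are taken in
    descending order until their cumulative share of the subspace's
    variance reaches ``cum_var``.  Decision factor: every eligible
    component, no cumulative threshold (the decision subspace is
    low-dimensional to begin with).
    """
    idx = result.components_of(factor)
    if idx.size == 0:
        raise ValueError(f"no components of factor {factor!r}")
    ev = result.explained_variance_ratio[idx]
    frac = ev / ev.sum()
    order = np.argsort(frac)[::-1]
    eligible = [i for i in order if ev[i] > min_var]
    if not eligible:
        raise ValueError(
            f"no {factor} component exceeds {min_var:.0%} of total variance")
    if factor == "stimulus":
        chosen, cum = [], 0.0
        for i in eligible:
            chosen.append(i)
            cum += frac[i]
            if cum >= cum_var:
                break
    else:
        chosen = eligible
    cols = idx[np.asarray(chosen)]
    u, _ = np.linalg.qr(result.encoders[:, cols])
    return SubspaceBasis(U=u, factor=factor,
                         variance_kept=float(frac[np.asarray(chosen)].sum()))


def subspace_angle(U_d, U_s, return_spectrum: bool = False):
    """Smallest principal angle (degrees) between two subspaces.

    θ = arccos(σ_max(U_dᵀ U_s)); with ``return_spectrum`` the full
    principal-angle spectrum (ascending, degrees) is returned as well.
    Non-orthonormal inputs are re-orthonormalized with a warning.
    """
    mats = []
    for u in (U_d, U_s):
        m = u.U if isinstance(u, SubspaceBasis) else np.asarray(u, dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        if not np.allclose(m.T @ m, np.eye(m.shape[1]), atol=1e-10):
            log.warning("subspace basis not orthonormal; re-orthonormalizing")
            m, _ = np.linalg.qr(m)
        mats.append(m)
    a, b = mats
    if a.shape[0] != b.shape[0]:
        raise ValueError("bases live in different unit dimensions")
    angles = np.degrees(scipy.linalg.subspace_angles(a, b))  # descending
    spectrum = angles[::-1]                                  # ascending
    theta = float(spectrum[0])
    return (theta, spectrum) if return_spectrum else theta


def session_angle(session: SessionData, tasks=None, p: int = 20,
                  sigma_ms: float = 50.0, ridge: float | None = None
                  ) -> tuple[float, np.ndarray]:
    """Full pipeline for one session: fit demixed components, select the
    decision and stimulus bases, return (smallest angle, spectrum)."""
    res = fit_demix(session, tasks=tasks, p=p, ridge=ridge, sigma_ms=sigma_ms)
    u_d = select_components(res, "decision")
    u_s = select_components(res, "stimulus")
    return subspace_angle(u_d, u_s, return_spectrum=True)


def shuffle_null(session: SessionData, tasks=None, p: int = 20,
                 n_shuffles: int = 10, seed: int = 0,
                 sigma_ms: float = 50.0, ridge: float | None = None,
                 max_resample: int = 100) -> AngleNull:
    """Observed stimulus–decision angle plus a label-shuffle null.

    For each of ``n_shuffles`` repeats, the stimulus labels and the
    decision labels are permuted independently across trials of the
    analyzed subset, and the full demix → select → angle pipeline is
    rerun.  A permutation that empties a condition cell is resampled
    (logged).  Deterministic given ``seed``.
    """
    sub = session.task_subset(tasks) if tasks is not None else session
    observed, spectrum = session_angle(sub, p=p, sigma_ms=sigma_ms, ridge=ridge)
    rng = np.random.default_rng(seed)
    null: list[float] = []
    while len(null) < n_shuffles:
        for attempt in range(max_resample):
            shuffled = SessionData(
                spike_counts=sub.spike_counts,
                task_label=sub.task_label,
                stimulus_label=rng.permutation(sub.stimulus_label),
                decision_label=rng.permutation(sub.decision_label),
                outcome=sub.outcome,
                event_times=sub.event_times,
                bin_ms=sub.bin_ms,
            )
            try:
                theta, _ = session_angle(shuffled, p=p, sigma_ms=sigma_ms,
                                         ridge=ridge)
            except ValueError as err:
                log.info("shuffle resampled (%s)", err)
                continue
            null.append(theta)
            break
        else:
            raise RuntimeError("could not find a valid label permutation")
    return AngleNull(observed_deg=observed, null_deg=null, seed=seed,
                     observed_spectrum_deg=spectrum)
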