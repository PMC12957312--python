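"""Demixed decomposition of condition-averaged population activity.

The condition-averaged tensor X_ave (units × stimuli × decisions ×
time) is split by factorial marginalization into a
condition-independent term, a stimulus term, a decision term and a
stimulus–decision interaction term; per-marginalization demixed axes
are then found by a regularized eigen-solver (PCA of each marginalized
term in coordinates whitened by the total covariance), pooled across
factors, ranked by explained variance and truncated to ``p``
components.  The resulting projection matrix W can be applied,
unchanged, to held-out tasks — the cross-projection at the heart of
the manifold-reuse analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocess import CondTensor, condition_average
from .simulate import SessionData

__all__ = ["Marginalization", "DemixResult", "marginalize", "fit_demix", "project"]

FACTORS = ("time", "stimulus", "decision", "interaction")


@dataclass
class Marginalization:
    """Factorial mean decomposition of a condition-averaged tensor.

    Each term has the full units × S × D × time shape;
    x_t + x_ts + x_td + x_tsd reconstructs the input exactly, and every
    non-``time`` term averages to zero over the factor(s) it varies with.
    """

    x_t: np.ndarray
    x_ts: np.ndarray
    x_td: np.ndarray
    x_tsd: np.ndarray

    def term(self, factor: str) -> np.ndarray:
        return {"time": self.x_t, "stimulus": self.x_ts,
                "decision": self.x_td, "interaction": self.x_tsd}[factor]


@dataclass
class DemixResult:
    """Fitted demixed components.

    ``W`` (units × p) holds decoding axes: latent trajectories are
    ``W.T @ x``.  ``encoders`` holds the matching unit-norm encoding
    axes whose span defines each factor's subspace in unit space.
    ``explained_variance_ratio`` is each component's share of the total
    condition-averaged variance.
    """

    W: np.ndarray
    encoders: np.ndarray
    factor_of_component: list[str]
    explained_variance_ratio: np.ndarray
    stimuli: list[str]
    decisions: list[str]
    p: int

    def components_of(self, factor: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.factor_of_component) == factor)


def marginalize(cond: CondTensor) -> Marginalization:
    """Split X_ave into condition-independent, stimulus, decision and
    interaction terms by factorial averaging.

    x_t is the mean over (S, D); x_ts the per-stimulus mean minus x_t;
    x_td the per-decision mean minus x_t; x_tsd the remainder.
    """
    v = cond.values
    n, s, d, t = v.shape
    if s < 2 and d < 2:
        raise ValueError("nothing to demix: need >= 2 stimuli or >= 2 decisions")
    x_t = v.mean(axis=(1, 2), keepdims=True)
    x_ts = v.mean(axis=2, keepdims=True) - x_t
    x_td = v.mean(axis=1, keepdims=True) - x_t
    x_tsd = v - x_t - x_ts - x_td
    bcast = np.broadcast_to
    return Marginalization(
        x_t=bcast(x_t, v.shape).copy(),
        x_ts=bcast(x_ts, v.shape).copy(),
        x_td=bcast(x_td, v.shape).copy(),
        x_tsd=x_tsd,
    )


def _flat(term: np.ndarray) -> np.ndarray:
    n = term.shape[0]
    return term.reshape(n, -1)


def fit_demix(session_or_cond, tasks=None, p: int | None = 20,
              ridge: float | None = None, sigma_ms: float = 50.0,
              denoise_dim: int | str | None = "auto") -> DemixResult:
    """Fit demixed components on a session (or a prebuilt CondTensor).

    The condition-averaged data are first denoised by projection onto
    the leading principal axes of the total covariance: single-trial
    averaging leaves a broadband noise floor spread over all units,
    and restricting the factor decompositions to the dominant
    population subspace keeps the axis estimates from being tilted by
    the sum of those near-threshold noise directions.  With
    ``denoise_dim="auto"`` (default) the retained dimensionality is
    the number of principal components above 1% of total variance,
    capped at 16 (the latent dimensionality used for decoding); an
    int fixes it, None disables denoising.

    For each marginalized term x_m (the design is balanced, so the four
    terms are mutually orthogonal and the total covariance is their
    sum), the encoding axes are the orthonormal eigenvectors of the
    term's covariance C_m, and each component's decoding axis is the
    ridge-regression readout of that component's trajectory from the
    full data, (C_tot + λI)⁻¹ C_m q — the encoder pushed through the
    regularized total-covariance whitener, which is what suppresses the
    other factors' variance in the projection.  Components from all
    factors are pooled, ranked by explained variance (each component's
    eigenvalue as a fraction of total variance, so a complete pool sums
    to 1 on balanced data) and truncated to ``p``.  λ defaults to
    1e-6 · tr(C_tot); with λ = 0 a rank-deficient total covariance
    raises.

    Decision-component signs are fixed so the 'up' trajectory has
    positive mean, making cross-session trajectory comparisons and the
    reuse correlation well defined.
    """
    if isinstance(session_or_cond, CondTensor):
        cond = session_or_cond
    else:
        cond = condition_average(session_or_cond, tasks=tasks, sigma_ms=sigma_ms)
    n, s, d, t = cond.values.shape
    if d < 2:
        raise ValueError("need >= 2 decisions to fit the decision factor")
    if p is not None and p > n:
        raise ValueError(f"p={p} exceeds the number of units {n}")

    centered = CondTensor(
        values=cond.values - cond.values.mean(axis=(1, 2, 3), keepdims=True),
        stimuli=cond.stimuli, decisions=cond.decisions,
        condition_counts=cond.condition_counts)
    marg = marginalize(centered)
    xf = _flat(centered.values)
    n_obs = xf.shape[1]
    c_tot = xf @ xf.T / n_obs
    if denoise_dim == "auto":
        eigval = scipy.linalg.eigvalsh(c_tot)
        denoise_dim = int(min(max((eigval > 0.01 * eigval.sum()).sum(), 2), 16))
    if denoise_dim is not None and denoise_dim < n:
        eigval, eigvec = scipy.linalg.eigh(c_tot)
        u_keep = eigvec[:, ::-1][:, :denoise_dim]
        proj = u_keep @ u_keep.T
        xf = proj @ xf
        for f in FACTORS:
            setattr(marg, {"time": "x_t", "stimulus": "x_ts",
                           "decision": "x_td", "interaction": "x_tsd"}[f],
                    np.einsum("nm,msdt->nsdt", proj, marg.term(f)))
        c_tot = xf @ xf.T / n_obs
    total_var = float(np.trace(c_tot))
    lam = 1e-6 * total_var if ridge is None else float(ridge)
    if lam == 0.0 and np.linalg.matrix_rank(c_tot) < n:
        raise np.linalg.LinAlgError(
            "total covariance is rank deficient with ridge=0; pass ridge > 0")
    reg = c_tot + lam * np.eye(n)

    terms = {f: _flat(marg.term(f)) for f in FACTORS}

    axes, encs, facs, evs = [], [], [], []
    for factor in FACTORS:
        xm = terms[factor]
        c_m = xm @ xm.T / n_obs
        eigval, eigvec = scipy.linalg.eigh(c_m)  # ascending
        keep = eigval > max(eigval[-1] * 1e-12, 1e-30)
        for k in np.flatnonzero(keep)[::-1]:     # descending eigenvalue
            q = eigvec[:, k]
            dvec = eigval[k] * scipy.linalg.solve(reg, q, assume_a="pos")
            axes.append(dvec)
            encs.append(q)
            facs.append(factor)
            evs.append(float(eigval[k]) / total_var)

    if not axes:
        raise ValueError("no nonzero marginalized variance; nothing to demix")
    order = np.argsort(evs)[::-1][:p] if p is not None else np.argsort(evs)[::-1]
    W = np.stack([axes[i] for i in order], axis=1)
    E = np.stack([encs[i] for i in order], axis=1)
    factor_of = [facs[i] for i in order]
    ev = np.asarray([evs[i] for i in order])

    # sign convention: decision components' 'up' trajectory positive
    up = cond.decisions.index("up") if "up" in cond.decisions else 0
    for k, factor in enumerate(factor_of):
        if factor == "decision":
            traj = np.einsum("n,nsdt->sdt", W[:, k], cond.values
                             - cond.values.mean(axis=(1, 2, 3), keepdims=True))
            if traj[:, up, :].mean() < 0:
                W[:, k] *= -1
                E[:, k] *= -1

    return DemixResult(W=W, encoders=E, factor_of_component=factor_of,
                       explained_variance_ratio=ev, stimuli=cond.stimuli,
                       decisions=cond.decisions, p=W.shape[1])


def project(data, result: DemixResult, factor: str | None = None) -> np.ndarray:
    """Project activity through the fitted axes without refitting.

    ``data`` may be a CondTensor, a SessionData (smoothed single
    trials), or any array whose first axis is units (or second axis,
    for trials × units × time).  Returns components × ... with the
    component axis restricted to ``factor``'s columns when given.
    Works identically on held-out tasks (cross-projection with a fixed
    W, e.g. task A's).
    """
    cols = (slice(None) if factor is None or factor == "all"
            else result.components_of(factor))
    w = result.W[:, cols]
    if isinstance(data, CondTensor):
        arr, unit_axis = data.values, 0
    elif isinstance(data, SessionData):
        from .preprocess import smooth_rates
        arr, unit_axis = smooth_rates(data.spike_counts, bin_ms=data.bin_ms), 1
    else:
        arr = np.asarray(data, dtype=float)
        unit_axis = 1 if arr.ndim == 3 and arr.shape[1] == result.W.shape[0] \
            and arr.shape[0] != result.W.shape[0] else 0
    if arr.shape[unit_axis] != result.W.shape[0]:
        raise ValueError(
            f"unit dimension {arr.shape[unit_axis]} does not match W "
            f"({result.W.shape[0]} units)")
    return np.moveaxis(np.tensordot(w, arr, axes=(0, unit_axis)), 0, unit_axis)
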