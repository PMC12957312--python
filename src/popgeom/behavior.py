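"""Behavioral learning metrics and the supporting statistical toolkit.

Covers: trials-to-criterion (accuracy ≥ 90% within a trailing 15-trial
window, normalized by session length, with a total-trials fallback for
tasks never acquired), reaction times, the reuse-vs-learning linear
regression, standardized effect sizes (Hedges' g with the small-sample
correction, Cohen's f and η² from one-way-ANOVA sums of squares), and
the Watson–Williams test for equality of mean directions of two
circular samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LearningResult",
    "EffectSizes",
    "trials_to_criterion",
    "reaction_time",
    "regress_reuse_vs_learning",
    "effect_size_suite",
    "hedges_g",
    "watson_williams",
]

log = logging.getLogger(__name__)


@dataclass
class LearningResult:
    criterion_trial: int | None
    n_session_trials: int
    normalized_trials: float


@dataclass
class EffectSizes:
    hedges_g: float | None = None
    cohens_f: float | None = None
    eta_squared: float | None = None
    t_statistic: float | None = None
    f_statistic: float | None = None
    p_value: float | None = None


def trials_to_criterion(outcomes, threshold: float = 0.9,
                        window: int = 15) -> LearningResult:
    """Earliest trial count t (t ≥ window) at which the trailing window
    of outcomes has mean accuracy ≥ ``threshold``.

    With the defaults this requires at least 14 of the last 15 trials
    correct.  If the criterion is never met, ``criterion_trial`` is
    None and ``normalized_trials`` falls back to 1.0 (the whole session
    was needed).  Otherwise ``normalized_trials`` =
    criterion_trial / n_session_trials.
    """
    x = np.asarray(outcomes)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    n = x.size
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    csum = np.concatenate([[0], np.cumsum(x)])
    win_mean = (csum[window:] - csum[:-window]) / window
    hits = np.flatnonzero(win_mean >= threshold - 1e-12)
    if hits.size == 0:
        return LearningResult(criterion_trial=None, n_session_trials=n,
                              normalized_trials=1.0)
    t = int(hits[0]) + window
    return LearningResult(criterion_trial=t, n_session_trials=n,
                          normalized_trials=t / n)


def reaction_time(event_times: dict[str, np.ndarray],
                  task_label: np.ndarray | None = None):
    """Per-trial reaction time (touch − go_cue, seconds).

    Trials with a missing event or touch ≤ go_cue are excluded with a
    warning.  Returns the per-trial array, or, if ``task_label`` is
    given, a dict task → (mean, SD, n).
    """
    go = np.asarray(event_times["go_cue"], dtype=float)
    touch = np.asarray(event_times["touch"], dtype=float)
    valid = np.isfinite(go) & np.isfinite(touch) & (touch > go)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("excluding %d trial(s) with missing/inverted events", n_bad)
    rt = np.where(valid, touch - go, np.nan)
    if task_label is None:
        return rt
    out = {}
    for task in np.unique(task_label):
        r = rt[(np.asarray(task_label) == task)]
        r = r[np.isfinite(r)]
        out[str(task)] = (float(r.mean()), float(r.std(ddof=1)) if r.size > 1
                          else 0.0, int(r.size))
    return out


def regress_reuse_vs_learning(reuse, trials):
    """OLS of trials-to-criterion on the manifold-reuse correlation.

    Returns (slope, intercept, R², two-sided p for the slope).  R² is
    relative to the intercept-only null model.
    """
    x = np.asarray(reuse, dtype=float)
    y = np.asarray(trials, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("reuse values are constant; slope undefined")
    if np.ptp(y) == 0:
        # flat response: the slope and R^2 are exactly zero
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))


def hedges_g(a, b, paired: bool = False) -> float:
    """Standardized mean difference with the small-sample correction
    J = 1 − 3/(4·df − 1).

    Unpaired: pooled-SD Cohen's d, df = n1 + n2 − 2.  Paired: mean
    difference over the SD of the differences, df = n − 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if d.mean() == 0 else np.inf
        df = d.size - 1
        g = d.mean() / sd
    else:
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            return 0.0 if a.mean() == b.mean() else np.inf
        g = (a.mean() - b.mean()) / np.sqrt(sp2)
    return float(g * (1.0 - 3.0 / (4.0 * df - 1.0)))


def _anova_ss(groups):
    grand = np.concatenate(groups)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    ss_between = float(sum(g.size * (g.mean() - grand.mean()) ** 2
                           for g in groups))
    ss_within = ss_total - ss_between
    return ss_between, ss_within, ss_total


def effect_size_suite(*groups, paired: bool = False) -> EffectSizes:
    """Effect sizes and test statistics for two or more groups.

    Two groups: Hedges' g plus a t-test (paired or two-sample).  Any
    number of groups: η² = SS_between/SS_total and Cohen's
    f = sqrt(η²/(1−η²)) from the one-way ANOVA decomposition, with the
    ANOVA F and p.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    out = EffectSizes()
    ss_b, ss_w, ss_t = _anova_ss(gs)
    if ss_t == 0:
        raise ValueError("zero total variance; effect sizes undefined")
    eta2 = ss_b / ss_t
    out.eta_squared = float(eta2)
    out.cohens_f = float(np.sqrt(eta2 / (1.0 - eta2))) if eta2 < 1 else np.inf
    f_res = stats.f_oneway(*gs)
    out.f_statistic, out.p_value = float(f_res.statistic), float(f_res.pvalue)
    if len(gs) == 2:
        out.hedges_g = hedges_g(gs[0], gs[1], paired=paired)
        t_res = (stats.ttest_rel(gs[0], gs[1]) if paired
                 else stats.ttest_ind(gs[0], gs[1]))
        out.t_statistic, out.p_value = float(t_res.statistic), float(t_res.pvalue)
    return out


# ---------------------------------------------------------------------------
# Watson–Williams test
# ---------------------------------------------------------------------------

def _circ_r(alpha: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * alpha).mean()))


def _kappa_ml(r: float, n: int) -> float:
    """Maximum-likelihood von Mises concentration from the resultant
    length (standard piecewise approximation, with small-n correction)."""
    if r < 0.53:
        kappa = 2 * r + r ** 3 + 5 * r ** 5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)
    if n <= 15 and kappa < 2:
        kappa = max(kappa - 2 / (n * kappa), 0.0)
    return float(kappa)


def watson_williams(angles_a, angles_b, degrees: bool = True):
    """Watson–Williams F-test for equal mean directions of two circular
    samples.

    F = K · (N−2)·(R1+R2−R) / (N−R1−R2), with R the resultant lengths
    and K = 1 + 3/(8κ̂) the concentration correction; p is from
    F(1, N−2).  Assumes von Mises samples with common, adequately large
    concentration (a warning is logged when the mean resultant length
    falls below 0.45, where the test is unreliable).
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 angles")
    if degrees:
        a, b = np.deg2rad(a), np.deg2rad(b)
    n1, n2 = a.size, b.size
    n = n1 + n2
    r1 = n1 * _circ_r(a)
    r2 = n2 * _circ_r(b)
    r = n * _circ_r(np.concatenate([a, b]))
    rw = (r1 + r2) / n
    if rw < 0.45:
        log.warning("mean resultant length %.2f < 0.45; Watson–Williams "
                    "assumptions are strained", rw)
    kappa = _kappa_ml(rw, n)
    if kappa <= 0:
        raise ValueError("undefined concentration (kappa <= 0)")
    correction = 1.0 + 3.0 / (8.0 * kappa)
    denom = n - r1 - r2
    if denom <= 0:
        # both samples perfectly concentrated; identical means -> F ~ 0
        return (0.0, 1.0) if abs(np.exp(1j * a).mean()
                                 - np.exp(1j * b).mean()) < 1e-12 else (np.inf, 0.0)
    f = correction * (n - 2) * (r1 + r2 - r) / denom
    f = max(f, 0.0)
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p
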