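"""Synthetic multi-task spiking sessions with known population geometry.

Emulates premotor-cortex recordings from a sequence of visuomotor
mapping tasks (A, B, C, Revisit-A, Reverse-A): each trial presents a
visual stimulus that maps to an up/down decision, and the population
carries a condition-independent signal, a decision signal whose
dynamics are shared across same-mapping tasks, and per-task stimulus
signals.  Two geometric quantities are planted exactly and recorded as
ground truth:

* the smallest principal angle between the stimulus-contrast span and
  the decision axis (``target_angle_deg``), and
* the Pearson correlation over time between task A's decision
  trajectory and every other task's (``reuse_rho``); Reverse-A carries
  the sign-flipped trajectory, modelling persistence of the old
  stimulus-keyed schema after the mapping is inverted.

Rates pass through a softplus and spikes are Poisson per 10 ms bin, so
counts are nonnegative integers with Fano factor ~1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "BehaviorSimConfig",
    "GroundTruth",
    "SessionData",
    "SAME_MAPPING_TASKS",
    "make_session",
    "make_behavior_sequence",
]

#: task roles whose stimulus→decision mapping matches task A's
SAME_MAPPING_TASKS = ("A", "B", "C", "Revisit-A")
_ALLOWED_TASKS = SAME_MAPPING_TASKS + ("Reverse-A",)
DECISIONS = ("up", "down")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic session generator.

    Parameters
    ----------
    n_units:
        Number of recorded units N.
    n_stimuli_per_task:
        Stimuli per task (the paired designs use 2; one monkey's
        stimulus decoder saw 6 categories).
    tasks:
        Ordered task roles drawn from {A, B, C, Revisit-A, Reverse-A}.
    trials_per_condition:
        Trials generated for every (task, stimulus, decision) cell;
        the design is balanced by default.
    n_bins:
        Time bins in the analysis epoch (100 bins of 10 ms = the 1 s
        window before the go cue).
    baseline_rate:
        Baseline firing rate in spikes/s.
    signal_gain:
        Scales all latent signals; 0 gives pure baseline Poisson noise.
    target_angle_deg:
        Planted smallest principal angle (degrees, in [0, 90]) between
        each task's stimulus-contrast span and the decision axis.
    reuse_rho:
        Planted Pearson correlation (over time) between task A's
        decision trajectory and the other same-mapping tasks'.
    reverse_flips_decision:
        If True, Reverse-A's decision trajectory is sign-flipped
        relative to the decision label (old schema keyed to stimulus),
        yielding reuse ≈ −reuse_rho.
    shared_stimulus_axes:
        If True all tasks use identical stimulus directions; default
        False (each task draws its own, matching the observed
        instability of stimulus representations across tasks).
    """

    n_units: int = 60
    n_stimuli_per_task: int = 2
    tasks: tuple[str, ...] = ("A", "B", "Revisit-A", "Reverse-A")
    trials_per_condition: int = 50
    n_bins: int = 100
    bin_ms: float = 10.0
    baseline_rate: float = 12.0
    signal_gain: float = 1.0
    loading_scale: float = 6.0
    target_angle_deg: float = 80.0
    reuse_rho: float = 0.9
    reverse_flips_decision: bool = True
    shared_stimulus_axes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_units, self.n_stimuli_per_task,
               self.trials_per_condition, self.n_bins) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.target_angle_deg <= 90.0:
            raise ValueError(
                f"target_angle_deg must lie in [0, 90], got {self.target_angle_deg}")
        if not -1.0 <= self.reuse_rho <= 1.0:
            raise ValueError(f"reuse_rho must lie in [-1, 1], got {self.reuse_rho}")
        bad = set(self.tasks) - set(_ALLOWED_TASKS)
        if bad:
            raise ValueError(f"unknown task roles: {sorted(bad)}")
        latent_dim = 2 + len(self.tasks) * max(self.n_stimuli_per_task - 1, 1)
        if latent_dim > self.n_units:
            raise ValueError(
                f"latent dimension {latent_dim} exceeds n_units {self.n_units}")


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Bernoulli learning-curve generator: success probability follows a
    saturating exponential from ``start_accuracy`` to ``asymptote_accuracy``."""

    n_trials: int = 200
    start_accuracy: float = 0.5
    asymptote_accuracy: float = 0.95
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for p in (self.start_accuracy, self.asymptote_accuracy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")
        if self.asymptote_accuracy < self.start_accuracy:
            raise ValueError("asymptote_accuracy must be >= start_accuracy")


@dataclass
class GroundTruth:
    """Hidden parameters of a simulated session (the recovery oracle)."""

    decision_axes: dict[str, np.ndarray]          # task -> unit-space axis (unit norm)
    stimulus_axes: dict[str, np.ndarray]          # task -> (n_stimuli, n_units), unit norm rows
    loading_matrix: np.ndarray                    # n_units x latent_dim
    realized_angle_deg: float
    realized_reuse: dict[str, float]              # task -> corr with task A (pre-noise)
    latent_time_courses: dict[str, np.ndarray]    # named 1-D profiles over time


@dataclass
class SessionData:
    """One session: spike-count tensor plus per-trial labels and events.

    ``spike_counts`` is trials (M) × units (N) × time bins (T) of
    nonnegative integers; labels are length-M arrays; ``event_times``
    maps event name -> length-M array of seconds (stimulus onset = 0).
    """

    spike_counts: np.ndarray
    task_label: np.ndarray
    stimulus_label: np.ndarray
    decision_label: np.ndarray
    outcome: np.ndarray
    event_times: dict[str, np.ndarray]
    bin_ms: float = 10.0
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.spike_counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.spike_counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spike_counts.shape[2]

    def __post_init__(self) -> None:
        m = self.spike_counts.shape[0]
        for name, lab in (("task_label", self.task_label),
                          ("stimulus_label", self.stimulus_label),
                          ("decision_label", self.decision_label),
                          ("outcome", self.outcome)):
            if len(lab) != m:
                raise ValueError(f"{name} has length {len(lab)}, expected {m} trials")
        if np.any(self.spike_counts < 0):
            raise ValueError("spike counts must be nonnegative")

    def subset(self, mask: np.ndarray) -> "SessionData":
        """Return the session restricted to trials where ``mask`` is True."""
        return SessionData(
            spike_counts=self.spike_counts[mask],
            task_label=self.task_label[mask],
            stimulus_label=self.stimulus_label[mask],
            decision_label=self.decision_label[mask],
            outcome=self.outcome[mask],
            event_times={k: v[mask] for k, v in self.event_times.items()},
            bin_ms=self.bin_ms,
            meta=dict(self.meta),
        )

    def task_subset(self, tasks) -> "SessionData":
        tasks = (tasks,) if isinstance(tasks, str) else tuple(tasks)
        return self.subset(np.isin(self.task_label, tasks))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _inv_softplus(y: float) -> float:
    # solve softplus(x) = y for y > 0
    return float(np.log(np.expm1(y)))


def _ramp(n_bins: int) -> np.ndarray:
    """Half-cosine preparatory ramp from 0 to 1 over the epoch."""
    t = np.linspace(0.0, 1.0, n_bins)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _bump(n_bins: int, center: float = 0.35, width: float = 0.12) -> np.ndarray:
    """Gaussian bump (stimulus transient) over the unit-length epoch."""
    t = np.linspace(0.0, 1.0, n_bins)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _decorrelated_profile(r: np.ndarray) -> np.ndarray:
    """A smooth profile with zero Pearson correlation with ``r`` and the
    same temporal standard deviation, used to dilute reuse."""
    t = np.linspace(0.0, 1.0, r.size)
    g = np.sin(2.0 * np.pi * t)
    rc = r - r.mean()
    g = g - g.mean()
    g = g - (g @ rc) / (rc @ rc) * rc
    g *= rc.std() / g.std()
    return g


def _stimulus_contrasts(n_stimuli: int) -> np.ndarray:
    """Orthonormal zero-sum contrast matrix, shape (n_stimuli, n_stimuli-1).

    Row s gives stimulus s's coordinates on the contrast directions;
    columns are orthonormal and sum to zero over stimuli (Helmert-like),
    so the stimulus term is centred by construction.
    """
    s = n_stimuli
    h = np.zeros((s, s - 1))
    for k in range(1, s):
        h[:k, k - 1] = 1.0
        h[k, k - 1] = -k
        h[:, k - 1] /= np.linalg.norm(h[:, k - 1])
    return h * np.sqrt(s - 1)  # keep per-stimulus norm O(1)


def make_session(config: SimConfig) -> tuple[SessionData, GroundTruth]:
    """Simulate one multi-task session; deterministic given ``config.seed``.

    Returns the session and its :class:`GroundTruth`.  The latent space
    is built in canonical coordinates — one condition-independent axis,
    one decision axis shared by same-mapping tasks, and per-task
    stimulus-contrast directions placed at exactly
    ``target_angle_deg`` from the decision axis — then mapped to unit
    space by a scaled orthonormal loading matrix, which preserves all
    angles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_s, n_bins = cfg.n_stimuli_per_task, cfg.n_bins
    n_contrast = max(n_s - 1, 1)
    n_tasks = len(cfg.tasks)
    latent_dim = 2 + n_tasks * n_contrast

    # --- canonical latent axes ---------------------------------------
    e_time = np.zeros(latent_dim); e_time[0] = 1.0
    d_axis = np.zeros(latent_dim); d_axis[1] = 1.0
    theta = np.deg2rad(cfg.target_angle_deg)
    contrasts = _stimulus_contrasts(n_s) if n_s > 1 else np.zeros((1, 1))

    # per-task stimulus-contrast directions: the first contrast lies at
    # angle theta from the decision axis, the rest orthogonal to it
    task_contrast_dirs: dict[str, np.ndarray] = {}
    for j, task in enumerate(cfg.tasks):
        jj = 0 if cfg.shared_stimulus_axes else j
        block = 2 + jj * n_contrast
        w = np.zeros((n_contrast, latent_dim))
        w[0, 1] = np.cos(theta)
        w[0, block] = np.sin(theta)
        for k in range(1, n_contrast):
            w[k, block + k] = 1.0
        task_contrast_dirs[task] = w

    # --- temporal profiles -------------------------------------------
    r = _ramp(n_bins)
    g = _decorrelated_profile(r)
    b = _bump(n_bins)
    a = 0.6 * _ramp(n_bins) + 0.4     # condition-independent drive

    rho = cfg.reuse_rho
    decision_course: dict[str, np.ndarray] = {}
    for task in cfg.tasks:
        if task == "A":
            m = r.copy()
        else:
            m = rho * r + np.sqrt(max(1.0 - rho * rho, 0.0)) * g
        if task == "Reverse-A" and cfg.reverse_flips_decision:
            m = -m
        decision_course[task] = m

    def _corr(x, y):
        xc, yc = x - x.mean(), y - y.mean()
        return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))

    realized_reuse = {t: _corr(decision_course["A"], decision_course[t])
                      for t in cfg.tasks if t != "A"}

    # --- loading to unit space ---------------------------------------
    q, _ = np.linalg.qr(rng.standard_normal((cfg.n_units, latent_dim)))
    loading = q * (cfg.loading_scale * np.sqrt(cfg.n_units))

    # realized angle: principal angle between stimulus-contrast span and
    # decision axis in unit space (loading is conformal, so it equals theta)
    w_a = task_contrast_dirs[cfg.tasks[0]]
    if n_s > 1:
        qa, _ = np.linalg.qr((loading @ w_a.T))
        da = loading @ d_axis
        da /= np.linalg.norm(da)
        sig = np.linalg.svd(qa.T @ da[:, None], compute_uv=False)
        realized_angle = float(np.degrees(np.arccos(np.clip(sig[0], -1, 1))))
    else:
        realized_angle = float("nan")

    # --- assemble trials ---------------------------------------------
    beta0 = _inv_softplus(cfg.baseline_rate)
    bin_s = cfg.bin_ms / 1000.0
    sign = {"up": 1.0, "down": -1.0}

    trials, tasks_l, stim_l, dec_l, outc_l = [], [], [], [], []
    grip, stim_on, go_t, release, touch = [], [], [], [], []
    for task in cfg.tasks:
        w = task_contrast_dirs[task]
        m = decision_course[task]
        # Revisit-A and Reverse-A re-present task A's stimuli
        identity_task = "A" if task in ("Revisit-A", "Reverse-A") else task
        for s in range(n_s):
            stim_latent = (contrasts[s] @ w) if n_s > 1 else np.zeros(latent_dim)
            # the task's stimulus→decision map: even stimuli → up, odd → down
            mapped = "up" if s % 2 == 0 else "down"
            if task == "Reverse-A":
                mapped = "down" if mapped == "up" else "up"
            for dec in DECISIONS:
                z = (a[None, :] * e_time[:, None]
                     + sign[dec] * m[None, :] * d_axis[:, None]
                     + b[None, :] * stim_latent[:, None])  # latent_dim x T
                rates = _softplus(beta0 + cfg.signal_gain * (loading @ z))
                lam = np.clip(rates * bin_s, 0.0, None)
                for _ in range(cfg.trials_per_condition):
                    trials.append(rng.poisson(lam))
                    tasks_l.append(task)
                    stim_l.append(f"{identity_task}:s{s}")
                    dec_l.append(dec)
                    outc_l.append(1 if dec == mapped else 0)
                    rt = 0.25 + rng.exponential(0.15)
                    mt = 0.15 + rng.exponential(0.05)
                    grip.append(-1.5 + rng.uniform(0.0, 0.2))
                    stim_on.append(0.0)
                    go_t.append(1.0)
                    release.append(1.0 + rt)
                    touch.append(1.0 + rt + mt)

    session = SessionData(
        spike_counts=np.asarray(trials, dtype=np.int64),
        task_label=np.asarray(tasks_l),
        stimulus_label=np.asarray(stim_l),
        decision_label=np.asarray(dec_l),
        outcome=np.asarray(outc_l, dtype=np.int64),
        event_times={
            "grip": np.asarray(grip),
            "stimulus_on": np.asarray(stim_on),
            "go_cue": np.asarray(go_t),
            "release": np.asarray(release),
            "touch": np.asarray(touch),
        },
        bin_ms=cfg.bin_ms,
        meta={"seed": cfg.seed, "tasks": list(cfg.tasks),
              "target_angle_deg": cfg.target_angle_deg,
              "reuse_rho": cfg.reuse_rho},
    )

    dec_unit = loading @ d_axis
    dec_unit /= np.linalg.norm(dec_unit)
    stim_unit = {}
    for task in cfg.tasks:
        if n_s > 1:
            v = contrasts @ task_contrast_dirs[task] @ loading.T
            v /= np.linalg.norm(v, axis=1, keepdims=True)
        else:
            v = np.zeros((1, cfg.n_units))
        stim_unit[task] = v

    truth = GroundTruth(
        decision_axes={t: dec_unit.copy() for t in cfg.tasks},
        stimulus_axes=stim_unit,
        loading_matrix=loading,
        realized_angle_deg=realized_angle,
        realized_reuse=realized_reuse,
        latent_time_courses={"ramp": r, "decorrelated": g, "bump": b,
                             **{f"decision:{t}": decision_course[t]
                                for t in cfg.tasks}},
    )
    return session, truth


def make_behavior_sequence(config: BehaviorSimConfig) -> np.ndarray:
    """Binary outcome sequence from a saturating-exponential learning curve.

    P(correct at trial k) = asymptote − (asymptote − start) · exp(−rate·k),
    k = 0 … n_trials−1; outcomes are independent Bernoulli draws,
    deterministic given the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = np.arange(cfg.n_trials)
    p = (cfg.asymptote_accuracy
         - (cfg.asymptote_accuracy - cfg.start_accuracy)
         * np.exp(-cfg.learning_rate * k))
    return (rng.random(cfg.n_trials) < p).astype(np.int64)
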