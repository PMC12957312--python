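"""Latent extraction and temporal-convolution classifiers.

Single-trial population activity is reduced to a fixed 16-dimensional
latent trajectory (a linear principal-axes extraction sharing the
M × 16 × T contract of nonlinear sequential autoencoders), and a small
two-layer temporal CNN classifies stimulus or decision from the
latents:

    H1 = maxpool(relu(conv(X, W1) + b1))
    H2 = maxpool(relu(conv(H1, W2) + b2))
    Y  = softmax(FC(dropout(H2)))

with 8 filters per layer, kernel 3, stride 1, padding 1, max-pool 2 and
dropout 0.5 before the fully connected head.  Training is plain
minibatch SGD on cross-entropy.  A trained model can be frozen and
evaluated on held-out tasks (cross-task generalization).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .preprocess import smooth_rates
from .simulate import SessionData

__all__ = [
    "LatentTensor",
    "DecoderModel",
    "extract_latent",
    "train_decoder",
    "cross_task_eval",
    "kfold_accuracy",
]


@dataclass
class LatentTensor:
    """Trials × dim × time latent trajectories with trial labels carried
    through from the source session."""

    values: np.ndarray
    task_label: np.ndarray | None = None
    projection: np.ndarray | None = None   # units × dim, reusable across tasks
    mean: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def extract_latent(session_or_tensor, dim: int = 16,
                   sigma_ms: float = 50.0) -> LatentTensor:
    """Project smoothed single-trial activity onto the top ``dim``
    principal axes of the trial-concatenated data.

    The fitted projection is stored on the result so held-out tasks of
    the same session can be mapped into the identical latent space via
    :meth:`apply_projection`.
    """
    if isinstance(session_or_tensor, SessionData):
        x = smooth_rates(session_or_tensor.spike_counts,
                         sigma_ms=sigma_ms, bin_ms=session_or_tensor.bin_ms)
        tasks = session_or_tensor.task_label
    else:
        x = np.asarray(session_or_tensor, dtype=float)
        tasks = None
    m, n, t = x.shape
    if dim > n:
        raise ValueError(f"latent dim {dim} exceeds unit count {n}")
    flat = x.transpose(1, 0, 2).reshape(n, m * t)
    mu = flat.mean(axis=1, keepdims=True)
    flat = flat - mu
    # principal axes of the unit covariance
    u, s, _ = np.linalg.svd(flat, full_matrices=False)
    proj = u[:, :dim]
    lat = np.einsum("nk,mnt->mkt", proj, x - mu[None, :, :])
    return LatentTensor(values=lat, task_label=tasks, projection=proj, mean=mu)


def apply_projection(latent: LatentTensor, session: SessionData,
                     sigma_ms: float = 50.0) -> LatentTensor:
    """Map another task's trials into an already-fitted latent space."""
    if latent.projection is None:
        raise ValueError("latent tensor carries no fitted projection")
    x = smooth_rates(session.spike_counts, sigma_ms=sigma_ms,
                     bin_ms=session.bin_ms)
    lat = np.einsum("nk,mnt->mkt", latent.projection,
                    x - latent.mean[None, :, :])
    return LatentTensor(values=lat, task_label=session.task_label,
                        projection=latent.projection, mean=latent.mean)


# ---------------------------------------------------------------------------
# two-layer temporal CNN
# ---------------------------------------------------------------------------

@dataclass
class DecoderModel:
    """Parameters and architecture of the temporal-convolution classifier."""

    W1: np.ndarray          # filters1 × channels × kernel
    b1: np.ndarray
    W2: np.ndarray          # filters2 × filters1 × kernel
    b2: np.ndarray
    Wfc: np.ndarray         # classes × flattened
    bfc: np.ndarray
    classes: np.ndarray
    dropout: float = 0.5
    frozen: bool = False
    train_accuracy: float = float("nan")
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for p in (self.W1, self.b1, self.W2, self.b2, self.Wfc, self.bfc):
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched 1-D convolution, stride 1, zero padding 1 (kernel 3).

    x: batch × channels × T, w: filters × channels × k → batch × filters × T.
    """
    k = w.shape[2]
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    t = x.shape[2]
    # im2col: batch × channels*k × T
    cols = np.stack([xp[:, :, i:i + t] for i in range(k)], axis=2)
    cols = cols.reshape(x.shape[0], -1, t)
    return np.einsum("fq,bqt->bft", w.reshape(w.shape[0], -1), cols) + b[None, :, None]


def _conv1d_grads(x, w, dout):
    """Gradients of _conv1d wrt weights, bias and input."""
    k = w.shape[2]
    pad = (k - 1) // 2
    t = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.stack([xp[:, :, i:i + t] for i in range(k)], axis=2)  # b,c,k,t
    dw = np.einsum("bft,bckt->fck", dout, cols)
    db = dout.sum(axis=(0, 2))
    # input gradient: full correlation of dout with flipped filters
    dxp = np.zeros_like(xp)
    for i in range(k):
        dxp[:, :, i:i + t] += np.einsum("fck,bft->bct", w[:, :, i:i + 1], dout)
    dx = dxp[:, :, pad:pad + t] if pad else dxp
    return dw, db, dx


def _maxpool(x: np.ndarray, width: int = 2):
    b, c, t = x.shape
    t2 = t // width
    xr = x[:, :, :t2 * width].reshape(b, c, t2, width)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx


def _maxpool_back(dout, idx, t, width: int = 2):
    b, c, t2 = dout.shape
    dx = np.zeros((b, c, t2, width))
    np.put_along_axis(dx, idx[..., None], dout[..., None], axis=3)
    out = np.zeros((b, c, t))
    out[:, :, :t2 * width] = dx.reshape(b, c, t2 * width)
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: DecoderModel, x: np.ndarray, rng=None, train: bool = False):
    cache = {}
    z1 = _conv1d(x, model.W1, model.b1)
    a1 = np.maximum(z1, 0.0)
    p1, i1 = _maxpool(a1)
    z2 = _conv1d(p1, model.W2, model.b2)
    a2 = np.maximum(z2, 0.0)
    p2, i2 = _maxpool(a2)
    flat = p2.reshape(p2.shape[0], -1)
    if train and model.dropout > 0:
        mask = (rng.random(flat.shape) >= model.dropout) / (1.0 - model.dropout)
        flat = flat * mask
        cache["mask"] = mask
    logits = flat @ model.Wfc.T + model.bfc
    probs = _softmax(logits)
    cache.update(x=x, z1=z1, a1=a1, p1=p1, i1=i1, z2=z2, a2=a2, p2=p2,
                 i2=i2, flat=flat, probs=probs)
    return probs, cache


def predict(model: DecoderModel, latents) -> np.ndarray:
    """Class predictions (forward pass only; dropout off, expectation
    scaling built in by the inverted-dropout convention)."""
    x = latents.values if isinstance(latents, LatentTensor) else np.asarray(latents)
    probs, _ = _forward(model, x, train=False)
    return model.classes[probs.argmax(axis=1)]


def _init_model(n_channels, t, classes, seed, n_filters=8, kernel=3,
                dropout=0.5) -> DecoderModel:
    rng = np.random.default_rng(seed)
    t_fc = (t // 2) // 2 * n_filters

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    return DecoderModel(
        W1=he((n_filters, n_channels, kernel), n_channels * kernel),
        b1=np.zeros(n_filters),
        W2=he((n_filters, n_filters, kernel), n_filters * kernel),
        b2=np.zeros(n_filters),
        Wfc=he((len(classes), t_fc), t_fc),
        bfc=np.zeros(len(classes)),
        classes=np.asarray(classes),
        dropout=dropout,
        seed=seed,
    )


def _sgd_epoch(model, x, y_onehot, rng, lr, batch_size):
    order = rng.permutation(x.shape[0])
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        xb, yb = x[idx], y_onehot[idx]
        probs, c = _forward(model, xb, rng=rng, train=True)
        nb = len(idx)
        dlogits = (probs - yb) / nb
        dWfc = dlogits.T @ c["flat"]
        dbfc = dlogits.sum(axis=0)
        dflat = dlogits @ model.Wfc
        if "mask" in c:
            dflat = dflat * c["mask"]
        dp2 = dflat.reshape(c["p2"].shape)
        da2 = _maxpool_back(dp2, c["i2"], c["a2"].shape[2])
        dz2 = da2 * (c["z2"] > 0)
        dW2, db2, dp1 = _conv1d_grads(c["p1"], model.W2, dz2)
        da1 = _maxpool_back(dp1, c["i1"], c["a1"].shape[2])
        dz1 = da1 * (c["z1"] > 0)
        dW1, db1, _ = _conv1d_grads(c["x"], model.W1, dz1)
        model.W1 -= lr * dW1; model.b1 -= lr * db1
        model.W2 -= lr * dW2; model.b2 -= lr * db2
        model.Wfc -= lr * dWfc; model.bfc -= lr * dbfc


def _fit(x, y, classes, seed, lr=0.05, epochs=200, batch_size=32,
         patience=30, tol=1e-4):
    """Train on (x, y); early-stops when training loss plateaus."""
    model = _init_model(x.shape[1], x.shape[2], classes, seed)
    rng = np.random.default_rng(seed + 1)
    y_idx = np.searchsorted(model.classes, y)
    onehot = np.eye(len(classes))[y_idx]
    # standardize channels once, absorbing scale into the data
    best, since = np.inf, 0
    for _ in range(epochs):
        _sgd_epoch(model, x, onehot, rng, lr, batch_size)
        probs, _ = _forward(model, x, train=False)
        loss = float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())
        if loss < best - tol:
            best, since = loss, 0
        else:
            since += 1
            if since >= patience:
                break
    preds = model.classes[probs.argmax(axis=1)]
    model.train_accuracy = float((preds == y).mean())
    return model


def _normalize(x, mu=None, sd=None):
    if mu is None:
        mu = x.mean(axis=(0, 2), keepdims=True)
        sd = x.std(axis=(0, 2), keepdims=True) + 1e-9
    return (x - mu) / sd, mu, sd


def train_decoder(latents, labels, test_size: float = 0.2, seed: int = 0,
                  lr: float = 0.05, epochs: int = 200,
                  batch_size: int = 32) -> tuple[DecoderModel, float]:
    """Train the temporal CNN on an 80/20 stratified split.

    Returns the trained model and held-out accuracy on the 20% split.
    Deterministic given ``seed`` (up to floating-point associativity).
    """
    x = latents.values if isinstance(latents, LatentTensor) else np.asarray(latents)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 5:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has fewer than 5 trials")
    xtr, xte, ytr, yte = train_test_split(
        x, y, test_size=test_size, random_state=seed, stratify=y)
    xtr, mu, sd = _normalize(xtr)
    model = _fit(xtr, ytr, classes, seed, lr=lr, epochs=epochs,
                 batch_size=batch_size)
    model.meta["norm_mu"], model.meta["norm_sd"] = mu, sd
    xte = (xte - mu) / sd
    acc = float((predict(model, xte) == yte).mean())
    model.frozen = True
    return model, acc


def cross_task_eval(model: DecoderModel, latents, labels) -> float:
    """Accuracy of a frozen model on new trials: forward pass only, no
    parameter update (the parameter hash is asserted unchanged)."""
    if not model.frozen:
        raise ValueError("model must be frozen before cross-task evaluation")
    y = np.asarray(labels)
    unseen = set(np.unique(y)) - set(model.classes.tolist())
    if unseen:
        raise ValueError(f"labels contain classes unseen in training: {sorted(unseen)}")
    x = latents.values if isinstance(latents, LatentTensor) else np.asarray(latents)
    if "norm_mu" in model.meta:
        x = (x - model.meta["norm_mu"]) / model.meta["norm_sd"]
    before = model.param_hash()
    acc = float((predict(model, x) == y).mean())
    assert model.param_hash() == before
    return acc


def kfold_accuracy(latents, labels, k: int = 10, seed: int = 0,
                   lr: float = 0.05, epochs: int = 200,
                   batch_size: int = 32) -> tuple[float, float]:
    """Stratified k-fold cross-validated accuracy: returns (mean, SD)
    over folds.

    When ``k`` exceeds the smallest class count (e.g. leave-one-out on
    a tiny set), plain shuffled folds are used instead of stratified
    ones; every training split must still contain all classes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = latents.values if isinstance(latents, LatentTensor) else np.asarray(latents)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    accs = []
    if k <= counts.min():
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < len(classes):
            raise ValueError("a training fold lost an entire class; "
                             "use a smaller k")
        xtr, mu, sd = _normalize(x[tr])
        model = _fit(xtr, y[tr], classes, seed + i, lr=lr, epochs=epochs,
                     batch_size=batch_size)
        xte = (x[te] - mu) / sd
        accs.append(float((predict(model, xte) == y[te]).mean()))
    return float(np.mean(accs)), float(np.std(accs))
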