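"""MS-CAGRU: multi-scale convolutional-autoencoder + GRU classifier.

Three 1-D convolutional encoder branches — one per feature set (original,
weighted, deep), with kernel sizes 3/5/7 giving the three receptive-field
scales — each optionally pretrained as an autoencoder by reconstruction MSE.
The flattened branch encodings concatenate into the fused representation EF,
which passes through one further convolutional encoding stage; that stage's
channel sequence is presented to a GRU as a step sequence (channel = time
step, channel width = step input), replacing the usual fully connected head.
The final hidden state feeds a linear-softmax output trained with
cross-entropy.

Everything is plain numpy with hand-written backpropagation and an Adam
optimizer; all stochasticity (initialization, batch order) derives from the
run seed, and inference is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureBundle",
    "MSCAGRUConfig",
    "GRUCellParams",
    "TrainedModel",
    "gru_step",
    "build_model",
    "encode_multiscale",
    "pretrain_autoencoders",
    "train_mscagru",
    "predict",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class FeatureBundle:
    """The three parallel feature matrices sharing a sample axis."""

    original: np.ndarray
    weighted: np.ndarray
    deep: np.ndarray
    fused: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.original = np.atleast_2d(np.asarray(self.original, dtype=float))
        self.weighted = np.atleast_2d(np.asarray(self.weighted, dtype=float))
        self.deep = np.atleast_2d(np.asarray(self.deep, dtype=float))
        n = self.original.shape[0]
        if self.weighted.shape[0] != n or self.deep.shape[0] != n:
            raise ValueError("original/weighted/deep row counts differ")

    @property
    def n_samples(self) -> int:
        return self.original.shape[0]

    @property
    def widths(self) -> tuple[int, int, int]:
        return (self.original.shape[1], self.weighted.shape[1], self.deep.shape[1])

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.original, self.weighted, self.deep)


@dataclass(frozen=True)
class MSCAGRUConfig:
    branch_kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    branch_channels: int = 8
    fusion_channels: int = 8
    fusion_kernel_size: int = 3
    gru_hidden: int = 16
    n_classes: int = 2
    pretrain_epochs: int = 15
    train_epochs: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 32
    activation: str = "tanh"  # 'tanh' | 'relu' | 'linear'
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.branch_kernel_sizes)
        object.__setattr__(self, "branch_kernel_sizes", ks)
        if any(k < 1 or k % 2 == 0 for k in ks) or self.fusion_kernel_size % 2 == 0:
            raise ValueError("kernel sizes must be odd and >= 1")
        if min(self.branch_channels, self.fusion_channels, self.gru_hidden,
               self.train_epochs, self.batch_size) < 1:
            raise ValueError("channel/hidden/epoch/batch counts must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.pretrain_epochs < 0 or self.learning_rate <= 0:
            raise ValueError("pretrain_epochs must be >= 0 and learning_rate > 0")
        if self.activation not in ("tanh", "relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class GRUCellParams:
    """Update gate (W_z, b_z), reset gate (W_r, b_r), candidate (W_c, b_c).

    Each weight matrix has shape (hidden, hidden + input); the hidden block
    comes first in the [h_prev, x] concatenation.
    """

    W_z: np.ndarray
    b_z: np.ndarray
    W_r: np.ndarray
    b_r: np.ndarray
    W_c: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1] - self.W_z.shape[0]


@dataclass
class TrainedModel:
    config: MSCAGRUConfig
    widths: tuple[int, int, int]
    params: dict[str, np.ndarray]
    classes: np.ndarray | None = None
    pretrain_loss: list[list[float]] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)

    @property
    def gru(self) -> GRUCellParams:
        p = self.params
        return GRUCellParams(p["W_z"], p["b_z"], p["W_r"], p["b_r"], p["W_c"], p["b_c"])


# ---------------------------------------------------------------------------
# primitive ops

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _act(x: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "tanh":
        out = np.tanh(x)
        return out, out
    if kind == "relu":
        mask = x > 0
        return x * mask, mask
    return x, x  # linear


def _act_backward(dout: np.ndarray, cache: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return dout * (1.0 - cache * cache)
    if kind == "relu":
        return dout * cache
    return dout


def _conv1d(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 1-D convolution. X (n, ci, L), W (co, ci, k) → (n, co, L)."""
    n, ci, L = X.shape
    co, _, k = W.shape
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
    Y = np.broadcast_to(b[None, :, None], (n, co, L)).copy()
    for dk in range(k):
        Y += np.einsum("oc,ncl->nol", W[:, :, dk], Xp[:, :, dk:dk + L])
    return Y


def _conv1d_backward(dY: np.ndarray, X: np.ndarray, W: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dX, dW, db) of the same-padded convolution."""
    n, ci, L = X.shape
    co, _, k = W.shape
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
    dXp = np.zeros_like(Xp)
    dW = np.zeros_like(W)
    for dk in range(k):
        dW[:, :, dk] = np.einsum("nol,ncl->oc", dY, Xp[:, :, dk:dk + L])
        dXp[:, :, dk:dk + L] += np.einsum("oc,nol->ncl", W[:, :, dk], dY)
    db = dY.sum(axis=(0, 2))
    dX = dXp[:, :, pad:pad + L] if pad else dXp
    return dX, dW, db


def gru_step(params: GRUCellParams, x: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU step: gated convex combination of previous state and candidate.

    z = σ(W_z·[h_prev, x] + b_z), r = σ(W_r·[h_prev, x] + b_r),
    c = tanh(W_c·[r⊙h_prev, x] + b_c), h = (1−z)⊙h_prev + z⊙c.
    Accepts a single vector or a batch (rows = samples).
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError("x/h_prev shapes do not conform to the cell parameters")
    hx = np.concatenate([h_prev, x], axis=-1)
    z = _sigmoid(hx @ params.W_z.T + params.b_z)
    r = _sigmoid(hx @ params.W_r.T + params.b_r)
    ch = np.concatenate([r * h_prev, x], axis=-1)
    c = np.tanh(ch @ params.W_c.T + params.b_c)
    return (1.0 - z) * h_prev + z * c


# ---------------------------------------------------------------------------
# model construction and forward/backward

_BRANCHES = ("orig", "wtd", "deep")


def build_model(widths: tuple[int, int, int], config: MSCAGRUConfig,
                rng=None) -> TrainedModel:
    """Initialize all parameters (Glorot-style scaled Gaussians, zero biases)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    C, C2, H = config.branch_channels, config.fusion_channels, config.gru_hidden
    params: dict[str, np.ndarray] = {}
    for name, k in zip(_BRANCHES, config.branch_kernel_sizes):
        params[f"enc_W_{name}"] = rng.normal(0.0, 1.0 / np.sqrt(k), size=(C, 1, k))
        params[f"enc_b_{name}"] = np.zeros(C)
        params[f"dec_W_{name}"] = rng.normal(0.0, 1.0 / np.sqrt(k * C), size=(1, C, k))
        params[f"dec_b_{name}"] = np.zeros(1)
    F = C * sum(widths)
    kf = config.fusion_kernel_size
    params["fuse_W"] = rng.normal(0.0, 1.0 / np.sqrt(kf), size=(C2, 1, kf))
    params["fuse_b"] = np.zeros(C2)
    for gate in ("z", "r", "c"):
        params[f"W_{gate}"] = rng.normal(0.0, 1.0 / np.sqrt(H + F), size=(H, H + F))
        params[f"b_{gate}"] = np.zeros(H)
    params["out_W"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=(config.n_classes, H))
    params["out_b"] = np.zeros(config.n_classes)
    return TrainedModel(config=config, widths=tuple(widths), params=params)


def _branch_forward(model: TrainedModel, X: np.ndarray, name: str):
    enc_in = X[:, None, :]  # (n, 1, L)
    pre = _conv1d(enc_in, model.params[f"enc_W_{name}"], model.params[f"enc_b_{name}"])
    out, cache = _act(pre, model.config.activation)
    return enc_in, out, cache


def encode_multiscale(bundle: FeatureBundle, model: TrainedModel) -> np.ndarray:
    """Fused representation EF: flattened branch encodings concatenated."""
    if bundle.widths != model.widths:
        raise ValueError(f"bundle widths {bundle.widths} != model widths {model.widths}")
    parts = []
    for X, name in zip(bundle.matrices(), _BRANCHES):
        _, out, _ = _branch_forward(model, X, name)
        parts.append(out.reshape(out.shape[0], out.shape[1] * out.shape[2]))
    fused = np.concatenate(parts, axis=1)
    bundle.fused = fused
    return fused


def _forward_full(model: TrainedModel, bundle: FeatureBundle):
    """Forward pass caching every intermediate needed for backprop."""
    cfg = model.config
    cache: dict = {"branch": {}}
    parts = []
    for X, name in zip(bundle.matrices(), _BRANCHES):
        enc_in, out, act_cache = _branch_forward(model, X, name)
        cache["branch"][name] = (enc_in, out, act_cache)
        parts.append(out.reshape(out.shape[0], out.shape[1] * out.shape[2]))
    EF = np.concatenate(parts, axis=1)  # (n, F)
    fuse_in = EF[:, None, :]
    fuse_pre = _conv1d(fuse_in, model.params["fuse_W"], model.params["fuse_b"])
    fuse_out, fuse_cache = _act(fuse_pre, cfg.activation)  # (n, C2, F)
    cache["fuse"] = (fuse_in, fuse_out, fuse_cache)

    gru = model.gru
    n = EF.shape[0]
    h = np.zeros((n, cfg.gru_hidden))
    steps = []
    for t in range(cfg.fusion_channels):
        x = fuse_out[:, t, :]
        hx = np.concatenate([h, x], axis=1)
        z = _sigmoid(hx @ gru.W_z.T + gru.b_z)
        r = _sigmoid(hx @ gru.W_r.T + gru.b_r)
        ch = np.concatenate([r * h, x], axis=1)
        c = np.tanh(ch @ gru.W_c.T + gru.b_c)
        h_new = (1.0 - z) * h + z * c
        steps.append((h, x, z, r, c, hx, ch))
        h = h_new
    cache["gru_steps"] = steps
    cache["h_final"] = h
    logits = h @ model.params["out_W"].T + model.params["out_b"]
    return logits, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _backward_full(model: TrainedModel, bundle: FeatureBundle, cache: dict,
                   dlogits: np.ndarray) -> dict[str, np.ndarray]:
    cfg = model.config
    p = model.params
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    h_final = cache["h_final"]
    grads["out_W"] = dlogits.T @ h_final
    grads["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ p["out_W"]

    H = cfg.gru_hidden
    dX_steps = []
    for (h_prev, x, z, r, c, hx, ch) in reversed(cache["gru_steps"]):
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)
        da_c = dc * (1.0 - c * c)
        grads["W_c"] += da_c.T @ ch
        grads["b_c"] += da_c.sum(axis=0)
        dch = da_c @ p["W_c"]
        drh, dx = dch[:, :H], dch[:, H:]
        dr = drh * h_prev
        dh_prev += drh * r
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        grads["W_z"] += da_z.T @ hx
        grads["b_z"] += da_z.sum(axis=0)
        grads["W_r"] += da_r.T @ hx
        grads["b_r"] += da_r.sum(axis=0)
        dhx = da_z @ p["W_z"] + da_r @ p["W_r"]
        dh_prev += dhx[:, :H]
        dx += dhx[:, H:]
        dX_steps.append(dx)
        dh = dh_prev
    dX_steps.reverse()

    dfuse_out = np.stack(dX_steps, axis=1)  # (n, C2, F)
    fuse_in, _, fuse_cache = cache["fuse"]
    dfuse_pre = _act_backward(dfuse_out, fuse_cache, cfg.activation)
    dfuse_in, dW, db = _conv1d_backward(dfuse_pre, fuse_in, p["fuse_W"])
    grads["fuse_W"], grads["fuse_b"] = dW, db
    dEF = dfuse_in[:, 0, :]

    offset = 0
    C = cfg.branch_channels
    for name, width in zip(_BRANCHES, model.widths):
        span = C * width
        dpart = dEF[:, offset:offset + span].reshape(dEF.shape[0], C, width)
        offset += span
        enc_in, _, act_cache = cache["branch"][name]
        dpre = _act_backward(dpart, act_cache, cfg.activation)
        _, dWe, dbe = _conv1d_backward(dpre, enc_in, p[f"enc_W_{name}"])
        grads[f"enc_W_{name}"], grads[f"enc_b_{name}"] = dWe, dbe
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training

def pretrain_autoencoders(bundle: FeatureBundle, config: MSCAGRUConfig,
                          model: TrainedModel | None = None) -> TrainedModel:
    """Reconstruction-MSE pretraining of each branch's encoder/decoder pair."""
    if bundle.n_samples == 0:
        raise ValueError("empty bundle")
    if model is None:
        model = build_model(bundle.widths, config)
    rng = np.random.default_rng(config.seed + 1)
    model.pretrain_loss = []
    for X, name in zip(bundle.matrices(), _BRANCHES):
        if X.shape[1] == 0:  # ablated (zero-width) feature set: nothing to reconstruct
            model.pretrain_loss.append([])
            continue
        keys = [f"enc_W_{name}", f"enc_b_{name}", f"dec_W_{name}", f"dec_b_{name}"]
        sub = {k: model.params[k] for k in keys}
        opt = _Adam(sub, config.learning_rate)
        curve = []
        n = X.shape[0]
        for _ in range(config.pretrain_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                xb = X[order[start:start + config.batch_size]]
                enc_in = xb[:, None, :]
                pre = _conv1d(enc_in, sub[keys[0]], sub[keys[1]])
                hid, act_cache = _act(pre, config.activation)
                recon = _conv1d(hid, sub[keys[2]], sub[keys[3]])
                err = recon - enc_in
                loss = float(np.mean(err * err))
                losses.append(loss)
                drecon = 2.0 * err / err.size
                dhid, dWd, dbd = _conv1d_backward(drecon, hid, sub[keys[2]])
                dpre = _act_backward(dhid, act_cache, config.activation)
                _, dWe, dbe = _conv1d_backward(dpre, enc_in, sub[keys[0]])
                opt.step(sub, {keys[0]: dWe, keys[1]: dbe, keys[2]: dWd, keys[3]: dbd})
            curve.append(float(np.mean(losses)))
        model.pretrain_loss.append(curve)
    return model


def train_mscagru(bundle: FeatureBundle, labels, config: MSCAGRUConfig) -> TrainedModel:
    """Pretrain branches (if configured), then supervised cross-entropy training."""
    labels = np.asarray(labels)
    if labels.shape[0] != bundle.n_samples:
        raise ValueError("label count does not match bundle rows")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes for supervised training")
    if classes.size != config.n_classes:
        config = MSCAGRUConfig(**{**config.__dict__, "n_classes": int(classes.size)})
    y = np.searchsorted(classes, labels)

    model = build_model(bundle.widths, config)
    model.classes = classes
    if config.pretrain_epochs > 0:
        pretrain_autoencoders(bundle, config, model)

    rng = np.random.default_rng(config.seed + 2)
    opt = _Adam(model.params, config.learning_rate)
    n = bundle.n_samples
    mats = bundle.matrices()
    for _ in range(config.train_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub_bundle = FeatureBundle(*(M[idx] for M in mats))
            logits, cache = _forward_full(model, sub_bundle)
            probs = _softmax(logits)
            b = idx.size
            loss = float(-np.mean(np.log(probs[np.arange(b), y[idx]] + 1e-12)))
            losses.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(b), y[idx]] -= 1.0
            dlogits /= b
            grads = _backward_full(model, sub_bundle, cache, dlogits)
            opt.step(model.params, grads)
        model.train_loss.append(float(np.mean(losses)))
    return model


def predict(model: TrainedModel, bundle: FeatureBundle) -> tuple[np.ndarray, np.ndarray]:
    """Class predictions and softmax probabilities; argmax ties break low-index."""
    if bundle.widths != model.widths:
        raise ValueError(f"bundle widths {bundle.widths} != model widths {model.widths}")
    logits, _ = _forward_full(model, bundle)
    probs = _softmax(logits)
    idx = np.argmax(probs, axis=1)
    classes = model.classes if model.classes is not None else np.arange(probs.shape[1])
    return classes[idx], probs
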