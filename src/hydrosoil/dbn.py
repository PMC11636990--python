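"""Deep belief network features via stacked restricted Boltzmann machines.

Each RBM is the canonical two-layer binary model with energy

    E(v, h) = − Σ_i g_i v_i − Σ_j y_j h_j − Σ_ij v_i W_ij h_j

and Boltzmann distribution p(v, h) = exp(−E)/Z. Layers are trained greedily
with CD-1 contrastive divergence on min-max-scaled inputs ([0, 1], training
anchors); layer k+1 trains on layer k's hidden *probabilities*, and the deep
feature matrix is the top layer's hidden probabilities — a deterministic map,
so downstream training is reproducible.

Between layers, hidden probabilities are affinely stretched to span [0, 1]
over the training data (anchors stored in the model and reused at transform
time). Without this, the small dynamic range of the first layer's
probabilities starves the next RBM of visible-unit contrast and the stack
degenerates to bias-only models on continuous tabular inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hydrosoil.data import LabeledTable, minmax_scale

__all__ = [
    "RBMParams",
    "DBNConfig",
    "DBNModel",
    "rbm_energy",
    "rbm_conditionals",
    "rbm_partition_function",
    "train_rbm",
    "fit_dbn",
    "transform_dbn",
]


@dataclass
class RBMParams:
    """weights: (n_visible, n_hidden); visible_bias: (n_visible,); hidden_bias: (n_hidden,)."""

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        D, F = self.weights.shape
        if self.visible_bias.shape != (D,) or self.hidden_bias.shape != (F,):
            raise ValueError("bias shapes inconsistent with weight matrix")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.visible_bias))
                and np.all(np.isfinite(self.hidden_bias))):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class DBNConfig:
    layer_sizes: tuple[int, ...] = (32, 16)
    epochs: int = 60
    learning_rate: float = 0.2
    cd_steps: int = 1
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_sizes or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be positive integers")
        if self.epochs < 1 or self.cd_steps < 1 or self.batch_size < 1:
            raise ValueError("epochs, cd_steps and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))


@dataclass
class DBNModel:
    layers: list[RBMParams]
    layer_sizes: tuple[int, ...]
    scaler_reference: LabeledTable  # training table whose min/max anchor the input scaling
    reconstruction_mse: list[list[float]] = field(default_factory=list)  # per layer, per epoch
    # inter-layer contrast anchors: (lo, hi) of layer k's training-time hidden
    # probabilities, applied before feeding layer k+1 (length len(layers)-1)
    layer_scalers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.n_hidden != b.n_visible:
                raise ValueError("adjacent RBM layer dimensions do not chain")


def rbm_energy(visible, hidden, params: RBMParams) -> float:
    """Joint energy −g·v − y·h − v·W·h for binary unit vectors."""
    v = np.asarray(visible, dtype=float)
    h = np.asarray(hidden, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("visible/hidden shape mismatch with parameters")
    return float(-(params.visible_bias @ v) - (params.hidden_bias @ h) - v @ params.weights @ h)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic


def rbm_conditionals(params: RBMParams, given, direction: str) -> np.ndarray:
    """Factorized conditional activation probabilities, one per target unit.

    ``direction='visible_to_hidden'`` maps v (values in [0,1]) to
    p(h_j = 1 | v) = logistic(y_j + Σ_i v_i W_ij); the reverse direction maps
    h to p(v_i = 1 | h) = logistic(g_i + Σ_j W_ij h_j).
    """
    g = np.asarray(given, dtype=float)
    if direction == "visible_to_hidden":
        if g.shape[-1] != params.n_visible:
            raise ValueError("given vector length != n_visible")
        return _sigmoid(params.hidden_bias + g @ params.weights)
    if direction == "hidden_to_visible":
        if g.shape[-1] != params.n_hidden:
            raise ValueError("given vector length != n_hidden")
        return _sigmoid(params.visible_bias + g @ params.weights.T)
    raise ValueError(f"unknown direction {direction!r}")


def rbm_partition_function(params: RBMParams) -> float:
    """Exhaustive Z = Σ_{v,h} exp(−E(v,h)); testing aid, guarded to D+F ≤ 20."""
    D, F = params.n_visible, params.n_hidden
    if D + F > 20:
        raise ValueError(f"enumeration guard: D+F = {D + F} exceeds 20")
    vs = np.array(np.meshgrid(*([[0, 1]] * D), indexing="ij")).reshape(D, -1).T if D else np.zeros((1, 0))
    hs = np.array(np.meshgrid(*([[0, 1]] * F), indexing="ij")).reshape(F, -1).T if F else np.zeros((1, 0))
    # E(v,h) over the grid, vectorized: −v·g − h·y − v W h
    ev = vs @ params.visible_bias
    eh = hs @ params.hidden_bias
    cross = vs @ params.weights @ hs.T
    energies = -(ev[:, None] + eh[None, :] + cross)
    return float(np.sum(np.exp(-energies)))


def train_rbm(data: np.ndarray, n_hidden: int, config: DBNConfig, rng=None
              ) -> tuple[RBMParams, list[float]]:
    """CD-k training on [0,1] data; returns parameters and per-epoch recon MSE.

    Weights start centered Gaussian (sd 0.01), biases zero. Each CD step uses
    sampled hidden states on the data side and probabilities for the
    reconstruction, the standard practical recipe.
    """
    X = np.asarray(data, dtype=float)
    if X.size == 0:
        raise ValueError("empty training data")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("training data must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, D = X.shape
    params = RBMParams(
        weights=rng.normal(0.0, 0.01, size=(D, n_hidden)),
        visible_bias=np.zeros(D),
        hidden_bias=np.zeros(n_hidden),
    )
    lr = config.learning_rate
    mse_curve: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            b = batch.shape[0]
            ph_data = rbm_conditionals(params, batch, "visible_to_hidden")
            h = (rng.random(ph_data.shape) < ph_data).astype(float)
            for _step in range(config.cd_steps):
                pv = rbm_conditionals(params, h, "hidden_to_visible")
                ph = rbm_conditionals(params, pv, "visible_to_hidden")
                if _step < config.cd_steps - 1:
                    h = (rng.random(ph.shape) < ph).astype(float)
            params.weights += lr * (batch.T @ ph_data - pv.T @ ph) / b
            params.visible_bias += lr * (batch - pv).mean(axis=0)
            params.hidden_bias += lr * (ph_data - ph).mean(axis=0)
        recon = rbm_conditionals(
            params, rbm_conditionals(params, X, "visible_to_hidden"), "hidden_to_visible"
        )
        mse_curve.append(float(np.mean((recon - X) ** 2)))
    return params, mse_curve


def fit_dbn(table: LabeledTable, config: DBNConfig,
            scaler_reference: LabeledTable | None = None) -> DBNModel:
    """Greedy layerwise DBN fit on min-max-scaled features.

    ``scaler_reference`` defaults to ``table`` itself (the training split);
    pass the training table when fitting is delegated elsewhere.
    """
    ref = scaler_reference if scaler_reference is not None else table
    X = minmax_scale(table, ref).features
    rng = np.random.default_rng(config.seed)
    layers: list[RBMParams] = []
    curves: list[list[float]] = []
    scalers: list[tuple[np.ndarray, np.ndarray]] = []
    current = X
    for depth, size in enumerate(config.layer_sizes):
        params, curve = train_rbm(current, size, config, rng)
        layers.append(params)
        curves.append(curve)
        current = rbm_conditionals(params, current, "visible_to_hidden")
        if depth < len(config.layer_sizes) - 1:
            lo, hi = current.min(axis=0), current.max(axis=0)
            scalers.append((lo, hi))
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            current = (current - lo) / span
    return DBNModel(layers=layers, layer_sizes=config.layer_sizes,
                    scaler_reference=ref, reconstruction_mse=curves,
                    layer_scalers=scalers)


def transform_dbn(model: DBNModel, table: LabeledTable) -> np.ndarray:
    """Top-layer hidden probabilities (deterministic deep features) per row."""
    if table.n_features != model.layers[0].n_visible:
        raise ValueError("feature count does not match the model's first layer")
    current = minmax_scale(table, model.scaler_reference).features
    for depth, params in enumerate(model.layers):
        current = rbm_conditionals(params, current, "visible_to_hidden")
        if depth < len(model.layer_scalers):
            lo, hi = model.layer_scalers[depth]
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            current = np.clip((current - lo) / span, 0.0, 1.0)
    return current
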