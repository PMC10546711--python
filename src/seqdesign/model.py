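"""Feed-forward residue classifier: architecture, gradients, Adam training.

The network maps a 180-value structural encoding to a 20-way softmax over the
standard amino acids through three 64-node hidden layers with ReLU
activations and dropout (p = 0.5, inverted scaling) after each hidden layer.
Training minimises the mean cross-entropy by mini-batch Adam over batches of
4096 residues; the parameters with the lowest validation loss seen during
training are the ones returned. Everything — initialisation, shuffling,
dropout masks — draws from a single seeded generator, so a (data, config)
pair reproduces bit-identical parameters.

Forward, backward and the optimiser are written directly in numpy; the
gradients are analytic and are validated against central finite differences
in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

N_CLASSES = 20


class DivergenceError(FloatingPointError):
    """Training loss became NaN/inf; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"divergence at epoch {epoch}")
        self.epoch = epoch


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults are the selected production architecture: 180 → 64 → 64 → 64 →
    20, dropout 0.5, Adam at learning rate 1e-3 (β₁=0.9, β₂=0.999, ε=1e-8),
    batches of 4096 residues, 200 epochs with best-validation-loss
    checkpointing (no early stop).
    """

    input_dim: int = 180
    hidden_layers: tuple[int, ...] = (64, 64, 64)
    dropout_p: float = 0.5
    classes: int = N_CLASSES
    batch_size: int = 4096
    max_epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        self.hidden_layers = tuple(int(w) for w in self.hidden_layers)
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("bad config: hidden widths must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("bad config: dropout_p must lie in [0, 1)")
        if self.batch_size < 1 or self.input_dim < 1 or self.classes < 2:
            raise ValueError("bad config: dimensions out of range")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_layers, self.classes]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class ModelParams:
    """Weights and biases plus the config they belong to and training history."""

    weights: list[np.ndarray]  # weights[l]: (fan_in, fan_out)
    biases: list[np.ndarray]  # biases[l]: (fan_out,)
    config: ModelConfig
    history: dict = field(default_factory=dict)

    def copy(self) -> "ModelParams":
        return ModelParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            config=self.config,
            history=dict(self.history),
        )

    def save(self, path) -> None:
        arrays = {}
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{layer}"] = w
            arrays[f"b{layer}"] = b
        for key, column in self.history.items():
            arrays[f"history_{key}"] = np.asarray(column)
        arrays["config"] = np.array(json.dumps(asdict(self.config)), dtype="U2048")
        arrays["format_version"] = np.array(1)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path) as data:
            config = ModelConfig(**json.loads(str(data["config"])))
            n_layers = len(config.layer_dims)
            weights = [data[f"W{l}"] for l in range(n_layers)]
            biases = [data[f"b{l}"] for l in range(n_layers)]
            history = {
                key[len("history_"):]: data[key]
                for key in data.files
                if key.startswith("history_")
            }
        return cls(weights=weights, biases=biases, config=config, history=history)


def parameter_count(config: ModelConfig) -> int:
    """Total trainable scalars: Σ (fan_in·fan_out + fan_out) over layers."""
    return sum(fi * fo + fo for fi, fo in config.layer_dims)


def init_model(config: ModelConfig, rng: np.random.Generator | None = None) -> ModelParams:
    """Initialise weights/biases with uniform fan-in scaling, U(±1/√fan_in)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in config.layer_dims:
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return ModelParams(weights=weights, biases=biases, config=config)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: ModelParams,
    x: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    _cache: list | None = None,
) -> np.ndarray:
    """Class probabilities for a batch, shape (B, classes); rows sum to 1.

    In ``train_mode`` each hidden ReLU output is followed by inverted
    dropout (masks drawn from ``rng``); in eval mode the pass is
    deterministic. ``_cache`` collects per-layer activations for backprop.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != params.config.input_dim:
        raise ValueError(
            f"shape mismatch: expected (B, {params.config.input_dim}), got {x.shape}"
        )
    p = params.config.dropout_p
    if train_mode and p > 0.0 and rng is None:
        raise ValueError("train_mode dropout requires an rng")
    h = x
    n_hidden = len(params.weights) - 1
    for layer in range(n_hidden):
        z = h @ params.weights[layer] + params.biases[layer]
        a = np.maximum(z, 0.0)
        if train_mode and p > 0.0:
            mask = (rng.random(a.shape) >= p) / (1.0 - p)
            a = a * mask
        else:
            mask = None
        if _cache is not None:
            _cache.append((h, z, mask))
        h = a
    logits = h @ params.weights[-1] + params.biases[-1]
    if _cache is not None:
        _cache.append((h, logits, None))
    return _softmax(logits)


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean over the batch of −log p(true class)."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p_true, 1e-300, None))))


def loss_and_gradients(
    params: ModelParams,
    x: np.ndarray,
    labels: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Cross-entropy loss and its analytic gradients w.r.t. every parameter.

    Returns ``(loss, grad_weights, grad_biases)``. The backward pass reuses
    the exact dropout masks sampled in the forward pass, so the gradients
    correspond to the sampled stochastic loss.
    """
    labels = np.asarray(labels, dtype=np.int64)
    cache: list = []
    probs = forward(params, x, train_mode=train_mode, rng=rng, _cache=cache)
    loss = cross_entropy(probs, labels)

    batch = len(labels)
    # softmax + CE gradient w.r.t. logits
    delta = probs.copy()
    delta[np.arange(batch), labels] -= 1.0
    delta /= batch

    grad_w = [np.empty_like(w) for w in params.weights]
    grad_b = [np.empty_like(b) for b in params.biases]
    for layer in range(len(params.weights) - 1, -1, -1):
        h_in, z, mask = cache[layer]
        grad_w[layer] = h_in.T @ delta
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ params.weights[layer].T
            _, prev_z, prev_mask = cache[layer - 1]
            if prev_mask is not None:  # dropout mask of the upstream activation
                delta = delta * prev_mask
            delta = delta * (prev_z > 0.0)
    return loss, grad_w, grad_b


def _recovery(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == labels))


def train(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    config: ModelConfig,
) -> ModelParams:
    """Train the classifier by mini-batch Adam on cross-entropy.

    Per epoch: reshuffle the training residues, sweep batches with Adam
    updates, then record train loss, validation loss and validation sequence
    recovery. The returned parameters are those with the minimum validation
    loss over all epochs; the full per-epoch history rides along in
    ``params.history``.

    Raises :class:`DivergenceError` if the loss ever goes non-finite.
    """
    train_features = np.asarray(train_features, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    val_features = np.asarray(val_features, dtype=np.float64)
    val_labels = np.asarray(val_labels, dtype=np.int64)
    if len(train_labels) == 0 or len(val_labels) == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    params = init_model(config, rng=rng)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in params.weights]
    v_w = [np.zeros_like(w) for w in params.weights]
    m_b = [np.zeros_like(b) for b in params.biases]
    v_b = [np.zeros_like(b) for b in params.biases]
    step = 0

    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_recovery": []}
    best = None
    best_val = np.inf

    n = len(train_labels)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grad_w, grad_b = loss_and_gradients(
                params,
                train_features[idx],
                train_labels[idx],
                train_mode=True,
                rng=rng,
            )
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            epoch_loss += loss * len(idx)
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - beta2**step) / (1 - beta1**step)
            )
            for layer in range(len(params.weights)):
                for g, m, v, p_arr in (
                    (grad_w[layer], m_w[layer], v_w[layer], params.weights[layer]),
                    (grad_b[layer], m_b[layer], v_b[layer], params.biases[layer]),
                ):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g * g
                    p_arr -= lr_t * m / (np.sqrt(v) + eps)

        val_probs = forward(params, val_features, train_mode=False)
        val_loss = cross_entropy(val_probs, val_labels)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["val_recovery"].append(_recovery(val_probs, val_labels))
        if val_loss < best_val:
            best_val = val_loss
            best = params.copy()

    best.history = {k: np.asarray(vals) for k, vals in history.items()}
    return best
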