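"""The convolutional fuzzy network: architecture, accounting, training.

Layer sequence (channels-last, input treated as a length-``input_len``
sequence with one channel):

    Conv1D(64, k=5, same) -> Conv1D(32, k=3, same) -> MaxPool(2) -> Flatten
    -> Fuzzy(n_rules=2) -> BatchNorm -> Dense(2) -> Defuzzy -> softmax

With the default 73-feature input the flatten width is
floor(73/2) * 32 = 1152 and the parameter ledger totals 11,186 (11,182
trainable + 4 non-trainable batch-norm statistics). Training minimises
categorical cross-entropy with Adam; all randomness (initialisation, batch
shuffling) derives from the config seed, so a fixed seed reproduces the
final weights and history bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix
from .io_deap import ValidationError
from .layers import (
    BatchNorm,
    Conv1D,
    DefuzzLayer,
    Dense,
    Flatten,
    FuzzyLayer,
    Layer,
    MaxPool1D,
    softmax,
)

__all__ = [
    "CFNNConfig",
    "ModelSummary",
    "CFNNNetwork",
    "build_model",
    "summarize",
    "forward",
    "train",
    "save_model",
    "load_model",
]


@dataclass
class CFNNConfig:
    """Architecture and optimisation hyperparameters.

    Defaults reproduce the reference architecture: 73 input features,
    64x5 and 32x3 same-padded 1-D convolutions, pool 2, two fuzzy rules,
    two classes, Adam with learning rate 0.01, batch size 256, 100 epochs.
    ``pad_features`` right-pads narrower feature rows (e.g. the 70 columns
    of 14 channels x 5 bands) with zeros up to ``input_len``.
    """

    input_len: int = 73
    conv1_filters: int = 64
    conv1_kernel: int = 5
    conv2_filters: int = 32
    conv2_kernel: int = 3
    pool_size: int = 2
    n_rules: int = 2
    n_classes: int = 2
    learning_rate: float = 0.01
    batch_size: int = 256
    epochs: int = 100
    aggregation: str = "geometric-mean"
    pad_features: bool = True
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_len < max(self.conv1_kernel, self.conv2_kernel):
            raise ValidationError("input_len must be >= the kernel sizes")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        if self.n_classes != 2:
            raise ValidationError("only binary classification heads are supported")
        if self.n_rules < 1:
            raise ValidationError("n_rules must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValidationError("invalid optimisation hyperparameters")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ModelSummary:
    """Per-layer shape/parameter ledger in the style of a framework summary."""

    rows: list[tuple[str, tuple, int, bool]]
    totals: tuple[int, int, int]  # (total, trainable, non_trainable)

    def __str__(self) -> str:
        lines = [f"{'Layer':<24}{'Output shape':<18}{'Param #':>10}  Trainable"]
        lines.append("-" * len(lines[0]))
        for name, shape, count, trainable in self.rows:
            shape_str = "(None, " + ", ".join(str(s) for s in shape) + ")"
            lines.append(f"{name:<24}{shape_str:<18}{count:>10}  {trainable}")
        lines.append("-" * len(lines[0]))
        total, trainable, non_trainable = self.totals
        lines.append(f"Total parameters: {total:,}")
        lines.append(f"Trainable parameters: {trainable:,}")
        lines.append(f"Non-trainable parameters: {non_trainable}")
        return "\n".join(lines)


class _Adam:
    """Adam optimiser over a list of (layer, key) parameter slots."""

    def __init__(self, slots: list[tuple[Layer, str]], lr: float) -> None:
        self.slots = slots
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(layer.params[key]) for layer, key in slots]
        self.v = [np.zeros_like(layer.params[key]) for layer, key in slots]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (layer, key) in enumerate(self.slots):
            g = layer.grads[key]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            layer.params[key] -= (
                self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            )


class CFNNNetwork:
    """The assembled network plus the input adapter (padding, standardization)."""

    def __init__(self, cfg: CFNNConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        pooled = cfg.input_len // cfg.pool_size
        self.flatten_width = pooled * cfg.conv2_filters
        self.layers: list[Layer] = [
            Conv1D(
                1, cfg.conv1_filters, cfg.conv1_kernel, rng,
                activation="relu", name="conv1d",
            ),
            Conv1D(
                cfg.conv1_filters, cfg.conv2_filters, cfg.conv2_kernel, rng,
                activation="relu", name="conv1d_1",
            ),
            MaxPool1D(cfg.pool_size, name="max_pooling1d"),
            Flatten(name="flatten"),
            FuzzyLayer(
                self.flatten_width, cfg.n_rules, rng,
                aggregation=cfg.aggregation, name="fuzzy",
            ),
            BatchNorm(cfg.n_rules, name="batch_normalization"),
            Dense(
                cfg.n_rules, cfg.n_classes, rng,
                activation="softplus", name="dense",
            ),
            DefuzzLayer(cfg.n_classes, cfg.n_classes, rng, name="defuzzy"),
        ]
        # feature standardization statistics, fitted on the training split
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None

    # -- input adapter -------------------------------------------------------
    def adapt(self, batch: np.ndarray, fit_scaler: bool = False) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 2:
            raise ValidationError("batch must be 2-D (examples x features)")
        width = batch.shape[1]
        if width != self.cfg.input_len:
            if not self.cfg.pad_features or width > self.cfg.input_len:
                raise ValidationError(
                    f"batch width {width} does not match input_len "
                    f"{self.cfg.input_len}"
                )
        if self.cfg.standardize:
            if fit_scaler:
                self.feature_mean = batch.mean(axis=0)
                std = batch.std(axis=0)
                self.feature_std = np.where(std > 0, std, 1.0)
            if self.feature_mean is not None:
                batch = (batch - self.feature_mean) / self.feature_std
        if width < self.cfg.input_len:
            batch = np.pad(batch, ((0, 0), (0, self.cfg.input_len - width)))
        return batch

    # -- passes --------------------------------------------------------------
    def logits(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        x = batch[:, :, None]  # (B, L, 1)
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        probs = softmax(self.logits(self.adapt(batch), training=False))
        if not np.all(np.isfinite(probs)):
            raise ValidationError("non-finite values in network output")
        return probs

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.predict_proba(batch).argmax(axis=1)

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def trainable_slots(self) -> list[tuple[Layer, str]]:
        slots: list[tuple[Layer, str]] = []
        for layer in self.layers:
            keys = (
                layer.trainable_keys()
                if isinstance(layer, BatchNorm)
                else layer.params.keys()
            )
            for key in keys:
                slots.append((layer, key))
        return slots

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{layer.name}/{key}": value.copy()
            for layer in self.layers
            for key, value in layer.params.items()
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key] = np.asarray(
                    weights[f"{layer.name}/{key}"], dtype=np.float64
                ).reshape(layer.params[key].shape)


def build_model(cfg: CFNNConfig | None = None) -> CFNNNetwork:
    """Build the network with deterministically seeded weights."""
    return CFNNNetwork(cfg or CFNNConfig())


def summarize(model: CFNNNetwork) -> ModelSummary:
    """Per-layer output shapes and parameter counts, plus totals."""
    rows: list[tuple[str, tuple, int, bool]] = []
    shape: tuple = (model.cfg.input_len, 1)
    total = trainable = non_trainable = 0
    for layer in model.layers:
        shape = layer.output_shape(shape)
        count = layer.n_params()
        nt = layer.n_non_trainable()
        rows.append((layer.name, shape, count, count - nt > 0))
        total += count
        trainable += count - nt
        non_trainable += nt
    rows.append(("activation", shape, 0, False))  # softmax head
    return ModelSummary(rows=rows, totals=(total, trainable, non_trainable))


def forward(model: CFNNNetwork, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities for a batch of feature rows."""
    return model.predict_proba(batch)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[labels]


def train(
    model: CFNNNetwork,
    features: FeatureMatrix | np.ndarray,
    dimension: str = "valence",
    cfg: CFNNConfig | None = None,
    train_idx: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Train with Adam on categorical cross-entropy.

    Parameters
    ----------
    model
        Network from :func:`build_model`.
    features
        A :class:`FeatureMatrix` (labels taken from ``dimension``) or a raw
        (n, features) array with ``labels`` supplied separately.
    dimension
        Which label column to fit when ``features`` is a FeatureMatrix.
    cfg
        Optimisation settings; defaults to the model's own config.
    train_idx
        Row indices to train on (the rest is untouched); all rows if None.

    Returns
    -------
    dict
        History with per-epoch ``loss`` and ``accuracy`` lists.
    """
    cfg = cfg or model.cfg
    if isinstance(features, FeatureMatrix):
        X = features.values
        y = features.labels(dimension)
    else:
        X = np.asarray(features, dtype=np.float64)
        if labels is None:
            raise ValidationError("labels required when features is an array")
        y = np.asarray(labels)
    if train_idx is not None:
        X, y = X[train_idx], y[train_idx]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training set contains a single class")
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 training examples")

    X = model.adapt(X, fit_scaler=True)
    Y = _one_hot(y, cfg.n_classes)
    n = X.shape[0]
    optimiser = _Adam(model.trainable_slots(), cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            model.zero_grads()
            logits = model.logits(xb, training=True)
            probs = softmax(logits)
            batch_loss = -np.sum(yb * np.log(probs + 1e-12))
            epoch_loss += batch_loss
            epoch_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            model._backward((probs - yb) / len(idx))
            optimiser.step()
        history["loss"].append(float(epoch_loss / n))
        history["accuracy"].append(float(epoch_correct / n))
    return history


def save_model(model: CFNNNetwork, path: str | Path) -> None:
    """Write a self-describing JSON checkpoint (config + weights + scaler)."""
    payload = {
        "config": asdict(model.cfg),
        "weights": {k: v.tolist() for k, v in model.get_weights().items()},
        "feature_mean": None
        if model.feature_mean is None
        else model.feature_mean.tolist(),
        "feature_std": None
        if model.feature_std is None
        else model.feature_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> CFNNNetwork:
    payload = json.loads(Path(path).read_text())
    model = CFNNNetwork(CFNNConfig(**payload["config"]))
    model.set_weights(
        {k: np.asarray(v) for k, v in payload["weights"].items()}
    )
    if payload["feature_mean"] is not None:
        model.feature_mean = np.asarray(payload["feature_mean"])
        model.feature_std = np.asarray(payload["feature_std"])
    return model
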