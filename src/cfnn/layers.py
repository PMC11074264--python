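"""NumPy layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``grads`` during ``backward``. Shapes
follow the channels-last convention: sequence inputs are
(batch, length, channels), vector inputs (batch, features).
"""

from __future__ import annotations

import numpy as np

from .fuzzy import SIGMA_MIN
from .io_deap import ValidationError

__all__ = [
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "FuzzyLayer",
    "BatchNorm",
    "Dense",
    "DefuzzLayer",
    "softmax",
]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift for overflow safety."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    # inverse of softplus, stable for y not tiny
    return y + np.log1p(-np.exp(-y))


class Layer:
    """Base layer: named parameters, matching gradient buffers, a cache."""

    name: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for key, value in self.params.items():
            self.grads[key] = np.zeros_like(value)

    def output_shape(self, input_shape: tuple) -> tuple:
        raise NotImplementedError

    # parameter accounting ---------------------------------------------------
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def n_non_trainable(self) -> int:
        return 0

    def n_trainable(self) -> int:
        return self.n_params() - self.n_non_trainable()


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding, optional ReLU.

    Weights are (kernel, in_channels, filters); parameter count is
    filters * kernel * in_channels + filters (the activation is free).
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
        activation: str = "relu",
        name: str = "conv1d",
    ) -> None:
        super().__init__()
        if kernel < 1 or kernel % 2 != 1:
            raise ValidationError("kernel must be a positive odd length")
        if activation not in ("relu", "linear"):
            raise ValidationError(f"unknown activation '{activation}'")
        self.name = name
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.activation = activation
        # fan-in-scaled (LeCun) uniform init keeps activation variance near 1
        # through the conv stack, which the unit-width memberships of the
        # downstream fuzzification layer rely on
        limit = np.sqrt(3.0 / (kernel * in_channels))
        self.params["W"] = rng.uniform(-limit, limit, (kernel, in_channels, filters))
        self.params["b"] = np.zeros(filters)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ValidationError(
                f"{self.name}: expected (batch, length, {self.in_channels}); "
                f"got {x.shape}"
            )
        batch, length, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        out = np.tile(self.params["b"], (batch, length, 1))
        W = self.params["W"]
        for k in range(self.kernel):
            out += xp[:, k : k + length, :] @ W[k]
        if self.activation == "relu":
            mask = out > 0
            out = out * mask
        else:
            mask = None
        self._cache = {"xp": xp, "length": length, "mask": mask}
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xp, length = self._cache["xp"], self._cache["length"]
        if self._cache["mask"] is not None:
            grad_out = grad_out * self._cache["mask"]
        W = self.params["W"]
        self.grads["b"] += grad_out.sum(axis=(0, 1))
        grad_xp = np.zeros_like(xp)
        for k in range(self.kernel):
            self.grads["W"][k] += np.einsum(
                "bli,blo->io", xp[:, k : k + length, :], grad_out
            )
            grad_xp[:, k : k + length, :] += grad_out @ W[k].T
        pad = self.kernel // 2
        return grad_xp[:, pad : pad + length, :]

    def output_shape(self, input_shape: tuple) -> tuple:
        return (input_shape[0], self.filters)


class MaxPool1D(Layer):
    """Max pooling with non-overlapping windows; trailing remainder dropped."""

    def __init__(self, size: int = 2, name: str = "max_pooling") -> None:
        super().__init__()
        if size < 1:
            raise ValidationError("pool size must be >= 1")
        self.name = name
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        batch, length, channels = x.shape
        out_len = length // self.size
        trimmed = x[:, : out_len * self.size, :].reshape(
            batch, out_len, self.size, channels
        )
        idx = trimmed.argmax(axis=2)
        self._cache = {"idx": idx, "in_shape": x.shape, "out_len": out_len}
        return np.take_along_axis(trimmed, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, in_shape, out_len = (
            self._cache["idx"],
            self._cache["in_shape"],
            self._cache["out_len"],
        )
        batch, length, channels = in_shape
        grad_trimmed = np.zeros((batch, out_len, self.size, channels))
        np.put_along_axis(grad_trimmed, idx[:, :, None, :], grad_out[:, :, None, :], axis=2)
        grad_x = np.zeros(in_shape)
        grad_x[:, : out_len * self.size, :] = grad_trimmed.reshape(
            batch, out_len * self.size, channels
        )
        return grad_x

    def output_shape(self, input_shape: tuple) -> tuple:
        return (input_shape[0] // self.size, input_shape[1])


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = {"shape": x.shape}
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._cache["shape"])

    def output_shape(self, input_shape: tuple) -> tuple:
        return (int(np.prod(input_shape)),)


class FuzzyLayer(Layer):
    """Batched fuzzification: n_inputs crisp features -> n_rules strengths.

    Parameters are the membership means and (reparameterized) widths:
    sigma = softplus(rho) + SIGMA_MIN keeps widths positive during
    unconstrained gradient descent. Parameter count is
    n_inputs * n_rules * 2, matching one (mean, sigma) pair per
    input-rule connection.
    """

    def __init__(
        self,
        n_inputs: int,
        n_rules: int,
        rng: np.random.Generator,
        aggregation: str = "geometric-mean",
        name: str = "fuzzy",
    ) -> None:
        super().__init__()
        if aggregation not in ("geometric-mean", "product-log"):
            raise ValidationError(f"unknown aggregation '{aggregation}'")
        self.name = name
        self.n_inputs = n_inputs
        self.n_rules = n_rules
        self.aggregation = aggregation
        self.params["means"] = rng.standard_normal((n_inputs, n_rules))
        # start at sigma = 1
        self.params["rho"] = np.full(
            (n_inputs, n_rules), float(_softplus_inv(np.array(1.0 - SIGMA_MIN)))
        )
        self.zero_grads()

    def sigmas(self) -> np.ndarray:
        return _softplus(self.params["rho"]) + SIGMA_MIN

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_inputs:
            raise ValidationError(
                f"{self.name}: expected (batch, {self.n_inputs}); got {x.shape}"
            )
        sig = self.sigmas()
        diff = x[:, :, None] - self.params["means"][None]  # (B, D, R)
        e = (diff**2 / (2.0 * sig**2)[None]).sum(axis=1)  # (B, R)
        if self.aggregation == "geometric-mean":
            s = np.exp(-e / self.n_inputs)
            jstar = None
        else:
            jstar = e.argmin(axis=1)
            s = np.exp(-(e - e[np.arange(e.shape[0]), jstar][:, None]))
        self._cache = {"x": x, "diff": diff, "sig": sig, "s": s, "jstar": jstar}
        return s

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, diff, sig, s, jstar = (
            self._cache["x"],
            self._cache["diff"],
            self._cache["sig"],
            self._cache["s"],
            self._cache["jstar"],
        )
        if self.aggregation == "geometric-mean":
            g = -grad_out * s / self.n_inputs  # (B, R): d loss / d e_bj
        else:
            g = -grad_out * s
            rows = np.arange(s.shape[0])
            g[rows, jstar] += (grad_out * s).sum(axis=1)
        de_dx = diff / (sig**2)[None]  # (B, D, R)
        grad_x = (de_dx * g[:, None, :]).sum(axis=2)
        self.grads["means"] += -(de_dx * g[:, None, :]).sum(axis=0)
        dsig = (-(diff**2) / (sig**3)[None] * g[:, None, :]).sum(axis=0)
        self.grads["rho"] += dsig / (1.0 + np.exp(-self.params["rho"]))
        return grad_x

    def output_shape(self, input_shape: tuple) -> tuple:
        return (self.n_rules,)


class BatchNorm(Layer):
    """Batch normalization over the feature axis.

    Four quantities per feature: trainable scale gamma and shift beta, plus
    non-trainable moving mean and variance used at evaluation time.
    Momentum and epsilon follow common deep-learning defaults (0.99, 1e-3).
    """

    def __init__(
        self,
        n_features: int,
        momentum: float = 0.99,
        eps: float = 1e-3,
        name: str = "batch_normalization",
    ) -> None:
        super().__init__()
        self.name = name
        self.n_features = n_features
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.params["moving_mean"] = np.zeros(n_features)
        self.params["moving_var"] = np.ones(n_features)
        self.zero_grads()

    def n_non_trainable(self) -> int:
        return int(
            self.params["moving_mean"].size + self.params["moving_var"].size
        )

    def trainable_keys(self) -> tuple[str, ...]:
        return ("gamma", "beta")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.params["moving_mean"] = (
                self.momentum * self.params["moving_mean"] + (1 - self.momentum) * mean
            )
            self.params["moving_var"] = (
                self.momentum * self.params["moving_var"] + (1 - self.momentum) * var
            )
        else:
            mean = self.params["moving_mean"]
            var = self.params["moving_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        self._cache = {"x_hat": x_hat, "inv_std": inv_std, "training": training}
        return self.params["gamma"] * x_hat + self.params["beta"]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache["x_hat"], self._cache["inv_std"]
        self.grads["gamma"] += (grad_out * x_hat).sum(axis=0)
        self.grads["beta"] += grad_out.sum(axis=0)
        g = grad_out * self.params["gamma"]
        if not self._cache["training"]:
            return g * inv_std
        n = grad_out.shape[0]
        return (
            inv_std
            / n
            * (n * g - g.sum(axis=0) - x_hat * (g * x_hat).sum(axis=0))
        )

    def output_shape(self, input_shape: tuple) -> tuple:
        return input_shape


class Dense(Layer):
    """Affine layer with optional ReLU or softplus activation.

    Softplus is the natural choice in front of centre-of-gravity
    defuzzification: it keeps every rule activation strictly positive, so
    the defuzzification denominator never vanishes and no unit can die.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        activation: str = "linear",
        name: str = "dense",
    ) -> None:
        super().__init__()
        if activation not in ("relu", "softplus", "linear"):
            raise ValidationError(f"unknown activation '{activation}'")
        self.name = name
        self.n_in = n_in
        self.n_out = n_out
        self.activation = activation
        limit = np.sqrt(3.0 / n_in)  # fan-in-scaled uniform
        self.params["W"] = rng.uniform(-limit, limit, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            out = z * (z > 0)
        elif self.activation == "softplus":
            out = np.logaddexp(0.0, z)
        else:
            out = z
        self._cache = {"x": x, "z": z}
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, z = self._cache["x"], self._cache["z"]
        if self.activation == "relu":
            grad_out = grad_out * (z > 0)
        elif self.activation == "softplus":
            grad_out = grad_out / (1.0 + np.exp(-z))
        self.grads["W"] += x.T @ grad_out
        self.grads["b"] += grad_out.sum(axis=0)
        return grad_out @ self.params["W"].T

    def output_shape(self, input_shape: tuple) -> tuple:
        return (self.n_out,)


class DefuzzLayer(Layer):
    """Batched centre-of-gravity defuzzification with learned centres.

    nu_bk = sum_j C_kj x_bj / (sum_j x_bj + eps); parameter count is
    n_outputs * n_inputs (the centre matrix).
    """

    def __init__(
        self,
        n_inputs: int,
        n_outputs: int,
        rng: np.random.Generator,
        eps: float = 1e-9,
        name: str = "defuzzy",
    ) -> None:
        super().__init__()
        self.name = name
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.eps = eps
        self.params["C"] = 0.1 * rng.standard_normal((n_outputs, n_inputs))
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        denom = x.sum(axis=1, keepdims=True) + self.eps
        nu = x @ self.params["C"].T / denom
        self._cache = {"x": x, "denom": denom, "nu": nu}
        return nu

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, denom, nu = self._cache["x"], self._cache["denom"], self._cache["nu"]
        # d nu_bk / d x_bj = (C_kj - nu_bk) / denom_b
        grad_x = np.einsum(
            "bk,kj->bj", grad_out, self.params["C"]
        ) - (grad_out * nu).sum(axis=1, keepdims=True)
        grad_x /= denom
        self.grads["C"] += (grad_out / denom).T @ x
        return grad_x

    def output_shape(self, input_shape: tuple) -> tuple:
        return (self.n_outputs,)
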