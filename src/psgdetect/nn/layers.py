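"""Neural-network layers on top of the autodiff tensors.

Conventions follow the common deep-learning toolkits: feature maps are
(batch, channels, length); attention operates on (batch, length, d_model).
Weight initialization is Kaiming-uniform for convolution/linear weights from
a generator owned by the enclosing model, so parameter values (and therefore
outputs) are reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm_train, concat

__all__ = [
    "Parameter", "Module", "Linear", "Conv1d", "BatchNorm1d",
    "MultiHeadSelfAttention", "relu", "sigmoid", "softmax",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable container tracking parameters, submodules and train mode."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        for k, b in getattr(self, "_buffers", {}).items():
            out[prefix + k] = b
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "/"))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        from .autodiff import get_dtype

        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=get_dtype()).copy()
        for k in getattr(self, "_buffers", {}):
            self._buffers[k] = np.asarray(state[prefix + k], dtype=np.float64).copy()
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + "/")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel), c_in * kernel))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel.

    Training uses batch statistics and updates exponential running averages;
    evaluation uses the running statistics so single-segment inference is
    well defined.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
            return out
        mu = self._buffers["running_mean"][None, :, None]
        var = self._buffers["running_var"][None, :, None]
        scale = self.gamma.reshape(1, -1, 1) * (1.0 / np.sqrt(var + self.eps))
        return x * scale + (self.beta.reshape(1, -1, 1) - Tensor(mu) * scale)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    return x.softmax(axis=axis)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with h parallel heads.

    Per head i the input is projected by W_i^Q, W_i^K, W_i^V (realized as
    fused d x d projections split along the feature axis), attention is
    softmax(Q_i K_i^T / sqrt(d_k)) V_i with d_k = d / h, and the concatenated
    heads pass through the output projection W^O.  Shape-preserving.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % heads:
            raise ValueError(f"d_model {d_model} not divisible by heads {heads}")
        self.heads = heads
        self.d_k = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """(B, h, L, L) softmax attention matrices, for inspection/tests."""
        q, k, _ = self._project(x)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        return softmax(scores, axis=-1).data

    def _project(self, x: Tensor):
        B, L, d = x.shape
        h, dk = self.heads, self.d_k

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dk).transpose(0, 2, 1, 3)  # (B, h, L, dk)

        return split(self.wq(x)), split(self.wk(x)), split(self.wv(x))

    def forward(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        q, k, v = self._project(x)
        q = q * (1.0 / np.sqrt(self.d_k))  # scale Q, not the L x L score matrix
        attn = softmax(q @ k.transpose(0, 1, 3, 2), axis=-1)
        heads = attn @ v  # (B, h, L, dk)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(merged)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    return concat(tensors, axis=1)
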