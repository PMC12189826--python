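"""Multi-scale attention U-Net for per-sample event probabilities.

The temporal segmentation network maps a preprocessed 60 s segment
(6000 samples x C channels at 100 Hz) to per-sample probabilities for the
two event classes [LM, SDB].  Each encoder level applies a parallel
multi-scale convolution block — three same-padding branches with kernel
sizes (5, 11, 17) matched to short transient EMG bursts and sustained
respiratory patterns, concatenated and fused by a width-1 convolution, then
batch normalization and ReLU — followed by factor-2 max pooling.  The
bottleneck adds multi-head self-attention (4 heads, residual) over the
compressed token sequence to supply global context, e.g. the flanking
breathing amplitude an apnea must be judged against.  The mirrored decoder
up-samples (nearest-neighbor + convolution), concatenates the encoder skip
at each level, and a final width-1 convolution with an independent per-class
sigmoid yields the probability raster; the two classes are not mutually
exclusive, so no softmax is applied across them.

Depth, widths and pooling are configurable; the attention bottleneck and the
multi-scale branches can each be disabled to reproduce single-kernel /
no-attention ablations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    BatchNorm1d,
    Conv1d,
    Module,
    MultiHeadSelfAttention,
    Tensor,
    concat,
    no_grad,
    relu,
    sigmoid,
)

__all__ = ["ModelConfig", "MultiScaleBlock", "AttentionUNet", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 5
    kernel_sizes: tuple[int, ...] = (5, 11, 17)
    depth: int = 4
    base_width: int = 16
    pool_factor: int = 2
    heads: int = 4
    out_classes: int = 2
    segment_len: int = 6000
    use_attention: bool = True
    positional_encoding: bool = False
    #: initial bias of the output head: a negative prior keeps the initial
    #: event probability low, which speeds up Dice training on sparse events
    head_bias_init: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd (same padding)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.segment_len % self.pool_factor**self.depth:
            raise ValueError(
                f"segment_len {self.segment_len} not divisible by "
                f"pool_factor^depth = {self.pool_factor ** self.depth}"
            )
        if (self.base_width * 2 ** (self.depth - 1)) % self.heads:
            raise ValueError("bottleneck width must be divisible by the head count")

    @property
    def level_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**i for i in range(self.depth))

    @property
    def bottleneck_len(self) -> int:
        return self.segment_len // self.pool_factor**self.depth


class MultiScaleBlock(Module):
    """Parallel multi-scale convolution branches + width-1 fusion + BN + ReLU."""

    def __init__(self, c_in: int, c_out: int, kernels: tuple[int, ...], rng):
        super().__init__()
        self.branches = [Conv1d(c_in, c_out, k, rng) for k in kernels]
        self.fuse = Conv1d(c_out * len(kernels), c_out, 1, rng)
        self.norm = BatchNorm1d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        y = concat([b(x) for b in self.branches], axis=1)
        return relu(self.norm(self.fuse(y)))


def _sinusoidal_encoding(length: int, d_model: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc  # (L, d)


class AttentionUNet(Module):
    """Encoder-decoder temporal segmentation network (see module docstring)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.level_widths
        kernels = config.kernel_sizes

        enc, dec = [], []
        c_prev = config.in_channels
        for w in widths:
            enc.append(MultiScaleBlock(c_prev, w, kernels, rng))
            c_prev = w
        self.encoder = enc
        self.bottleneck = MultiScaleBlock(widths[-1], widths[-1], kernels, rng)
        if config.use_attention:
            self.attention = MultiHeadSelfAttention(widths[-1], config.heads, rng)
        c_prev = widths[-1]
        for w in reversed(widths):
            # up-sampled features concatenated with the skip of width w
            dec.append(MultiScaleBlock(c_prev + w, w, kernels, rng))
            c_prev = w
        self.decoder = dec
        self.head = Conv1d(widths[0], config.out_classes, 1, rng)
        self.head.bias.data[:] = config.head_bias_init

    def forward(self, x: Tensor) -> Tensor:
        """(B, C_in, L) -> per-sample probabilities (B, L, n_classes)."""
        cfg = self.config
        if x.shape[1] != cfg.in_channels or x.shape[2] != cfg.segment_len:
            raise ValueError(
                f"expected input (B, {cfg.in_channels}, {cfg.segment_len}), got {x.shape}"
            )
        skips = []
        for block in self.encoder:
            x = block(x)
            skips.append(x)
            x = x.maxpool1d(cfg.pool_factor)
        x = self.bottleneck(x)
        if cfg.use_attention:
            tokens = x.transpose(0, 2, 1)  # (B, L', d)
            if cfg.positional_encoding:
                tokens = tokens + _sinusoidal_encoding(tokens.shape[1], tokens.shape[2])
            x = (tokens + self.attention(tokens)).transpose(0, 2, 1)
        for block, skip in zip(self.decoder, reversed(skips)):
            x = x.upsample_nearest(cfg.pool_factor)
            x = block(concat([x, skip], axis=1))
        logits = self.head(x)  # (B, n_classes, L)
        return sigmoid(logits).transpose(0, 2, 1)

    def predict_probs(self, signals: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference on an (N, L, C) stack of segments -> (N, L, n_classes)."""
        self.eval()
        signals = np.asarray(signals, float)
        if signals.ndim == 2:
            signals = signals[None]
        out = []
        with no_grad():
            for i in range(0, len(signals), batch_size):
                batch = signals[i : i + batch_size].transpose(0, 2, 1)
                out.append(self.forward(Tensor(batch)).data)
        return np.concatenate(out, axis=0)


def save_checkpoint(path, net: AttentionUNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + config (+ optional training log)."""
    state = net.named_state()
    meta = {"config": asdict(net.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[AttentionUNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        net = AttentionUNet(ModelConfig(**cfg))
        net.load_state({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta.get("extra", {})
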