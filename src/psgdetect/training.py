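"""Dice-loss training with patient-wise splitting.

The loss is the class-averaged soft Dice loss

    L = 1 - (1/C) sum_i (2 |X_i . Y_i| + s) / (|X_i| + |Y_i| + s),  s = 1e-3,

where X_i are the predicted per-sample probabilities of class i over the
whole batch, Y_i the binary targets, |X_i . Y_i| the elementwise-product sum
and |X_i|, |Y_i| plain sums; the Laplace term s keeps empty classes finite
(an all-empty class contributes zero loss).  The soft relaxation makes the
set-overlap loss differentiable; identical binary prediction and target give
exactly 0.  Dice handles the heavy class imbalance of sparse events better
than per-sample cross-entropy.

Training uses Adam (lr 1e-3, weight decay 1e-4, batch size 128 over 50
epochs at full scale), no schedule and no early stopping; the checkpoint
with the best epoch loss is kept.  Patients are split 9:1 into train/test by
patient identifier, never by segment, so no night contributes to both sides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .network import AttentionUNet, ModelConfig
from .nn import Adam, Tensor
from .preprocess import Segment

__all__ = ["TrainConfig", "dice_loss", "split_patients", "train"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 128
    smooth: float = 1e-3
    test_fraction: float = 0.1  # the 9:1 patient split
    seed: int = 0
    #: "batch": Dice pooled over all samples of a class in the batch;
    #: "segment": Dice per segment, then averaged
    dice_aggregation: str = "batch"

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.smooth) < 0 or self.lr == 0:
            raise ValueError("lr positive; weight_decay/smooth nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.dice_aggregation not in ("batch", "segment"):
            raise ValueError("dice_aggregation must be 'batch' or 'segment'")


def dice_loss(pred, target, smooth: float = 1e-3, aggregation: str = "batch"):
    """Soft Dice loss averaged over classes; accepts Tensors or arrays.

    ``pred`` and ``target`` are (..., C) with matching shapes; all leading
    axes are pooled per class ("batch") or per leading item ("segment").
    Returns a scalar :class:`Tensor` (differentiable if ``pred`` is).
    """
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    t = np.asarray(target.data if isinstance(target, Tensor) else target, float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("target must be binary")
    n_classes = p.shape[-1]
    if aggregation == "batch":
        axes = tuple(range(p.ndim - 1))
    else:
        axes = tuple(range(1, p.ndim - 1))
    inter = (p * t).sum(axis=axes)
    sums = p.sum(axis=axes) + Tensor(t.sum(axis=axes))
    dice = (2.0 * inter + smooth) / (sums + smooth)
    return 1.0 - dice.mean()


def split_patients(patient_ids, test_fraction: float = 0.1, seed: int = 0):
    """Reproducible disjoint exhaustive patient split; test size round(n/10), min 1."""
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(len(ids) * test_fraction)))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return train, test


def _stack(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.signals for s in segments]).transpose(0, 2, 1)  # (B, C, T)
    y = np.stack([s.labels for s in segments]).astype(float)  # (B, T, 2)
    return x, y


def train(
    segments: list[Segment],
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    log_path=None,
    progress: bool = False,
) -> tuple[AttentionUNet, list[dict]]:
    """Train a network on labeled segments; returns (best net, loss history).

    The per-epoch mean loss is logged (optionally to CSV); the weights of the
    epoch with the lowest mean loss are restored before returning, so the
    best-so-far loss is monotone over the history.
    """
    if not segments:
        raise ValueError("empty training set")
    net = AttentionUNet(model_config)
    opt = Adam(net.parameters(), lr=train_config.lr, weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    history: list[dict] = []
    best = (np.inf, None)
    for epoch in range(1, train_config.epochs + 1):
        net.train()
        order = rng.permutation(len(segments))
        losses, weights = [], []
        for i in range(0, len(order), train_config.batch_size):
            batch = [segments[j] for j in order[i : i + train_config.batch_size]]
            x, y = _stack(batch)
            opt.zero_grad()
            loss = dice_loss(
                net(Tensor(x)), y, train_config.smooth, train_config.dice_aggregation
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(batch))
        epoch_loss = float(np.average(losses, weights=weights))
        history.append({"epoch": epoch, "loss": epoch_loss})
        if progress:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}")
        if epoch_loss < best[0]:
            best = (epoch_loss, {k: v.copy() for k, v in net.named_state().items()})
    if best[1] is not None:
        net.load_state(best[1])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss"])
            writer.writeheader()
            writer.writerows(history)
    return net, history
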