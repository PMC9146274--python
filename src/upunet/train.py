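"""Training protocol for the restoration networks.

Half-mean-square regression loss per pixel per batch item, augmented with an
l2 penalty ``lambda * sum(w^2)`` over convolution weights only (biases and
batch-norm parameters are not penalized).  Optimization uses Adam with
standard moment decays, an initial learning rate of 0.01 dropped by a factor
of 0.2 every 25 epochs (piecewise constant), mini-batches of 50, and 200
maximum epochs; there is no early stopping and the validation loss is
monitoring-only.  Runs are fully seeded: initialization, shuffling, and
dropout all derive from one seed, so two runs with identical data and seeds
produce bit-identical weights on one platform.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field as dc_field

import numpy as np

from .nn import DTYPE, Adam, Param
from .model import Network

logger = logging.getLogger("upunet")


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.01
    drop_factor: float = 0.2
    drop_period_epochs: int = 25
    batch_size: int = 50
    max_epochs: int = 200
    l2_lambda: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.drop_period_epochs <= 0 or self.batch_size <= 0:
            raise ValueError("rates, periods and batch size must be positive")
        if not (0.0 < self.drop_factor <= 1.0):
            raise ValueError("drop_factor must be in (0, 1]")


@dataclass
class TrainHistory:
    train_loss: list[float] = dc_field(default_factory=list)
    val_loss: list[float] = dc_field(default_factory=list)
    lr: list[float] = dc_field(default_factory=list)
    epoch_seconds: list[float] = dc_field(default_factory=list)
    network: Network | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "lr": self.lr,
            "seconds": self.epoch_seconds,
        })


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Piecewise-constant schedule: lr = lr0 * drop^floor((epoch-1)/period)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return cfg.initial_lr * cfg.drop_factor ** ((epoch - 1) // cfg.drop_period_epochs)


def l2_penalty(params: list[Param], lam: float) -> float:
    """lambda * sum of squared penalized weights."""
    if lam == 0:
        return 0.0
    return lam * float(sum(np.sum(p.value.astype(np.float64) ** 2)
                           for p in params if p.penalized))


def training_loss(prediction: np.ndarray, target: np.ndarray,
                  params: list[Param] | None = None, l2_lambda: float = 0.0) -> float:
    """Half mean-square error per pixel per item, plus the l2 penalty.

    ``(1 / (2 B P)) * sum((prediction - target)^2) + lambda * sum(w^2)``
    where B is the batch size and P the pixels per frame.
    """
    prediction = np.asarray(prediction)
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {target.shape}")
    diff = prediction.astype(np.float64) - target.astype(np.float64)
    data = 0.5 * float(np.mean(diff ** 2))
    return data + l2_penalty(params or [], l2_lambda)


def _stack(pairs, indices) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([pairs[i].input_frame for i in indices])[:, None].astype(DTYPE)
    y = np.stack([pairs[i].target_frame for i in indices])[:, None].astype(DTYPE)
    return x, y


def evaluate_loss(network: Network, pairs, batch_size: int = 16,
                  params=None, l2_lambda: float = 0.0) -> float:
    """Mean loss over a split in inference mode (running batch-norm stats)."""
    total = 0.0
    count = 0
    for i in range(0, len(pairs), batch_size):
        idx = range(i, min(i + batch_size, len(pairs)))
        x, y = _stack(pairs, idx)
        pred = network.forward(x, training=False)
        diff = pred.astype(np.float64) - y.astype(np.float64)
        total += 0.5 * float(np.sum(diff ** 2)) / y[0].size
        count += len(x)
    return total / count + l2_penalty(params or [], l2_lambda)


def train_model(network: Network, dataset, cfg: TrainConfig | None = None) -> TrainHistory:
    """Run the full mini-batch protocol; returns the history (final weights in place).

    ``dataset`` is either a :class:`~upunet.simulate.Dataset` or a
    ``(train_pairs, val_pairs)`` tuple.  Raises on divergence (non-finite
    loss).
    """
    cfg = cfg or TrainConfig()
    if hasattr(dataset, "train"):
        train_pairs, val_pairs = dataset.train, dataset.val
    else:
        train_pairs, val_pairs = dataset
    if not train_pairs:
        raise ValueError("empty training split")
    if cfg.batch_size > len(train_pairs):
        raise ValueError("batch_size exceeds training-set size")

    params = network.params()
    opt = Adam(params, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps, l2_lambda=cfg.l2_lambda)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if hasattr(network, "dropout_rng"):
        network.dropout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        network.dropout.rng = network.dropout_rng

    history = TrainHistory(network=network)
    n = len(train_pairs)
    for epoch in range(1, cfg.max_epochs + 1):
        t0 = time.perf_counter()
        lr = lr_at_epoch(cfg, epoch)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y = _stack(train_pairs, idx)
            pred = network.forward(x, training=True)
            diff = (pred - y).astype(np.float64)
            data_loss = 0.5 * float(np.mean(diff ** 2))
            loss = data_loss + l2_penalty(params, cfg.l2_lambda)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "lower the learning rate or check the data scale"
                )
            opt.zero_grad()
            network.backward((diff / diff.size).astype(DTYPE))
            opt.step(lr)
            epoch_loss += loss
            n_batches += 1
        val = evaluate_loss(network, val_pairs, params=params, l2_lambda=cfg.l2_lambda) \
            if val_pairs else float("nan")
        history.train_loss.append(epoch_loss / n_batches)
        history.val_loss.append(val)
        history.lr.append(lr)
        history.epoch_seconds.append(time.perf_counter() - t0)
        logger.info("epoch %d/%d lr=%.5g train=%.5g val=%.5g (%.1fs)",
                    epoch, cfg.max_epochs, lr, history.train_loss[-1], val,
                    history.epoch_seconds[-1])
    return history


def split_dataset(items: list, fractions: tuple[float, float, float], seed: int = 0):
    """Disjoint, exhaustive, seeded permutation split (remainder to train)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(items)
    n_val = int(math.floor(fractions[1] * n))
    n_test = int(math.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if fractions[0] > 0 and n_train == 0:
        raise ValueError("train split is empty")
    perm = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in perm[:n_train]]
    val = [items[i] for i in perm[n_train:n_train + n_val]]
    test = [items[i] for i in perm[n_train + n_val:]]
    return train, val, test
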