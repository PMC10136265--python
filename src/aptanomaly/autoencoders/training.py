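"""Seeded training loop shared by all three networks.

The loss is the mean squared error between a segment and its reconstruction,
minimized with Adam (default learning rate 1e-3), minibatches of 5 and the
training set reshuffled every epoch; the LSTM networks train for at most 50
epochs by default.  Everything is driven by a single NumPy generator, so a
fixed seed gives bit-identical parameters on a fixed platform.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from ..errors import TrainingDivergenceError, ValidationError
from ..signal_model import SegmentDataset
from .lstm import LSTMAEParams, LSTMAutoencoder
from .vanilla import VanillaAE

__all__ = ["NETWORK_KINDS", "TrainingConfig", "build_network",
           "train_autoencoder", "reconstruct", "reconstruction_errors"]

NETWORK_KINDS = ("vanilla", "ulstm", "blstm")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (defaults follow the study's stated choices)."""

    optimizer: str = "adam"
    max_epochs: int = 50
    batch_size: int = 5
    shuffle_each_epoch: bool = True
    learning_rate: float = 1e-3
    l2_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")


def build_network(kind: str, input_length: int, l2_penalty: float = 0.0):
    if kind == "vanilla":
        # 16 hidden units at protocol-scale segment lengths; shorter inputs
        # shrink the bottleneck to stay undercomplete
        hidden = min(16, int(input_length) - 1)
        return VanillaAE(input_length, hidden_size=hidden, l2_penalty=l2_penalty)
    if kind == "ulstm":
        return LSTMAutoencoder(input_length, LSTMAEParams("unidirectional"))
    if kind == "blstm":
        return LSTMAutoencoder(input_length, LSTMAEParams("bidirectional"))
    raise ValidationError(f"unknown network kind {kind!r}; expected one of "
                          f"{NETWORK_KINDS}")


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k].reshape(p.shape)
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _mean_loss(net, X: np.ndarray) -> float:
    Xhat = net.forward_batch(X)
    return float(np.mean((Xhat - X) ** 2))


def train_autoencoder(kind: str, train: SegmentDataset, cfg: TrainingConfig):
    """Train a network of ``kind`` on a normal-only training set.

    Returns the trained network, carrying a ``loss_trace`` attribute: entry 0
    is the mean loss at initialization, entry e >= 1 the mean minibatch loss
    of epoch e.  Non-finite losses abort with the epoch index.
    """
    if len(train) == 0:
        raise ValidationError("training set is empty")
    if train.role == "test":
        raise ValidationError("refusing to train on a test-role dataset")
    if any(seg.label != 1 for seg in train):
        raise ValidationError("training set must contain only normal segments")
    X = train.matrix
    net = build_network(kind, train.segment_length, l2_penalty=cfg.l2_penalty)
    rng = np.random.default_rng(cfg.seed)
    net.initialize(rng)
    params = net.parameters()
    opt = _Adam(params, lr=cfg.learning_rate)
    n = X.shape[0]
    trace: List[float] = [_mean_loss(net, X)]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            Xhat = net.forward_batch(batch)
            diff = Xhat - batch
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch, loss)
            grads = net.backward(2.0 * diff / diff.size)
            params = net.parameters()
            opt.step(params, grads)
            net.set_parameters(params)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    net.loss_trace = trace
    net.training_config = cfg
    return net


def reconstruct(net, segments: SegmentDataset) -> np.ndarray:
    """Reconstructions of every segment, stacked (n, L)."""
    if segments.segment_length != net.input_length:
        raise ValidationError(
            f"segment length {segments.segment_length} does not match network "
            f"input {net.input_length}"
        )
    if len(segments) == 0:
        return np.empty((0, net.input_length))
    return net.forward_batch(segments.matrix)


def reconstruction_errors(net, segments: SegmentDataset) -> np.ndarray:
    """Per-segment mean squared reconstruction error (the anomaly score)."""
    X = segments.matrix
    if len(segments) == 0:
        return np.empty(0)
    Xhat = reconstruct(net, segments)
    return np.mean((Xhat - X) ** 2, axis=1)
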