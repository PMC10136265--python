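"""The vanilla autoencoder: one hidden layer, undercomplete.

Encoder ``Z = f_e(We X + be)`` with a sigmoid, decoder
``X_hat = f_d(Wd Z + bd)`` with the identity (the inputs are z-scored and may
be negative, so a bounded decoder output would need hidden rescaling).
Hidden size defaults to 16 latent units.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from ..errors import ValidationError
from .activations import sigmoid

__all__ = ["VanillaAEParams", "vanilla_forward", "VanillaAE"]

_ACTIVATIONS: Dict[str, Callable] = {
    "sigmoid": sigmoid,
    "identity": lambda z: np.asarray(z, dtype=float),
    "tanh": np.tanh,
}


@dataclass
class VanillaAEParams:
    """Weights of a single-hidden-layer autoencoder (M hidden, N input)."""

    We: np.ndarray          # (M, N)
    be: np.ndarray          # (M,)
    Wd: np.ndarray          # (N, M)
    bd: np.ndarray          # (N,)
    encoder_activation: str = "sigmoid"
    decoder_activation: str = "identity"

    def __post_init__(self):
        self.We = np.asarray(self.We, dtype=float)
        self.be = np.asarray(self.be, dtype=float)
        self.Wd = np.asarray(self.Wd, dtype=float)
        self.bd = np.asarray(self.bd, dtype=float)
        M, N = self.We.shape
        if self.be.shape != (M,) or self.Wd.shape != (N, M) or self.bd.shape != (N,):
            raise ValidationError(
                f"inconsistent shapes: We {self.We.shape}, be {self.be.shape}, "
                f"Wd {self.Wd.shape}, bd {self.bd.shape}"
            )
        for name in (self.encoder_activation, self.decoder_activation):
            if name not in _ACTIVATIONS:
                raise ValidationError(f"unknown activation {name!r}")

    @property
    def hidden_size(self) -> int:
        return self.We.shape[0]

    @property
    def input_length(self) -> int:
        return self.We.shape[1]


def vanilla_forward(
    params: VanillaAEParams, x: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Single-vector forward pass; returns ``(z, x_hat)``.

    The latent ``z`` is exposed deliberately — it is the learned feature
    representation of the segment.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.input_length,):
        raise ValidationError(
            f"input length {x.shape} does not match network input "
            f"({params.input_length},)"
        )
    fe = _ACTIVATIONS[params.encoder_activation]
    fd = _ACTIVATIONS[params.decoder_activation]
    z = fe(params.We @ x + params.be)
    x_hat = fd(params.Wd @ z + params.bd)
    return z, x_hat


class VanillaAE:
    """Trainable wrapper with batched forward/backward for MSE training."""

    kind = "vanilla"

    def __init__(self, input_length: int, hidden_size: int = 16,
                 l2_penalty: float = 0.0):
        if not 0 < hidden_size:
            raise ValidationError("hidden_size must be positive")
        if hidden_size >= input_length:
            raise ValidationError(
                "vanilla AE must be undercomplete (hidden_size < input_length)"
            )
        self.input_length = int(input_length)
        self.hidden_size = int(hidden_size)
        self.l2_penalty = float(l2_penalty)
        self.params: VanillaAEParams | None = None
        self._cache = None

    def initialize(self, rng: np.random.Generator) -> None:
        """Glorot-uniform weights, zero biases."""
        N, M = self.input_length, self.hidden_size

        def glorot(fan_out, fan_in):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_out, fan_in))

        self.params = VanillaAEParams(
            We=glorot(M, N), be=np.zeros(M), Wd=glorot(N, M), bd=np.zeros(N)
        )

    def parameters(self) -> Dict[str, np.ndarray]:
        p = self.params
        return {"We": p.We, "be": p.be, "Wd": p.Wd, "bd": p.bd}

    def set_parameters(self, arrays: Dict[str, np.ndarray]) -> None:
        self.params = VanillaAEParams(
            We=arrays["We"], be=arrays["be"], Wd=arrays["Wd"], bd=arrays["bd"]
        )

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        """Batched reconstruction of an (B, N) matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_length:
            raise ValidationError(
                f"segment length {X.shape[1]} does not match network input "
                f"{self.input_length}"
            )
        p = self.params
        Z = sigmoid(X @ p.We.T + p.be)
        Xhat = Z @ p.Wd.T + p.bd
        self._cache = (X, Z)
        return Xhat

    def backward(self, dXhat: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. parameters, given dL/dXhat."""
        X, Z = self._cache
        p = self.params
        grads = {
            "Wd": dXhat.T @ Z,
            "bd": dXhat.sum(axis=0),
        }
        dZ = dXhat @ p.Wd
        dpre = dZ * Z * (1.0 - Z)
        grads["We"] = dpre.T @ X
        grads["be"] = dpre.sum(axis=0)
        if self.l2_penalty > 0:
            grads["We"] = grads["We"] + self.l2_penalty * p.We
            grads["Wd"] = grads["Wd"] + self.l2_penalty * p.Wd
        return grads

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = self.params
        return sigmoid(X @ p.We.T + p.be)
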