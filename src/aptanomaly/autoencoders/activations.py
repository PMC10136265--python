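"""Elementwise activations used by every network."""
from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "tanh_act"]


def sigmoid(z):
    """Logistic sigmoid 1 / (1 + e^{-z}), elementwise and overflow-safe."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def tanh_act(z):
    """Hyperbolic tangent (e^{2z} - 1) / (e^{2z} + 1), elementwise."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    if out.ndim == 0:
        return float(out)
    return out
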