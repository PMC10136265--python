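"""LSTM machinery and the sequence-to-sequence LSTM autoencoders.

The cell follows the standard gate equations: forget, input and output gates
through the sigmoid, the cell candidate through tanh,

    f_t = sigma(Wfx x_t + Wfh h_{t-1} + bf)
    i_t = sigma(Wix x_t + Wih h_{t-1} + bi)
    g_t = tanh (Wcx x_t + Wch h_{t-1} + bc)
    c_t = f_t * c_{t-1} + i_t * g_t
    o_t = sigma(Wox x_t + Woh h_{t-1} + bo)
    h_t = o_t * tanh(c_t)

:func:`lstm_cell_step` is the literal, per-gate form of these equations.  The
batched :class:`LSTMLayer` packs the four gates into single matrices (gate
order ``i, f, g, o``) for speed; a property test holds the two routes to
within 1e-12 of each other.

Autoencoder topology (both directions): encoder LSTM(32) -> LSTM(16) (the
16-unit latent layer, matching the vanilla AE's hidden size), decoder
LSTM(32) -> per-time-step linear map to the single output channel.  Each
segment enters as a length-L sequence of 1-dimensional observations.  The
bidirectional variant runs every LSTM layer in both temporal directions and
concatenates the two hidden sequences.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from ..errors import ValidationError
from .activations import sigmoid, tanh_act

__all__ = ["LSTMCellParams", "lstm_cell_step", "LSTMLayer", "BiLSTMLayer",
           "TimeLinear", "LSTMAEParams", "LSTMAutoencoder"]


@dataclass
class LSTMCellParams:
    """The eight weight matrices and four bias vectors of one LSTM cell.

    Input weights are (H, F), recurrent weights (H, H), biases (H,).
    """

    Wfx: np.ndarray
    Wix: np.ndarray
    Wox: np.ndarray
    Wcx: np.ndarray
    Wfh: np.ndarray
    Wih: np.ndarray
    Woh: np.ndarray
    Wch: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bo: np.ndarray
    bc: np.ndarray

    def __post_init__(self):
        for name in ("Wfx", "Wix", "Wox", "Wcx", "Wfh", "Wih", "Woh", "Wch",
                     "bf", "bi", "bo", "bc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        H, F = self.Wfx.shape
        for name in ("Wix", "Wox", "Wcx"):
            if getattr(self, name).shape != (H, F):
                raise ValidationError(f"{name} must have shape {(H, F)}")
        for name in ("Wfh", "Wih", "Woh", "Wch"):
            if getattr(self, name).shape != (H, H):
                raise ValidationError(f"{name} must have shape {(H, H)}")
        for name in ("bf", "bi", "bo", "bc"):
            if getattr(self, name).shape != (H,):
                raise ValidationError(f"{name} must have shape {(H,)}")

    @property
    def hidden_size(self) -> int:
        return self.Wfx.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wfx.shape[1]

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
                    ) -> "LSTMCellParams":
        """Unpack an (F, 4H)/(H, 4H)/(4H,) gate-stacked parameter set."""
        H = Wh.shape[0]
        i, f, g, o = (slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H),
                      slice(3 * H, 4 * H))
        return cls(
            Wix=Wx[:, i].T, Wfx=Wx[:, f].T, Wcx=Wx[:, g].T, Wox=Wx[:, o].T,
            Wih=Wh[:, i].T, Wfh=Wh[:, f].T, Wch=Wh[:, g].T, Woh=Wh[:, o].T,
            bi=b[i], bf=b[f], bc=b[g], bo=b[o],
        )


def lstm_cell_step(
    params: LSTMCellParams, x_t: np.ndarray, h_prev: np.ndarray,
    c_prev: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One literal evaluation of the gate equations; returns ``(h_t, c_t)``."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H, F = params.hidden_size, params.input_size
    if x_t.shape != (F,) or h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValidationError(
            f"shape mismatch: x_t {x_t.shape} (want {(F,)}), h_prev "
            f"{h_prev.shape}, c_prev {c_prev.shape} (want {(H,)})"
        )
    f_t = sigmoid(params.Wfx @ x_t + params.Wfh @ h_prev + params.bf)
    i_t = sigmoid(params.Wix @ x_t + params.Wih @ h_prev + params.bi)
    g_t = tanh_act(params.Wcx @ x_t + params.Wch @ h_prev + params.bc)
    c_t = f_t * c_prev + i_t * g_t
    o_t = sigmoid(params.Wox @ x_t + params.Woh @ h_prev + params.bo)
    h_t = o_t * tanh_act(c_t)
    return h_t, c_t


class LSTMLayer:
    """A single-direction, sequence-to-sequence LSTM layer (batched).

    Parameters are gate-stacked: ``Wx`` (F, 4H), ``Wh`` (H, 4H), ``b`` (4H,)
    with gate order ``i, f, g, o``.  ``reverse=True`` processes the sequence
    back-to-front (the backward half of a bidirectional layer).
    """

    def __init__(self, input_size: int, hidden_size: int, reverse: bool = False):
        self.input_size = int(input_size)
        self.hidden_size = int(hidden_size)
        self.reverse = bool(reverse)
        self.Wx = np.zeros((input_size, 4 * hidden_size))
        self.Wh = np.zeros((hidden_size, 4 * hidden_size))
        self.b = np.zeros(4 * hidden_size)
        self._cache = None

    def initialize(self, rng: np.random.Generator) -> None:
        F, H = self.input_size, self.hidden_size
        lim_x = np.sqrt(6.0 / (F + 4 * H))
        lim_h = np.sqrt(6.0 / (H + 4 * H))
        self.Wx = rng.uniform(-lim_x, lim_x, size=(F, 4 * H))
        self.Wh = rng.uniform(-lim_h, lim_h, size=(H, 4 * H))
        self.b = np.zeros(4 * H)

    def cell_params(self) -> LSTMCellParams:
        return LSTMCellParams.from_packed(self.Wx, self.Wh, self.b)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """(B, T, F) -> (B, T, H), zero initial state."""
        if self.reverse:
            X = X[:, ::-1, :]
        B, T, F = X.shape
        H = self.hidden_size
        pre_x = X.reshape(B * T, F) @ self.Wx
        pre_x = pre_x.reshape(B, T, 4 * H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        I = np.empty((B, T, H)); Fg = np.empty((B, T, H))
        G = np.empty((B, T, H)); O = np.empty((B, T, H))
        C = np.empty((B, T, H)); TC = np.empty((B, T, H))
        Hprev = np.empty((B, T, H))
        Hout = np.empty((B, T, H))
        for t in range(T):
            Hprev[:, t] = h
            z = pre_x[:, t] + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], Fg[:, t], G[:, t], O[:, t] = i, f, g, o
            C[:, t], TC[:, t], Hout[:, t] = c, tc, h
        self._cache = (X, I, Fg, G, O, C, TC, Hprev)
        if self.reverse:
            return Hout[:, ::-1, :]
        return Hout

    def backward(self, dHout: np.ndarray) -> np.ndarray:
        """Backprop through time; stores grads, returns dX (input layout)."""
        if self.reverse:
            dHout = dHout[:, ::-1, :]
        X, I, Fg, G, O, C, TC, Hprev = self._cache
        B, T, F = X.shape
        H = self.hidden_size
        dZ = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dHout[:, t] + dh_next
            i, f, g, o = I[:, t], Fg[:, t], G[:, t], O[:, t]
            tc = TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dZ[:, t, :H] = di * i * (1.0 - i)
            dZ[:, t, H:2 * H] = df * f * (1.0 - f)
            dZ[:, t, 2 * H:3 * H] = dg * (1.0 - g * g)
            dZ[:, t, 3 * H:] = do * o * (1.0 - o)
            dh_next = dZ[:, t] @ self.Wh.T
        flatZ = dZ.reshape(B * T, 4 * H)
        self.grads = {
            "Wx": X.reshape(B * T, F).T @ flatZ,
            "Wh": Hprev.reshape(B * T, H).T @ flatZ,
            "b": flatZ.sum(axis=0),
        }
        dX = (flatZ @ self.Wx.T).reshape(B, T, F)
        if self.reverse:
            dX = dX[:, ::-1, :]
        return dX

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def set_parameters(self, arrays: Dict[str, np.ndarray]) -> None:
        self.Wx = np.asarray(arrays["Wx"], dtype=float)
        self.Wh = np.asarray(arrays["Wh"], dtype=float)
        self.b = np.asarray(arrays["b"], dtype=float)


class BiLSTMLayer:
    """Forward + backward LSTM over the same input; outputs concatenated."""

    def __init__(self, input_size: int, hidden_size: int):
        self.fwd = LSTMLayer(input_size, hidden_size, reverse=False)
        self.bwd = LSTMLayer(input_size, hidden_size, reverse=True)
        self.input_size = input_size
        self.hidden_size = hidden_size

    @property
    def output_size(self) -> int:
        return 2 * self.hidden_size

    def initialize(self, rng: np.random.Generator) -> None:
        self.fwd.initialize(rng)
        self.bwd.initialize(rng)

    def forward(self, X: np.ndarray) -> np.ndarray:
        return np.concatenate([self.fwd.forward(X), self.bwd.forward(X)], axis=2)

    def backward(self, dH: np.ndarray) -> np.ndarray:
        H = self.hidden_size
        return self.fwd.backward(dH[:, :, :H]) + self.bwd.backward(dH[:, :, H:])

    def parameters(self) -> Dict[str, np.ndarray]:
        out = {}
        for tag, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in layer.parameters().items():
                out[f"{tag}.{k}"] = v
        return out

    def set_parameters(self, arrays: Dict[str, np.ndarray]) -> None:
        self.fwd.set_parameters({k[4:]: v for k, v in arrays.items()
                                 if k.startswith("fwd.")})
        self.bwd.set_parameters({k[4:]: v for k, v in arrays.items()
                                 if k.startswith("bwd.")})


class TimeLinear:
    """Per-time-step affine map (F features -> 1 output channel)."""

    def __init__(self, input_size: int):
        self.input_size = int(input_size)
        self.W = np.zeros((input_size, 1))
        self.b = np.zeros(1)
        self._cache = None

    def initialize(self, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (self.input_size + 1))
        self.W = rng.uniform(-limit, limit, size=(self.input_size, 1))
        self.b = np.zeros(1)

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._cache = X
        return X @ self.W + self.b

    def backward(self, dY: np.ndarray) -> np.ndarray:
        X = self._cache
        B, T, F = X.shape
        flatX = X.reshape(B * T, F)
        flatY = dY.reshape(B * T, 1)
        self.grads = {"W": flatX.T @ flatY, "b": flatY.sum(axis=0)}
        return (flatY @ self.W.T).reshape(B, T, F)

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def set_parameters(self, arrays: Dict[str, np.ndarray]) -> None:
        self.W = np.asarray(arrays["W"], dtype=float)
        self.b = np.asarray(arrays["b"], dtype=float)


@dataclass(frozen=True)
class LSTMAEParams:
    """Topology constants of the LSTM autoencoders.

    The latent layer has 16 hidden units (equal to the vanilla AE's hidden
    size, so every network passes similarly sized features to its decoder);
    the flanking encoder/decoder layers have 32.
    """

    direction: str = "unidirectional"
    outer_hidden: int = 32
    latent_hidden: int = 16

    def __post_init__(self):
        if self.direction not in ("unidirectional", "bidirectional"):
            raise ValidationError(f"unknown direction {self.direction!r}")


class LSTMAutoencoder:
    """Sequence-to-sequence LSTM autoencoder (ULSTM or BLSTM)."""

    def __init__(self, input_length: int, topology: LSTMAEParams | None = None):
        self.input_length = int(input_length)
        self.topology = topology or LSTMAEParams()
        bi = self.topology.direction == "bidirectional"
        self.kind = "blstm" if bi else "ulstm"
        oh, lh = self.topology.outer_hidden, self.topology.latent_hidden
        Layer = BiLSTMLayer if bi else LSTMLayer
        mult = 2 if bi else 1
        self.layers = [
            ("enc.l1", Layer(1, oh)),
            ("enc.l2", Layer(oh * mult, lh)),        # latent layer
            ("dec.l1", Layer(lh * mult, oh)),
            ("dec.out", TimeLinear(oh * mult)),
        ]

    def initialize(self, rng: np.random.Generator) -> None:
        for _, layer in self.layers:
            layer.initialize(rng)

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        """(B, L) segments in, (B, L) reconstructions out."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_length:
            raise ValidationError(
                f"segment length {X.shape[1]} does not match network input "
                f"{self.input_length}"
            )
        out = X[:, :, None]
        for _, layer in self.layers:
            out = layer.forward(out)
        return out[:, :, 0]

    def backward(self, dXhat: np.ndarray) -> Dict[str, np.ndarray]:
        grad = dXhat[:, :, None]
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        out = {}
        for name, layer in self.layers:
            if isinstance(layer, BiLSTMLayer):
                for tag, sub in (("fwd", layer.fwd), ("bwd", layer.bwd)):
                    for k, g in sub.grads.items():
                        out[f"{name}.{tag}.{k}"] = g
            else:
                for k, g in layer.grads.items():
                    out[f"{name}.{k}"] = g
        return out

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent sequence from the 16-unit layer, (B, L, latent_features)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, :, None]
        out = self.layers[0][1].forward(X)
        return self.layers[1][1].forward(out)

    def parameters(self) -> Dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for k, v in layer.parameters().items():
                out[f"{name}.{k}"] = v
        return out

    def set_parameters(self, arrays: Dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            prefix = name + "."
            layer.set_parameters(
                {k[len(prefix):]: v for k, v in arrays.items()
                 if k.startswith(prefix)}
            )
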