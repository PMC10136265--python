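"""Portable model container (HDF5).

Layout::

    /                 attrs: format_version, kind, input_length
    /weights/<name>   one dataset per parameter, canonical names
    /training         attrs: the TrainingConfig fields
    /loss_trace       per-epoch mean loss (entry 0 = at initialization)
    /kde/...          added by the thresholding module for detectors

Weights are stored as float64, so a save/load round-trip is bit-exact.
"""
from __future__ import annotations

from typing import Optional

import h5py
import numpy as np

from ..errors import ValidationError
from .training import TrainingConfig, build_network

FORMAT_VERSION = 1

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]


def save_model(net, path, mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = net.kind
        f.attrs["input_length"] = net.input_length
        wg = f.require_group("weights")
        for name, arr in net.parameters().items():
            wg.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
        cfg: Optional[TrainingConfig] = getattr(net, "training_config", None)
        if cfg is not None:
            tg = f.require_group("training")
            for key, val in cfg.__dict__.items():
                tg.attrs[key] = val
        trace = getattr(net, "loss_trace", None)
        if trace is not None:
            f.create_dataset("loss_trace", data=np.asarray(trace, dtype=np.float64))


def load_model(path):
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValidationError(f"unsupported model format version {version}")
        kind = f.attrs["kind"]
        kind = kind.decode() if isinstance(kind, bytes) else str(kind)
        net = build_network(kind, int(f.attrs["input_length"]))
        weights = {name: ds[()] for name, ds in f["weights"].items()}
        net.set_parameters(weights)
        if "training" in f:
            attrs = dict(f["training"].attrs)
            net.training_config = TrainingConfig(
                optimizer=str(attrs.get("optimizer", "adam")),
                max_epochs=int(attrs.get("max_epochs", 50)),
                batch_size=int(attrs.get("batch_size", 5)),
                shuffle_each_epoch=bool(attrs.get("shuffle_each_epoch", True)),
                learning_rate=float(attrs.get("learning_rate", 1e-3)),
                l2_penalty=float(attrs.get("l2_penalty", 0.0)),
                seed=int(attrs.get("seed", 0)),
            )
        if "loss_trace" in f:
            net.loss_trace = [float(x) for x in f["loss_trace"][()]]
    return net
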