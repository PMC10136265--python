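"""Canonical synthetic benchmark: fixed-size train/test segment datasets.

Used by the calibration checks and example workflows: a normal-only training
set plus a balanced test set of normal and whole-signal-anomalous (broken
transistor and no-sense) segments, all generated from one seed.
"""
from __future__ import annotations

import math
from dataclasses import replace
from typing import List, Tuple

import numpy as np

from .errors import ValidationError
from .preprocess import normalize_signal, segment_signal
from .signal_model import Segment, SegmentDataset
from .synth import SynthConfig, generate_normal_signal, inject_anomaly

__all__ = ["benchmark_datasets"]


def _signal_segments(config: SynthConfig, signal_id: str, kind: str | None,
                     L: int) -> List[Segment]:
    sig = generate_normal_signal(config, signal_id)
    if kind is not None:
        sig = inject_anomaly(sig, kind, config)
    return segment_signal(normalize_signal(sig), L)


def benchmark_datasets(
    seed: int,
    config: SynthConfig | None = None,
    n_train_segments: int = 60,
    n_test_normal: int = 20,
    n_test_anomalous: int = 20,
) -> Tuple[SegmentDataset, SegmentDataset]:
    """Build the canonical benchmark under ``seed``.

    Training segments come from fresh normal signals; test anomalies are
    split evenly between the ``broken_transistor`` and ``no_sense`` classes
    (the whole-signal anomaly types, so every segment they contribute is
    anomalous).  Segment counts are exact: surplus segments from the last
    generated signal are dropped deterministically.
    """
    if min(n_train_segments, n_test_normal, n_test_anomalous) < 0:
        raise ValidationError("counts must be >= 0")
    config = replace(config or SynthConfig(), seed=int(seed))
    per_signal = len(config.schedule.ladder)
    L = config.schedule.n_interval_samples

    def take(prefix: str, kind: str | None, count: int) -> List[Segment]:
        out: List[Segment] = []
        i = 0
        while len(out) < count:
            out.extend(_signal_segments(config, f"{prefix}-{i:03d}", kind, L))
            i += 1
        return out[:count]

    train = take("train", None, n_train_segments)
    test = take("test-normal", None, n_test_normal)
    n_broken = n_test_anomalous // 2
    test += take("broken_transistor", "broken_transistor", n_broken)
    test += take("no_sense", "no_sense", n_test_anomalous - n_broken)
    return (
        SegmentDataset(train, segment_length=L, role="train"),
        SegmentDataset(test, segment_length=L, role="test"),
    )
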