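"""Data preparation: z-score normalization, segmentation, labelling, split.

The whole-signal z-score puts every experiment on a common scale before
segmentation; segments inherit the quality labels assigned at collection and
are split into a normal-only training set and a mixed test set (the pipeline
is semi-supervised).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import DegenerateSignalError, ValidationError
from .signal_model import RawSignal, Segment, SegmentDataset

__all__ = ["SplitSpec", "normalize_signal", "segment_signal", "split_dataset",
           "default_segment_length"]


@dataclass(frozen=True)
class SplitSpec:
    """Target training fraction of the total segment count, plus a seed.

    The study allocated roughly 45% of the adenosine segments and just under
    35% of the oestradiol segments to training, limited by the number of
    normal segments available.
    """

    train_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")


def normalize_signal(signal: RawSignal) -> RawSignal:
    """Z-score the ENTIRE signal: x -> (x - mean) / sd, sd with n-1 denominator.

    Times, schedule and quality labels are untouched.  Constant signals (and
    signals with fewer than two samples) cannot be scaled and raise
    :class:`DegenerateSignalError`.
    """
    x = signal.currents
    if x.size < 2:
        raise DegenerateSignalError(
            f"signal {signal.signal_id!r}: need at least 2 samples to normalize"
        )
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        raise DegenerateSignalError(
            f"signal {signal.signal_id!r}: constant signal (sd = 0) cannot be z-scored"
        )
    return signal.with_currents((x - mu) / sigma)


def default_segment_length(signal: RawSignal) -> int:
    """The injection-window length in samples — the natural segment length."""
    return signal.schedule.n_interval_samples


def segment_signal(signal: RawSignal, target_length: int | None = None) -> List[Segment]:
    """Cut one (normalized) signal into per-concentration segments.

    Every concentration window contributes its LAST ``target_length`` samples,
    so the long initial-load window is truncated to the same length as the
    injection windows and keeps the steady state closest to the first
    injection.  Windows are half-open sample-index ranges.
    """
    L = default_segment_length(signal) if target_length is None else int(target_length)
    if L < 1:
        raise ValidationError("target_length must be >= 1")
    segments = []
    for label, (start, stop) in zip(signal.schedule.ladder,
                                    signal.schedule.window_bounds()):
        if stop - start < L:
            raise ValidationError(
                f"signal {signal.signal_id!r}: window {label!r} has "
                f"{stop - start} samples, shorter than target length {L}"
            )
        segments.append(
            Segment(
                signal_id=signal.signal_id,
                concentration_class=label,
                values=signal.currents[stop - L:stop].copy(),
                quality=signal.segment_quality[label],
            )
        )
    return segments


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_dataset(
    segments: List[Segment], spec: SplitSpec
) -> Tuple[SegmentDataset, SegmentDataset]:
    """Seeded normal-only train / mixed test split.

    The training set holds ``round(train_fraction * total)`` normal segments
    sampled uniformly without replacement; everything else (normal and
    anomalous) is the test set.  Raises if the request exceeds the available
    normal segments, suggesting the maximum feasible fraction.
    """
    if not segments:
        raise ValidationError("no segments to split")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValidationError(f"segments have mixed lengths {sorted(lengths)}")
    L = lengths.pop()
    total = len(segments)
    normal_idx = [i for i, s in enumerate(segments) if s.label == 1]
    if not normal_idx:
        raise ValidationError("no normal segments available for training")
    n_train = _round_half_away(spec.train_fraction * total)
    if n_train < 1:
        raise ValidationError("train_fraction yields an empty training set")
    if n_train > len(normal_idx):
        max_frac = len(normal_idx) / total
        raise ValidationError(
            f"requested {n_train} training segments but only {len(normal_idx)} "
            f"normal segments exist; maximum feasible train_fraction is "
            f"{max_frac:.3f}"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = set(rng.choice(np.array(normal_idx), size=n_train, replace=False).tolist())
    train = [segments[i] for i in sorted(chosen)]
    test = [segments[i] for i in range(total) if i not in chosen]
    return (
        SegmentDataset(train, segment_length=L, role="train"),
        SegmentDataset(test, segment_length=L, role="test"),
    )
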