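"""Core data types for aptasensor drain-current signals.

A sensing experiment records a univariate drain-current time series while the
analyte concentration in the sensor well is raised step-wise: an initial load
period with no analyte, then injections at a fixed interval, each one moving
the well to the next rung of a concentration ladder.  The stretch of signal at
constant concentration is a *segment*; segments are the unit of anomaly
detection.  Each segment carries a quality label assigned at collection time
(``normal``, ``marginal``, ``no_sense``, ``broken``); everything other than
``normal`` counts as an anomaly.

On-disk formats
---------------
* signal CSV: header ``time_s,current``, UTF-8, decimal point;
* schedule JSON: keys ``initial_load_duration_s``, ``injection_interval_s``,
  ``time_step_s``, ``ladder`` (ordered list of concentration labels) and
  ``quality`` (label -> quality map);
* segment store: one CSV per dataset with columns
  ``signal_id,concentration,quality,label,v0..v{L-1}``.

Floats are written with 17 significant digits so round-trips are bit-exact.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Quality",
    "InjectionSchedule",
    "RawSignal",
    "Segment",
    "SegmentDataset",
    "read_signal",
    "write_signal",
    "read_segments",
    "write_segments",
]

#: relative tolerance on the uniform-time-step check
_STEP_RTOL = 1e-6


class Quality(str, Enum):
    """Per-segment quality assigned at data collection."""

    NORMAL = "normal"
    MARGINAL = "marginal"
    NO_SENSE = "no_sense"
    BROKEN = "broken"

    @property
    def is_normal(self) -> bool:
        return self is Quality.NORMAL

    @classmethod
    def parse(cls, value: "str | Quality") -> "Quality":
        if isinstance(value, Quality):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValidationError(
                f"unknown quality label {value!r}; expected one of "
                f"{[q.value for q in cls]}"
            ) from None


@dataclass(frozen=True)
class InjectionSchedule:
    """Protocol constants of one sensing run.

    The adenosine protocol used 1000 s initial load, injections every 500 s
    and a 1 s time step; the oestradiol protocol 600 s / 300 s / 1.081 s.
    """

    initial_load_duration_s: float
    injection_interval_s: float
    time_step_s: float
    ladder: tuple

    def __post_init__(self):
        if self.initial_load_duration_s <= 0:
            raise ValidationError("initial_load_duration_s must be > 0")
        if self.injection_interval_s <= 0:
            raise ValidationError("injection_interval_s must be > 0")
        if self.time_step_s <= 0:
            raise ValidationError("time_step_s must be > 0")
        object.__setattr__(self, "ladder", tuple(str(c) for c in self.ladder))
        if len(self.ladder) < 2:
            raise ValidationError("concentration ladder needs at least 2 entries")
        if len(set(self.ladder)) != len(self.ladder):
            raise ValidationError("concentration ladder entries must be unique")

    @property
    def n_initial_samples(self) -> int:
        return int(round(self.initial_load_duration_s / self.time_step_s))

    @property
    def n_interval_samples(self) -> int:
        return int(round(self.injection_interval_s / self.time_step_s))

    @property
    def n_samples(self) -> int:
        """Total samples of a schedule-conforming signal."""
        return self.n_initial_samples + (len(self.ladder) - 1) * self.n_interval_samples

    def window_bounds(self) -> List[tuple]:
        """Half-open ``[start, stop)`` sample bounds of each concentration window.

        Window 0 is the initial load; window k >= 1 starts at the k-th
        injection.  Sample indices are 0-based.
        """
        n0, ni = self.n_initial_samples, self.n_interval_samples
        bounds = [(0, n0)]
        for k in range(1, len(self.ladder)):
            start = n0 + (k - 1) * ni
            bounds.append((start, start + ni))
        return bounds

    def to_dict(self, quality: Dict[str, str] | None = None) -> dict:
        d = {
            "initial_load_duration_s": self.initial_load_duration_s,
            "injection_interval_s": self.injection_interval_s,
            "time_step_s": self.time_step_s,
            "ladder": list(self.ladder),
        }
        if quality is not None:
            d["quality"] = dict(quality)
        return d


@dataclass
class RawSignal:
    """One experiment: a drain-current series plus its protocol and quality map."""

    signal_id: str
    times: np.ndarray
    currents: np.ndarray
    schedule: InjectionSchedule
    segment_quality: Dict[str, Quality] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        self.segment_quality = {
            str(k): Quality.parse(v) for k, v in self.segment_quality.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.times.size == 0:
            raise ValidationError(f"signal {self.signal_id!r}: no samples")
        if self.times.shape != self.currents.shape or self.times.ndim != 1:
            raise ValidationError(
                f"signal {self.signal_id!r}: times and currents must be equal-length "
                f"1-D vectors (got {self.times.shape} vs {self.currents.shape})"
            )
        step = self.schedule.time_step_s
        diffs = np.diff(self.times)
        if diffs.size:
            if np.any(diffs <= 0):
                row = int(np.argmax(diffs <= 0)) + 1
                raise ValidationError(
                    f"signal {self.signal_id!r}: non-monotone time at row {row}"
                )
            bad = np.abs(diffs - step) > _STEP_RTOL * step
            if np.any(bad):
                row = int(np.argmax(bad)) + 1
                raise ValidationError(
                    f"signal {self.signal_id!r}: non-uniform time step at row {row} "
                    f"(expected {step}, got {diffs[row - 1]})"
                )
        expected = self.schedule.n_samples
        if self.times.size != expected:
            raise ValidationError(
                f"signal {self.signal_id!r}: {self.times.size} samples but the "
                f"schedule implies {expected}"
            )
        for label in self.schedule.ladder:
            if label not in self.segment_quality:
                raise ValidationError(
                    f"signal {self.signal_id!r}: unlabelled segment {label!r}"
                )

    @property
    def n(self) -> int:
        return int(self.times.size)

    def copy(self) -> "RawSignal":
        return RawSignal(
            signal_id=self.signal_id,
            times=self.times.copy(),
            currents=self.currents.copy(),
            schedule=self.schedule,
            segment_quality=dict(self.segment_quality),
        )

    def with_currents(self, currents: np.ndarray, **quality_updates) -> "RawSignal":
        out = self.copy()
        out.currents = np.asarray(currents, dtype=float)
        out.segment_quality.update(
            {k: Quality.parse(v) for k, v in quality_updates.items()}
        )
        out.validate()
        return out


@dataclass
class Segment:
    """A fixed-length, normalized window of one concentration class.

    ``label`` is the binary detection target: 1 for normal, 0 for anomaly.
    It is fully determined by ``quality`` (only ``normal`` quality is normal).
    """

    signal_id: str
    concentration_class: str
    values: np.ndarray
    quality: Quality

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.quality = Quality.parse(self.quality)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("segment values must be a nonempty 1-D vector")

    @property
    def label(self) -> int:
        return 1 if self.quality.is_normal else 0

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class SegmentDataset:
    """A list of equal-length segments with a train/test role.

    A ``train`` dataset may contain only normal segments — the pipeline is
    semi-supervised and never shows anomalies to the networks.
    """

    segments: List[Segment]
    segment_length: int
    role: str = "all"

    def __post_init__(self):
        if self.role not in ("train", "test", "all"):
            raise ValidationError(f"unknown dataset role {self.role!r}")
        if self.segment_length < 1:
            raise ValidationError("segment_length must be >= 1")
        for seg in self.segments:
            if len(seg) != self.segment_length:
                raise ValidationError(
                    f"segment {seg.signal_id}/{seg.concentration_class} has length "
                    f"{len(seg)}; dataset requires {self.segment_length}"
                )
        if self.role == "train":
            for seg in self.segments:
                if seg.label != 1:
                    raise ValidationError(
                        "train dataset must contain only normal segments; "
                        f"{seg.signal_id}/{seg.concentration_class} is "
                        f"{seg.quality.value}"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def matrix(self) -> np.ndarray:
        """Segments stacked as an (n, L) array."""
        if not self.segments:
            return np.empty((0, self.segment_length))
        return np.stack([s.values for s in self.segments])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)


# ---------------------------------------------------------------------------
# I/O


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def read_signal(path_csv, path_schedule) -> RawSignal:
    """Read a signal CSV plus its sidecar schedule/quality JSON."""
    path_csv = Path(path_csv)
    df = pd.read_csv(path_csv, float_precision="round_trip")
    for col in ("time_s", "current"):
        if col not in df.columns:
            raise ValidationError(f"{path_csv}: missing column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path_csv}: no samples")
    with open(path_schedule, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("initial_load_duration_s", "injection_interval_s", "time_step_s",
                "ladder", "quality"):
        if key not in meta:
            raise ValidationError(f"{path_schedule}: missing key {key!r}")
    schedule = InjectionSchedule(
        initial_load_duration_s=float(meta["initial_load_duration_s"]),
        injection_interval_s=float(meta["injection_interval_s"]),
        time_step_s=float(meta["time_step_s"]),
        ladder=meta["ladder"],
    )
    signal_id = str(meta.get("signal_id", path_csv.stem))
    return RawSignal(
        signal_id=signal_id,
        times=df["time_s"].to_numpy(dtype=float),
        currents=df["current"].to_numpy(dtype=float),
        schedule=schedule,
        segment_quality=meta["quality"],
    )


def write_signal(signal: RawSignal, path_csv, path_schedule) -> None:
    """Write a signal and its sidecar; ``read_signal`` inverts this exactly."""
    signal.validate()
    with open(path_csv, "w", encoding="utf-8", newline="") as fh:
        fh.write("time_s,current\n")
        for t, c in zip(signal.times, signal.currents):
            fh.write(f"{_fmt(t)},{_fmt(c)}\n")
    meta = signal.schedule.to_dict(
        quality={k: q.value for k, q in signal.segment_quality.items()}
    )
    meta["signal_id"] = signal.signal_id
    with open(path_schedule, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def write_segments(dataset: SegmentDataset, path) -> None:
    """Write a segment store CSV (validates the dataset before any write)."""
    SegmentDataset(dataset.segments, dataset.segment_length, dataset.role)
    cols = ["signal_id", "concentration", "quality", "label"] + [
        f"v{i}" for i in range(dataset.segment_length)
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        for seg in dataset.segments:
            row = [seg.signal_id, seg.concentration_class, seg.quality.value,
                   str(seg.label)]
            row.extend(_fmt(v) for v in seg.values)
            fh.write(",".join(row) + "\n")


def read_segments(path, role: str = "all") -> SegmentDataset:
    """Read a segment store CSV written by :func:`write_segments`."""
    df = pd.read_csv(path, dtype={"signal_id": str, "concentration": str},
                     float_precision="round_trip")
    value_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    for col in ("signal_id", "concentration", "quality", "label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if not value_cols:
        raise ValidationError(f"{path}: no value columns v0..")
    value_cols.sort(key=lambda c: int(c[1:]))
    L = len(value_cols)
    values = df[value_cols].to_numpy(dtype=float)
    segments = []
    for i in range(len(df)):
        seg = Segment(
            signal_id=df["signal_id"].iat[i],
            concentration_class=df["concentration"].iat[i],
            values=values[i],
            quality=Quality.parse(df["quality"].iat[i]),
        )
        if seg.label != int(df["label"].iat[i]):
            raise ValidationError(
                f"{path}: label column disagrees with quality for "
                f"{seg.signal_id}/{seg.concentration_class}"
            )
        segments.append(seg)
    return SegmentDataset(segments=segments, segment_length=L, role=role)
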