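"""Seeded simulator of aptasensor drain-current signals.

The real datasets behind this pipeline (carbon-nanotube FET aptasensors for
adenosine and oestradiol) are restricted, so this module generates signals
with the same statistical anatomy the detector consumes:

* a step-wise concentration ladder — an initial no-analyte load period, then
  injections at a fixed interval;
* an injection peak at the start of each concentration window whose amplitude
  grows with the ladder rank (a well-behaved sensor responds more strongly to
  a higher concentration), relaxing exponentially back toward the drift line;
* a steady monotone drift (rising for the adenosine-like chemistry, falling
  for the oestradiol-like one);
* i.i.d. Gaussian measurement noise.

Four anomaly classes mirror the taxonomy used when labelling the real data:

``abnormal_points``
    isolated spikes; the signal is still *normal* (these are treated as noise,
    not sensor failure, so no segment is relabelled);
``abnormal_interval``
    a contiguous run of whole segments overwritten with erratic values; those
    segments become ``marginal``;
``broken_transistor``
    the whole series replaced (flat line + noise, or a high-variance walk);
    every segment becomes ``broken``;
``no_sense``
    injection peaks suppressed — the sensor ignores the analyte; every
    segment becomes ``no_sense``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._seeding import derive_seed
from .errors import ValidationError
from .signal_model import InjectionSchedule, Quality, RawSignal

__all__ = [
    "AnomalyParams",
    "SynthConfig",
    "ANOMALY_KINDS",
    "adenosine_like_schedule",
    "oestradiol_like_schedule",
    "generate_normal_signal",
    "peak_component",
    "inject_anomaly",
    "generate_benchmark",
]

ANOMALY_KINDS = ("abnormal_points", "abnormal_interval", "broken_transistor",
                 "no_sense")


def adenosine_like_schedule() -> InjectionSchedule:
    """The adenosine protocol: 1000 s load, 500 s injections, 1 s step."""
    return InjectionSchedule(
        initial_load_duration_s=1000.0,
        injection_interval_s=500.0,
        time_step_s=1.0,
        ladder=("No Analyte", "1 nM", "10 nM", "100 nM", "1 μM", "10 μM"),
    )


def oestradiol_like_schedule() -> InjectionSchedule:
    """The oestradiol protocol: 600 s load, 300 s injections, 1.081 s step."""
    return InjectionSchedule(
        initial_load_duration_s=600.0,
        injection_interval_s=300.0,
        time_step_s=1.081,
        ladder=("No Analyte", "1 nM", "10 nM", "100 nM", "1 μM", "10 μM"),
    )


@dataclass(frozen=True)
class AnomalyParams:
    """Per-class knobs for anomaly injection.

    ``spike_amplitude``/``spike_count`` shape the isolated abnormal points;
    ``interval_gain`` is the noise amplification of an abnormal interval and
    ``interval_span`` how many consecutive segments it covers;
    ``broken_mode`` selects the broken-transistor signature;
    ``suppression_factor`` multiplies peak amplitudes for no-sense signals
    (0 removes them entirely);
    ``erratic_step_sd`` is the random-walk step of the erratic broken mode.
    """

    spike_amplitude: float = 10.0
    spike_count: int = 4
    interval_gain: float = 5.0
    interval_span: int = 2
    broken_mode: str = "flat"
    suppression_factor: float = 0.0
    erratic_step_sd: float = 2.0

    def __post_init__(self):
        if self.broken_mode not in ("flat", "erratic"):
            raise ValidationError(
                f"broken_mode must be 'flat' or 'erratic', got {self.broken_mode!r}"
            )
        if self.spike_count < 0 or self.interval_span < 1:
            raise ValidationError("spike_count >= 0 and interval_span >= 1 required")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValidationError("suppression_factor must be in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults emulate the adenosine-like chemistry.

    Units are arbitrary current units (the detector z-scores everything
    anyway); the drift rate is units/s, positive for the adenosine-like rise
    and negative for the oestradiol-like decay.
    """

    schedule: InjectionSchedule = field(default_factory=adenosine_like_schedule)
    baseline_current: float = 100.0
    segment_drift_rate: float = 0.01
    peak_gain: float = 3.0
    peak_decay_time_s: float = 150.0
    noise_sd: float = 0.5
    anomaly_params: AnomalyParams = field(default_factory=AnomalyParams)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.peak_gain < 0:
            raise ValidationError("peak_gain must be >= 0")
        if self.peak_decay_time_s <= 0:
            raise ValidationError("peak_decay_time_s must be > 0")


def _signal_rng(config: SynthConfig, signal_id: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(config.seed, f"synth:{signal_id}"))


def _times(schedule: InjectionSchedule) -> np.ndarray:
    n = schedule.n_samples
    return schedule.time_step_s * np.arange(1, n + 1)


def drift_line(config: SynthConfig, times: np.ndarray) -> np.ndarray:
    """The deterministic baseline + linear drift component."""
    return config.baseline_current + config.segment_drift_rate * (times - times[0])


def peak_component(config: SynthConfig, times: np.ndarray) -> np.ndarray:
    """Deterministic injection-peak component of a normal signal.

    Window k (k >= 1, k = ladder rank of the injected concentration) carries
    an instantaneous step of amplitude ``k * peak_gain`` at its first sample,
    relaxing exponentially toward the drift line with time constant
    ``peak_decay_time_s``.  Peaks live within their own window, so the
    amplitude right at injection k is exactly k * peak_gain above the drift
    line.  The initial no-analyte window has no peak.
    """
    schedule = config.schedule
    out = np.zeros_like(times)
    for k, (start, stop) in enumerate(schedule.window_bounds()):
        if k == 0:
            continue
        t_rel = times[start:stop] - times[start]
        out[start:stop] = (config.peak_gain * k) * np.exp(
            -t_rel / config.peak_decay_time_s
        )
    return out


def generate_normal_signal(config: SynthConfig, signal_id: str) -> RawSignal:
    """One normal signal: drift + injection peaks + Gaussian noise.

    Deterministic given ``(config.seed, signal_id)``.
    """
    times = _times(config.schedule)
    rng = _signal_rng(config, signal_id)
    noise = rng.normal(0.0, config.noise_sd, times.size) if config.noise_sd > 0 \
        else np.zeros_like(times)
    currents = drift_line(config, times) + peak_component(config, times) + noise
    quality = {label: Quality.NORMAL for label in config.schedule.ladder}
    return RawSignal(signal_id=signal_id, times=times, currents=currents,
                     schedule=config.schedule, segment_quality=quality)


def inject_anomaly(
    signal: RawSignal,
    kind: str,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    interval_segments: Optional[Tuple[int, int]] = None,
) -> RawSignal:
    """Return a copy of ``signal`` carrying one anomaly class.

    ``rng`` defaults to a stream derived from the config seed, the signal id
    and the anomaly kind.  ``interval_segments`` optionally pins the half-open
    window-index range ``[start, stop)`` of an abnormal interval; otherwise it
    is placed at random with span ``anomaly_params.interval_span``.

    The ``no_sense`` transform subtracts the deterministic peak component the
    generator would have produced, so it assumes ``signal`` was generated
    under the same ``config``.
    """
    if kind not in ANOMALY_KINDS:
        raise ValidationError(f"unknown anomaly kind {kind!r}; expected one of "
                              f"{ANOMALY_KINDS}")
    if rng is None:
        rng = np.random.default_rng(
            derive_seed(config.seed, f"anomaly:{kind}:{signal.signal_id}")
        )
    ap = config.anomaly_params
    schedule = signal.schedule
    n = signal.n
    currents = signal.currents.copy()

    if kind == "abnormal_points":
        if ap.spike_count > 0:
            pos = rng.choice(n, size=min(ap.spike_count, n), replace=False)
            signs = rng.choice([-1.0, 1.0], size=pos.size)
            currents[pos] += signs * ap.spike_amplitude
        return signal.with_currents(currents)  # qualities stay normal

    if kind == "abnormal_interval":
        n_windows = len(schedule.ladder)
        span = min(ap.interval_span, n_windows)
        if interval_segments is None:
            start = int(rng.integers(0, n_windows - span + 1))
            interval_segments = (start, start + span)
        lo, hi = interval_segments
        if not (0 <= lo < hi <= n_windows):
            raise ValidationError(
                f"interval_segments {interval_segments} outside [0, {n_windows})"
            )
        bounds = schedule.window_bounds()
        updates = {}
        for k in range(lo, hi):
            a, b = bounds[k]
            level = float(np.mean(signal.currents[a:b]))
            currents[a:b] = level + ap.interval_gain * rng.standard_normal(b - a)
            updates[schedule.ladder[k]] = Quality.MARGINAL
        return signal.with_currents(currents, **updates)

    if kind == "broken_transistor":
        if ap.broken_mode == "flat":
            currents = config.baseline_current + (
                rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0
                else np.zeros(n)
            )
        else:  # erratic: high-variance random walk around the baseline
            currents = config.baseline_current + np.cumsum(
                rng.normal(0.0, ap.erratic_step_sd, n)
            )
        updates = {label: Quality.BROKEN for label in schedule.ladder}
        return signal.with_currents(currents, **updates)

    # no_sense: suppress the injection peaks the generator put in
    peaks = peak_component(config, signal.times)
    currents = currents - (1.0 - ap.suppression_factor) * peaks
    updates = {label: Quality.NO_SENSE for label in schedule.ladder}
    return signal.with_currents(currents, **updates)


def generate_benchmark(
    config: SynthConfig, n_normal: int, n_per_anomaly_class: int
) -> List[RawSignal]:
    """A labelled, seeded collection: ``n_normal`` normal signals plus
    ``n_per_anomaly_class`` of each anomaly class (in ANOMALY_KINDS order)."""
    if n_normal < 0 or n_per_anomaly_class < 0:
        raise ValidationError("counts must be >= 0")
    signals: List[RawSignal] = []
    for i in range(n_normal):
        signals.append(generate_normal_signal(config, f"normal-{i:03d}"))
    for kind in ANOMALY_KINDS:
        for i in range(n_per_anomaly_class):
            base = generate_normal_signal(config, f"{kind}-{i:03d}")
            signals.append(inject_anomaly(base, kind, config))
    return signals


def anomaly_kind_of(signal_id: str) -> str:
    """Recover the benchmark class from a generated signal id."""
    for kind in ANOMALY_KINDS:
        if signal_id.startswith(kind):
            return kind
    return "normal"
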