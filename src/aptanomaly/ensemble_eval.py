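"""The five prediction models, confusion counts and the four metrics.

Three models use a single detector each (vanilla, ULSTM, BLSTM).  The two
integrated models combine an LSTM detector with the vanilla detector: a
segment the LSTM flags is an anomaly outright; segments the LSTM passes are
relabelled by the vanilla detector.  That truth table is exactly the logical
AND of the two "normal" verdicts, so the integrated anomaly set is the union
of the components' anomaly sets.

Metrics (positive class = anomaly by default, configurable):

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)
    F1 = harmonic mean of the two       accuracy = (TP + TN) / (P + N)

Zero-denominator metrics are reported as not-applicable (``None``), never
silently as 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .signal_model import SegmentDataset
from .thresholding import DetectorModel

__all__ = ["MODEL_NAMES", "integrate", "ConfusionCounts", "confusion",
           "Metrics", "metrics", "EvaluationReport", "evaluate_models"]

MODEL_NAMES = ("vanilla", "ulstm", "blstm", "ulstm+vanilla", "blstm+vanilla")


def integrate(zeta1: int, zeta2: Optional[int]) -> int:
    """Integrated decision from an LSTM verdict and a vanilla verdict.

    ``zeta1`` is the LSTM decision; segments it flags (0) are anomalies and
    the vanilla verdict is not consulted (may be ``None``).  Segments it
    passes (1) take the vanilla verdict ``zeta2``, which must then be present.
    """
    if zeta1 not in (0, 1):
        raise ValidationError(f"zeta1 must be 0 or 1, got {zeta1!r}")
    if zeta1 == 0:
        return 0
    if zeta2 is None:
        raise ValidationError("zeta2 required when the LSTM verdict is normal")
    if zeta2 not in (0, 1):
        raise ValidationError(f"zeta2 must be 0 or 1, got {zeta2!r}")
    return zeta2


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    positive_class: str = "anomaly"

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")
        if self.positive_class not in ("anomaly", "normal"):
            raise ValidationError("positive_class must be 'anomaly' or 'normal'")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
                "positive_class": self.positive_class}


def confusion(decisions: Sequence[int], labels: Sequence[int],
              positive_class: str = "anomaly") -> ConfusionCounts:
    """Tally a confusion matrix from binary decisions and ground-truth labels.

    Both sequences use the 1 = normal / 0 = anomaly convention;
    ``positive_class`` picks which of the two counts as positive.
    """
    decisions = np.asarray(decisions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if decisions.shape != labels.shape or decisions.ndim != 1:
        raise ValidationError(
            f"decisions and labels must be equal-length vectors "
            f"({decisions.shape} vs {labels.shape})"
        )
    if decisions.size == 0:
        raise ValidationError("nothing to evaluate")
    pos = 0 if positive_class == "anomaly" else 1
    TP = int(np.sum((decisions == pos) & (labels == pos)))
    FP = int(np.sum((decisions == pos) & (labels != pos)))
    TN = int(np.sum((decisions != pos) & (labels != pos)))
    FN = int(np.sum((decisions != pos) & (labels == pos)))
    return ConfusionCounts(TP, FP, TN, FN, positive_class=positive_class)


@dataclass(frozen=True)
class Metrics:
    """The four ratios; ``None`` marks a metric with a zero denominator."""

    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]

    def to_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "precision": self.precision,
                "f1": self.f1, "accuracy": self.accuracy}


def metrics(counts: ConfusionCounts) -> Metrics:
    sens = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    prec = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2.0 * prec * sens / (prec + sens)
    elif sens is not None and prec is not None:
        f1 = 0.0
    else:
        f1 = None
    acc = (counts.TP + counts.TN) / counts.total if counts.total else None
    return Metrics(sensitivity=sens, precision=prec, f1=f1, accuracy=acc)


@dataclass
class EvaluationReport:
    """Per-model evaluation: counts, metrics and per-segment decisions."""

    model: str
    counts: ConfusionCounts
    metrics: Metrics
    decisions: np.ndarray
    errors: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "counts": self.counts.to_dict(),
            "metrics": self.metrics.to_dict(),
            "decisions": [int(z) for z in self.decisions],
        }
        if self.errors is not None:
            d["errors"] = [float(e) for e in self.errors]
        return d


def evaluate_models(
    detectors: Dict[str, DetectorModel],
    test: SegmentDataset,
    positive_class: str = "anomaly",
) -> Dict[str, EvaluationReport]:
    """Evaluate every available model (and integrated pair) on the test set.

    ``detectors`` maps network kinds (``vanilla``/``ulstm``/``blstm``) to
    fitted detectors.  Integrated models are produced for every LSTM kind
    present alongside a vanilla detector.
    """
    if len(test) == 0:
        raise ValidationError("empty test set")
    labels = test.labels
    reports: Dict[str, EvaluationReport] = {}
    decisions: Dict[str, np.ndarray] = {}
    errors: Dict[str, np.ndarray] = {}
    for kind, det in detectors.items():
        errs = det.errors(test)
        dec = np.where(errs > det.tau_u, 0, 1).astype(int)
        decisions[kind] = dec
        errors[kind] = errs
        reports[kind] = EvaluationReport(
            model=kind,
            counts=(c := confusion(dec, labels, positive_class)),
            metrics=metrics(c),
            decisions=dec,
            errors=errs,
        )
    if "vanilla" in detectors:
        for lstm_kind in ("ulstm", "blstm"):
            if lstm_kind not in detectors:
                continue
            name = f"{lstm_kind}+vanilla"
            dec = np.array(
                [integrate(z1, z2) for z1, z2 in
                 zip(decisions[lstm_kind], decisions["vanilla"])],
                dtype=int,
            )
            reports[name] = EvaluationReport(
                model=name,
                counts=(c := confusion(dec, labels, positive_class)),
                metrics=metrics(c),
                decisions=dec,
            )
    return reports
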