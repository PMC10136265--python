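"""Reconstruction-error scoring and KDE-based threshold extraction.

The anomaly score of a segment is the mean squared error (MSE) between the
segment and its autoencoder reconstruction.  The scores of the (normal-only)
training set form a sample R = {r_1 .. r_m}; a Gaussian kernel density
estimate with the Gaussian-reference plug-in bandwidth

    H_opt ~= 1.06 * sigma * m^(-1/5)

(sample standard deviation with the m-1 denominator) models their
distribution.  The central confidence interval [tau_l, tau_u] at the default
90% level is read off the estimated distribution by inverting its CDF — the
KDE CDF is a closed-form equal-weight mixture of Gaussian CDFs, so the
inversion is a bracketed root find, not a density grid.  The upper endpoint
tau_u is the decision boundary: a segment whose error exceeds tau_u is
declared an anomaly.  The lower endpoint is deliberately ignored — an error
below tau_l just means the reconstruction is unusually faithful.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import h5py
import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .autoencoders import load_model, reconstruction_errors, save_model
from .errors import DegenerateSampleError, ValidationError
from .signal_model import SegmentDataset

__all__ = [
    "mse",
    "ErrorSample",
    "ErrorDensityModel",
    "silverman_bandwidth",
    "silverman_bandwidth_formula",
    "kde_density",
    "kde_cdf",
    "kde_interval",
    "decide",
    "DetectorModel",
    "fit_detector",
    "save_detector",
    "load_detector",
]


def mse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared componentwise difference (the reconstruction error)."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {x_hat.shape}")
    if x.size == 0:
        raise ValidationError("mse of empty vectors is undefined")
    return float(np.mean((x_hat - x) ** 2))


@dataclass(frozen=True)
class ErrorSample:
    """A sample of m >= 2 finite, nonnegative reconstruction errors."""

    errors: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.errors, dtype=float).ravel()
        object.__setattr__(self, "errors", arr)
        if arr.size < 2:
            raise ValidationError("error sample needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("error sample contains non-finite values")
        if np.any(arr < 0):
            raise ValidationError("reconstruction errors must be nonnegative")

    @property
    def m(self) -> int:
        return int(self.errors.size)


def _as_points(sample) -> np.ndarray:
    """The underlying sample values of an ErrorSample or plain array.

    The KDE layer itself is distribution-agnostic (it is exercised on signed
    synthetic draws in calibration checks); only :class:`ErrorSample` carries
    the nonnegativity invariant of reconstruction errors.
    """
    if isinstance(sample, ErrorSample):
        return sample.errors
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size < 2:
        raise ValidationError("sample needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("sample contains non-finite values")
    return arr


def silverman_bandwidth_formula(sigma: float, m: int) -> float:
    """The plug-in rule H = 1.06 * sigma * m^(-1/5), with no sample guards."""
    return 1.06 * float(sigma) * float(m) ** (-0.2)


def silverman_bandwidth(sample) -> float:
    """Plug-in bandwidth of a sample (sd with the m-1 denominator)."""
    pts = _as_points(sample)
    sigma = float(np.std(pts, ddof=1))
    if sigma == 0.0:
        raise DegenerateSampleError(
            "all errors identical (sd = 0); no bandwidth can be derived"
        )
    return silverman_bandwidth_formula(sigma, pts.size)


@dataclass
class ErrorDensityModel:
    """A fitted Gaussian-KDE error distribution with its decision interval."""

    sample: ErrorSample
    bandwidth: float
    level: float = 0.90
    tau_l: float = 0.0
    tau_u: float = 0.0
    kernel: str = "gaussian"

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be > 0")
        if not 0.0 < self.level < 1.0:
            raise ValidationError("level must be in (0, 1)")
        if self.kernel != "gaussian":
            raise ValidationError("only the Gaussian kernel is supported")
        if self.tau_l >= self.tau_u:
            raise ValidationError("tau_l must be < tau_u")


def kde_density(model_or_sample, r, bandwidth: Optional[float] = None):
    """KDE density rho(r) = (1/(mH)) sum_i K((r - r_i)/H), Gaussian K.

    Accepts either an :class:`ErrorDensityModel` or an array of sample points
    plus an explicit ``bandwidth``.  Vectorized over ``r``.
    """
    if isinstance(model_or_sample, ErrorDensityModel):
        pts = model_or_sample.sample.errors
        H = model_or_sample.bandwidth
    else:
        pts = np.asarray(model_or_sample, dtype=float).ravel()
        if bandwidth is None:
            raise ValidationError("bandwidth required when no model is given")
        H = float(bandwidth)
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    vals = norm.pdf((np.atleast_1d(r)[:, None] - pts[None, :]) / H).mean(axis=1) / H
    return float(vals[0]) if scalar else vals


def kde_cdf(points: np.ndarray, bandwidth: float, r) -> np.ndarray:
    """Closed-form CDF of the KDE: equal-weight mixture of Gaussian CDFs."""
    pts = np.asarray(points, dtype=float).ravel()
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    vals = norm.cdf((np.atleast_1d(r)[:, None] - pts[None, :]) / bandwidth).mean(axis=1)
    return float(vals[0]) if scalar else vals


def _invert_cdf(points: np.ndarray, H: float, p: float) -> float:
    lo = float(points.min() - 40.0 * H)
    hi = float(points.max() + 40.0 * H)
    return float(brentq(lambda r: kde_cdf(points, H, r) - p, lo, hi,
                        xtol=1e-13, rtol=8.9e-16, maxiter=200))


def kde_interval(
    sample,
    level: float = 0.90,
    bandwidth: Optional[float] = None,
    two_sided: bool = True,
) -> Tuple[float, float]:
    """Endpoints of the confidence interval of the KDE-estimated distribution.

    With ``two_sided`` (the default reading of a "90% confidence interval"),
    ``tau_l`` and ``tau_u`` are the (1-level)/2 and 1-(1-level)/2 quantiles of
    the estimated distribution; the one-sided alternative puts ``tau_u`` at
    the ``level`` quantile directly.  Inversion is exact to ~1e-10 in CDF.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    pts = _as_points(sample)
    H = silverman_bandwidth(pts) if bandwidth is None else float(bandwidth)
    if H <= 0:
        raise ValidationError("bandwidth must be > 0")
    if two_sided:
        p_l, p_u = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    else:
        p_l, p_u = 0.0, level
    tau_u = _invert_cdf(pts, H, p_u)
    tau_l = _invert_cdf(pts, H, p_l) if p_l > 0 else float("-inf")
    return tau_l, tau_u


def decide(r: float, tau_u: float) -> int:
    """Anomaly decision: 0 (anomaly) iff r > tau_u, else 1 (normal).

    The boundary is inclusive on the normal side; the lower interval endpoint
    plays no role in the decision.
    """
    if not (np.isfinite(r) and np.isfinite(tau_u)):
        raise ValidationError("decide() requires finite inputs")
    return 0 if r > tau_u else 1


@dataclass
class DetectorModel:
    """A trained network plus the error-density model that thresholds it."""

    network: object
    density: ErrorDensityModel

    @property
    def kind(self) -> str:
        return self.network.kind

    @property
    def tau_u(self) -> float:
        return self.density.tau_u

    def errors(self, segments: SegmentDataset) -> np.ndarray:
        return reconstruction_errors(self.network, segments)

    def predict(self, segments: SegmentDataset) -> np.ndarray:
        """Binary decisions (1 normal / 0 anomaly) for every segment."""
        errs = self.errors(segments)
        return np.where(errs > self.density.tau_u, 0, 1).astype(int)


def fit_detector(network, train: SegmentDataset, level: float = 0.90,
                 two_sided: bool = True) -> DetectorModel:
    """Score the training set, fit the KDE and extract the threshold."""
    errs = reconstruction_errors(network, train)
    sample = ErrorSample(errs)
    H = silverman_bandwidth(sample)
    tau_l, tau_u = kde_interval(sample, level=level, bandwidth=H,
                                two_sided=two_sided)
    density = ErrorDensityModel(sample=sample, bandwidth=H, level=level,
                                tau_l=tau_l, tau_u=tau_u)
    return DetectorModel(network=network, density=density)


def save_detector(detector: DetectorModel, path) -> None:
    """Model container plus a ``kde`` group; thresholds stored as float64."""
    save_model(detector.network, path, mode="w")
    d = detector.density
    with h5py.File(path, "a") as f:
        kg = f.create_group("kde")
        kg.create_dataset("errors", data=d.sample.errors.astype(np.float64))
        kg.attrs["bandwidth"] = float(d.bandwidth)
        kg.attrs["level"] = float(d.level)
        kg.attrs["tau_l"] = float(d.tau_l)
        kg.attrs["tau_u"] = float(d.tau_u)
        kg.attrs["kernel"] = d.kernel


def load_detector(path) -> DetectorModel:
    network = load_model(path)
    with h5py.File(path, "r") as f:
        if "kde" not in f:
            raise ValidationError(f"{path}: no kde group; not a detector artifact")
        kg = f["kde"]
        kernel = kg.attrs["kernel"]
        kernel = kernel.decode() if isinstance(kernel, bytes) else str(kernel)
        density = ErrorDensityModel(
            sample=ErrorSample(kg["errors"][()]),
            bandwidth=float(kg.attrs["bandwidth"]),
            level=float(kg.attrs["level"]),
            tau_l=float(kg.attrs["tau_l"]),
            tau_u=float(kg.attrs["tau_u"]),
        )
    return DetectorModel(network=network, density=density)
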