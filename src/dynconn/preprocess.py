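"""Post-ICA time-series cleaning.

The inputs are IC time courses, so all operations are one-dimensional and
applied per node: removal of initial non-equilibrium frames, joint
polynomial detrending (orders 0..3 in a single least-squares projection),
spike compression against a robust MAD-scaled baseline, and zero-phase
Butterworth low-pass filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import SubjectTimeSeries

__all__ = [
    "PreprocessConfig",
    "drop_initial",
    "detrend_poly",
    "despike",
    "lowpass",
    "preprocess_subject",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters.

    ``despike_threshold`` (c1) and ``despike_cap`` (c2) are in units of the
    MAD-based robust standard deviation: residuals beyond c1 are compressed
    by a saturating tanh map that never exceeds c2.
    """

    n_drop: int = 10
    detrend_order: int = 3
    despike_threshold: float = 2.5
    despike_cap: float = 4.0
    lowpass_hz: float = 0.15
    filter_order: int = 5

    def __post_init__(self) -> None:
        if self.n_drop < 0:
            raise ValueError("n_drop must be nonnegative")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be nonnegative")
        if not (0 < self.despike_threshold < self.despike_cap):
            raise ValueError("need 0 < despike_threshold < despike_cap")
        if self.lowpass_hz <= 0:
            raise ValueError("lowpass_hz must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be a positive integer")


def drop_initial(ts: SubjectTimeSeries, n_drop: int) -> SubjectTimeSeries:
    """Remove the first ``n_drop`` time points (pre-steady-state frames)."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= ts.n_timepoints:
        raise ValueError(
            f"cannot drop {n_drop} of {ts.n_timepoints} time points"
        )
    return SubjectTimeSeries(
        subject_id=ts.subject_id,
        data=ts.data[:, n_drop:].copy(),
        tr_seconds=ts.tr_seconds,
    )


def _poly_design(n: int, order: int) -> np.ndarray:
    # Legendre-style orthogonal polynomial basis on [-1, 1] for conditioning
    t = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(t, order)


def detrend_poly(series: np.ndarray, order: int = 3) -> np.ndarray:
    """Regress out polynomial trends of degree 0..order in one projection.

    The residual is orthogonal to every polynomial of degree <= order in
    the time index and has (numerically) zero mean.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n <= order + 1:
        raise ValueError(f"series of length {n} too short for order {order}")
    X = _poly_design(n, order)
    coef, *_ = np.linalg.lstsq(X, series.T if series.ndim == 2 else series, rcond=None)
    fitted = X @ coef
    return series - (fitted.T if series.ndim == 2 else fitted)


def despike(
    series: np.ndarray, c1: float = 2.5, c2: float = 4.0,
    baseline_order: int = 3,
) -> np.ndarray:
    """Compress spikes toward a smooth robust baseline.

    A polynomial baseline is fit by least squares; residuals are scaled by
    the MAD-based robust sigma.  Scaled residuals s with |s| > c1 are
    replaced by ``sign(s) * (c1 + (c2-c1) * tanh((|s|-c1)/(c2-c1)))`` so the
    output never deviates from the baseline by more than c2 robust sigmas;
    samples within the threshold are untouched.  A constant (zero-MAD)
    series is returned unchanged with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    n = series.shape[-1]
    order = min(baseline_order, max(0, n - 2))
    X = _poly_design(n, order)
    coef, *_ = np.linalg.lstsq(X, series, rcond=None)
    baseline = X @ coef
    resid = series - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        warnings.warn("zero MAD; series returned unchanged", stacklevel=2)
        return series.copy()
    s = resid / sigma
    out_s = s.copy()
    mask = np.abs(s) > c1
    out_s[mask] = np.sign(s[mask]) * (
        c1 + (c2 - c1) * np.tanh((np.abs(s[mask]) - c1) / (c2 - c1))
    )
    return baseline + out_s * sigma


def lowpass(
    series: np.ndarray,
    lowpass_hz: float,
    tr_seconds: float,
    filter_order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Applied forward and backward (``sosfiltfilt``), so the effective
    amplitude response is the squared Butterworth magnitude and there is no
    group delay.  The cutoff must lie below the Nyquist frequency
    ``1 / (2 * tr_seconds)``.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if lowpass_hz >= nyquist:
        raise ValueError(
            f"cutoff {lowpass_hz} Hz must be below Nyquist {nyquist:.4g} Hz"
        )
    sos = butter(filter_order, lowpass_hz, btype="low", fs=1.0 / tr_seconds,
                 output="sos")
    return sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def preprocess_subject(
    ts: SubjectTimeSeries, cfg: PreprocessConfig = PreprocessConfig()
) -> SubjectTimeSeries:
    """Full per-subject cleaning chain: drop, detrend, despike, low-pass."""
    out = drop_initial(ts, cfg.n_drop) if cfg.n_drop else ts
    data = detrend_poly(out.data, cfg.detrend_order)
    data = np.vstack([
        despike(row, cfg.despike_threshold, cfg.despike_cap) for row in data
    ])
    data = lowpass(data, cfg.lowpass_hz, ts.tr_seconds, cfg.filter_order)
    return SubjectTimeSeries(
        subject_id=ts.subject_id, data=data, tr_seconds=ts.tr_seconds
    )
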