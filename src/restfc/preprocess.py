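"""Per-ROI z-normalization and temporal band-pass filtering.

Filtering is zero-phase (forward-backward Butterworth), the rsfMRI standard:
the paper-grade preprocessing band for BOLD is 0.001-0.1 Hz, but note that on
a 420 s record a 0.001 Hz low edge mostly acts as detrending. z-scoring uses
the sample SD (denominator T-1), the same convention as the MAD/SD statistics
downstream, so that the point-process threshold "1 sigma" is exactly 1.0 on a
z-scored series.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import RoiTimeSeriesMatrix

__all__ = ["zscore", "bandpass", "BandpassFilter"]

logger = logging.getLogger(__name__)


def _zscore_array(values: np.ndarray, roi_labels=None) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.nonzero(sd == 0)[0][0])
        name = roi_labels[j] if roi_labels is not None else f"column {j}"
        raise ValueError(
            f"ROI {name!r} is constant (zero variance); cannot z-score"
        )
    return (values - values.mean(axis=0)) / sd


def zscore(ts: RoiTimeSeriesMatrix) -> RoiTimeSeriesMatrix:
    """Z-score each ROI column to mean 0, sample SD 1 (denominator T-1)."""
    return ts.with_values(_zscore_array(ts.values, ts.roi_labels))


def _bandpass_array(
    values: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float, order: int = 2
) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high edge {high_hz} Hz reaches Nyquist {nyquist} Hz at TR = {tr_seconds} s"
        )
    duration = values.shape[0] * tr_seconds
    if low_hz > 0 and 1.0 / low_hz > duration:
        logger.warning(
            "low band edge %g Hz has period %.0f s, longer than the %.0f s "
            "record; it mostly detrends rather than filters",
            low_hz, 1.0 / low_hz, duration,
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz / nyquist, btype="lowpass", output="sos")
    else:
        sos = signal.butter(
            order, [low_hz / nyquist, high_hz / nyquist], btype="bandpass", output="sos"
        )
    return signal.sosfiltfilt(sos, values, axis=0)


def bandpass(
    ts: RoiTimeSeriesMatrix, low_hz: float, high_hz: float, order: int = 2
) -> RoiTimeSeriesMatrix:
    """Zero-phase Butterworth band-pass applied to every ROI column.

    The identical filter acts on all columns, which preserves the expected
    instantaneous cross-correlation structure of broad-band signals.
    """
    return ts.with_values(
        _bandpass_array(ts.values, ts.tr_seconds, low_hz, high_hz, order)
    )


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`bandpass` + :func:`zscore`.

    ``transform`` accepts a T x N array (or a list of them) sampled at
    ``tr_seconds`` and returns the filtered (optionally z-scored) array(s).
    """

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.05,
                 order: int = 2, tr_seconds: float = 3.0, zscore: bool = False):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order
        self.tr_seconds = tr_seconds
        self.zscore = zscore

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X[0] if isinstance(X, list) else X).shape[-1]
        return self

    def _one(self, x: np.ndarray) -> np.ndarray:
        out = _bandpass_array(
            np.asarray(x, dtype=float), self.tr_seconds, self.low_hz, self.high_hz,
            self.order,
        )
        if self.zscore:
            out = _zscore_array(out)
        return out

    def transform(self, X):
        if isinstance(X, list):
            return [self._one(x) for x in X]
        return self._one(X)
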