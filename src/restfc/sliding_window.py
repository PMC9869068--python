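"""Sliding-window FC, across-window variability, and window-length assessment.

The default analysis window is 30 timepoints (90 s at TR = 3 s) with step 1
(maximally overlapping windows); the window-length assessment sweeps window
sizes from 5 timepoints to the full record to expose the
sensitivity/robustness trade-off: short windows inflate across-window SD,
long windows converge to the static FC (exactly so at w = T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import _pearson_matrix, pearson_fc
from .containers import RoiTimeSeriesMatrix, SymmetricEdgeMatrix

__all__ = [
    "WindowSpec",
    "make_windows",
    "windowed_fc",
    "fc_variability",
    "window_size_assessment",
    "SlidingWindowVariability",
]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open index windows [s, s + length) over a T-point record."""

    length_tp: int
    step_tp: int
    starts: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def make_windows(n_timepoints: int, length_tp: int, step_tp: int = 1) -> WindowSpec:
    """Enumerate window start indices; trailing partial windows are dropped."""
    if length_tp < 2:
        raise ValueError(f"window length must be >= 2 timepoints, got {length_tp}")
    if length_tp > n_timepoints:
        raise ValueError(
            f"window length {length_tp} exceeds record length {n_timepoints}"
        )
    if step_tp < 1:
        raise ValueError(f"step must be >= 1, got {step_tp}")
    starts = tuple(range(0, n_timepoints - length_tp + 1, step_tp))
    return WindowSpec(length_tp, step_tp, starts)


def windowed_fc(ts: RoiTimeSeriesMatrix, spec: WindowSpec) -> list[SymmetricEdgeMatrix]:
    """Static FC computed independently inside each window, in window order."""
    out = []
    for s in spec.starts:
        chunk = ts.values[s : s + spec.length_tp]
        if (chunk.std(axis=0, ddof=1) == 0).any():
            j = int(np.nonzero(chunk.std(axis=0, ddof=1) == 0)[0][0])
            raise ValueError(
                f"ROI {ts.roi_labels[j]!r} is constant inside window starting "
                f"at timepoint {s}"
            )
        out.append(
            SymmetricEdgeMatrix(
                ts.roi_labels, _pearson_matrix(chunk), "pearson_r", ts.subject_id
            )
        )
    return out


def fc_variability(stack: list[SymmetricEdgeMatrix]) -> SymmetricEdgeMatrix:
    """Entrywise sample SD of FC across windows (the dFC variability map)."""
    if len(stack) < 2:
        raise ValueError(f"need >= 2 windows for across-window SD, got {len(stack)}")
    labels = stack[0].roi_labels
    cube = np.stack([m.values for m in stack])
    values = cube.std(axis=0, ddof=1)
    # entries identical across all windows have exactly zero spread; the
    # floating mean subtraction otherwise leaves ~1e-17 residue
    values[(cube == cube[0]).all(axis=0)] = 0.0
    np.fill_diagonal(values, 0.0)
    values[values < 0] = 0.0
    return SymmetricEdgeMatrix(labels, values, "sd_across_windows", stack[0].subject_id)


def window_size_assessment(
    ts: RoiTimeSeriesMatrix,
    w_min: int = 5,
    w_max: int | None = None,
    increment: int = 1,
    step_tp: int = 1,
) -> pd.DataFrame:
    """Mean FC and mean across-window SD as functions of window length.

    For each window length w the record is cut into maximally overlapping
    windows; ``mean_fc`` averages the upper-triangle FC over all edges and
    windows, ``mean_sd`` averages the across-window SD over edges (0 when a
    length admits a single window).  ``diff`` columns subtract the static
    full-record values, so both difference curves are exactly 0 at w = T.
    """
    t = ts.n_timepoints
    if w_max is None:
        w_max = t
    if not 2 <= w_min <= w_max <= t:
        raise ValueError(f"need 2 <= w_min <= w_max <= T, got ({w_min}, {w_max}, T={t})")
    static = pearson_fc(ts)
    static_mean = float(static.upper_triangle().mean())
    iu = np.triu_indices(ts.n_rois, k=1)
    rows = []
    for w in range(w_min, w_max + 1, increment):
        spec = make_windows(t, w, step_tp)
        edges = np.stack(
            [_pearson_matrix(ts.values[s : s + w])[iu] for s in spec.starts]
        )
        mean_fc = float(edges.mean())
        mean_sd = float(edges.std(axis=0, ddof=1).mean()) if spec.n_windows > 1 else 0.0
        rows.append(
            {
                "window_tp": w,
                "n_windows": spec.n_windows,
                "mean_fc": mean_fc,
                "mean_sd": mean_sd,
                "diff_fc_from_static": mean_fc - static_mean,
                "diff_sd_from_zero": mean_sd - 0.0,
            }
        )
    return pd.DataFrame(rows)


class SlidingWindowVariability(TransformerMixin, BaseEstimator):
    """Sklearn transformer: T x N series -> per-edge across-window FC SD.

    ``transform`` maps a list of T x N arrays (or one array) to an
    ``(n_subjects, n_edges)`` matrix of upper-triangle SD-across-windows
    values (or full N x N maps with ``vectorize=False``).
    """

    def __init__(self, window_tp: int = 30, step_tp: int = 1, vectorize: bool = True):
        self.window_tp = window_tp
        self.step_tp = step_tp
        self.vectorize = vectorize

    def fit(self, X, y=None):
        first = np.asarray(X[0] if isinstance(X, (list, tuple)) else X)
        self.n_features_in_ = first.shape[-1]
        return self

    def _one(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        spec = make_windows(x.shape[0], self.window_tp, self.step_tp)
        if spec.n_windows < 2:
            raise ValueError("window/step leave fewer than 2 windows")
        stack = np.stack([_pearson_matrix(x[s : s + spec.length_tp]) for s in spec.starts])
        sd = stack.std(axis=0, ddof=1)
        np.fill_diagonal(sd, 0.0)
        if self.vectorize:
            return sd[np.triu_indices(sd.shape[0], k=1)]
        return sd

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return np.stack([self._one(x) for x in X])
        return self._one(X)
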