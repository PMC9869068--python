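"""Static functional connectivity: Pearson FC matrices, group aggregation,
global mean FC, and scaled-MAD outlier screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CohortManifest, RoiTimeSeriesMatrix, SymmetricEdgeMatrix

__all__ = [
    "pearson_fc",
    "global_mean_fc",
    "global_mean_edge_value",
    "group_mean_fc",
    "mad_outliers",
    "OutlierMask",
    "MAD_SCALE",
    "PearsonConnectivity",
]

logger = logging.getLogger(__name__)

#: Normal-consistency constant making the scaled MAD estimate the SD
#: of Gaussian data.
MAD_SCALE = 1.4826


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"column {j} is constant; Pearson correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def pearson_fc(ts: RoiTimeSeriesMatrix) -> SymmetricEdgeMatrix:
    """Pairwise Pearson correlation over the entire time series (static FC)."""
    return SymmetricEdgeMatrix(
        ts.roi_labels, _pearson_matrix(ts.values), "pearson_r", ts.subject_id
    )


def global_mean_fc(matrix: SymmetricEdgeMatrix) -> float:
    """Mean FC over the strict upper triangle (diagonal excluded)."""
    if matrix.metric_kind != "pearson_r":
        raise ValueError(f"expected a pearson_r matrix, got {matrix.metric_kind!r}")
    return float(matrix.upper_triangle().mean())


def global_mean_edge_value(matrix: SymmetricEdgeMatrix) -> float:
    """Strict-upper-triangle mean for any edge metric (SD, co-activation)."""
    return float(matrix.upper_triangle().mean())


def group_mean_fc(
    matrices_by_group: Mapping[str, Sequence[SymmetricEdgeMatrix]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Entrywise mean and sample SD of edge matrices per group.

    Returns ``{group: (mean_matrix, sd_matrix)}``; every group needs at least
    two subjects for a sample SD.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group, mats in matrices_by_group.items():
        if len(mats) < 2:
            raise ValueError(
                f"group {group!r} has {len(mats)} subject(s); need >= 2"
            )
        labels = mats[0].roi_labels
        for m in mats[1:]:
            if m.roi_labels != labels:
                raise ValueError(f"group {group!r}: inconsistent ROI labels")
        stack = np.stack([m.values for m in mats])
        out[group] = (stack.mean(axis=0), stack.std(axis=0, ddof=1))
    return out


@dataclass(frozen=True)
class OutlierMask:
    """Subjects excluded at one edge within one group by the MAD screen."""

    edge: tuple[int, int]
    group: str
    excluded_subject_ids: frozenset[str]


def mad_outliers(
    values: Sequence[float],
    subject_ids: Sequence[str] | None = None,
    n_mads: float = 3.0,
    edge: tuple[int, int] = (-1, -1),
    group: str = "",
) -> OutlierMask:
    """Flag values more than ``n_mads`` scaled MADs from the median.

    The scaled MAD is ``1.4826 * median(|x - median|)``, the usual robust SD
    estimate.  When the MAD degenerates to 0 (over half the values tied at
    the median), any value different from the median is flagged and a warning
    is logged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 values for a MAD screen, got {x.size}")
    if subject_ids is None:
        subject_ids = [str(i) for i in range(x.size)]
    if len(subject_ids) != x.size:
        raise ValueError("subject_ids and values have different lengths")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.warning(
            "degenerate MAD = 0 (group %s, edge %s): flagging every value "
            "different from the median", group or "?", edge,
        )
        flagged = x != med
    else:
        flagged = np.abs(x - med) > n_mads * MAD_SCALE * mad
    excluded = frozenset(s for s, f in zip(subject_ids, flagged) if f)
    return OutlierMask(edge=tuple(edge), group=group, excluded_subject_ids=excluded)


class PearsonConnectivity(TransformerMixin, BaseEstimator):
    """Sklearn transformer: T x N time series -> vectorized static FC.

    ``transform`` maps a list of T x N arrays (or a single one) to an
    ``(n_subjects, n_edges)`` array of strict-upper-triangle Pearson
    correlations, ready for edge-wise model selection or classification.
    Set ``vectorize=False`` to get full N x N matrices instead.
    """

    def __init__(self, vectorize: bool = True):
        self.vectorize = vectorize

    def fit(self, X, y=None):
        first = np.asarray(X[0] if isinstance(X, (list, tuple)) else X)
        self.n_features_in_ = first.shape[-1]
        return self

    def _one(self, x: np.ndarray) -> np.ndarray:
        corr = _pearson_matrix(np.asarray(x, dtype=float))
        if self.vectorize:
            return corr[np.triu_indices(corr.shape[0], k=1)]
        return corr

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return np.stack([self._one(x) for x in X])
        return self._one(X)
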