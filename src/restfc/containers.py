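"""Labelled in-memory containers shared by every analysis stage.

Edge indexing is positional and global: entry ``(i, j)`` of any edge-level
matrix always refers to ``roi_labels[i]`` and ``roi_labels[j]`` in the column
order of the subject time-series files. Column order is therefore significant
and validated across a cohort before any group statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeriesMatrix",
    "CohortManifest",
    "ManifestEntry",
    "SymmetricEdgeMatrix",
    "EventRaster",
    "BinaryAdjacency",
    "GraphMetricsRecord",
    "DEFAULT_GROUP_ORDER",
]

#: Canonical clinical-group ordering used throughout: healthy controls,
#: early MCI, late MCI, Alzheimer's disease.
DEFAULT_GROUP_ORDER = ("HC", "EMCI", "LMCI", "AD")

#: Metric kinds an edge-level matrix may hold, with diagonal conventions:
#: pearson_r -> diagonal 1; sd_across_windows -> diagonal 0;
#: coactivation_count -> diagonal = per-ROI event totals.
EDGE_METRIC_KINDS = ("pearson_r", "sd_across_windows", "coactivation_count")


def _check_labels(roi_labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(str(x) for x in roi_labels)
    if len(labels) < 2:
        raise ValueError(f"need at least 2 ROI labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate ROI labels: {dupes}")
    return labels


@dataclass(frozen=True)
class RoiTimeSeriesMatrix:
    """One subject's T x N BOLD matrix (rows = timepoints, columns = ROIs)."""

    subject_id: str
    roi_labels: tuple[str, ...]
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_labels", _check_labels(self.roi_labels))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        t, n = values.shape
        if t < 2:
            raise ValueError(f"need at least 2 timepoints, got {t}")
        if n != len(self.roi_labels):
            raise ValueError(
                f"{n} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at timepoint {bad[0]}, "
                f"ROI {self.roi_labels[bad[1]]!r}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds

    def with_values(self, values: np.ndarray) -> "RoiTimeSeriesMatrix":
        """Copy of this container with replaced data, same metadata."""
        return RoiTimeSeriesMatrix(
            self.subject_id, self.roi_labels, values, self.tr_seconds
        )


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    group: str
    path: str


@dataclass(frozen=True)
class CohortManifest:
    """Subject roster: who belongs to which group and where their data live."""

    entries: tuple[ManifestEntry, ...]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        ids = [e.subject_id for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate subject ids in manifest: {dupes}")
        for e in entries:
            if not e.group:
                raise ValueError(f"subject {e.subject_id!r} has an empty group")
        seen = {e.group for e in entries}
        order = tuple(self.group_order)
        missing = seen - set(order)
        if missing:
            raise ValueError(f"groups {sorted(missing)} not in group_order {order}")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "group_order", order)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(e.subject_id for e in self.entries)

    @property
    def groups(self) -> tuple[str, ...]:
        """Groups actually present, in group_order."""
        present = {e.group for e in self.entries}
        return tuple(g for g in self.group_order if g in present)

    def subjects_in(self, group: str) -> tuple[str, ...]:
        return tuple(e.subject_id for e in self.entries if e.group == group)

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.subjects_in(g)) for g in self.groups}

    def require_min_group_size(self, n: int = 2) -> None:
        small = {g: k for g, k in self.group_sizes().items() if k < n}
        if small:
            raise ValueError(
                f"groups with fewer than {n} subjects: {small}; "
                "statistics need at least that many per group"
            )


@dataclass(frozen=True)
class SymmetricEdgeMatrix:
    """N x N symmetric matrix of one edge-level metric.

    ``metric_kind`` fixes the diagonal convention (see EDGE_METRIC_KINDS).
    """

    roi_labels: tuple[str, ...]
    values: np.ndarray
    metric_kind: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_labels", _check_labels(self.roi_labels))
        values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if values.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {values.shape}")
        if self.metric_kind not in EDGE_METRIC_KINDS:
            raise ValueError(
                f"unknown metric_kind {self.metric_kind!r}; "
                f"expected one of {EDGE_METRIC_KINDS}"
            )
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if self.metric_kind == "pearson_r":
            if values.min() < -1 - 1e-10 or values.max() > 1 + 1e-10:
                raise ValueError("pearson_r entries must lie in [-1, 1]")
            if not np.allclose(np.diag(values), 1.0, atol=1e-10):
                raise ValueError("pearson_r diagonal must be 1")
        elif self.metric_kind == "sd_across_windows":
            if values.min() < -1e-12:
                raise ValueError("sd_across_windows entries must be >= 0")
            if not np.allclose(np.diag(values), 0.0, atol=1e-10):
                raise ValueError("sd_across_windows diagonal must be 0")
        elif self.metric_kind == "coactivation_count":
            if values.min() < 0:
                raise ValueError("coactivation counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("coactivation counts must be integers")
        object.__setattr__(self, "values", values)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries in row-major (i < j) order."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class EventRaster:
    """T x N binary raster of suprathreshold BOLD events on z-scored series."""

    roi_labels: tuple[str, ...]
    events: np.ndarray
    threshold_sigma: float = 1.0
    mode: str = "point"

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_labels", _check_labels(self.roi_labels))
        events = np.asarray(self.events)
        if events.ndim != 2 or events.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"events must be T x {len(self.roi_labels)}, got {events.shape}"
            )
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event raster entries must be 0 or 1")
        if self.mode not in ("point", "upcrossing"):
            raise ValueError(f"mode must be 'point' or 'upcrossing', got {self.mode!r}")
        object.__setattr__(self, "events", events.astype(np.int8))

    @property
    def n_timepoints(self) -> int:
        return self.events.shape[0]

    def event_counts(self) -> np.ndarray:
        """Per-ROI event totals."""
        return self.events.sum(axis=0).astype(int)


@dataclass(frozen=True)
class BinaryAdjacency:
    """Undirected, unweighted graph from thresholding an FC matrix."""

    roi_labels: tuple[str, ...]
    adjacency: np.ndarray
    threshold_r: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_labels", _check_labels(self.roi_labels))
        adj = np.asarray(self.adjacency)
        n = len(self.roi_labels)
        if adj.shape != (n, n):
            raise ValueError(f"expected {(n, n)} adjacency, got {adj.shape}")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(adj).any():
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return len(self.roi_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class GraphMetricsRecord:
    """Per-subject scalar graph metrics at one binarization threshold."""

    subject_id: str
    threshold_r: float
    char_path_length: float
    mean_clustering: float
    mean_degree: float
    frac_disconnected_pairs: float
    scale_free_r2: float = field(default=float("nan"))
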