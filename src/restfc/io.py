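"""Plain-text readers/writers for every on-disk artifact, plus cohort checks.

File dialects (all inspectable with a pager):

* time series — TSV, one header row of ROI labels, T numeric rows.
  The repetition time is *not* stored in the file; it comes from config or a
  CLI flag, keeping the files plain matrices.
* manifest — CSV with columns ``subject_id,group,path``.
* symmetric edge matrices — TSV with a leading label column and a label
  header; stored full (both triangles) and symmetry-checked on read.
* edge result tables — TSV in long format (one row per edge per post-hoc
  pair), written/read through pandas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_GROUP_ORDER,
    CohortManifest,
    ManifestEntry,
    RoiTimeSeriesMatrix,
    SymmetricEdgeMatrix,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "read_edge_matrix",
    "write_edge_matrix",
    "read_result_table",
    "write_result_table",
    "load_cohort",
    "validate_cohort",
    "CohortValidationReport",
]


def read_timeseries(
    path: str | os.PathLike, subject_id: str | None = None, tr_seconds: float = 3.0
) -> RoiTimeSeriesMatrix:
    """Read a TSV time-series file (header = ROI labels, rows = timepoints).

    ``tr_seconds`` is supplied by the caller (config/CLI), not the file.
    """
    path = os.fspath(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} cells, "
                    f"expected {len(labels)}"
                )
            row = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, "
                        f"ROI {labels[j]!r}"
                    ) from None
            rows.append(row)
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    values = np.asarray(rows, dtype=float)
    if values.size and not np.isfinite(values).all():
        t, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at timepoint {t}, ROI {labels[j]!r}"
        )
    return RoiTimeSeriesMatrix(subject_id, tuple(labels), values, tr_seconds)


def write_timeseries(ts: RoiTimeSeriesMatrix, path: str | os.PathLike) -> None:
    """Write a time-series matrix as TSV with 17 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(ts.roi_labels) + "\n")
        for row in ts.values:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def read_manifest(
    path: str | os.PathLike, group_order: tuple[str, ...] | None = None
) -> CohortManifest:
    """Read a CSV manifest (subject_id, group, path).

    Groups are ordered as first seen unless ``group_order`` is given; if the
    observed groups are exactly the canonical four clinical groups, the
    canonical HC < EMCI < LMCI < AD ordering is used.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: manifest must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries = tuple(
        ManifestEntry(r.subject_id, r.group, r.path) for r in df.itertuples()
    )
    if group_order is None:
        seen: list[str] = []
        for e in entries:
            if e.group not in seen:
                seen.append(e.group)
        if set(seen) == set(DEFAULT_GROUP_ORDER):
            group_order = DEFAULT_GROUP_ORDER
        else:
            group_order = tuple(seen)
    return CohortManifest(entries, group_order)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(e.subject_id, e.group, e.path) for e in manifest.entries],
        columns=["subject_id", "group", "path"],
    )
    df.to_csv(path, index=False)


def read_edge_matrix(path: str | os.PathLike, metric_kind: str) -> SymmetricEdgeMatrix:
    """Read a labelled full N x N matrix TSV; symmetry is re-checked."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return SymmetricEdgeMatrix(labels, df.to_numpy(dtype=float), metric_kind)


def write_edge_matrix(mat: SymmetricEdgeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(mat.values, index=mat.roi_labels, columns=mat.roi_labels)
    if mat.metric_kind == "coactivation_count":
        df = df.astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.17g")


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_result_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_cohort(
    manifest: CohortManifest,
    base_dir: str | os.PathLike | None = None,
    tr_seconds: float = 3.0,
) -> dict[str, RoiTimeSeriesMatrix]:
    """Load every subject in the manifest; missing files name the subject."""
    out: dict[str, RoiTimeSeriesMatrix] = {}
    for e in manifest.entries:
        path = e.path
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(os.fspath(base_dir), path)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"subject {e.subject_id!r}: time-series file {path!r} is "
                "missing; the subject must be removed from the manifest "
                "before analysis"
            )
        out[e.subject_id] = read_timeseries(path, e.subject_id, tr_seconds)
    return out


@dataclass(frozen=True)
class CohortValidationReport:
    """Outcome of cross-subject consistency checks; empty means clean."""

    problems: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.problems

    def raise_if_failed(self) -> None:
        if self.problems:
            raise ValueError(
                "cohort validation failed:\n" + "\n".join(self.problems)
            )


def validate_cohort(
    manifest: CohortManifest, matrices: dict[str, RoiTimeSeriesMatrix]
) -> CohortValidationReport:
    """Check that all subjects share ROI labels/order, T and TR.

    Column order is significant — edge (i, j) indexes roi_labels positionally
    in every downstream matrix — so a permuted ROI header is an error, not a
    reorderable difference.
    """
    problems: list[str] = []
    missing = [s for s in manifest.subject_ids if s not in matrices]
    problems += [f"subject {s!r}: no loaded time series" for s in missing]
    loaded = [s for s in manifest.subject_ids if s in matrices]
    if not loaded:
        problems.append("no subjects loaded")
        return CohortValidationReport(tuple(problems))
    ref = matrices[loaded[0]]
    for s in loaded[1:]:
        m = matrices[s]
        if m.roi_labels != ref.roi_labels:
            if set(m.roi_labels) == set(ref.roi_labels):
                problems.append(
                    f"subject {s!r}: ROI columns are permuted relative to "
                    f"{ref.subject_id!r} (order is significant)"
                )
            else:
                problems.append(
                    f"subject {s!r}: ROI label set differs from "
                    f"{ref.subject_id!r}"
                )
        if m.n_timepoints != ref.n_timepoints:
            problems.append(
                f"subject {s!r}: {m.n_timepoints} timepoints, expected "
                f"{ref.n_timepoints}"
            )
        if m.tr_seconds != ref.tr_seconds:
            problems.append(
                f"subject {s!r}: TR {m.tr_seconds} s, expected {ref.tr_seconds} s"
            )
    return CohortValidationReport(tuple(problems))
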