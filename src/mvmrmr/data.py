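"""Labeled single- and multi-view data containers, delimited-table I/O, and
the standard multi-omics preprocessing filters.

A *view* is one data source (one omics modality) as a samples x features
matrix with named columns. A :class:`MultiViewDataset` aligns several views
over the same samples and carries one shared binary label vector, e.g.
short- vs long-term survival.

Preprocessing mirrors the common multi-omics recipe: drop features with any
missing value, rescale to the unit interval, then remove low-variance
features. Missing values never survive :func:`drop_missing_features`; all
downstream stages assume complete matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "View",
    "MultiViewDataset",
    "SelectionResult",
    "read_view",
    "read_labels",
    "align_views",
    "drop_missing_features",
    "rescale_unit_interval",
    "variance_filter",
    "label_survival",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class View:
    """One labeled feature matrix: ``m`` samples by ``n`` named features.

    Parameters
    ----------
    name : str
        Identifier of the data source (e.g. ``"cna"``, ``"rnaseq"``).
    matrix : ndarray of shape (m, n)
        Real-valued feature matrix; NaN marks a missing entry.
    feature_names : tuple of str
        Unique column names, one per feature.
    sample_ids : tuple of str, optional
        Unique row identifiers; required for alignment across views.
    """

    name: str
    matrix: np.ndarray
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValidationError(f"view {self.name!r}: matrix must be 2-D")
        if matrix.shape[0] == 0:
            raise ValidationError(f"view {self.name!r}: needs at least one sample")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if len(self.feature_names) != matrix.shape[1]:
            raise ValidationError(
                f"view {self.name!r}: {len(self.feature_names)} feature names "
                f"for {matrix.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError(f"view {self.name!r}: duplicate feature names")
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            if len(ids) != matrix.shape[0]:
                raise ValidationError(
                    f"view {self.name!r}: {len(ids)} sample ids for "
                    f"{matrix.shape[0]} rows"
                )
            if len(set(ids)) != len(ids):
                raise ValidationError(f"view {self.name!r}: duplicate sample ids")
            object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_features(self, indices: Sequence[int]) -> "View":
        """Return a new view restricted to the given feature columns."""
        idx = list(indices)
        return View(
            name=self.name,
            matrix=self.matrix[:, idx],
            feature_names=tuple(self.feature_names[i] for i in idx),
            sample_ids=self.sample_ids,
        )

    def select_samples(self, indices: Sequence[int]) -> "View":
        """Return a new view restricted to the given sample rows."""
        idx = list(indices)
        return View(
            name=self.name,
            matrix=self.matrix[idx, :],
            feature_names=self.feature_names,
            sample_ids=tuple(self.sample_ids[i] for i in idx)
            if self.sample_ids is not None
            else None,
        )


@dataclass(frozen=True)
class MultiViewDataset:
    """An aligned collection of views sharing samples and binary labels."""

    views: tuple[View, ...]
    labels: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        views = tuple(self.views)
        if len(views) < 1:
            raise ValidationError("a multi-view dataset needs at least one view")
        object.__setattr__(self, "views", views)
        y = np.asarray(self.labels)
        if y.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")
        y = y.astype(int)
        object.__setattr__(self, "labels", y)
        m = views[0].n_samples
        for view in views:
            if view.n_samples != m:
                raise ValidationError(
                    f"view {view.name!r} has {view.n_samples} samples, expected {m}"
                )
        if y.shape[0] != m:
            raise ValidationError(f"{y.shape[0]} labels for {m} samples")
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            if len(ids) != m or len(set(ids)) != m:
                raise ValidationError("sample_ids must be unique, one per sample")
            object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.views[0].n_samples

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_features_total(self) -> int:
        return sum(v.n_features for v in self.views)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("labels must contain both classes")

    def select_samples(self, indices: Sequence[int]) -> "MultiViewDataset":
        idx = list(indices)
        return MultiViewDataset(
            views=tuple(v.select_samples(idx) for v in self.views),
            labels=self.labels[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx)
            if self.sample_ids is not None
            else None,
        )

    def concatenated(self, sep: str = "::") -> View:
        """Single view holding all columns, names prefixed by view name.

        Prefixing guarantees uniqueness: e.g. a copy-number and an
        expression view may both carry a column for the same gene symbol.
        """
        matrix = np.hstack([v.matrix for v in self.views])
        names = tuple(
            f"{v.name}{sep}{f}" for v in self.views for f in v.feature_names
        )
        return View(
            name="concatenated",
            matrix=matrix,
            feature_names=names,
            sample_ids=self.sample_ids,
        )


@dataclass(frozen=True)
class SelectionResult:
    """Per-view selected feature indices plus the global selection order.

    ``selection_order`` is the ordered list of ``(view_index, feature_index)``
    pairs in the order the greedy procedure picked them;
    ``per_view_indices`` is exactly its partition by view.
    """

    per_view_indices: tuple[tuple[int, ...], ...]
    selection_order: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        per_view = tuple(tuple(s) for s in self.per_view_indices)
        order = tuple((int(v), int(j)) for v, j in self.selection_order)
        object.__setattr__(self, "per_view_indices", per_view)
        object.__setattr__(self, "selection_order", order)
        if len(set(order)) != len(order):
            raise ValidationError("a feature appears twice in the selection order")
        total = sum(len(s) for s in per_view)
        if total != len(order):
            raise ValidationError("per-view counts do not match the global order")
        rebuilt = [sorted(j for v, j in order if v == i) for i in range(len(per_view))]
        if [sorted(s) for s in per_view] != rebuilt:
            raise ValidationError(
                "per_view_indices is not the partition of selection_order by view"
            )

    @property
    def k(self) -> int:
        return len(self.selection_order)

    @classmethod
    def from_order(
        cls, order: Sequence[tuple[int, int]], n_views: int
    ) -> "SelectionResult":
        per_view = [[] for _ in range(n_views)]
        for v, j in order:
            per_view[v].append(j)
        return cls(
            per_view_indices=tuple(tuple(s) for s in per_view),
            selection_order=tuple(order),
        )

    def to_named(self, mvd: MultiViewDataset) -> dict[str, list[str]]:
        """Serialize as ``{view_name: [feature_name, ...]}`` (JSON-ready)."""
        return {
            view.name: [view.feature_names[j] for j in idx]
            for view, idx in zip(mvd.views, self.per_view_indices)
        }

    def save_json(self, path: str | Path, mvd: MultiViewDataset) -> None:
        doc = {
            "per_view": self.to_named(mvd),
            "selection_order": [
                {"view": mvd.views[v].name, "feature": mvd.views[v].feature_names[j]}
                for v, j in self.selection_order
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> np.ndarray:
    """Read a single-column binary label file (no header required)."""
    raw = pd.read_csv(path, header=None).squeeze("columns")
    if isinstance(raw, pd.DataFrame):
        raise ValidationError(f"label file {path} must have one column")
    values = pd.to_numeric(raw, errors="coerce")
    # Tolerate a header cell by dropping a leading non-numeric entry.
    if np.isnan(values.iloc[0]) and len(values) > 1:
        values = values.iloc[1:]
    y = values.to_numpy()
    if np.isnan(y).any():
        raise ValidationError(f"label file {path} contains non-numeric entries")
    if not np.isin(y, (0, 1)).all():
        bad = sorted(set(y[~np.isin(y, (0, 1))]))
        raise ValidationError(f"labels must be 0/1; found {bad}")
    return y.astype(int)


def read_view(
    path: str | Path,
    delimiter: str = ",",
    labels: str | Path | None = None,
    name: str | None = None,
    index_col: int | None = 0,
) -> tuple[View, np.ndarray | None]:
    """Read a delimited feature table (samples x features, header row).

    Parameters
    ----------
    path : path
        Delimited text file; first row holds feature names, first column
        (by default) holds sample ids. Pass ``index_col=None`` for tables
        without an id column.
    delimiter : str
        Field separator, ``","`` for CSV and ``"\\t"`` for TSV.
    labels : path or str, optional
        Either a path to a single-column 0/1 label file (one value per
        sample) or the name of a label column inside the table.
    name : str, optional
        View name; defaults to the file stem.

    Returns
    -------
    (View, labels or None)
        Non-numeric cells become NaN missing markers; the caller decides
        how to treat them (normally :func:`drop_missing_features`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, header=0, index_col=index_col)
    if frame.shape[1] == 0:
        raise ValidationError(f"{path}: no feature columns found")

    y: np.ndarray | None = None
    if labels is not None:
        label_path = Path(str(labels))
        if str(labels) in frame.columns:
            col = pd.to_numeric(frame[str(labels)], errors="coerce").to_numpy()
            if np.isnan(col).any() or not np.isin(col, (0, 1)).all():
                raise ValidationError(f"label column {labels!r} is not binary 0/1")
            y = col.astype(int)
            frame = frame.drop(columns=[str(labels)])
        elif label_path.exists():
            y = read_labels(label_path)
            if len(y) != frame.shape[0]:
                raise ValidationError(
                    f"{len(y)} labels for {frame.shape[0]} samples in {path}"
                )
        else:
            raise FileNotFoundError(f"label locator {labels!r} is neither a column nor a file")

    matrix = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    sample_ids = (
        tuple(str(s) for s in frame.index) if index_col is not None else None
    )
    view = View(
        name=name if name is not None else path.stem,
        matrix=matrix,
        feature_names=tuple(str(c) for c in frame.columns),
        sample_ids=sample_ids,
    )
    return view, y


def write_view(view: View, path: str | Path, delimiter: str = ",") -> None:
    """Write a view back to a delimited table (inverse of :func:`read_view`)."""
    frame = pd.DataFrame(
        view.matrix,
        columns=list(view.feature_names),
        index=list(view.sample_ids) if view.sample_ids is not None else None,
    )
    frame.to_csv(path, sep=delimiter, index=view.sample_ids is not None)


# ---------------------------------------------------------------------------
# Alignment and preprocessing
# ---------------------------------------------------------------------------


def align_views(
    views: Sequence[View],
    labels_by_id: dict[str, int] | None = None,
    labels: np.ndarray | None = None,
) -> tuple[MultiViewDataset, dict[str, int]]:
    """Restrict views to their common samples, in one canonical order.

    Only samples present in every view (and, when given, in the label map)
    are retained — the standard intersection step when assembling a
    multi-omics cohort. The canonical order is the lexicographic sort of
    the shared sample ids, for reproducibility.

    Returns the aligned dataset and a ``{view_name: n_dropped}`` report.
    """
    if not views:
        raise ValidationError("no views to align")
    for view in views:
        if view.sample_ids is None:
            raise ValidationError(f"view {view.name!r} carries no sample ids")
    common: set[str] = set(views[0].sample_ids)
    for view in views[1:]:
        common &= set(view.sample_ids)
    if labels_by_id is not None:
        common &= set(labels_by_id)
    if not common:
        raise ValidationError("sample-id intersection across views is empty")
    order = sorted(common)

    aligned = []
    dropped: dict[str, int] = {}
    for view in views:
        pos = {s: i for i, s in enumerate(view.sample_ids)}
        aligned.append(view.select_samples([pos[s] for s in order]))
        dropped[view.name] = view.n_samples - len(order)

    if labels_by_id is not None:
        y = np.array([labels_by_id[s] for s in order])
    elif labels is not None:
        # Positional labels are only meaningful when every view already
        # lists the same samples in the same order.
        first = views[0].sample_ids
        if any(v.sample_ids != first for v in views[1:]):
            raise ValidationError(
                "positional labels require identically ordered sample ids; "
                "pass labels_by_id instead"
            )
        pos = {s: i for i, s in enumerate(first)}
        y = np.asarray(labels)[[pos[s] for s in order]]
    else:
        raise ValidationError("provide labels_by_id or labels")

    mvd = MultiViewDataset(views=tuple(aligned), labels=y, sample_ids=tuple(order))
    return mvd, dropped


def drop_missing_features(view: View) -> View:
    """Remove every feature column containing at least one missing value."""
    keep = ~np.isnan(view.matrix).any(axis=0)
    if not keep.any():
        warnings.warn(
            f"view {view.name!r}: all features contain missing values; "
            "result has zero columns",
            stacklevel=2,
        )
    return view.select_features(np.flatnonzero(keep))


def rescale_unit_interval(view: View, axis: str = "per_feature") -> View:
    """Min-max rescale each feature (or each sample) to [0, 1].

    Constant slices map to all-zeros rather than NaN so a subsequent
    variance filter removes them cleanly.
    """
    if np.isnan(view.matrix).any():
        raise ValidationError("rescaling requires a complete matrix; drop missing features first")
    if axis not in ("per_feature", "per_sample"):
        raise ValidationError("axis must be 'per_feature' or 'per_sample'")
    X = view.matrix
    ax = 0 if axis == "per_feature" else 1
    lo = X.min(axis=ax, keepdims=True)
    hi = X.max(axis=ax, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (X - lo) / np.where(span == 0, 1.0, span), 0.0)
    return View(view.name, scaled, view.feature_names, view.sample_ids)


def variance_filter(view: View, threshold: float = 0.02) -> View:
    """Keep features whose population variance is at least ``threshold``.

    Features with variance strictly below the threshold are removed; a
    feature sitting exactly at the threshold is kept. Variance divides by
    ``m`` (population form), matching the convention of most
    feature-screening implementations.
    """
    if np.isnan(view.matrix).any():
        raise ValidationError("variance filter requires a complete matrix")
    var = view.matrix.var(axis=0)  # ddof=0: population variance
    keep = np.flatnonzero(var >= threshold)
    return view.select_features(keep)


def label_survival(
    times: np.ndarray,
    vital_status: np.ndarray,
    cutoff: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize survival outcomes at a follow-up cutoff (years).

    A sample with survival time at or beyond the cutoff is a long-term
    survivor (label 1). A sample observed for less than the cutoff is a
    short-term survivor (label 0) only when its vital status is 0; a
    censored short-follow-up sample (any other status) cannot be assigned
    either class and is excluded.

    Returns
    -------
    (labels, mask)
        ``labels`` over the retained samples, and a boolean ``mask`` over
        the input marking which samples were retained.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(vital_status)
    if t.shape != s.shape:
        raise ValidationError("times and vital_status must have equal length")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    long_term = t >= cutoff
    short_term = (t < cutoff) & (s == 0)
    mask = long_term | short_term
    labels = long_term[mask].astype(int)
    return labels, mask
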