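"""Two-stage gated feature-selection framework for multi-view data.

Stage I holds one view-specific filter per view, each with an enable gate
E_i: a disabled filter passes *no* data downstream (the view is deleted,
not zero-filled). The pass-through ``AllFilter`` forwards every input
feature; the embedded sparse filter ranks features by the absolute
coefficients of an L1-penalized linear fit. Stage II holds a single filter
that is either single-view — applied to the concatenation of the surviving
views, with feature names prefixed by view to keep them unique — or
multi-view (MRMR-mv), applied to the surviving views jointly.

The pipeline has scikit-learn fit/transform semantics: ``fit`` learns every
enabled filter's feature set F_i from training data; ``transform`` is a
pure, name-keyed column projection onto the fitted selection, so test-time
application never re-learns and tolerates permuted column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import Lasso

from mvmrmr.data import MultiViewDataset, SelectionResult, ValidationError, View
from mvmrmr.mrmr import mrmr_select
from mvmrmr.multiview import mrmr_mv_select

__all__ = [
    "FilterSpec",
    "TwoStagePipeline",
    "embedded_sparse_filter",
    "all_filter",
    "register_stage1_filter",
]

STAGE1_KINDS = ("all_filter", "lasso_like_embedded")
STAGE2_SINGLE_VIEW = ("all_filter", "mrmr")
STAGE2_MULTI_VIEW = ("mrmr_mv", "mrmr_per_view")
CONCAT_SEP = "::"


def all_filter(view: View, y: np.ndarray, **_params) -> list[int]:
    """Pass-through Stage-I filter: forwards every feature unchanged."""
    return list(range(view.n_features))


def embedded_sparse_filter(
    view: View,
    y: np.ndarray,
    strength: float = 1e-4,
    top_n: int | None = None,
) -> list[int]:
    """Rank features by |coefficient| of an L1-penalized linear fit.

    Fits a lasso regression of the 0/1 labels on the view's features at the
    given regularization strength and returns the ``top_n`` feature indices
    ordered by absolute coefficient, largest first (so nonzero coefficients
    always precede zeroed-out ones; within ties the lower index wins).
    Any compliant sparse linear learner satisfies this contract.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("embedded sparse filter needs both classes")
    model = Lasso(alpha=strength, max_iter=5000)
    model.fit(view.matrix, y)
    coef = np.abs(np.asarray(model.coef_))
    ranked = np.lexsort((np.arange(len(coef)), -coef))
    if top_n is None:
        top_n = view.n_features
    return [int(i) for i in ranked[: min(top_n, view.n_features)]]


_STAGE1_REGISTRY: dict[str, Callable] = {
    "all_filter": all_filter,
    "lasso_like_embedded": embedded_sparse_filter,
}


def register_stage1_filter(name: str, fn: Callable) -> None:
    """Register a custom Stage-I filter: ``fn(view, y, **params) -> indices``."""
    _STAGE1_REGISTRY[name] = fn


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter and its gate.

    ``kind`` names a Stage-I filter (``all_filter``, ``lasso_like_embedded``
    or a registered custom name) or a Stage-II filter (``all_filter``,
    ``mrmr``, ``mrmr_per_view`` — single-view kinds — or ``mrmr_mv``);
    ``params`` holds its keyword arguments (k, f, g, P, strength, ...);
    ``enabled`` is the gate E_i (Stage I only).
    """

    kind: str
    params: dict = field(default_factory=dict)
    enabled: bool = True

    def with_params(self, **updates) -> "FilterSpec":
        return replace(self, params={**self.params, **updates})


def _split_even(k: int, n_views: int) -> list[int]:
    """Split a total budget k across views as evenly as possible."""
    base, extra = divmod(k, n_views)
    return [base + (1 if i < extra else 0) for i in range(n_views)]


class TwoStagePipeline:
    """Gated two-stage feature-selection pipeline with fit/transform modes.

    Parameters
    ----------
    stage1 : sequence of FilterSpec
        One spec per view, in view order. Disabled specs delete their view.
    stage2 : FilterSpec
        The final filter; single-view kinds see the concatenation of the
        surviving Stage-I outputs, multi-view kinds see them as views.
    seed : int, optional
        Seed for stochastic Stage-II filters (the MRMR-mv view schedule).
    """

    def __init__(
        self,
        stage1: Sequence[FilterSpec],
        stage2: FilterSpec,
        seed: int | None = None,
    ) -> None:
        self.stage1 = list(stage1)
        self.stage2 = stage2
        self.seed = seed
        self.fitted_state: dict | None = None
        for spec in self.stage1:
            if spec.kind not in _STAGE1_REGISTRY:
                raise ValidationError(f"unknown Stage-I filter kind {spec.kind!r}")
        if stage2.kind not in STAGE2_SINGLE_VIEW + STAGE2_MULTI_VIEW:
            raise ValidationError(f"unknown Stage-II filter kind {stage2.kind!r}")
        if not any(spec.enabled for spec in self.stage1):
            raise ValidationError("all Stage-I filters are disabled")

    # -- training mode ------------------------------------------------------

    def fit(self, mvd: MultiViewDataset) -> "TwoStagePipeline":
        """Learn every enabled filter's feature set from training data."""
        if len(self.stage1) != mvd.n_views:
            raise ValidationError(
                f"{len(self.stage1)} Stage-I specs for {mvd.n_views} views"
            )
        y = mvd.labels

        stage1_named: dict[str, list[str]] = {}
        surviving: list[View] = []
        for spec, view in zip(self.stage1, mvd.views):
            if not spec.enabled:
                continue
            fn = _STAGE1_REGISTRY[spec.kind]
            idx = fn(view, y, **spec.params)
            stage1_named[view.name] = [view.feature_names[i] for i in idx]
            surviving.append(view.select_features(idx))

        reduced = MultiViewDataset(
            views=tuple(surviving), labels=y, sample_ids=mvd.sample_ids
        )
        final = self._fit_stage2(reduced)
        self.fitted_state = {"stage1": stage1_named, "final": final}
        return self

    def _fit_stage2(self, reduced: MultiViewDataset) -> dict[str, list[str]]:
        spec = self.stage2
        params = dict(spec.params)

        if spec.kind == "all_filter":
            return {v.name: list(v.feature_names) for v in reduced.views}

        if spec.kind == "mrmr":
            concat = reduced.concatenated(sep=CONCAT_SEP)
            k = params.pop("k")
            if k > concat.n_features:
                raise ValidationError(
                    f"Stage-II k={k} exceeds {concat.n_features} surviving features"
                )
            result = mrmr_select(concat, reduced.labels, k=k, **params)
            names = [concat.feature_names[j] for _, j in result.selection_order]
            return _unprefix(names, [v.name for v in reduced.views])

        if spec.kind == "mrmr_per_view":
            # SV_S baseline: independent per-view MRMR, budget split evenly.
            k = params.pop("k")
            if k > reduced.n_features_total:
                raise ValidationError(
                    f"Stage-II k={k} exceeds {reduced.n_features_total} surviving features"
                )
            budgets = _split_even(k, reduced.n_views)
            final: dict[str, list[str]] = {}
            for view, k_i in zip(reduced.views, budgets):
                if k_i == 0:
                    continue
                if k_i > view.n_features:
                    raise ValidationError(
                        f"per-view budget {k_i} exceeds view {view.name!r}"
                    )
                res = mrmr_select(view, reduced.labels, k=k_i, **params)
                final[view.name] = [
                    view.feature_names[j] for _, j in res.selection_order
                ]
            return final

        # mrmr_mv
        k = params.pop("k")
        params.setdefault("seed", self.seed)
        result = mrmr_mv_select(reduced, k=k, **params)
        return {
            view.name: [view.feature_names[j] for j in idx]
            for view, idx in zip(reduced.views, result.per_view_indices)
            if idx
        }

    # -- test / operation mode ---------------------------------------------

    def transform(self, mvd: MultiViewDataset) -> MultiViewDataset:
        """Project a dataset onto the fitted selection (no re-learning).

        Projection is keyed by feature name, so test tables may list their
        columns in any order; a missing selected feature is an error.
        """
        if self.fitted_state is None:
            raise ValidationError("pipeline is not fitted; call fit first")
        final = self.fitted_state["final"]
        by_name = {v.name: v for v in mvd.views}
        out: list[View] = []
        for view_name, feature_names in final.items():
            if view_name not in by_name:
                raise ValidationError(f"dataset is missing view {view_name!r}")
            view = by_name[view_name]
            pos = {f: i for i, f in enumerate(view.feature_names)}
            missing = [f for f in feature_names if f not in pos]
            if missing:
                raise ValidationError(
                    f"view {view_name!r} is missing selected features {missing[:5]}"
                )
            out.append(view.select_features([pos[f] for f in feature_names]))
        return MultiViewDataset(
            views=tuple(out), labels=mvd.labels, sample_ids=mvd.sample_ids
        )

    def fit_transform(self, mvd: MultiViewDataset) -> MultiViewDataset:
        return self.fit(mvd).transform(mvd)

    # -- serialization ------------------------------------------------------

    def selection_manifest(self) -> dict:
        if self.fitted_state is None:
            raise ValidationError("pipeline is not fitted")
        return {
            "stage1": self.fitted_state["stage1"],
            "final": self.fitted_state["final"],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.selection_manifest(), indent=2) + "\n")


def _unprefix(names: list[str], view_names: list[str]) -> dict[str, list[str]]:
    """Map view-prefixed concatenated names back to per-view name lists."""
    final: dict[str, list[str]] = {}
    for name in names:
        for view_name in view_names:
            prefix = view_name + CONCAT_SEP
            if name.startswith(prefix):
                final.setdefault(view_name, []).append(name[len(prefix):])
                break
        else:
            raise ValidationError(f"cannot attribute feature {name!r} to a view")
    return final
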