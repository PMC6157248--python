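"""Repeated stratified cross-validation harness and strategy comparison.

Performance of a feature-selection + classifier combination is estimated
with repeated stratified k-fold cross-validation (default 10 repeats of
5-fold): in every fold the *entire* pipeline — Stage-I filters, Stage-II
selection, and the classifier — is fitted on the training folds only and
scored on the held-out fold by AUC. Selecting features outside the fold
loop would leak label information; the harness makes that impossible by
construction, and the suite's tests verify it.

The strategy suite compares the integration strategies on identical fold
splits: per-view single-view models (SV), MRMR on the concatenated views
(SV_C), per-view MRMR with budgets split across views (SV_S), multi-view
MRMR-mv (MV), and an ensemble averaging the predictions of the best SV
model and the MV model. The P-sensitivity sweep evaluates the MV model
over a grid of two-view importance distributions P = (p1, 1-p1) and
summarizes the spread per k as the percent relative range
100 * (max - min) / mean of the recorded AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from mvmrmr.data import MultiViewDataset, ValidationError
from mvmrmr.framework import FilterSpec, TwoStagePipeline

__all__ = [
    "CVProtocol",
    "StrategyResult",
    "make_learner",
    "repeated_cv",
    "ensemble_average",
    "strategy_suite",
    "p_sensitivity",
    "percent_relative_range",
]


@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified k-fold protocol.

    Fold assignment for repeat r is seeded with ``seed + r`` so repeats are
    independent but every strategy evaluated under the same protocol sees
    identical splits (paired comparison).
    """

    n_folds: int = 5
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def splits(
        self, y: np.ndarray
    ) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
        """Yield (repeat, fold, train_idx, test_idx) for every fold."""
        y = np.asarray(y)
        for repeat in range(self.n_repeats):
            if self.stratified:
                splitter = StratifiedKFold(
                    n_splits=self.n_folds, shuffle=True, random_state=self.seed + repeat
                )
            else:
                from sklearn.model_selection import KFold

                splitter = KFold(
                    n_splits=self.n_folds, shuffle=True, random_state=self.seed + repeat
                )
            for fold, (train, test) in enumerate(splitter.split(np.zeros_like(y), y)):
                yield repeat, fold, train, test


@dataclass
class StrategyResult:
    """Fold-level AUCs of one (strategy, k, learner) combination."""

    strategy: str
    aucs: np.ndarray  # shape (n_repeats, n_folds)
    k: int | None = None
    learner: str | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


_LEARNERS: dict[str, Callable] = {
    "random_forest": lambda seed, **kw: RandomForestClassifier(
        n_estimators=kw.pop("n_estimators", 500), random_state=seed, **kw
    ),
    "gradient_boosting": lambda seed, **kw: GradientBoostingClassifier(
        n_estimators=kw.pop("n_estimators", 500), random_state=seed, **kw
    ),
    "logistic_l1": lambda seed, **kw: LogisticRegression(
        l1_ratio=1.0, solver="liblinear", random_state=seed, **kw
    ),
}


def make_learner(name: str, seed: int = 0, **params):
    """Instantiate a shipped classifier by name.

    Defaults mirror common practice for cancer-survival benchmarks: a
    500-tree random forest, 500-round gradient boosting, and L1-regularized
    logistic regression. Any estimator with ``fit`` and ``predict_proba``
    satisfies the learner contract; these are replaceable plumbing.
    """
    try:
        return _LEARNERS[name](seed, **params)
    except KeyError:
        raise ValidationError(
            f"unknown learner {name!r}; known: {sorted(_LEARNERS)}"
        ) from None


def register_learner(name: str, factory: Callable) -> None:
    """Register a custom learner factory ``(seed, **params) -> estimator``."""
    _LEARNERS[name] = factory


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _design_matrix(mvd: MultiViewDataset) -> np.ndarray:
    return np.hstack([v.matrix for v in mvd.views])


def repeated_cv(
    mvd: MultiViewDataset,
    pipeline: TwoStagePipeline,
    learner,
    protocol: CVProtocol | None = None,
    strategy: str = "pipeline",
) -> StrategyResult:
    """Estimate AUC of a selection pipeline + classifier by repeated CV.

    The pipeline and a clone of the learner are fitted on the training
    folds only; the held-out fold is projected through the fitted pipeline
    and scored. Returns all fold AUCs and their mean.
    """
    protocol = protocol or CVProtocol()
    mvd.require_both_classes()
    aucs = np.empty((protocol.n_repeats, protocol.n_folds))
    for repeat, fold, train, test in protocol.splits(mvd.labels):
        train_mvd = mvd.select_samples(train)
        test_mvd = mvd.select_samples(test)
        pipeline.fit(train_mvd)
        Xtr = _design_matrix(pipeline.transform(train_mvd))
        Xte = _design_matrix(pipeline.transform(test_mvd))
        model = clone(learner)
        model.fit(Xtr, train_mvd.labels)
        if len(np.unique(test_mvd.labels)) < 2:
            raise ValidationError(
                "a fold is missing a class; use stratified folds"
            )
        aucs[repeat, fold] = roc_auc_score(test_mvd.labels, _scores(model, Xte))
    return StrategyResult(strategy=strategy, aucs=aucs)


def ensemble_average(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Unweighted elementwise mean of two per-sample score vectors."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValidationError("score vectors must have equal length")
    return (p1 + p2) / 2.0


def _fold_seed(base: int, repeat: int, fold: int) -> int:
    """Deterministic per-fold sub-seed below 2**31."""
    return int(
        np.random.SeedSequence([base, repeat, fold]).generate_state(1)[0] % (2**31)
    )


def _strategy_pipelines(
    mvd: MultiViewDataset,
    k: int,
    f: str,
    g: str,
    P,
    stage1_kind: str,
    stage1_params: dict,
    fold_seed: int,
    strategies: Sequence[str],
    exponent: int,
) -> dict[str, TwoStagePipeline]:
    """Build one unfitted pipeline per requested strategy."""
    v = mvd.n_views

    def stage1(enabled_mask: Sequence[bool]) -> list[FilterSpec]:
        return [
            FilterSpec(stage1_kind, dict(stage1_params), enabled=en)
            for en in enabled_mask
        ]

    pipelines: dict[str, TwoStagePipeline] = {}
    mrmr_params = {"k": k, "f": f, "g": g, "exponent": exponent}
    for i, view in enumerate(mvd.views):
        name = f"SV_{view.name}"
        if name in strategies:
            mask = [j == i for j in range(v)]
            pipelines[name] = TwoStagePipeline(
                stage1(mask), FilterSpec("mrmr", dict(mrmr_params))
            )
    if "SV_C" in strategies:
        pipelines["SV_C"] = TwoStagePipeline(
            stage1([True] * v), FilterSpec("mrmr", dict(mrmr_params))
        )
    if "SV_S" in strategies:
        pipelines["SV_S"] = TwoStagePipeline(
            stage1([True] * v), FilterSpec("mrmr_per_view", dict(mrmr_params))
        )
    if "MV" in strategies or "Ensemble" in strategies:
        pipelines["MV"] = TwoStagePipeline(
            stage1([True] * v),
            FilterSpec("mrmr_mv", {**mrmr_params, "P": P}),
            seed=fold_seed,
        )
    return pipelines


DEFAULT_STRATEGIES = ("SV_per_view", "SV_C", "SV_S", "MV", "Ensemble")


def strategy_suite(
    mvd: MultiViewDataset,
    k_grid: Sequence[int],
    learners: Sequence[str] = ("logistic_l1",),
    protocol: CVProtocol | None = None,
    f: str = "f_stat",
    g: str = "abs_pearson",
    P=None,
    stage1_kind: str = "all_filter",
    stage1_params: dict | None = None,
    strategies: Sequence[str] = DEFAULT_STRATEGIES,
    learner_params: dict | None = None,
    exponent: int = 2,
) -> pd.DataFrame:
    """Compare integration strategies on shared CV splits.

    For every k in ``k_grid`` and every learner, evaluates the requested
    strategies — per-view SV models, SV_C (MRMR on the concatenation),
    SV_S (per-view MRMR, budget split evenly), MV (MRMR-mv) and Ensemble
    (mean of best-SV and MV predicted scores) — under the same repeated
    stratified CV splits, so comparisons are paired.

    Returns a tidy frame with columns
    ``strategy, learner, k, repeat, fold, auc``.
    """
    protocol = protocol or CVProtocol()
    mvd.require_both_classes()
    learner_params = learner_params or {}

    wanted = list(strategies)
    if "SV_per_view" in wanted:
        wanted.remove("SV_per_view")
        wanted = [f"SV_{v.name}" for v in mvd.views] + wanted
    need_ensemble = "Ensemble" in wanted
    fit_names = [s for s in wanted if s != "Ensemble"]
    if need_ensemble and "MV" not in fit_names:
        fit_names.append("MV")
    sv_names = [s for s in fit_names if s.startswith("SV_") and s not in ("SV_C", "SV_S")]
    if need_ensemble and not sv_names:
        raise ValidationError("Ensemble requires at least one per-view SV strategy")

    rows: list[dict] = []
    for k in k_grid:
        for learner_name in learners:
            learner = make_learner(learner_name, seed=protocol.seed, **learner_params)
            fold_scores: dict[str, dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]] = {
                s: {} for s in fit_names
            }
            for repeat, fold, train, test in protocol.splits(mvd.labels):
                train_mvd = mvd.select_samples(train)
                test_mvd = mvd.select_samples(test)
                pipelines = _strategy_pipelines(
                    mvd, k, f, g, P, stage1_kind, stage1_params or {},
                    _fold_seed(protocol.seed, repeat, fold), fit_names, exponent,
                )
                for name in fit_names:
                    pipe = pipelines[name]
                    pipe.fit(train_mvd)
                    Xtr = _design_matrix(pipe.transform(train_mvd))
                    Xte = _design_matrix(pipe.transform(test_mvd))
                    model = clone(learner)
                    model.fit(Xtr, train_mvd.labels)
                    scores = _scores(model, Xte)
                    fold_scores[name][(repeat, fold)] = (test_mvd.labels, scores)
                    if name in wanted:
                        rows.append(
                            {
                                "strategy": name,
                                "learner": learner_name,
                                "k": k,
                                "repeat": repeat,
                                "fold": fold,
                                "auc": roc_auc_score(test_mvd.labels, scores),
                            }
                        )
            if need_ensemble:
                best_sv = max(
                    sv_names,
                    key=lambda s: np.mean(
                        [
                            roc_auc_score(yy, ss)
                            for yy, ss in fold_scores[s].values()
                        ]
                    ),
                )
                for (repeat, fold), (yy, sv_scores) in fold_scores[best_sv].items():
                    _, mv_scores = fold_scores["MV"][(repeat, fold)]
                    rows.append(
                        {
                            "strategy": "Ensemble",
                            "learner": learner_name,
                            "k": k,
                            "repeat": repeat,
                            "fold": fold,
                            "auc": roc_auc_score(
                                yy, ensemble_average(sv_scores, mv_scores)
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC per (strategy, learner, k) from a tidy results frame."""
    return (
        results.groupby(["strategy", "learner", "k"], as_index=False)["auc"]
        .mean()
        .rename(columns={"auc": "mean_auc"})
    )


def percent_relative_range(values: Sequence[float]) -> float:
    """100 * (max - min) / mean — spread of AUCs relative to their level."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("percent_relative_range of an empty sequence")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("percent_relative_range undefined for zero mean")
    return float(100.0 * (values.max() - values.min()) / mean)


def p_sensitivity(
    mvd: MultiViewDataset,
    k_grid: Sequence[int],
    p_grid: Sequence[float] | None = None,
    learner: str = "random_forest",
    protocol: CVProtocol | None = None,
    f: str = "f_stat",
    g: str = "abs_pearson",
    learner_params: dict | None = None,
    exponent: int = 2,
) -> pd.DataFrame:
    """Sensitivity of the MV model to the view-importance distribution P.

    For a two-view dataset, evaluates MRMR-mv at every P = (p1, 1-p1) on
    the grid (default p1 = 0, 0.1, ..., 1) under shared CV splits, and for
    each k reports the percent relative range of the mean AUCs across the
    grid. Returns a frame with columns ``k, p1, mean_auc`` plus an
    attached per-k summary in ``frame.attrs['prr']``.
    """
    if mvd.n_views != 2:
        raise ValidationError("p_sensitivity is defined for exactly two views")
    protocol = protocol or CVProtocol()
    if p_grid is None:
        p_grid = [round(0.1 * i, 1) for i in range(11)]
    rows = []
    for k in k_grid:
        for p1 in p_grid:
            result = strategy_suite(
                mvd,
                k_grid=[k],
                learners=[learner],
                protocol=protocol,
                f=f,
                g=g,
                P=(p1, 1.0 - p1),
                strategies=("MV",),
                learner_params=learner_params,
                exponent=exponent,
            )
            rows.append({"k": k, "p1": p1, "mean_auc": result["auc"].mean()})
    frame = pd.DataFrame(rows)
    frame.attrs["prr"] = {
        int(k): percent_relative_range(sub["mean_auc"])
        for k, sub in frame.groupby("k")
    }
    return frame
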