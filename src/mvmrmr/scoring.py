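"""Relevance and redundancy scoring for MRMR-style selection.

Relevance f(x, y) measures the association between one feature and the
binary labels; redundancy g(x_i, x_j) measures similarity between two
features. The shipped relevance functions are the chi-squared statistic,
the one-way ANOVA F statistic, a deterministic plug-in mutual-information
estimate, and CFM — the equal-weight average of the three after min-max
normalization over a candidate pool. The shipped redundancy function is
the absolute Pearson correlation.

All scorers are deterministic: the MI estimate discretizes each feature
into equal-width bins (default 10, suited to [0,1]-scaled data) and applies
the plug-in formula, so a greedy selection trace is exactly reproducible.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.feature_selection import f_classif as _sk_f_classif
from sklearn.metrics import mutual_info_score as _sk_mutual_info

from mvmrmr.data import ValidationError

__all__ = [
    "abs_pearson",
    "relevance",
    "cfm_relevance",
    "ScoreCache",
    "get_relevance",
    "get_redundancy",
    "register_relevance",
    "register_redundancy",
    "RELEVANCE_NAMES",
]

MI_BINS_DEFAULT = 10


def abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute sample Pearson correlation, the redundancy function.

    Symmetric, in [0, 1], and equal to 1 for any non-constant vector
    against itself. A constant vector carries no signal, so its redundancy
    with anything is defined as 0 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("abs_pearson requires two equal-length vectors")
    if a.size < 2:
        raise ValidationError("abs_pearson requires length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        return 0.0
    return float(min(abs(da @ db) / denom, 1.0))


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("feature and labels must be equal-length vectors")
    if np.isnan(x).any():
        raise ValidationError("feature vector contains missing values")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    return x, y.astype(int)


def chi2_relevance(x: np.ndarray, y: np.ndarray) -> float:
    """One-feature chi-squared statistic of x against the class labels."""
    x, y = _check_xy(x, y)
    if (x < 0).any():
        raise ValidationError("chi2 relevance requires non-negative features")
    stat, _ = _sk_chi2(x.reshape(-1, 1), y)
    value = float(stat[0])
    return 0.0 if np.isnan(value) else value


def f_stat_relevance(x: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F statistic between the two class groups."""
    x, y = _check_xy(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, _ = _sk_f_classif(x.reshape(-1, 1), y)
    value = float(stat[0])
    return 0.0 if np.isnan(value) else value


def mutual_information_relevance(
    x: np.ndarray, y: np.ndarray, n_bins: int = MI_BINS_DEFAULT
) -> float:
    """Plug-in mutual information (nats) after equal-width binning of x.

    The feature range is split into ``n_bins`` equal-width bins and MI is
    computed from the empirical joint distribution of (bin, label). The
    estimate is deterministic given the input, unlike nearest-neighbour
    estimators, so selection traces built on it are reproducible.
    """
    x, y = _check_xy(x, y)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    binned = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    return float(max(_sk_mutual_info(binned, y), 0.0))


def cfm_relevance(
    X: np.ndarray,
    y: np.ndarray,
    n_bins: int = MI_BINS_DEFAULT,
) -> np.ndarray:
    """Combined relevance (CFM): average of chi2, F and MI over a pool.

    The three raw scores live on incommensurable scales (an F statistic can
    be orders of magnitude above an MI in nats), so each component is
    min-max normalized to [0, 1] across the candidate pool before the
    equal-weight average. Because of that normalization CFM is only defined
    relative to a pool of at least two features; this function therefore
    scores the whole pool at once and returns one value per column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("CFM requires a candidate pool of at least two features")
    components = np.empty((3, X.shape[1]))
    for col in range(X.shape[1]):
        components[0, col] = chi2_relevance(X[:, col], y)
        components[1, col] = f_stat_relevance(X[:, col], y)
        components[2, col] = mutual_information_relevance(X[:, col], y, n_bins)
    lo = components.min(axis=1, keepdims=True)
    span = components.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0  # a flat component contributes 0 for every feature
    normalized = (components - lo) / span
    return normalized.mean(axis=0)


RelevanceFn = Callable[[np.ndarray, np.ndarray], float]
RedundancyFn = Callable[[np.ndarray, np.ndarray], float]

_RELEVANCE: dict[str, RelevanceFn] = {
    "chi2": chi2_relevance,
    "f_stat": f_stat_relevance,
    "mutual_information": mutual_information_relevance,
}
_REDUNDANCY: dict[str, RedundancyFn] = {
    "abs_pearson": abs_pearson,
}

RELEVANCE_NAMES = ("chi2", "f_stat", "mutual_information", "cfm")


def register_relevance(name: str, fn: RelevanceFn) -> None:
    """Register a custom relevance function under a configuration name."""
    _RELEVANCE[name] = fn


def register_redundancy(name: str, fn: RedundancyFn) -> None:
    """Register a custom redundancy function under a configuration name."""
    _REDUNDANCY[name] = fn


def get_relevance(name: str) -> RelevanceFn:
    if name == "cfm":
        raise ValidationError(
            "cfm is pool-normalized; score pools with relevance_vector/cfm_relevance"
        )
    try:
        return _RELEVANCE[name]
    except KeyError:
        raise ValidationError(
            f"unknown relevance {name!r}; known: {sorted(_RELEVANCE) + ['cfm']}"
        ) from None


def get_redundancy(name: str) -> RedundancyFn:
    try:
        return _REDUNDANCY[name]
    except KeyError:
        raise ValidationError(
            f"unknown redundancy {name!r}; known: {sorted(_REDUNDANCY)}"
        ) from None


def relevance(f_name: str, x: np.ndarray, y: np.ndarray) -> float:
    """Score one feature against the labels by relevance-function name."""
    return get_relevance(f_name)(x, y)


def relevance_vector(f_name: str, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Relevance of every column of X; the only entry point for ``cfm``."""
    X = np.asarray(X, dtype=float)
    if f_name == "cfm":
        return cfm_relevance(X, y)
    fn = get_relevance(f_name)
    return np.array([fn(X[:, j], y) for j in range(X.shape[1])])


class ScoreCache:
    """Memo of relevance and redundancy values over a fixed dataset.

    Transparent by construction: a hit returns the bit-identical float
    that recomputation would produce, so cached and uncached greedy runs
    select identical features.
    """

    def __init__(self) -> None:
        self._relevance: dict[tuple[int, int], float] = {}
        self._redundancy: dict[tuple[tuple[int, int], tuple[int, int]], float] = {}

    def relevance(
        self,
        key: tuple[int, int],
        fn: RelevanceFn,
        x: np.ndarray,
        y: np.ndarray,
    ) -> float:
        if key not in self._relevance:
            self._relevance[key] = fn(x, y)
        return self._relevance[key]

    def redundancy(
        self,
        key_a: tuple[int, int],
        key_b: tuple[int, int],
        fn: RedundancyFn,
        a: np.ndarray,
        b: np.ndarray,
    ) -> float:
        key = (key_a, key_b) if key_a <= key_b else (key_b, key_a)
        if key not in self._redundancy:
            self._redundancy[key] = fn(a, b)
        return self._redundancy[key]
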