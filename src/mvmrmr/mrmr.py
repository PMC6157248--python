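"""Greedy single-view minimum-redundancy maximum-relevance selection.

The exact MRMR subset problem is combinatorial (O(n^k) subsets), so the
standard heuristic is greedy: seed with the single most relevant feature,
then repeatedly add the candidate j maximizing

    f(x_j, y) - (1/|S|^e) * sum_{l in S} g(x_j, x_l)

where S is the set already selected. The redundancy divisor exponent e
defaults to 2; the classical variant e = 1 (plain mean redundancy) is
available via ``exponent=1``. With e = 2 the penalty shrinks as selection
grows, progressively favouring relevance over redundancy.

Ties at the argmax are broken toward the lowest feature index, making the
trace fully deterministic for deterministic f. Negative scores do not stop
selection: exactly k features are always returned when k candidates exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from mvmrmr.data import SelectionResult, ValidationError, View
from mvmrmr.scoring import (
    abs_pearson,
    get_redundancy,
    get_relevance,
    relevance_vector,
)

__all__ = ["MRMRState", "mrmr_score", "mrmr_select"]


@dataclass
class MRMRState:
    """Snapshot of a greedy MRMR run: ordered picks and remaining pool."""

    selected: list[int]
    candidates: set[int]
    k: int
    exponent: int = 2

    def __post_init__(self) -> None:
        if self.exponent not in (1, 2):
            raise ValidationError("redundancy exponent must be 1 or 2")
        if set(self.selected) & self.candidates:
            raise ValidationError("selected and candidate sets overlap")
        if len(self.selected) > self.k:
            raise ValidationError("more selections than k")


def _as_matrix(data: View | np.ndarray) -> np.ndarray:
    if isinstance(data, View):
        return data.matrix
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D feature matrix or a View")
    return X


def _resolve_g(g) -> Callable[[np.ndarray, np.ndarray], float]:
    return get_redundancy(g) if isinstance(g, str) else g


def _abs_corr_with(X: np.ndarray, col: np.ndarray) -> np.ndarray:
    """|Pearson| of every column of X against one vector, vectorized.

    Zero-variance columns (either side) yield 0, matching
    :func:`mvmrmr.scoring.abs_pearson`.
    """
    Xc = X - X.mean(axis=0)
    c = col - col.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (c @ c))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, np.abs(Xc.T @ c) / np.where(denom == 0, 1, denom), 0.0)
    return np.minimum(r, 1.0)


def mrmr_score(
    j: int,
    state: MRMRState,
    data: View | np.ndarray,
    y: np.ndarray,
    f: str | Callable[[np.ndarray, np.ndarray], float] = "f_stat",
    g: str | Callable[[np.ndarray, np.ndarray], float] = "abs_pearson",
    relevance_value: float | None = None,
) -> float:
    """Score one candidate under the greedy MRMR criterion.

    Returns ``f(x_j, y) - (1/|S|^e) * sum_{l in S} g(x_j, x_l)`` for the
    current state. ``relevance_value`` short-circuits the relevance term
    when it is already known (e.g. from a precomputed pool scoring, which
    is also the only way to score under the pool-normalized ``cfm``).
    """
    X = _as_matrix(data)
    if j in state.selected:
        raise ValidationError(f"candidate {j} is already selected")
    if not state.selected:
        raise ValidationError("mrmr_score requires at least one selected feature")
    if relevance_value is None:
        f_fn = get_relevance(f) if isinstance(f, str) else f
        relevance_value = f_fn(X[:, j], y)
    g_fn = _resolve_g(g)
    penalty = sum(g_fn(X[:, j], X[:, l]) for l in state.selected)
    return float(relevance_value - penalty / len(state.selected) ** state.exponent)


def mrmr_select(
    data: View | np.ndarray,
    y: np.ndarray,
    k: int,
    f: str | Callable[[np.ndarray, np.ndarray], float] = "f_stat",
    g: str | Callable[[np.ndarray, np.ndarray], float] = "abs_pearson",
    exponent: int = 2,
) -> SelectionResult:
    """Select k features greedily under the MRMR criterion.

    Parameters
    ----------
    data : View or ndarray (m, n)
        Feature matrix (complete, numeric).
    y : ndarray (m,)
        Binary labels with both classes present.
    k : int
        Number of features to select, 1 <= k <= n.
    f : relevance name or callable
        ``"chi2"``, ``"f_stat"``, ``"mutual_information"``, ``"cfm"`` or a
        custom ``(x, y) -> float``.
    g : redundancy name or callable
        ``"abs_pearson"`` or a custom ``(a, b) -> float``.
    exponent : {1, 2}
        Redundancy divisor exponent e in 1/|S|^e.

    Returns
    -------
    SelectionResult
        Single-view result: ``selection_order`` is the pick order, with
        view index 0 throughout.
    """
    X = _as_matrix(data)
    y = np.asarray(y)
    n = X.shape[1]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must be in [1, {n}]")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    if exponent not in (1, 2):
        raise ValidationError("redundancy exponent must be 1 or 2")

    if callable(f):
        rel = np.array([f(X[:, j], y) for j in range(n)])
    else:
        rel = relevance_vector(f, X, y)

    order = _greedy_order(X, rel, k, g, exponent)
    return SelectionResult.from_order([(0, j) for j in order], n_views=1)


def _greedy_order(
    X: np.ndarray,
    rel: np.ndarray,
    k: int,
    g,
    exponent: int,
) -> list[int]:
    """Core greedy loop over one pool given precomputed relevance values."""
    n = X.shape[1]
    vector_g = g == "abs_pearson" or g is abs_pearson
    g_fn = None if vector_g else _resolve_g(g)

    selected: list[int] = []
    red_sum = np.zeros(n)
    available = np.ones(n, dtype=bool)

    first = int(np.flatnonzero(rel == rel.max())[0])
    selected.append(first)
    available[first] = False

    while len(selected) < k:
        last = X[:, selected[-1]]
        if vector_g:
            red_sum += _abs_corr_with(X, last)
        else:
            for j in np.flatnonzero(available):
                red_sum[j] += g_fn(X[:, j], last)
        scores = rel - red_sum / len(selected) ** exponent
        scores[~available] = -np.inf
        best = int(np.flatnonzero(scores == scores.max())[0])
        selected.append(best)
        available[best] = False
    return selected
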