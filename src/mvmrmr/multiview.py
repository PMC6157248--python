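"""Multi-view MRMR: greedy selection with view steps allocated by sampling.

The multi-view variant (MRMR-mv) extends greedy MRMR to several feature
matrices (views) over the same samples. A categorical distribution
P = (p_1 ... p_v) encodes the prior importance of each view. The procedure:

1. draw a schedule C of k-1 view indices i.i.d. from P (with replacement);
2. select the single most relevant feature across *all* views — note this
   first pick ignores P entirely, so even P = (1, 0) can open with a
   feature from view 2;
3. for t = 1 ... k-1, restrict candidates to view C[t] and select its
   feature maximizing f(x_j, y) - (1/|S_all|^e) * sum_{l in S_all} g(x_j, x_l),
   where S_all is the union of selections from every view so far.

Penalizing against selections from all views is what lets the method keep
complementary features across views while rejecting cross-view duplicates
(e.g. a copy-number column and an expression column tracking the same
amplified locus).

If a scheduled view runs out of candidates, that step's view is redrawn
from P restricted (and renormalized) to views with candidates remaining,
preserving both the total count k and the spirit of P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from mvmrmr.data import MultiViewDataset, SelectionResult, ValidationError
from mvmrmr.mrmr import _abs_corr_with, _resolve_g
from mvmrmr.scoring import abs_pearson, cfm_relevance, get_relevance, relevance_vector

__all__ = [
    "ViewSamplingDistribution",
    "sample_view_schedule",
    "global_max_relevance",
    "mrmr_mv_select",
]


@dataclass(frozen=True)
class ViewSamplingDistribution:
    """Categorical view-importance distribution P = (p_1 ... p_v)."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.probabilities)
        if len(p) < 1:
            raise ValidationError("P needs at least one view")
        if any(x < 0 for x in p):
            raise ValidationError("P entries must be non-negative")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValidationError(f"P must sum to 1 (got {sum(p)})")
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform(cls, n_views: int) -> "ViewSamplingDistribution":
        return cls(tuple([1.0 / n_views] * n_views))

    @property
    def n_views(self) -> int:
        return len(self.probabilities)


def _as_distribution(P, n_views: int) -> ViewSamplingDistribution:
    if P is None:
        return ViewSamplingDistribution.uniform(n_views)
    if isinstance(P, ViewSamplingDistribution):
        dist = P
    else:
        dist = ViewSamplingDistribution(tuple(P))
    if dist.n_views != n_views:
        raise ValidationError(f"P has {dist.n_views} entries for {n_views} views")
    return dist


def sample_view_schedule(
    P: ViewSamplingDistribution | tuple[float, ...],
    k: int,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Draw the k-1 view indices (0-based) governing steps 2 ... k.

    Draws are independent with replacement from P; a Generator (or seed)
    makes the schedule reproducible. k = 1 yields an empty schedule: the
    only pick is the global max-relevance feature.
    """
    dist = P if isinstance(P, ViewSamplingDistribution) else ViewSamplingDistribution(tuple(P))
    if k < 1:
        raise ValidationError("k must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if k == 1:
        return []
    draws = gen.choice(dist.n_views, size=k - 1, p=dist.probabilities)
    return [int(c) for c in draws]


def _relevance_by_view(
    mvd: MultiViewDataset,
    f: str | Callable[[np.ndarray, np.ndarray], float],
) -> list[np.ndarray]:
    """Relevance of every feature, per view.

    CFM is pool-normalized; in the multi-view setting the pool is the union
    of all views' features so that scores are commensurable across views.
    """
    y = mvd.labels
    if f == "cfm":
        pooled = np.hstack([v.matrix for v in mvd.views])
        scores = cfm_relevance(pooled, y)
        out, start = [], 0
        for view in mvd.views:
            out.append(scores[start : start + view.n_features])
            start += view.n_features
        return out
    if callable(f):
        return [
            np.array([f(v.matrix[:, j], y) for j in range(v.n_features)])
            for v in mvd.views
        ]
    get_relevance(f)  # validate the name early
    return [relevance_vector(f, v.matrix, y) for v in mvd.views]


def global_max_relevance(
    mvd: MultiViewDataset,
    f: str | Callable[[np.ndarray, np.ndarray], float] = "f_stat",
    rel_by_view: list[np.ndarray] | None = None,
) -> tuple[int, int]:
    """Most relevant (view, feature) pair across every view.

    Ties break toward the lowest view index, then the lowest feature index.
    """
    if any(v.n_features == 0 for v in mvd.views):
        raise ValidationError("every view must be non-empty")
    if rel_by_view is None:
        mvd.require_both_classes()
        rel_by_view = _relevance_by_view(mvd, f)
    best = (-np.inf, -1, -1)
    for vi, rel in enumerate(rel_by_view):
        j = int(np.flatnonzero(rel == rel.max())[0])
        if rel[j] > best[0]:
            best = (float(rel[j]), vi, j)
    return best[1], best[2]


def mrmr_mv_select(
    mvd: MultiViewDataset,
    k: int,
    f: str | Callable[[np.ndarray, np.ndarray], float] = "f_stat",
    g: str | Callable[[np.ndarray, np.ndarray], float] = "abs_pearson",
    P: ViewSamplingDistribution | tuple[float, ...] | None = None,
    seed: int | np.random.Generator | None = None,
    exponent: int = 2,
    return_schedule: bool = False,
):
    """Greedy multi-view MRMR selection of k features.

    Parameters
    ----------
    mvd : MultiViewDataset
        Aligned views with shared binary labels.
    k : int
        Total number of features to select across views.
    f, g : names or callables
        Relevance and redundancy functions (see :mod:`mvmrmr.scoring`).
    P : ViewSamplingDistribution or probability sequence, optional
        View-importance distribution; uniform when omitted.
    seed : int or Generator, optional
        Drives schedule sampling (and any exhaustion redraws); selection
        given the schedule is deterministic.
    exponent : {1, 2}
        Redundancy divisor exponent e in 1/|S_all|^e.
    return_schedule : bool
        Also return the realized view schedule (0-based, one entry per
        post-first step).

    Returns
    -------
    SelectionResult  (or ``(SelectionResult, schedule)``)
        Per-view index sets plus the global pick order.
    """
    mvd.require_both_classes()
    if exponent not in (1, 2):
        raise ValidationError("redundancy exponent must be 1 or 2")
    total = mvd.n_features_total
    if not 1 <= k <= total:
        raise ValidationError(f"k={k} must be in [1, {total}]")
    dist = _as_distribution(P, mvd.n_views)
    gen = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rel_by_view = _relevance_by_view(mvd, f)
    schedule = sample_view_schedule(dist, k, gen)

    vector_g = g == "abs_pearson" or g is abs_pearson
    g_fn = None if vector_g else _resolve_g(g)

    n_per_view = [v.n_features for v in mvd.views]
    available = [np.ones(n, dtype=bool) for n in n_per_view]
    red_sum = [np.zeros(n) for n in n_per_view]
    remaining = list(n_per_view)

    order: list[tuple[int, int]] = []
    realized: list[int] = []

    def take(vi: int, j: int) -> None:
        order.append((vi, j))
        available[vi][j] = False
        remaining[vi] -= 1
        col = mvd.views[vi].matrix[:, j]
        for wi, view in enumerate(mvd.views):
            if vector_g:
                red_sum[wi] += _abs_corr_with(view.matrix, col)
            else:
                for cand in np.flatnonzero(available[wi]):
                    red_sum[wi][cand] += g_fn(view.matrix[:, cand], col)

    # Step 1: globally most relevant feature, independent of P.
    vi0, j0 = global_max_relevance(mvd, f, rel_by_view=rel_by_view)
    take(vi0, j0)

    for step, scheduled in enumerate(schedule, start=1):
        vi = scheduled
        if remaining[vi] == 0:
            vi = _redraw_view(dist, remaining, gen)
        realized.append(vi)
        scores = rel_by_view[vi] - red_sum[vi] / len(order) ** exponent
        scores = np.where(available[vi], scores, -np.inf)
        j = int(np.flatnonzero(scores == scores.max())[0])
        take(vi, j)

    result = SelectionResult.from_order(order, n_views=mvd.n_views)
    if return_schedule:
        return result, realized
    return result


def _redraw_view(
    dist: ViewSamplingDistribution,
    remaining: list[int],
    gen: np.random.Generator,
) -> int:
    """Redraw an exhausted step's view from P restricted to live views."""
    live = [i for i, r in enumerate(remaining) if r > 0]
    if not live:
        raise ValidationError("all views exhausted before reaching k")
    weights = np.array([dist.probabilities[i] for i in live])
    if weights.sum() == 0:
        weights = np.ones(len(live))  # P gave live views zero mass: fall back to uniform
    weights = weights / weights.sum()
    return int(gen.choice(live, p=weights))
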