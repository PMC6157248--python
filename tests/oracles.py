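"""Independent brute-force oracles for the greedy selection procedures.

These deliberately avoid the library's vectorized/cached code paths: every
candidate is re-scored from scratch at every iteration with plain Python
loops and scalar scoring calls, so they can certify the optimized
implementations on small problems.
"""

from __future__ import annotations

import numpy as np


def pearson_abs(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def anova_f(x, y) -> float:
    """Direct two-group one-way ANOVA F from the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y)
    g0, g1 = x[y == 0], x[y == 1]
    n0, n1 = len(g0), len(g1)
    grand = x.mean()
    ss_between = n0 * (g0.mean() - grand) ** 2 + n1 * (g1.mean() - grand) ** 2
    ss_within = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return float((ss_between / 1.0) / (ss_within / (n0 + n1 - 2)))


def greedy_mrmr_oracle(X, y, k, f_fn, g_fn=pearson_abs, exponent=2):
    """Re-scoring greedy MRMR: loops, no caching, no vectorization."""
    X = np.asarray(X, float)
    n = X.shape[1]
    rel = [f_fn(X[:, j], y) for j in range(n)]
    selected = [int(np.argmax(rel))]  # argmax returns the lowest tied index
    while len(selected) < k:
        best_j, best_score = None, None
        for j in range(n):
            if j in selected:
                continue
            penalty = sum(g_fn(X[:, j], X[:, l]) for l in selected)
            score = rel[j] - penalty / len(selected) ** exponent
            if best_score is None or score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def greedy_mrmr_mv_oracle(mvd, k, schedule, f_fn, g_fn=pearson_abs, exponent=2):
    """Replay the multi-view greedy line by line for a given view schedule.

    ``schedule`` is the realized list of k-1 view indices. Step 1 takes the
    globally most relevant feature (lowest view, then feature, on ties);
    each later step restricts candidates to the scheduled view but
    penalizes against everything selected so far in any view.
    """
    y = mvd.labels
    rel = [
        [f_fn(v.matrix[:, j], y) for j in range(v.n_features)] for v in mvd.views
    ]
    best = None
    for vi, scores in enumerate(rel):
        for j, s in enumerate(scores):
            if best is None or s > best[0]:
                best = (s, vi, j)
    order = [(best[1], best[2])]

    for vi in schedule:
        view = mvd.views[vi]
        best_j, best_score = None, None
        for j in range(view.n_features):
            if (vi, j) in order:
                continue
            penalty = sum(
                g_fn(view.matrix[:, j], mvd.views[wv].matrix[:, wj])
                for wv, wj in order
            )
            score = rel[vi][j] - penalty / len(order) ** exponent
            if best_score is None or score > best_score:
                best_j, best_score = j, score
        order.append((vi, best_j))
    return order


def mann_whitney_auc(y, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (rank definition)."""
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))


def plugin_mi(x_binned, y) -> float:
    """Plug-in mutual information (nats) from the empirical joint table."""
    x_binned = np.asarray(x_binned)
    y = np.asarray(y)
    n = len(y)
    mi = 0.0
    for xv in np.unique(x_binned):
        for yv in np.unique(y):
            pxy = ((x_binned == xv) & (y == yv)).sum() / n
            if pxy == 0:
                continue
            px = (x_binned == xv).sum() / n
            py = (y == yv).sum() / n
            mi += pxy * np.log(pxy / (px * py))
    return mi
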