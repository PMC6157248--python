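"""Synthetic multi-view datasets with planted, known structure.

The generator emulates the structure of a multi-omics cohort at a scale
where ground truth is known exactly: each view carries

* *relevant* features — class-conditional Gaussians whose means differ
  between the two classes by ``effect_size`` (in units of ``noise_sd``);
* *within-view redundant* features — noisy copies of that view's relevant
  features at a target correlation ``rho_within``;
* *cross-view redundant* features — noisy copies of another view's
  relevant features at correlation ``rho_cross`` (the multi-omics analogue
  of a copy-number column and an expression column tracking one locus);
* *noise* features — class-independent Gaussians.

Copies achieve their target correlation exactly in expectation by adding
fresh Gaussian noise with sd ``sigma * sqrt(1/rho^2 - 1)`` where ``sigma``
is the source feature's standard deviation. All features are min-max
rescaled to [0, 1] afterwards (rescaling is affine per feature, so planted
correlations are unchanged). Generation is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mvmrmr.data import MultiViewDataset, SelectionResult, ValidationError, View

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_score"]


def _per_view(value, v: int, name: str) -> list[int]:
    if isinstance(value, (int, np.integer)):
        return [int(value)] * v
    out = [int(x) for x in value]
    if len(out) != v:
        raise ValidationError(f"{name} must have one entry per view")
    return out


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic labeled multi-view dataset.

    Parameters
    ----------
    m : int
        Number of samples.
    n_features : int or per-view sequence
        Total features per view.
    n_relevant : int or per-view sequence
        Planted class-associated features per view.
    n_redundant_within : int or per-view sequence
        Noisy within-view copies of relevant features per view.
    n_cross_pairs : int
        Cross-view redundant pairs; pair ``p`` copies relevant feature
        ``p // v`` of view ``p % v`` into the next view (cyclically).
    rho_within, rho_cross : float in (0, 1]
        Target Pearson correlation of within-/cross-view copies.
    class_balance : float in (0, 1)
        Fraction of positive labels (realized exactly, up to rounding).
    effect_size : float
        Between-class mean shift of relevant features, in noise_sd units.
    noise_sd : float
        Within-class standard deviation of every Gaussian feature.
    seed : int
        Generator seed; the dataset is a pure function of the spec.
    """

    m: int = 300
    n_views: int = 2
    n_features: int | Sequence[int] = 200
    n_relevant: int | Sequence[int] = 10
    n_redundant_within: int | Sequence[int] = 0
    n_cross_pairs: int = 0
    rho_within: float = 0.9
    rho_cross: float = 0.9
    class_balance: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    view_names: tuple[str, ...] | None = None

    def resolved(self) -> dict:
        v = self.n_views
        n_features = _per_view(self.n_features, v, "n_features")
        n_relevant = _per_view(self.n_relevant, v, "n_relevant")
        n_within = _per_view(self.n_redundant_within, v, "n_redundant_within")
        n_cross_in = [0] * v  # copies *received* by each view
        for p in range(self.n_cross_pairs):
            src = p % v
            n_cross_in[(src + 1) % v] += 1
            if n_relevant[src] == 0:
                raise ValidationError("cross pair sourced from a view with no relevant features")
        if not 0 < self.class_balance < 1:
            raise ValidationError("class_balance must be in (0, 1)")
        if not (0 < self.rho_within <= 1 and 0 < self.rho_cross <= 1):
            raise ValidationError("correlations must lie in (0, 1]")
        if self.m < 2:
            raise ValidationError("need at least two samples")
        for i in range(v):
            planted = n_relevant[i] + n_within[i] + n_cross_in[i]
            if planted > n_features[i]:
                raise ValidationError(
                    f"view {i}: {planted} planted features exceed n_features={n_features[i]}"
                )
        names = self.view_names or tuple(f"view{i + 1}" for i in range(v))
        if len(names) != v:
            raise ValidationError("view_names must have one entry per view")
        return {
            "n_features": n_features,
            "n_relevant": n_relevant,
            "n_within": n_within,
            "n_cross_in": n_cross_in,
            "names": names,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated dataset.

    ``relevant`` lists each view's class-associated feature indices;
    ``redundancy_map`` lists ``(original, copy)`` pairs of
    ``(view_index, feature_index)`` coordinates, within and across views.
    """

    relevant: tuple[tuple[int, ...], ...]
    redundancy_map: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def canonical(self, coord: tuple[int, int]) -> tuple[int, int]:
        """Map a copy back to its planted original (identity otherwise)."""
        mapping = dict((copy, orig) for orig, copy in self.redundancy_map)
        seen = set()
        while coord in mapping and coord not in seen:
            seen.add(coord)
            coord = mapping[coord]
        return coord

    def to_dict(self) -> dict:
        return {
            "relevant": [list(r) for r in self.relevant],
            "redundancy_map": [
                {"original": list(o), "copy": list(c)} for o, c in self.redundancy_map
            ],
        }


def _labels(m: int, balance: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(m * balance))
    n_pos = min(max(n_pos, 1), m - 1)  # both classes always present
    y = np.zeros(m, dtype=int)
    y[rng.permutation(m)[:n_pos]] = 1
    return y


def _noisy_copy(
    source: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    if rho == 1.0:
        return source.copy()
    sigma = source.std()
    if sigma == 0:
        return source.copy()
    return source + rng.normal(0.0, sigma * np.sqrt(1.0 / rho**2 - 1.0), source.shape)


def _rescale01(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0, keepdims=True)
    span = X.max(axis=0, keepdims=True) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def generate(spec: SyntheticSpec) -> tuple[MultiViewDataset, GroundTruth]:
    """Generate one dataset and its ground truth from a spec.

    Column layout per view: relevant features first, then within-view
    copies, then received cross-view copies, then noise. The ground truth
    records the same layout, so tests never rely on position conventions.
    """
    r = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    v = spec.n_views
    y = _labels(spec.m, spec.class_balance, rng)
    shift = spec.effect_size * spec.noise_sd

    # Pass 1: relevant + noise blocks per view (copies need sources first).
    relevant_cols: list[list[np.ndarray]] = []
    for i in range(v):
        cols = [
            rng.normal(0.0, spec.noise_sd, spec.m) + shift * y
            for _ in range(r["n_relevant"][i])
        ]
        relevant_cols.append(cols)

    redundancy: list[tuple[tuple[int, int], tuple[int, int]]] = []
    within_cols: list[list[np.ndarray]] = [[] for _ in range(v)]
    for i in range(v):
        for c in range(r["n_within"][i]):
            src = c % max(r["n_relevant"][i], 1)
            if r["n_relevant"][i] == 0:
                raise ValidationError(f"view {i}: within-view copies need relevant features")
            within_cols[i].append(_noisy_copy(relevant_cols[i][src], spec.rho_within, rng))
            copy_idx = r["n_relevant"][i] + c
            redundancy.append(((i, src), (i, copy_idx)))

    cross_cols: list[list[np.ndarray]] = [[] for _ in range(v)]
    cross_src: list[list[tuple[int, int]]] = [[] for _ in range(v)]
    for p in range(spec.n_cross_pairs):
        src_view = p % v
        dst_view = (src_view + 1) % v
        src_feat = (p // v) % r["n_relevant"][src_view]
        cross_cols[dst_view].append(
            _noisy_copy(relevant_cols[src_view][src_feat], spec.rho_cross, rng)
        )
        cross_src[dst_view].append((src_view, src_feat))

    sample_ids = tuple(f"s{j}" for j in range(spec.m))
    views: list[View] = []
    truth_relevant: list[tuple[int, ...]] = []
    for i in range(v):
        n_rel, n_wit = r["n_relevant"][i], r["n_within"][i]
        n_cross = len(cross_cols[i])
        n_noise = r["n_features"][i] - n_rel - n_wit - n_cross
        for c, (sv, sf) in enumerate(cross_src[i]):
            redundancy.append(((sv, sf), (i, n_rel + n_wit + c)))
        noise = rng.normal(0.0, spec.noise_sd, (spec.m, n_noise))
        blocks = relevant_cols[i] + within_cols[i] + cross_cols[i]
        matrix = (
            np.column_stack(blocks + [noise]) if blocks else noise
        )
        matrix = _rescale01(matrix)
        names = tuple(f"{r['names'][i]}_f{j}" for j in range(r["n_features"][i]))
        views.append(
            View(
                name=r["names"][i], matrix=matrix, feature_names=names,
                sample_ids=sample_ids,
            )
        )
        truth_relevant.append(tuple(range(n_rel)))

    mvd = MultiViewDataset(views=tuple(views), labels=y, sample_ids=sample_ids)
    truth = GroundTruth(
        relevant=tuple(truth_relevant), redundancy_map=tuple(redundancy)
    )
    return mvd, truth


def recovery_score(
    selection: SelectionResult, truth: GroundTruth
) -> tuple[float, float]:
    """Redundancy-aware precision and recall of relevant-feature recovery.

    A selected planted copy counts as recovering its original, but an
    original and its own copy together count as one recovered signal.
    Precision is the fraction of selected features that carry planted
    signal; recall is the fraction of distinct planted signals recovered.
    Conventions at the degenerate edges: empty selection gives precision 0;
    an empty relevant set gives recall 1.
    """
    relevant = {
        (vi, j) for vi, feats in enumerate(truth.relevant) for j in feats
    }
    selected = [coord for coord in _iter_selection(selection)]
    canonical_hits = set()
    n_hit = 0
    for coord in selected:
        canon = truth.canonical(coord)
        if canon in relevant:
            n_hit += 1
            canonical_hits.add(canon)
    precision = n_hit / len(selected) if selected else 0.0
    recall = len(canonical_hits) / len(relevant) if relevant else 1.0
    return precision, recall


def _iter_selection(selection: SelectionResult):
    yield from selection.selection_order
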