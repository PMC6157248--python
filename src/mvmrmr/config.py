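"""Declarative run configuration: YAML in, resolved YAML out.

A RunConfig fully determines a selection or evaluation run: input view
tables and label locator, preprocessing toggles, the two-stage pipeline,
the CV protocol, the k grid, the view-importance distribution P, and one
global seed. Every run writes its resolved configuration next to its
outputs so results are reproducible from the output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mvmrmr.data import (
    MultiViewDataset,
    ValidationError,
    align_views,
    drop_missing_features,
    read_labels,
    read_view,
    rescale_unit_interval,
    variance_filter,
)
from mvmrmr.framework import FilterSpec, TwoStagePipeline

log = logging.getLogger("mvmrmr")

__all__ = ["RunConfig", "load_dataset", "build_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    views: list[dict] = field(default_factory=list)  # {path, name?, delimiter?}
    labels: str | None = None  # single-column file or a column name
    rescale_axis: str = "per_feature"
    variance_threshold: float = 0.02
    preprocess: bool = True
    stage1: list[dict] = field(default_factory=list)  # {kind, params?, enabled?}
    stage2: dict = field(default_factory=lambda: {"kind": "all_filter"})
    n_folds: int = 5
    n_repeats: int = 10
    k_grid: list[int] = field(default_factory=lambda: [10])
    learners: list[str] = field(default_factory=lambda: ["random_forest"])
    learner_params: dict = field(default_factory=dict)
    strategies: list[str] = field(
        default_factory=lambda: ["SV_per_view", "SV_C", "SV_S", "MV", "Ensemble"]
    )
    relevance: str = "f_stat"
    redundancy: str = "abs_pearson"
    P: list[float] | None = None
    seed: int = 0
    output_dir: str = "mvmrmr_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def write_resolved(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_yaml(out / "resolved_config.yaml")
        return out


def load_dataset(config: RunConfig) -> MultiViewDataset:
    """Read, preprocess and align the configured views and labels."""
    if not config.views:
        raise ValidationError("config lists no views")
    views, label_vectors = [], []
    for entry in config.views:
        view, y = read_view(
            entry["path"],
            delimiter=entry.get("delimiter", ","),
            labels=config.labels,
            name=entry.get("name"),
        )
        log.info("view %s: %d samples x %d features (raw)", view.name, view.n_samples, view.n_features)
        if config.preprocess:
            view = drop_missing_features(view)
            view = rescale_unit_interval(view, axis=config.rescale_axis)
            view = variance_filter(view, threshold=config.variance_threshold)
            log.info("view %s: %d features after preprocessing", view.name, view.n_features)
        views.append(view)
        label_vectors.append(y)

    y = next((v for v in label_vectors if v is not None), None)
    if y is None:
        raise ValidationError("no labels found; set the 'labels' config key")

    if all(v.sample_ids is not None for v in views):
        first = views[0]
        if first.sample_ids is not None and y is not None:
            labels_by_id = {s: int(lab) for s, lab in zip(first.sample_ids, y)}
            mvd, dropped = align_views(views, labels_by_id=labels_by_id)
            for name, n in dropped.items():
                if n:
                    log.info("view %s: dropped %d unshared samples", name, n)
            return mvd
    matrices_m = {v.n_samples for v in views}
    if len(matrices_m) != 1:
        raise ValidationError("views disagree on sample count and carry no ids")
    return MultiViewDataset(views=tuple(views), labels=y)


def build_pipeline(config: RunConfig, n_views: int) -> TwoStagePipeline:
    """Materialize the configured two-stage pipeline."""
    stage1_specs = config.stage1 or [{"kind": "all_filter"}] * n_views
    if len(stage1_specs) == 1 and n_views > 1:
        stage1_specs = stage1_specs * n_views
    stage1 = [
        FilterSpec(
            s.get("kind", "all_filter"),
            dict(s.get("params", {})),
            enabled=bool(s.get("enabled", True)),
        )
        for s in stage1_specs
    ]
    stage2_params = dict(config.stage2.get("params", {}))
    if config.stage2.get("kind") == "mrmr_mv" and config.P is not None:
        stage2_params.setdefault("P", tuple(config.P))
    stage2 = FilterSpec(config.stage2.get("kind", "all_filter"), stage2_params)
    return TwoStagePipeline(stage1, stage2, seed=config.seed)
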