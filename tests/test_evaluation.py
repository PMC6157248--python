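"""CV harness: AUC correctness, stratification, leakage, strategy suite."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mvmrmr.data import MultiViewDataset, ValidationError
from mvmrmr.evaluation import (
    CVProtocol,
    ensemble_average,
    make_learner,
    p_sensitivity,
    percent_relative_range,
    repeated_cv,
    strategy_suite,
    summarize,
)
from mvmrmr.framework import FilterSpec, TwoStagePipeline
from mvmrmr.synthetic import SyntheticSpec, generate
from conftest import make_mvd
from oracles import mann_whitney_auc


def small_protocol(seed=0, repeats=1, folds=3):
    return CVProtocol(n_folds=folds, n_repeats=repeats, seed=seed)


@pytest.fixture
def signal_mvd():
    mvd, _ = generate(
        SyntheticSpec(m=120, n_views=2, n_features=12, n_relevant=3, effect_size=1.2, seed=4)
    )
    return mvd


class TestProtocol:
    def test_folds_partition_samples(self):
        y = np.tile([0, 1], 25)
        protocol = small_protocol(folds=5)
        seen = []
        for _, _, train, test in protocol.splits(y):
            seen.extend(test)
            assert set(train) | set(test) == set(range(50))
            assert not set(train) & set(test)
        assert sorted(seen) == list(range(50))

    def test_stratified_folds_balance_classes(self):
        y = np.array([1] * 21 + [0] * 29)
        protocol = CVProtocol(n_folds=5, n_repeats=2, seed=1)
        ideal = 21 / 5
        for _, _, _, test in protocol.splits(y):
            pos = y[test].sum()
            assert abs(pos - ideal) <= 1

    def test_repeats_use_different_partitions(self):
        y = np.tile([0, 1], 30)
        protocol = CVProtocol(n_folds=5, n_repeats=2, seed=0)
        folds = {}
        for repeat, fold, _, test in protocol.splits(y):
            folds[(repeat, fold)] = tuple(sorted(test))
        assert folds[(0, 0)] != folds[(1, 0)]


class TestAUC:
    def test_auc_matches_rank_statistic_definition(self, rng):
        for _ in range(20):
            y = (rng.uniform(size=30) < 0.4).astype(int)
            if y.sum() in (0, len(y)):
                continue
            scores = rng.uniform(size=30)
            assert roc_auc_score(y, scores) == pytest.approx(
                mann_whitney_auc(y, scores), abs=1e-12
            )

    def test_auc_with_tied_scores(self, rng):
        y = np.tile([0, 1], 10)
        scores = np.round(rng.uniform(size=20), 1)  # force ties
        assert roc_auc_score(y, scores) == pytest.approx(
            mann_whitney_auc(y, scores), abs=1e-12
        )


class TestRepeatedCV:
    def _pipeline(self, n_views):
        return TwoStagePipeline(
            [FilterSpec("all_filter")] * n_views, FilterSpec("mrmr", {"k": 3})
        )

    def test_separable_data_reaches_auc_one(self, rng):
        y = np.tile([0, 1], 30)
        X = rng.uniform(size=(60, 5))
        X[:, 2] = y.astype(float)
        mvd = make_mvd([X], y)
        result = repeated_cv(
            mvd, self._pipeline(1), make_learner("logistic_l1"), small_protocol()
        )
        assert result.mean_auc == pytest.approx(1.0)

    def test_same_seed_identical_fold_aucs(self, signal_mvd):
        a = repeated_cv(
            signal_mvd, self._pipeline(2), make_learner("logistic_l1"), small_protocol(7)
        )
        b = repeated_cv(
            signal_mvd, self._pipeline(2), make_learner("logistic_l1"), small_protocol(7)
        )
        assert np.array_equal(a.aucs, b.aucs)

    def test_selection_ignores_held_out_labels(self, signal_mvd):
        """In-fold selection must depend on training folds only."""
        protocol = small_protocol(3)
        y = signal_mvd.labels
        for _, _, train, test in protocol.splits(y):
            train_mvd = signal_mvd.select_samples(train)
            pipe = self._pipeline(2).fit(train_mvd)
            reference = pipe.fitted_state["final"]

            corrupted_labels = y.copy()
            corrupted_labels[test] = 1 - corrupted_labels[test]
            corrupted = MultiViewDataset(
                views=signal_mvd.views, labels=corrupted_labels,
                sample_ids=signal_mvd.sample_ids,
            )
            pipe2 = self._pipeline(2).fit(corrupted.select_samples(train))
            assert pipe2.fitted_state["final"] == reference


class TestEnsembleAverage:
    def test_idempotent_on_equal_inputs(self):
        p = np.array([0.2, 0.8, 0.5])
        assert np.array_equal(ensemble_average(p, p), p)

    def test_elementwise_mean(self):
        out = ensemble_average(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.array_equal(out, [0.5, 0.5])

    def test_auc_invariant_when_averaging_with_itself(self, rng):
        y = np.tile([0, 1], 15)
        p = rng.uniform(size=30)
        assert roc_auc_score(y, ensemble_average(p, p)) == roc_auc_score(y, p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_average(np.ones(3), np.ones(4))


class TestStrategySuite:
    def test_tidy_shape_one_row_per_cell(self, signal_mvd):
        df = strategy_suite(
            signal_mvd, k_grid=[3, 5], learners=["logistic_l1"],
            protocol=small_protocol(), f="f_stat",
        )
        strategies = {"SV_view1", "SV_view2", "SV_C", "SV_S", "MV", "Ensemble"}
        assert set(df["strategy"]) == strategies
        # one row per (strategy, k, repeat, fold)
        assert len(df) == len(strategies) * 2 * 1 * 3
        assert df["auc"].between(0, 1).all()

    def test_single_view_reduction_collapses_strategies(self, rng):
        y = np.tile([0, 1], 30)
        X = rng.uniform(size=(60, 8))
        X[:, 1] = np.clip(0.2 + 0.5 * y + 0.1 * rng.normal(size=60), 0, 1)
        mvd = make_mvd([X], y)
        df = strategy_suite(
            mvd, k_grid=[4], learners=["logistic_l1"], protocol=small_protocol(),
            strategies=("SV_per_view", "SV_C", "SV_S", "MV"),
        )
        pivot = df.pivot_table(index=["repeat", "fold"], columns="strategy", values="auc")
        for column in ("SV_C", "SV_S", "MV"):
            assert np.allclose(pivot["SV_v1"], pivot[column])

    def test_restricting_strategies(self, signal_mvd):
        df = strategy_suite(
            signal_mvd, k_grid=[3], learners=["logistic_l1"],
            protocol=small_protocol(), strategies=("MV",),
        )
        assert set(df["strategy"]) == {"MV"}

    def test_permuted_labels_score_near_chance(self, rng):
        y = rng.permutation(np.tile([0, 1], 1000))
        X1 = rng.uniform(size=(2000, 6))
        X2 = rng.uniform(size=(2000, 6))
        mvd = make_mvd([X1, X2], y)
        df = strategy_suite(
            mvd, k_grid=[4], learners=["logistic_l1"],
            protocol=CVProtocol(n_folds=5, n_repeats=1, seed=0),
            strategies=("MV",),
        )
        assert abs(df["auc"].mean() - 0.5) <= 0.05

    def test_summarize_means(self, signal_mvd):
        df = strategy_suite(
            signal_mvd, k_grid=[3], learners=["logistic_l1"],
            protocol=small_protocol(), strategies=("MV", "SV_C"),
        )
        summary = summarize(df)
        mv_mean = df[df.strategy == "MV"]["auc"].mean()
        assert summary.loc[summary.strategy == "MV", "mean_auc"].iloc[0] == pytest.approx(mv_mean)


class TestPSensitivity:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.7] * 11, 0.0),
            ([0.6, 0.7], 100 * 0.1 / 0.65),
        ],
    )
    def test_percent_relative_range_formula(self, values, expected):
        assert percent_relative_range(values) == pytest.approx(expected)

    def test_constant_shift_decreases_statistic(self, rng):
        values = rng.uniform(0.5, 0.7, size=11)
        shifted = values + 0.2
        assert percent_relative_range(shifted) < percent_relative_range(values)

    def test_sweep_table_and_attrs(self, signal_mvd):
        frame = p_sensitivity(
            signal_mvd, k_grid=[3], p_grid=[0.0, 0.5, 1.0],
            learner="logistic_l1", protocol=small_protocol(),
        )
        assert set(frame["p1"]) == {0.0, 0.5, 1.0}
        assert set(frame.attrs["prr"]) == {3}
        sub = frame[frame.k == 3]["mean_auc"]
        assert frame.attrs["prr"][3] == pytest.approx(percent_relative_range(sub))

    def test_requires_two_views(self, rng):
        y = np.tile([0, 1], 10)
        mvd = make_mvd([rng.uniform(size=(20, 4))], y)
        with pytest.raises(ValidationError):
            p_sensitivity(mvd, k_grid=[2], learner="logistic_l1")
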