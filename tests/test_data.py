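"""Data containers, table I/O, alignment and preprocessing filters."""

import numpy as np
import pytest

from mvmrmr.data import (
    MultiViewDataset,
    SelectionResult,
    ValidationError,
    View,
    align_views,
    drop_missing_features,
    label_survival,
    read_view,
    rescale_unit_interval,
    variance_filter,
)
from conftest import make_view


class TestContainers:
    def test_view_rejects_mismatched_feature_names(self):
        with pytest.raises(ValidationError):
            View("v", np.zeros((3, 2)), ("a",))

    def test_view_rejects_duplicate_feature_names(self):
        with pytest.raises(ValidationError):
            View("v", np.zeros((3, 2)), ("a", "a"))

    def test_dataset_rejects_non_binary_labels(self):
        v = make_view(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            MultiViewDataset((v,), np.array([0, 1, 2]))

    def test_dataset_rejects_row_mismatch(self):
        v1 = make_view(np.zeros((3, 2)))
        v2 = make_view(np.zeros((4, 2)))
        with pytest.raises(ValidationError):
            MultiViewDataset((v1, v2), np.array([0, 1, 1]))

    def test_selection_result_partition_is_checked(self):
        with pytest.raises(ValidationError):
            SelectionResult(per_view_indices=((0,), ()), selection_order=((1, 0),))

    def test_selection_result_round_trip(self):
        order = [(0, 3), (1, 1), (0, 0)]
        res = SelectionResult.from_order(order, n_views=2)
        assert res.per_view_indices == ((3, 0), (1,))
        assert res.k == 3


class TestReadView:
    def test_csv_with_label_file(self, tmp_path):
        (tmp_path / "t.csv").write_text("id,g1,g2\ns1,0.1,0.2\ns2,0.3,0.4\ns3,0.5,0.6\n")
        (tmp_path / "y.csv").write_text("0\n1\n1\n")
        view, y = read_view(tmp_path / "t.csv", labels=tmp_path / "y.csv")
        assert view.n_samples == 3 and view.n_features == 2
        assert view.feature_names == ("g1", "g2")
        assert list(y) == [0, 1, 1]

    def test_empty_cell_becomes_missing(self, tmp_path):
        (tmp_path / "t.csv").write_text("id,g1,g2\ns1,,0.2\ns2,0.3,0.4\n")
        view, _ = read_view(tmp_path / "t.csv")
        assert np.isnan(view.matrix[0, 0])
        assert not np.isnan(view.matrix).all()

    def test_non_binary_labels_rejected(self, tmp_path):
        (tmp_path / "t.csv").write_text("id,g1\ns1,0.1\ns2,0.2\n")
        (tmp_path / "y.csv").write_text("0\n2\n")
        with pytest.raises(ValidationError):
            read_view(tmp_path / "t.csv", labels=tmp_path / "y.csv")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_view(tmp_path / "absent.csv")

    def test_label_column_inside_table(self, tmp_path):
        (tmp_path / "t.csv").write_text("id,g1,label\ns1,0.1,0\ns2,0.2,1\n")
        view, y = read_view(tmp_path / "t.csv", labels="label")
        assert view.feature_names == ("g1",)
        assert list(y) == [0, 1]


class TestAlignViews:
    def _views(self, ids1, ids2):
        v1 = make_view(np.arange(len(ids1) * 2).reshape(len(ids1), 2), "a", sample_ids=ids1)
        v2 = make_view(np.arange(len(ids2) * 2).reshape(len(ids2), 2), "b", sample_ids=ids2)
        return v1, v2

    def test_intersection_sorted(self):
        v1, v2 = self._views(("A", "B", "C"), ("D", "C", "B"))
        labels = {"A": 0, "B": 1, "C": 0, "D": 1}
        mvd, dropped = align_views([v1, v2], labels_by_id=labels)
        assert mvd.sample_ids == ("B", "C")
        assert all(v.sample_ids == ("B", "C") for v in mvd.views)
        assert dropped == {"a": 1, "b": 1}
        assert list(mvd.labels) == [1, 0]

    def test_identical_sets_keep_everything(self):
        v1, v2 = self._views(("A", "B"), ("A", "B"))
        mvd, dropped = align_views([v1, v2], labels_by_id={"A": 0, "B": 1})
        assert mvd.n_samples == 2 and dropped == {"a": 0, "b": 0}

    def test_disjoint_sets_error(self):
        v1, v2 = self._views(("A",), ("B",))
        with pytest.raises(ValidationError):
            align_views([v1, v2], labels_by_id={"A": 0, "B": 1})

    def test_rows_follow_ids_not_positions(self):
        # view b lists the shared samples in reverse order; values must travel
        v1 = make_view([[1.0, 1.0], [2.0, 2.0]], "a", sample_ids=("A", "B"))
        v2 = make_view([[20.0, 20.0], [10.0, 10.0]], "b", sample_ids=("B", "A"))
        mvd, _ = align_views([v1, v2], labels_by_id={"A": 0, "B": 1})
        assert mvd.sample_ids == ("A", "B")
        assert mvd.views[1].matrix[0, 0] == 10.0


class TestPreprocessing:
    def test_drop_missing_removes_only_affected_columns(self):
        view = make_view([[1.0, np.nan], [2.0, 3.0]])
        out = drop_missing_features(view)
        assert out.feature_names == ("f0",)

    def test_drop_missing_identity_when_complete(self):
        view = make_view([[1.0, 2.0], [3.0, 4.0]])
        out = drop_missing_features(view)
        assert np.array_equal(out.matrix, view.matrix)

    def test_drop_missing_all_columns_warns(self):
        view = make_view([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.warns(UserWarning):
            out = drop_missing_features(view)
        assert out.n_features == 0

    @pytest.mark.parametrize(
        "column, expected",
        [([2.0, 4.0, 6.0], [0.0, 0.5, 1.0]), ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0])],
    )
    def test_rescale_per_feature(self, column, expected):
        view = make_view(np.array(column).reshape(-1, 1))
        out = rescale_unit_interval(view)
        assert np.allclose(out.matrix[:, 0], expected)

    def test_rescale_idempotent_on_full_range(self):
        view = make_view([[0.0, 1.0], [1.0, 0.0], [0.5, 0.25]])
        once = rescale_unit_interval(view)
        twice = rescale_unit_interval(once)
        assert np.allclose(once.matrix, view.matrix)
        assert np.allclose(twice.matrix, once.matrix)

    def test_rescale_per_sample_axis(self):
        view = make_view([[0.0, 2.0, 4.0]])
        out = rescale_unit_interval(view, axis="per_sample")
        assert np.allclose(out.matrix, [[0.0, 0.5, 1.0]])

    def test_variance_filter_boundary_kept_constant_removed(self):
        # population variance of [0,0.2,0.4] is 0.0266..; of [0,0.2,0.2] 0.0088..
        col_keep = [0.0, 0.2, 0.4]
        col_drop = [0.0, 0.2, 0.2]
        col_const = [0.3, 0.3, 0.3]
        view = make_view(np.column_stack([col_keep, col_drop, col_const]))
        out = variance_filter(view, threshold=0.02)
        assert out.feature_names == ("f0",)

    def test_variance_exactly_at_threshold_is_kept(self):
        col = np.array([0.0, 0.0, 1.0, 1.0])  # population variance 0.25
        view = make_view(col.reshape(-1, 1))
        assert variance_filter(view, threshold=0.25).n_features == 1
        assert variance_filter(view, threshold=0.2500001).n_features == 0

    def test_variance_threshold_zero_is_identity(self, rng):
        view = make_view(rng.uniform(size=(10, 6)))
        out = variance_filter(view, threshold=0.0)
        assert out.feature_names == view.feature_names

    def test_pipeline_composition_is_deterministic(self, rng):
        X = rng.uniform(size=(20, 8))
        X[3, 2] = np.nan
        view = make_view(X)

        def run(v):
            return variance_filter(rescale_unit_interval(drop_missing_features(v)), 0.02)

        a, b = run(view), run(view)
        assert a.feature_names == b.feature_names
        assert np.array_equal(a.matrix, b.matrix)


class TestLabelSurvival:
    @pytest.mark.parametrize(
        "time, status, expected",
        [(4.0, 1, 1), (3.0, 1, 1), (3.0, 0, 1), (1.5, 0, 0)],
    )
    def test_rule_table(self, time, status, expected):
        labels, mask = label_survival(np.array([time]), np.array([status]))
        assert mask[0]
        assert labels[0] == expected

    def test_censored_short_followup_excluded(self):
        labels, mask = label_survival(np.array([1.5, 4.0]), np.array([1, 1]))
        assert list(mask) == [False, True]
        assert list(labels) == [1]

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            label_survival(np.array([-1.0]), np.array([0]))
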