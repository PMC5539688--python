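import itertools
import math

import numpy as np
import pandas as pd
import pytest

import falltiers as ft
from falltiers.tree import candidate_thresholds


def dataset(labels, **columns):
    return ft.LabeledDataset(pd.DataFrame(columns), np.array(labels, dtype=object))


def entropy(labels):
    n = len(labels)
    h = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        h -= p * math.log2(p)
    return h


def brute_force_best_ratio(X: pd.DataFrame, y):
    """Exhaustive gain-ratio maximum over all midpoint splits (independent
    entropy arithmetic)."""
    y = list(y)
    best = 0.0
    for col in X.columns:
        for thr in candidate_thresholds(X[col].to_numpy(dtype=float)):
            left = [lab for v, lab in zip(X[col], y) if v <= thr]
            right = [lab for v, lab in zip(X[col], y) if v > thr]
            if not left or not right:
                continue
            n = len(y)
            gain = entropy(y) - len(left) / n * entropy(left) - len(right) / n * entropy(right)
            if gain <= 1e-12:
                continue
            split_info = entropy(["L"] * len(left) + ["R"] * len(right))
            best = max(best, gain / split_info)
    return best


class TestGainRatio:
    def test_perfect_balanced_split_is_one(self):
        data = dataset(["FALL", "FALL", "NON_FALL", "NON_FALL"], f=[1.0, 2.0, 8.0, 9.0])
        assert ft.gain_ratio(data, "f", 5.0) == pytest.approx(1.0)

    def test_uninformative_split_is_zero(self):
        # same class proportions (1:1) on both sides
        data = dataset(
            ["FALL", "NON_FALL", "FALL", "NON_FALL"], f=[1.0, 2.0, 8.0, 9.0]
        )
        assert ft.gain_ratio(data, "f", 5.0) == 0.0

    def test_six_instance_table_matches_entropy_oracle(self):
        # split 4|2: left 3 FALL + 1 NON_FALL, right 2 NON_FALL
        labels = ["FALL", "FALL", "FALL", "NON_FALL", "NON_FALL", "NON_FALL"]
        values = [1.0, 2.0, 3.0, 4.0, 8.0, 9.0]
        data = dataset(labels, f=values)
        h = entropy(labels)
        h_left = entropy(labels[:4])
        gain = h - 4 / 6 * h_left - 0.0
        split_info = entropy(["L"] * 4 + ["R"] * 2)
        assert ft.gain_ratio(data, "f", 5.0) == pytest.approx(gain / split_info)

    def test_empty_side_rejected(self):
        data = dataset(["FALL", "NON_FALL"], f=[1.0, 2.0])
        with pytest.raises(ValueError):
            ft.gain_ratio(data, "f", 5.0)


class TestTraining:
    def test_separable_data_yields_midpoint_stump(self):
        data = dataset(
            ["NON_FALL", "NON_FALL", "FALL", "FALL"], f=[1.0, 2.0, 8.0, 9.0]
        )
        model = ft.train_tree(data)
        assert model.root.feature == "f"
        assert model.root.threshold == pytest.approx(5.0)
        assert model.root.depth() == 1
        for v, expected in [(1.0, "NON_FALL"), (9.0, "FALL")]:
            assert ft.predict(model, {"f": v}) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ft.train_tree(dataset(["FALL"] * 4, f=[1.0, 2.0, 3.0, 4.0]))

    def test_same_seed_same_structure(self):
        rng = np.random.default_rng(2)
        data = dataset(
            ["FALL"] * 10 + ["NON_FALL"] * 10,
            a=rng.normal(size=20), b=rng.normal(size=20),
        )
        m1 = ft.train_tree(data, seed=3)
        m2 = ft.train_tree(data, seed=3)
        from falltiers.tree import _node_to_dict

        assert _node_to_dict(m1.root) == _node_to_dict(m2.root)

    def test_root_split_is_brute_force_optimal_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            X = pd.DataFrame(
                {
                    "a": rng.choice([0.0, 1.0, 2.0, 3.0], size=n),
                    "b": rng.choice([0.0, 1.0, 2.0, 3.0], size=n),
                }
            )
            y = rng.choice(["FALL", "NON_FALL"], size=n)
            if len(set(y)) < 2:
                continue
            data = ft.LabeledDataset(X, y)
            best = brute_force_best_ratio(X, y)
            model = ft.train_tree(data, min_leaf=1)
            if model.root.is_leaf:
                assert best == 0.0
            else:
                achieved = ft.gain_ratio(data, model.root.feature, model.root.threshold)
                assert achieved == pytest.approx(best, abs=1e-12)

    def test_depth_bounded_by_candidate_thresholds(self):
        rng = np.random.default_rng(7)
        data = dataset(
            list(rng.choice(["FALL", "NON_FALL"], size=30)),
            a=list(rng.choice([0.0, 1.0, 2.0], size=30)),
            b=list(rng.choice([0.0, 1.0], size=30)),
        )
        if len(set(data.y)) < 2:
            pytest.skip("degenerate draw")
        model = ft.train_tree(data, min_leaf=1)
        n_thresholds = sum(
            len(candidate_thresholds(data.X[c].to_numpy())) for c in data.X.columns
        )
        assert model.root.depth() <= n_thresholds


class TestPrediction:
    @pytest.fixture
    def stump(self):
        data = dataset(["NON_FALL", "NON_FALL", "FALL", "FALL"], f=[1.0, 2.0, 8.0, 9.0])
        return ft.train_tree(data)

    def test_boundary_goes_left(self, stump):
        assert ft.predict(stump, {"f": 5.0}) == "NON_FALL"
        assert ft.predict(stump, {"f": 3.0}) == "NON_FALL"
        assert ft.predict(stump, {"f": 5.0000001}) == "FALL"

    def test_missing_feature_named(self, stump):
        with pytest.raises(KeyError, match="f"):
            ft.predict(stump, {"g": 1.0})


class TestModelIO:
    def test_round_trip_predicts_identically(self, tmp_path, stump_grid=None):
        data = dataset(["NON_FALL", "NON_FALL", "FALL", "FALL"], f=[1.0, 2.0, 8.0, 9.0])
        model = ft.train_tree(data)
        path = tmp_path / "model.json"
        ft.save_model(model, path)
        back = ft.load_model(path)
        for v in np.linspace(-5, 15, 41):
            assert ft.predict(back, {"f": v}) == ft.predict(model, {"f": v})
        assert back.features == model.features

    def test_truncated_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "model.json"
        data = dataset(["NON_FALL", "NON_FALL", "FALL", "FALL"], f=[1.0, 2.0, 8.0, 9.0])
        ft.save_model(ft.train_tree(data), path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(ft.ModelFormatError):
            ft.load_model(path)

    def test_round_trip_preserves_confusion_matrix(self, tmp_path, trained_model):
        trace, manifest = ft.generate_benchmark(10, 30, seed=77)
        cfg = ft.EngineConfig()
        dec1, _, _ = ft.run_pipeline(trace.frames(), cfg, trained_model)
        path = tmp_path / "m.json"
        ft.save_model(trained_model, path)
        dec2, _, _ = ft.run_pipeline(trace.frames(), cfg, ft.load_model(path))
        assert ft.evaluate_run(dec1, manifest) == ft.evaluate_run(dec2, manifest)
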