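"""Gain-ratio tree construction, prediction, metrics, and cross-validation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from finstart.classify import (
    ConfusionMatrix, DecisionTree, TreeParams, compute_metrics,
    cross_validate, detection_threshold_from_tree, train_tree,
)
from finstart.sensor_io import ValidationError
from finstart import reference, synth


def entropy(labels):
    n = len(labels)
    out = 0.0
    for c in set(labels):
        p = sum(1 for v in labels if v == c) / n
        out -= p * math.log2(p)
    return out


def exhaustive_best_split(table, min_leaf=2):
    """Independent brute-force gain-ratio search over every midpoint."""
    labels = list(table["label"])
    n = len(labels)
    parent = entropy(labels)
    best = None
    for feat in sorted(c for c in table.columns if c != "label"):
        vals = sorted(set(table[feat]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [l for v, l in zip(table[feat], labels) if v < thr]
            right = [l for v, l in zip(table[feat], labels) if v >= thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = parent - (
                len(left) / n * entropy(left) + len(right) / n * entropy(right)
            )
            if gain <= 1e-12:
                continue
            split_info = entropy(["L"] * len(left) + ["R"] * len(right))
            ratio = gain / split_info
            key = (-ratio, feat, thr)
            if best is None or key < best:
                best = key
    return best   # (-ratio, feat, thr) or None


class TestTrainTree:
    def test_separable_1d(self):
        table = pd.DataFrame({
            "x": [1.0, 2, 3, 10, 11, 12],
            "label": ["feeding"] * 3 + ["escape"] * 3,
        })
        tree = train_tree(table)
        assert tree.depth() == 1
        assert 3 < tree.root.threshold < 10
        assert (tree.predict(table[["x"]]) == table["label"]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "a": rng.normal(0, 1, 8).round(2),
            "b": rng.normal(0, 1, 8).round(2),
            "label": rng.choice(["escape", "feeding"], 8),
        })
        best = exhaustive_best_split(table)
        tree = train_tree(table)
        if best is None:
            assert tree.root.is_leaf
        else:
            _, feat, thr = best
            assert tree.root.feature == feat
            assert tree.root.threshold == pytest.approx(thr)

    @pytest.mark.parametrize("seed", range(3))
    def test_split_oracle_200_rows(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = pd.DataFrame({
            "a": rng.normal(0, 1, 200),
            "b": rng.normal(0.8, 1, 200),
            "label": rng.choice(["escape", "feeding"], 200),
        })
        best = exhaustive_best_split(table)
        tree = train_tree(table)
        if best is None:
            assert tree.root.is_leaf
        else:
            ratio, feat, thr = best
            assert (tree.root.feature, tree.root.threshold) == (
                feat, pytest.approx(thr)
            )

    def test_single_class_single_leaf(self):
        table = pd.DataFrame({"x": [1.0, 2, 3], "label": ["escape"] * 3})
        tree = train_tree(table, TreeParams(min_leaf=1))
        assert tree.root.is_leaf
        assert tree.root.prediction == "escape"

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            train_tree(pd.DataFrame({"x": [], "label": []}))

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "a": rng.normal(0, 1, 60),
            "label": rng.choice(["escape", "feeding"], 60),
        })
        tree = train_tree(table)

        def check(node):
            if node.is_leaf:
                return
            for cls in node.counts:
                assert node.counts[cls] == (
                    node.left.counts[cls] + node.right.counts[cls]
                )
            check(node.left)
            check(node.right)

        check(tree.root)

    def test_paper_scale_synthetic_two_feature_tree(self):
        # escape/feeding features at published effect sizes: the root split
        # lands on the informative lateral-acceleration peak, its threshold
        # between the class means, and pruning only shrinks the tree
        rng = np.random.default_rng(5)
        n = 41
        table = pd.concat([
            synth.sample_class_features("escape", n, "interaxial", rng=rng),
            synth.sample_class_features("feeding", n, "interaxial", rng=rng),
        ], ignore_index=True)[["DiffRangeAxAy", "DiffMaxGxGz", "label"]]
        grown = train_tree(table, TreeParams(min_leaf=5))
        pruned = train_tree(table, TreeParams(min_leaf=5, prune=True))
        assert grown.root.feature == "DiffRangeAxAy"
        assert 27.74 < grown.root.threshold < 63.77
        assert pruned.depth() <= grown.depth()
        shallow = train_tree(table, TreeParams(min_leaf=5, max_depth=2))
        preds = shallow.predict(table.drop(columns="label"))
        assert np.mean(preds == table["label"]) >= 0.75

    def test_json_round_trip(self):
        table = pd.DataFrame({
            "x": [1.0, 2, 3, 10, 11, 12],
            "label": ["feeding"] * 3 + ["escape"] * 3,
        })
        tree = train_tree(table)
        back = DecisionTree.from_json(tree.to_json())
        assert back.root.to_dict() == tree.root.to_dict()


class TestPredict:
    def test_single_leaf_constant(self):
        table = pd.DataFrame({"x": [1.0, 1.0], "label": ["escape", "escape"]})
        tree = train_tree(table, TreeParams(min_leaf=1))
        assert tree.predict_row({"x": 99.0}) == "escape"

    def test_boundary_goes_right(self):
        table = pd.DataFrame({
            "x": [0.0, 0, 0, 2, 2, 2],
            "label": ["feeding"] * 3 + ["escape"] * 3,
        })
        tree = train_tree(table)
        thr = tree.root.threshold
        right = tree.root.right.prediction
        assert tree.predict_row({"x": thr}) == right

    def test_missing_feature_schema_error(self):
        table = pd.DataFrame({
            "x": [1.0, 2, 3, 10, 11, 12],
            "label": ["feeding"] * 3 + ["escape"] * 3,
        })
        tree = train_tree(table)
        with pytest.raises(KeyError, match="x"):
            tree.predict_row({"y": 0.0})

    def test_agrees_with_rule_trace_oracle(self, rng):
        table = pd.DataFrame({
            "a": rng.normal(0, 1, 100),
            "b": rng.normal(0, 1, 100),
            "label": rng.choice(["escape", "feeding"], 100),
        })
        tree = train_tree(table)

        def trace(row):
            node = tree.root
            while not node.is_leaf:
                node = (node.left if row[node.feature] < node.threshold
                        else node.right)
            return max(sorted(node.counts), key=lambda c: node.counts[c])

        probes = pd.DataFrame({
            "a": rng.normal(0, 2, 1000), "b": rng.normal(0, 2, 1000)
        })
        preds = tree.predict(probes)
        oracle = [trace(r) for r in probes.to_dict("records")]
        assert (preds == np.array(oracle)).all()


class TestMetrics:
    def test_published_all_combined_counts(self):
        # confusion counts reconstructed from the published per-class
        # recalls (0.78 escape, 0.90 feeding at n = 41 each)
        cm = ConfusionMatrix(tp=32, fn=9, tn=37, fp=4)
        m = compute_metrics(cm)
        assert round(m["accuracy"], 2) == 0.84
        assert round(m["precision"], 2) == 0.89
        assert round(m["recall"], 2) == 0.78
        assert round(m["f_measure"], 2) == 0.83

    def test_balanced_noise(self):
        m = compute_metrics(ConfusionMatrix(10, 10, 10, 10))
        assert all(m[k] == 0.5 for k in ("accuracy", "precision", "recall",
                                         "f_measure"))

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=41, fp=0, tn=41, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_undefined_not_zero(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=10, fn=5))
        assert m["precision"] is None
        assert m["accuracy"] == pytest.approx(10 / 15)

    def test_accuracy_invariant_to_positive_class_swap(self):
        cm = ConfusionMatrix(tp=32, fn=9, tn=37, fp=4)
        swapped = ConfusionMatrix(tp=37, fn=4, tn=32, fp=9)
        assert compute_metrics(cm)["accuracy"] == compute_metrics(swapped)["accuracy"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestCrossValidate:
    def separable_table(self, n=50):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "x": np.concatenate([rng.normal(0, 1, n), rng.normal(20, 1, n)]),
            "label": ["feeding"] * n + ["escape"] * n,
        })

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_separable_accuracy_one(self, seed):
        report = cross_validate(self.separable_table(), k=10, seed=seed)
        assert report.accuracy == 1.0

    def test_label_permuted_null_near_half(self):
        accs = []
        base = self.separable_table()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = base.copy()
            table["label"] = rng.permutation(table["label"].to_numpy())
            accs.append(cross_validate(table, k=10, seed=seed).accuracy)
        assert 0.35 < np.mean(accs) < 0.65

    def test_same_seed_identical_report(self):
        table = self.separable_table()
        a = cross_validate(table, k=10, seed=42)
        b = cross_validate(table, k=10, seed=42)
        assert a.to_dict() == b.to_dict()

    def test_pooled_accuracy_equals_correct_over_n(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "x": rng.normal(0, 1, 60),
            "label": rng.choice(["escape", "feeding"], 60),
        })
        report = cross_validate(table, k=6, seed=0)
        per_class = report.per_class["escape"]
        cm_total = sum(
            report.per_class["escape"][k] is not None for k in per_class
        )
        # pooled accuracy must equal total correct / n by construction
        correct = report.accuracy * len(table)
        assert correct == pytest.approx(round(correct))

    def test_small_class_falls_back_non_stratified(self, caplog):
        table = self.separable_table(n=30)
        table.loc[:3, "label"] = "routine"
        table = table[(table["label"] != "feeding") | (table.index < 40)]
        with caplog.at_level("WARNING", logger="finstart"):
            cross_validate(table, k=10, seed=0)
        assert any("non-stratified" in r.message for r in caplog.records)


class TestDetectionThreshold:
    def test_separable_between_classes(self):
        thr = detection_threshold_from_tree(
            np.array([10.0, 11, 12, 2, 2.5, 3]),
            np.array(["FS"] * 3 + ["RM"] * 3),
        )
        assert 3 < thr < 10

    @pytest.mark.parametrize("seed", range(20))
    def test_simulated_sd_thresholds_between_class_means(self, seed):
        # FS windowed SD ~ N(11.77, .53*sqrt(82)); RM ~ N(2.47, .12*sqrt(82))
        rng = np.random.default_rng(seed)
        n = reference.N_SD_WINDOWS
        fs = rng.normal(
            reference.FS_SD_MA[0], reference.class_sd(reference.FS_SD_MA[1], n), n
        )
        rm = rng.normal(
            reference.RM_SD_MA[0], reference.class_sd(reference.RM_SD_MA[1], n), n
        )
        thr = detection_threshold_from_tree(
            np.concatenate([fs, rm]), np.array(["FS"] * n + ["RM"] * n)
        )
        assert reference.RM_SD_MA[0] < thr < reference.FS_SD_MA[0]

    def test_identical_distribution_no_threshold(self):
        # both classes occupy every value equally: no positive-gain split
        vals = np.tile([1.0, 1.0, 2.0, 2.0], 5)
        labels = np.tile(["FS", "RM", "FS", "RM"], 5)
        assert detection_threshold_from_tree(vals, labels) is None

    def test_single_label_rejected(self):
        with pytest.raises(ValidationError):
            detection_threshold_from_tree(np.ones(5), np.array(["FS"] * 5))
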