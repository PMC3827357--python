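"""C4.5-style decision tree, confusion-matrix metrics, and cross-validation.

The tree partitions recursively on continuous features.  Candidate
thresholds are midpoints between consecutive sorted distinct values whose
class profiles differ; the split maximising the information-gain ratio
(information gain divided by split information, both in bits) is chosen,
with ties broken by lower feature name then lower threshold.  Growth stops
at purity, at ``min_leaf``, or when no split has positive gain.  Prediction
descends with the fixed convention ``value < threshold -> left,
>= threshold -> right``.

Evaluation uses the standard confusion-matrix metrics

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

pooled over seeded stratified 10-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .sensor_io import ValidationError

logger = logging.getLogger("finstart")


@dataclass(frozen=True)
class TreeParams:
    min_leaf: int = 2
    max_depth: int | None = None
    prune: bool = False          # pessimistic (upper-confidence) pruning
    prune_cf: float = 0.25

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValidationError("max_depth must be >= 0")


@dataclass
class TreeNode:
    """Internal node (feature + threshold) or leaf (feature is None)."""

    counts: dict[str, int]
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> str:
        # majority class; ties broken by class-name order for determinism
        return max(sorted(self.counts), key=lambda c: self.counts[c])

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"counts": self.counts}
        if not self.is_leaf:
            d.update(
                feature=self.feature, threshold=self.threshold,
                left=self.left.to_dict(), right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TreeNode":
        node = cls(counts={k: int(v) for k, v in d["counts"].items()})
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class DecisionTree:
    root: TreeNode
    params: TreeParams = field(default_factory=TreeParams)
    classes: tuple[str, ...] = ()

    def predict_row(self, row: Mapping[str, float]) -> str:
        node = self.root
        while not node.is_leaf:
            if node.feature not in row:
                raise KeyError(
                    f"feature {node.feature!r} required by the tree is missing"
                )
            node = node.left if row[node.feature] < node.threshold else node.right
        return node.prediction

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([
            self.predict_row(row) for row in table.to_dict("records")
        ])

    def depth(self) -> int:
        return self.root.depth()

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"classes": list(self.classes), "tree": self.root.to_dict()}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str) -> "DecisionTree":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls(root=TreeNode.from_dict(d["tree"]), classes=tuple(d["classes"]))


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.array([(labels == c).sum() for c in classes])


def _best_split(
    X: pd.DataFrame, labels: np.ndarray, classes: np.ndarray, params: TreeParams
) -> tuple[str, float, float] | None:
    """Best (feature, threshold, gain_ratio) by exhaustive midpoint search.

    Returns None when no candidate split has positive information gain.
    Deterministic: ties by (gain ratio, feature name, threshold).
    """
    n = len(labels)
    parent_entropy = _entropy(_class_counts(labels, classes))
    best: tuple[float, str, float] | None = None   # (-gain_ratio, name, thr)
    for feat in sorted(X.columns):
        values = X[feat].to_numpy(dtype=float)
        order = np.argsort(values, kind="stable")
        v = values[order]
        y = labels[order]
        distinct_idx = np.flatnonzero(np.diff(v)) + 1   # start of each new value
        if distinct_idx.size == 0:
            continue
        # class profile per distinct-value block
        blocks = np.split(np.arange(n), distinct_idx)
        profiles = [frozenset(y[b]) for b in blocks]
        boundaries = []
        for b in range(len(blocks) - 1):
            pure_same = (
                len(profiles[b]) == 1 and profiles[b] == profiles[b + 1]
            )
            if not pure_same:
                boundaries.append(b)
        for b in boundaries:
            n_left = blocks[b][-1] + 1
            if n_left < params.min_leaf or n - n_left < params.min_leaf:
                continue
            thr = 0.5 * (v[n_left - 1] + v[n_left])
            if not (v[n_left - 1] < thr <= v[n_left]):
                continue   # numerically degenerate midpoint
            left_counts = _class_counts(y[:n_left], classes)
            right_counts = _class_counts(y[n_left:], classes)
            gain = parent_entropy - (
                n_left / n * _entropy(left_counts)
                + (n - n_left) / n * _entropy(right_counts)
            )
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([n_left, n - n_left]))
            ratio = gain / split_info
            key = (-ratio, feat, thr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    neg_ratio, feat, thr = best
    return feat, thr, -neg_ratio


def train_tree(
    table: pd.DataFrame, params: TreeParams = TreeParams()
) -> DecisionTree:
    """Grow a gain-ratio decision tree from a labelled feature table."""
    if "label" not in table.columns:
        raise ValidationError("feature table must have a 'label' column")
    if len(table) == 0:
        raise ValidationError("cannot train on an empty table")
    labels = table["label"].to_numpy()
    classes = np.array(sorted(pd.unique(labels)))
    X = table.drop(columns="label")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        y = labels[idx]
        counts = {str(c): int((y == c).sum()) for c in classes}
        node = TreeNode(counts=counts)
        if (
            len(np.unique(y)) <= 1
            or len(idx) < 2 * params.min_leaf
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            return node
        split = _best_split(X.iloc[idx], y, classes, params)
        if split is None:
            return node
        feat, thr, _ = split
        mask = X[feat].to_numpy(dtype=float)[idx] < thr
        node.feature, node.threshold = feat, float(thr)
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    root = grow(np.arange(len(table)), 0)
    if params.prune:
        _pessimistic_prune(root, params.prune_cf)
    return DecisionTree(root=root, params=params, classes=tuple(str(c) for c in classes))


def _ucb_errors(n: int, e: int, cf: float) -> float:
    """Upper confidence bound on the error count of a leaf (C4.5 estimate)."""
    from scipy import stats as sps

    if n == 0:
        return 0.0
    p = sps.beta.ppf(1 - cf, e + 1, n - e) if e < n else 1.0
    return n * p


def _pessimistic_prune(node: TreeNode, cf: float) -> float:
    """Subtree replacement by the pessimistic-error criterion; returns the
    estimated error count of the (possibly pruned) node."""
    n = node.n
    e_leaf = n - node.counts.get(node.prediction, 0)
    est_leaf = _ucb_errors(n, e_leaf, cf)
    if node.is_leaf:
        return est_leaf
    est_subtree = _pessimistic_prune(node.left, cf) + _pessimistic_prune(node.right, cf)
    if est_leaf <= est_subtree + 0.1:
        node.feature = node.threshold = node.left = node.right = None
        return est_leaf
    return est_subtree


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall and F-measure from confusion counts.

    A zero denominator yields ``None`` (undefined, not 0) for that metric.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f = None
        if precision is None or recall is None:
            logger.warning("undefined precision/recall: zero denominator")
    else:
        f = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f_measure": f}


@dataclass
class EvalReport:
    """Cross-validation outcome: pooled per-class metrics + overall accuracy."""

    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    fold_assignments: np.ndarray
    seed: int
    k: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "fold_assignments": self.fold_assignments.tolist(),
            "seed": self.seed,
            "k": self.k,
        }


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded fold assignment, stratified by class when every class has >= k
    rows; otherwise plain shuffled round-robin with a logged warning."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        for c in classes:
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            folds[idx] = np.arange(len(idx)) % k
    else:
        logger.warning(
            "class with fewer than %d rows: falling back to non-stratified folds", k
        )
        idx = rng.permutation(len(labels))
        folds[idx] = np.arange(len(labels)) % k
    return folds


def cross_validate(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    params: TreeParams = TreeParams(),
) -> EvalReport:
    """Seeded stratified k-fold cross-validation with pooled confusion counts.

    Each class is designated positive in turn for per-class precision /
    recall / F; overall accuracy is pooled over folds and identical whichever
    class is called positive.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(table) < k:
        raise ValidationError(f"need at least k={k} rows, got {len(table)}")
    table = table.reset_index(drop=True)
    labels = table["label"].to_numpy()
    folds = _stratified_folds(labels, k, seed)
    predicted = np.empty(len(table), dtype=object)
    for fold in range(k):
        test_mask = folds == fold
        if not test_mask.any():
            continue
        tree = train_tree(table.loc[~test_mask], params)
        predicted[test_mask] = tree.predict(
            table.loc[test_mask].drop(columns="label")
        )
    accuracy = float(np.mean(predicted == labels))
    per_class: dict[str, dict[str, float | None]] = {}
    for c in sorted(pd.unique(labels)):
        cm = ConfusionMatrix(
            tp=int(((predicted == c) & (labels == c)).sum()),
            fp=int(((predicted == c) & (labels != c)).sum()),
            tn=int(((predicted != c) & (labels != c)).sum()),
            fn=int(((predicted != c) & (labels == c)).sum()),
        )
        per_class[str(c)] = compute_metrics(cm)
    return EvalReport(
        accuracy=accuracy, per_class=per_class, fold_assignments=folds,
        seed=seed, k=k,
    )


def detection_threshold_from_tree(
    sd_values: np.ndarray, labels: np.ndarray
) -> float | None:
    """Optimal detection threshold: a depth-1 tree on one SD variable.

    This is how SD-of-MA / SD-of-MG detection thresholds are established
    from labelled fast-start vs routine windows.  Returns None when no
    positive-gain split exists (e.g. identically distributed input).
    """
    table = pd.DataFrame({"sd": np.asarray(sd_values, dtype=float),
                          "label": np.asarray(labels)})
    if len(pd.unique(table["label"])) < 2:
        raise ValidationError("both labels must be present")
    tree = train_tree(table, TreeParams(min_leaf=1, max_depth=1))
    if tree.root.is_leaf:
        return None
    return float(tree.root.threshold)


__all__ = [
    "TreeParams", "TreeNode", "DecisionTree", "ConfusionMatrix", "EvalReport",
    "train_tree", "compute_metrics", "cross_validate",
    "detection_threshold_from_tree",
]
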