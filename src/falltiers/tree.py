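"""Gain-ratio decision tree: C4.5-style binary induction on continuous features.

Candidate splits are midpoints between consecutive distinct sorted values
of each feature.  Among candidates with strictly positive information
gain, the split maximizing gain ratio (information gain divided by split
information, both in bits) is chosen; ties go to the lowest
feature-schema index, then the lowest threshold.  Recursion stops at a
pure node, when fewer than ``2 * min_leaf`` instances remain, or when no
candidate has positive gain; leaves predict their majority class.  No
pruning is applied — the bare induction rule is kept reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .selection import LabeledDataset

MODEL_SCHEMA_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass
class TreeNode:
    """Internal split node (``x[feature] <= threshold`` goes left) or leaf."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    prediction: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.prediction is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


@dataclass
class TrainedModel:
    root: TreeNode
    features: list[str]
    metadata: dict = field(default_factory=dict)


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes])


def split_entropy_stats(y: np.ndarray, mask_left: np.ndarray, classes: Sequence[str]):
    """(information gain, split information) in bits for a boolean partition."""
    n = len(y)
    nl = int(mask_left.sum())
    nr = n - nl
    if nl == 0 or nr == 0:
        raise ValueError("split must leave both sides non-empty")
    h = _entropy_bits(_class_counts(y, classes))
    hl = _entropy_bits(_class_counts(y[mask_left], classes))
    hr = _entropy_bits(_class_counts(y[~mask_left], classes))
    gain = h - (nl / n) * hl - (nr / n) * hr
    split_info = _entropy_bits(np.array([nl, nr]))
    return gain, split_info


def gain_ratio(data: LabeledDataset, feature: str, threshold: float) -> float:
    """Gain ratio of the binary split ``feature <= threshold``."""
    x = data.X[feature].to_numpy(dtype=float)
    gain, split_info = split_entropy_stats(data.y, x <= threshold, data.classes)
    if gain <= 0:
        return 0.0
    return gain / split_info


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values."""
    u = np.unique(values)
    return (u[:-1] + u[1:]) / 2.0


def _best_split(X: pd.DataFrame, y: np.ndarray, classes: list[str]):
    best = None  # (ratio, schema_index, threshold, feature)
    for col_pos, name in enumerate(X.columns):
        order = FEATURE_NAMES.index(name) if name in FEATURE_NAMES else len(FEATURE_NAMES) + col_pos
        x = X[name].to_numpy(dtype=float)
        for thr in candidate_thresholds(x):
            gain, split_info = split_entropy_stats(y, x <= thr, classes)
            if gain <= 1e-12 or split_info <= 0:
                continue
            ratio = gain / split_info
            key = (-ratio, order, thr)
            if best is None or key < best[0]:
                best = (key, name, float(thr))
    if best is None:
        return None
    return best[1], best[2], -best[0][0]


def _grow(X: pd.DataFrame, y: np.ndarray, classes: list[str], min_leaf: int) -> TreeNode:
    counts = {c: int((y == c).sum()) for c in classes}
    majority = max(counts, key=lambda c: (counts[c], -classes.index(c)))
    present = [c for c in classes if counts[c] > 0]
    if len(present) == 1 or len(y) < 2 * min_leaf:
        return TreeNode(prediction=majority, counts=counts)
    found = _best_split(X, y, classes)
    if found is None:
        return TreeNode(prediction=majority, counts=counts)
    feature, threshold, _ = found
    mask = X[feature].to_numpy(dtype=float) <= threshold
    return TreeNode(
        feature=feature,
        threshold=threshold,
        left=_grow(X[mask], y[mask], classes, min_leaf),
        right=_grow(X[~mask], y[~mask], classes, min_leaf),
        counts=counts,
    )


def train_tree(data: LabeledDataset, min_leaf: int = 2, seed: int | None = None) -> TrainedModel:
    """Induce a gain-ratio tree on the dataset's feature columns.

    Induction is deterministic; ``seed`` is recorded in the metadata for
    provenance only.
    """
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    root = _grow(data.X.reset_index(drop=True), data.y, classes, min_leaf)
    return TrainedModel(
        root=root,
        features=list(data.X.columns),
        metadata={
            "seed": seed,
            "min_leaf": min_leaf,
            "classes": classes,
            "n_train": len(data),
            "schema_version": MODEL_SCHEMA_VERSION,
        },
    )


def predict(model: TrainedModel, features: Mapping[str, float] | pd.Series) -> str:
    """Deterministic root-to-leaf traversal; ``<= threshold`` goes left."""
    node = model.root
    while not node.is_leaf:
        if node.feature not in features:
            raise KeyError(f"feature vector is missing feature {node.feature!r}")
        node = node.left if features[node.feature] <= node.threshold else node.right
    return node.prediction


def predict_many(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    return np.array([predict(model, row) for _, row in table.iterrows()], dtype=object)


# ------------------------------------------------------------ model I/O ----


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"leaf": node.prediction, "counts": node.counts}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "counts": node.counts,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(obj: dict, path: str) -> TreeNode:
    if not isinstance(obj, dict):
        raise ModelFormatError(f"expected an object at {path}")
    if "leaf" in obj:
        return TreeNode(prediction=obj["leaf"], counts=dict(obj.get("counts", {})))
    try:
        return TreeNode(
            feature=obj["feature"],
            threshold=float(obj["threshold"]),
            counts=dict(obj.get("counts", {})),
            left=_node_from_dict(obj["left"], path + ".left"),
            right=_node_from_dict(obj["right"], path + ".right"),
        )
    except KeyError as exc:
        raise ModelFormatError(f"missing key {exc} at {path}") from exc


def save_model(model: TrainedModel, path) -> None:
    """Serialize the model as a human-readable JSON tree document."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "features": model.features,
        "metadata": model.metadata,
        "tree": _node_to_dict(model.root),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("features", "tree"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level key {key!r}")
    return TrainedModel(
        root=_node_from_dict(doc["tree"], "tree"),
        features=list(doc["features"]),
        metadata=dict(doc.get("metadata", {})),
    )
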