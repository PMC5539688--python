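"""Feature ranking and top-k selection.

Two rankers are provided.  ``oner_rank`` scores each feature by the
training accuracy of its best one-level rule (a supervised discretization
into intervals, each interval predicting its majority class) — the final
detector configuration keeps the top 5 features by this score.
``relieff_rank`` is the classical Relief weight estimate: a feature gains
weight when it separates an instance from its nearest opposite-class miss
and loses weight when it differs from the nearest same-class hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, LABEL_COLUMN

FALL = "FALL"
NON_FALL = "NON_FALL"


@dataclass
class LabeledDataset:
    """Feature matrix plus per-row class labels."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")

    @classmethod
    def from_table(cls, table: pd.DataFrame, label_column: str = LABEL_COLUMN) -> "LabeledDataset":
        return cls(table.drop(columns=[label_column]), table[label_column].to_numpy())

    def __len__(self) -> int:
        return len(self.y)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.y))

    def project(self, names: Sequence[str]) -> "LabeledDataset":
        """Restrict to a feature subset; rows and labels stay aligned."""
        return LabeledDataset(self.X[list(names)].copy(), self.y.copy())


@dataclass
class FeatureRanking:
    """Features ordered by non-increasing score."""

    entries: list[tuple[str, float]]
    method: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.names,
                "score": [s for _, s in self.entries],
                "rank": np.arange(1, len(self.entries) + 1),
                "method": self.method,
            }
        )


def _schema_order(name: str, columns: Sequence[str]) -> int:
    # Frozen feature-schema order breaks score ties reproducibly; columns
    # outside the schema fall back to their table order.
    try:
        return FEATURE_NAMES.index(name)
    except ValueError:
        return len(FEATURE_NAMES) + list(columns).index(name)


def _sorted_ranking(scores: dict[str, float], columns: Sequence[str], method: str) -> FeatureRanking:
    ordered = sorted(scores, key=lambda n: (-scores[n], _schema_order(n, columns)))
    return FeatureRanking([(n, float(scores[n])) for n in ordered], method)


# ---------------------------------------------------------------- OneR ----


def _oner_intervals(values: np.ndarray, labels: np.ndarray, min_bucket: int, classes: list[str]):
    """Supervised discretization: intervals each holding >= min_bucket
    instances of their majority class (last interval may be smaller);
    adjacent intervals with the same majority class are merged."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    n = len(v)
    buckets: list[dict[str, int]] = []
    i = 0
    while i < n:
        counts: dict[str, int] = {}
        j = i
        while j < n:  # grow until the majority class reaches min_bucket
            counts[y[j]] = counts.get(y[j], 0) + 1
            j += 1
            if counts[_majority(counts, classes)] >= min_bucket:
                break
        majority = _majority(counts, classes)
        # a boundary may not split equal values, and it moves forward over
        # any run of further majority-class instances
        while j < n and (v[j] == v[j - 1] or y[j] == majority):
            counts[y[j]] = counts.get(y[j], 0) + 1
            j += 1
        buckets.append(counts)
        i = j
    # merge adjacent buckets with equal majority class
    merged: list[dict[str, int]] = []
    for b in buckets:
        if merged and _majority(merged[-1], classes) == _majority(b, classes):
            for c, k in b.items():
                merged[-1][c] = merged[-1].get(c, 0) + k
        else:
            merged.append(dict(b))
    return merged


def _majority(counts: dict[str, int], classes: list[str]) -> str:
    return max(counts, key=lambda c: (counts[c], -classes.index(c)))


def oner_rank(data: LabeledDataset, min_bucket: int = 6, seed: int | None = None) -> FeatureRanking:
    """Rank features by one-rule training accuracy (higher is better).

    ``min_bucket`` is the minimum number of majority-class instances per
    discretization interval.  The procedure is deterministic; ``seed`` is
    accepted for interface symmetry with the other rankers.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("ranking requires at least 2 classes")
    scores: dict[str, float] = {}
    for name in data.X.columns:
        buckets = _oner_intervals(data.X[name].to_numpy(dtype=float), data.y, min_bucket, classes)
        correct = sum(b[_majority(b, classes)] for b in buckets)
        scores[name] = correct / len(data)
    return _sorted_ranking(scores, data.X.columns, "oner")


# -------------------------------------------------------------- Relief ----


def relieff_rank(
    data: LabeledDataset,
    n_samples: int | None = None,
    k_neighbors: int = 1,
    seed: int | None = None,
) -> FeatureRanking:
    """Classical Relief feature weights, min-max normalized, binary classes.

    For each sampled instance the weight of every feature moves up by its
    normalized distance to the nearest miss and down by its distance to the
    nearest hit, averaged over samples (and over ``k_neighbors`` neighbors).
    """
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("Relief requires at least 2 classes")
    for c in classes:
        if (data.y == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 instances")
    X = data.X.to_numpy(dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = (X - lo) / span
    Xn[:, hi == lo] = 0.0  # constant features contribute nothing

    n = len(data)
    rng = np.random.default_rng(seed)
    if n_samples is None or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=n_samples, replace=False)

    w = np.zeros(Xn.shape[1])
    for i in sample_idx:
        d = np.abs(Xn - Xn[i]).sum(axis=1)
        same = data.y == data.y[i]
        hit_pool = np.flatnonzero(same)
        hit_pool = hit_pool[hit_pool != i]
        miss_pool = np.flatnonzero(~same)
        k = min(k_neighbors, len(hit_pool), len(miss_pool))
        hits = hit_pool[np.argsort(d[hit_pool], kind="stable")[:k]]
        misses = miss_pool[np.argsort(d[miss_pool], kind="stable")[:k]]
        for h, m in zip(hits, misses):
            w += (np.abs(Xn[m] - Xn[i]) - np.abs(Xn[h] - Xn[i])) / (len(sample_idx) * k)
    scores = dict(zip(data.X.columns, w))
    return _sorted_ranking(scores, data.X.columns, "relieff")


def select_top_k(ranking: FeatureRanking, k: int = 5) -> list[str]:
    """First k feature names of the ranking, in rank order."""
    if not 1 <= k <= len(ranking.entries):
        raise ValueError(f"k must be in [1, {len(ranking.entries)}], got {k}")
    return ranking.names[:k]
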