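"""Time-domain feature extraction: 43 features per frame.

Per axis (x, y, z): average, population standard deviation, maximum,
average absolute consecutive difference, and a 10-bin equal-width binned
distribution over the frame's own [min, max] range (fractions).  Plus one
scalar, the average resultant acceleration — the mean per-sample signal
vector magnitude.  3×(1+1+1+1+10) + 1 = 43.

Feature names and their order are frozen in :data:`FEATURE_NAMES`; trained
models and feature tables index by these names so vectors never mis-align.
All acceleration-valued features are in m/s²; bin fractions are
dimensionless and sum to 1 per axis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .signal_model import AccelFrame

AXES = ("x", "y", "z")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"avg_{a}" for a in AXES]
    + [f"std_{a}" for a in AXES]
    + [f"max_{a}" for a in AXES]
    + [f"acd_{a}" for a in AXES]
    + ["ara"]
    + [f"bin_{a}_{i}" for a in AXES for i in range(10)]
)

N_FEATURES = len(FEATURE_NAMES)  # 43

LABEL_COLUMN = "label"


def average_resultant_acceleration(frame: AccelFrame) -> float:
    """Mean per-sample signal vector magnitude over the frame, m/s²."""
    if len(frame) == 0:
        raise ValueError("frame is empty")
    return float(np.linalg.norm(frame.data, axis=1).mean())


def binned_distribution(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Fraction of values in each of ``n_bins`` equal-width bins over [min, max].

    The last bin is right-closed, the others right-open.  A degenerate range
    (max == min) puts all mass in bin 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    lo, hi = v.min(), v.max()
    out = np.zeros(n_bins)
    if hi == lo:
        out[0] = 1.0
        return out
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)
    np.add.at(out, idx, 1.0)
    return out / v.size


def extract_features(frame: AccelFrame) -> pd.Series:
    """Compute the 43-feature vector of a frame, indexed by FEATURE_NAMES."""
    if len(frame) < 2:
        raise ValueError("feature extraction needs at least 2 samples per frame")
    d = frame.data
    avg = d.mean(axis=0)
    std = d.std(axis=0)  # population (divide by N)
    mx = d.max(axis=0)
    acd = np.abs(np.diff(d, axis=0)).mean(axis=0)
    ara = average_resultant_acceleration(frame)
    bins = np.concatenate([binned_distribution(d[:, k]) for k in range(3)])
    values = np.concatenate([avg, std, mx, acd, [ara], bins])
    return pd.Series(values, index=list(FEATURE_NAMES))


def feature_table(frames: Sequence[AccelFrame], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Feature vectors for many frames as one DataFrame (plus a label column).

    Labels default to each frame's own ``label`` attribute.
    """
    rows = [extract_features(f) for f in frames]
    table = pd.DataFrame(rows).reset_index(drop=True)
    if labels is None:
        labels = [f.label for f in frames]
    table[LABEL_COLUMN] = list(labels)
    return table
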