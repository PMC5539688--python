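"""Evaluation statistics: confusion matrices, sensitivity/specificity,
F-measure, class-balanced accuracy, McNemar comparison, and ROC-style
threshold calibration for the DT tier.

Events (not frames) are the unit of scoring: a fall event counts as
detected when at least one of its frames is decided FALL, matching how a
monitoring system is judged in practice.  A frame-level view is available
separately for long false-positive analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .double_threshold import DTConfig, DTRegion, classify_dt, frame_sv
from .engine import EngineConfig, Outcome, TierDecision
from .pre_elimination import frame_is_motionless
from .selection import FALL
from .signal_model import AccelFrame, StreamConfig


def round_pct(value: float, ndigits: int = 1) -> float:
    """Half-up rounding for reported percentages (raw values keep full precision)."""
    factor = 10**ndigits
    return math.floor(value * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with FALL as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def sensitivity(cm: ConfusionMatrix) -> float:
    """Recall on falls, percent: 100·TP/(TP+FN)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no positive events")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Recall on non-falls, percent: 100·TN/(TN+FP)."""
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no negative events")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def f_measure(cm: ConfusionMatrix) -> float:
    """F-measure on the fall class: 2·TP / (2·TP + FP + FN)."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise ValueError("F-measure undefined: no positives predicted or present")
    return 2 * cm.tp / denom


def balanced_accuracy(sensitivity_pct: float, specificity_pct: float) -> float:
    """Mean of sensitivity and specificity (percent) — neutral to class imbalance."""
    for v in (sensitivity_pct, specificity_pct):
        if not 0 <= v <= 100:
            raise ValueError("sensitivity/specificity must be percentages in [0, 100]")
    return (sensitivity_pct + specificity_pct) / 2.0


# -------------------------------------------------------------- McNemar ----


@dataclass(frozen=True)
class PairedOutcomes:
    """Discordant counts of two methods on the same events: ``b`` events
    method A got right and B wrong, ``c`` the reverse."""

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("discordant counts must be non-negative")

    @classmethod
    def from_correctness(cls, a_correct: Sequence[bool], b_correct: Sequence[bool]) -> "PairedOutcomes":
        a = np.asarray(a_correct, dtype=bool)
        b = np.asarray(b_correct, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("correctness vectors must have equal length")
        return cls(int((a & ~b).sum()), int((~a & b).sum()))


def mcnemar_test(
    pairs: PairedOutcomes,
    continuity_correction: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Asymptotic McNemar test on the discordant pair counts.

    Statistic (b−c)²/(b+c) — or (|b−c|−1)²/(b+c) with the continuity
    correction, floored at 0 — referred to chi-square with 1 df.  The
    default p-value is two-sided; ``alternative="greater"`` halves it for
    the directional hypothesis that method A beats method B (b > c).
    """
    b, c = pairs.b, pairs.c
    if b + c == 0:
        raise ValueError("McNemar test undefined with no discordant pairs")
    if continuity_correction:
        num = max(abs(b - c) - 1, 0) ** 2
    else:
        num = (b - c) ** 2
    statistic = num / (b + c)
    p = float(sps.chi2.sf(statistic, df=1))
    if alternative == "two-sided":
        return statistic, p
    if alternative == "greater":
        return statistic, p / 2 if b >= c else 1 - p / 2
    raise ValueError(f"unknown alternative {alternative!r}")


def mcnemar_exact(pairs: PairedOutcomes) -> float:
    """Exact binomial sign-test p-value (two-sided), the small-sample oracle."""
    b, c = pairs.b, pairs.c
    if b + c == 0:
        raise ValueError("undefined with no discordant pairs")
    res = sps.binomtest(min(b, c), b + c, 0.5, alternative="two-sided")
    return float(res.pvalue)


# --------------------------------------------------------- run scoring ----


def _as_decision_table(decisions) -> pd.DataFrame:
    if isinstance(decisions, pd.DataFrame):
        return decisions
    from .engine import decisions_frame

    return decisions_frame(list(decisions))


def evaluate_run(
    decisions,
    manifest: pd.DataFrame,
    group_by: str | None = None,
) -> ConfusionMatrix | dict[str, ConfusionMatrix]:
    """Event-level confusion matrix of a pipeline run against a manifest.

    An event is detected when at least one frame of its (inclusive) span
    was decided FALL.  ``group_by`` names a manifest column to aggregate
    per group (e.g. ``kind``).
    """
    table = _as_decision_table(decisions)
    decided = dict(zip(table["frame_index"], table["outcome"]))
    required = ("event_id", "label", "start_frame", "end_frame")
    for col in required:
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")

    def _score(rows: pd.DataFrame) -> ConfusionMatrix:
        tp = fp = fn = tn = 0
        for row in rows.itertuples():
            span = range(int(row.start_frame), int(row.end_frame) + 1)
            missing = [i for i in span if i not in decided]
            if missing:
                raise ValueError(
                    f"event {row.event_id}: no decision for frame {missing[0]}"
                )
            detected = any(decided[i] == Outcome.FALL.value for i in span)
            if row.label == FALL:
                tp += detected
                fn += not detected
            else:
                fp += detected
                tn += not detected
        return ConfusionMatrix(tp, fp, fn, tn)

    if group_by is None:
        return _score(manifest)
    return {key: _score(rows) for key, rows in manifest.groupby(group_by, sort=True)}


def frame_false_positive_rate(decisions, frame_labels: pd.DataFrame) -> float:
    """Fraction of truly non-fall frames decided FALL — the long-run
    daily false-alarm view."""
    table = _as_decision_table(decisions)
    merged = table.merge(frame_labels, on="frame_index", how="inner")
    neg = merged[merged["label"] != FALL]
    if len(neg) == 0:
        raise ValueError("no non-fall frames to score")
    return float((neg["outcome"] == Outcome.FALL.value).mean())


# ----------------------------------------------------------- calibration ----


def _dt_only_event_status(
    frames: Sequence[AccelFrame],
    sv: np.ndarray,
    motionless: np.ndarray,
    manifest_row,
    dt_cfg: DTConfig,
) -> tuple[bool, bool]:
    """(detected_by_dt, touched_region_ii) for one event span."""
    detected = False
    ambiguous = False
    for i in range(int(manifest_row.start_frame), int(manifest_row.end_frame) + 1):
        if motionless[i] or i + 1 >= len(frames):
            continue
        decision = classify_dt(sv[i], sv[i + 1], dt_cfg)
        if decision.region is DTRegion.III:
            detected = True
        elif decision.region is DTRegion.II:
            ambiguous = True
    return detected, ambiguous


def calibrate_thresholds(
    trace,
    manifest: pd.DataFrame,
    grid: Iterable[DTConfig],
    mode: str = "oracle",
    config: EngineConfig | None = None,
) -> tuple[pd.DataFrame, DTConfig]:
    """Sweep DT threshold triples over a labeled trace and score each point.

    For every grid point the PE and DT tiers run as in the pipeline.  In
    ``"oracle"`` mode a region-II event is resolved by its true label (an
    upper bound assuming a perfect ML tier); in ``"exclude"`` mode events
    whose fate rests on region II are dropped from that grid point's
    scoring.  Returns the full TPR/FPR table and the grid point with
    maximal TPR among those attaining the minimal FPR.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if mode not in ("oracle", "exclude"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    config = config or EngineConfig()
    frames = trace.frames(config.stream) if hasattr(trace, "frames") else list(trace)
    sv = np.array([frame_sv(f, config.stream) for f in frames])
    motionless = np.array([frame_is_motionless(f, config.pe) for f in frames])

    rows = []
    for cfg in grid:
        tp = fp = fn = tn = 0
        for row in manifest.itertuples():
            detected, ambiguous = _dt_only_event_status(frames, sv, motionless, row, cfg)
            is_fall = row.label == FALL
            if not detected and ambiguous:
                if mode == "exclude":
                    continue
                detected = is_fall  # oracle ML resolves region II correctly
            if is_fall:
                tp += detected
                fn += not detected
            else:
                fp += detected
                tn += not detected
        tpr = tp / (tp + fn) if tp + fn else float("nan")
        fpr = fp / (fp + tn) if fp + tn else float("nan")
        rows.append(
            {
                "th_low": cfg.th_low,
                "th_high": cfg.th_high,
                "th_inactivity": cfg.th_inactivity,
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "tpr": tpr, "fpr": fpr,
            }
        )
    table = pd.DataFrame(rows)
    # lexicographic choice: minimal FPR first, then maximal TPR, then grid order
    order = sorted(
        range(len(grid)),
        key=lambda i: (table["fpr"][i], -table["tpr"][i], i),
    )
    return table, grid[order[0]]
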