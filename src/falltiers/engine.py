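"""Three-tier detection engine: PE → DT → ML over a frame stream.

Each frame is first offered to the pre-elimination tier; a motionless
frame is discarded there and incurs no further computation.  A moving
frame is classified by double thresholding against the next frame's
signal-vector magnitude (one-frame lookahead, ≈ one frame of latency);
only region-II frames pay for feature extraction and a tree prediction.
Per-tier call counters make this energy-saving routing observable.

The final frame of a finite stream has no successor for the DT lookahead:
it is resolved by PE if motionless and otherwise reported with the
``AMBIGUOUS_END`` sentinel outcome (a continuously monitoring device
never reaches this case).

A 20-second alert-cancellation state machine (:func:`step_alert`) and a
double-buffered sample feed mirroring the acquisition/detection split of
the deployed system are included; both run in simulated time.
"""

from __future__ import annotations

import enum
import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .double_threshold import DTConfig, DTOutcome, DTRegion, classify_dt, frame_sv
from .features import extract_features
from .pre_elimination import PEConfig, frame_is_motionless
from .selection import FALL
from .signal_model import AccelFrame, AccelSample, StreamConfig, frame_stream
from .tree import TrainedModel, predict

logger = logging.getLogger("falltiers")


class Outcome(str, enum.Enum):
    ELIMINATED_MOTIONLESS = "ELIMINATED_MOTIONLESS"
    DAILY_ACTIVITY = "DAILY_ACTIVITY"
    FALL = "FALL"
    AMBIGUOUS_END = "AMBIGUOUS_END"  # last frame of a finite stream, not motionless


class Tier(str, enum.Enum):
    PE = "PE"
    DT = "DT"
    ML = "ML"


@dataclass(frozen=True)
class TierDecision:
    """Outcome of one frame's trip through the tiers, with provenance."""

    frame_index: int
    t_start: float
    outcome: Outcome
    decided_by: Tier
    dt_region: DTRegion | None = None
    ml_label: str | None = None
    sv_t: float | None = None
    sv_t1: float | None = None

    def __post_init__(self) -> None:
        if self.decided_by is Tier.PE and self.outcome is not Outcome.ELIMINATED_MOTIONLESS:
            raise ValueError("PE decisions must be ELIMINATED_MOTIONLESS")
        if self.decided_by is not Tier.PE and self.outcome is Outcome.ELIMINATED_MOTIONLESS:
            raise ValueError("only PE may eliminate a frame")
        if self.outcome is Outcome.FALL and self.decided_by is Tier.DT and self.dt_region is not DTRegion.III:
            raise ValueError("a DT fall must come from region III")


@dataclass
class RoutingStats:
    """How many frames each tier resolved — the energy-saving accounting."""

    pe: int = 0
    dt: int = 0
    ml: int = 0

    @property
    def total(self) -> int:
        return self.pe + self.dt + self.ml

    def fractions(self) -> dict[str, float]:
        n = self.total
        if n == 0:
            return {"pe": 0.0, "dt": 0.0, "ml": 0.0}
        return {"pe": self.pe / n, "dt": self.dt / n, "ml": self.ml / n}


@dataclass
class CallCounters:
    """Observability of per-tier work (the computational energy proxy)."""

    pe_checks: int = 0
    sv_computations: int = 0
    feature_extractions: int = 0
    tree_predictions: int = 0


@dataclass
class EngineConfig:
    stream: StreamConfig = field(default_factory=StreamConfig)
    pe: PEConfig = field(default_factory=PEConfig)
    dt: DTConfig = field(default_factory=DTConfig)


class Detector:
    """Stateful three-tier detector over whole frames.

    ``model`` may be None for streams that never reach region II; a
    region-II frame without a model raises.
    """

    def __init__(self, config: EngineConfig | None = None, model: TrainedModel | None = None):
        self.config = config or EngineConfig()
        self.model = model
        self.counters = CallCounters()
        self._sv_cache: dict[int, float] = {}

    def _frame_sv(self, frame: AccelFrame) -> float:
        if frame.frame_index not in self._sv_cache:
            self.counters.sv_computations += 1
            self._sv_cache[frame.frame_index] = frame_sv(frame, self.config.stream)
        return self._sv_cache[frame.frame_index]

    def decide(self, frame: AccelFrame, next_frame: AccelFrame | None) -> TierDecision:
        """Decide one frame given its successor (None at end of stream)."""
        self.counters.pe_checks += 1
        if frame_is_motionless(frame, self.config.pe):
            return TierDecision(
                frame.frame_index, frame.t_start, Outcome.ELIMINATED_MOTIONLESS, Tier.PE
            )
        if next_frame is None:
            logger.info("frame %d: stream ended before DT lookahead", frame.frame_index)
            return TierDecision(frame.frame_index, frame.t_start, Outcome.AMBIGUOUS_END, Tier.DT)
        sv_t = self._frame_sv(frame)
        sv_t1 = self._frame_sv(next_frame)
        dt_decision = classify_dt(sv_t, sv_t1, self.config.dt)
        if dt_decision.outcome is DTOutcome.HARSH_FALL:
            return TierDecision(
                frame.frame_index, frame.t_start, Outcome.FALL, Tier.DT,
                dt_region=dt_decision.region, sv_t=sv_t, sv_t1=sv_t1,
            )
        if dt_decision.outcome is DTOutcome.DAILY_ACTIVITY:
            return TierDecision(
                frame.frame_index, frame.t_start, Outcome.DAILY_ACTIVITY, Tier.DT,
                dt_region=dt_decision.region, sv_t=sv_t, sv_t1=sv_t1,
            )
        # region II → ML tier
        if self.model is None:
            raise ValueError(
                f"frame {frame.frame_index} reached region II but no trained model is configured"
            )
        self.counters.feature_extractions += 1
        features = extract_features(frame)
        self.counters.tree_predictions += 1
        label = predict(self.model, features)
        outcome = Outcome.FALL if label == FALL else Outcome.DAILY_ACTIVITY
        return TierDecision(
            frame.frame_index, frame.t_start, outcome, Tier.ML,
            dt_region=dt_decision.region, ml_label=label, sv_t=sv_t, sv_t1=sv_t1,
        )


def run_pipeline(
    frames: Sequence[AccelFrame],
    config: EngineConfig | None = None,
    model: TrainedModel | None = None,
) -> tuple[list[TierDecision], RoutingStats, CallCounters]:
    """Run the three tiers over a finite frame sequence (batch mode)."""
    detector = Detector(config, model)
    decisions = []
    for i, frame in enumerate(frames):
        nxt = frames[i + 1] if i + 1 < len(frames) else None
        decisions.append(detector.decide(frame, nxt))
    stats = RoutingStats()
    for d in decisions:
        setattr(stats, d.decided_by.value.lower(), getattr(stats, d.decided_by.value.lower()) + 1)
    return decisions, stats, detector.counters


def decisions_frame(decisions: Sequence[TierDecision]) -> pd.DataFrame:
    """Decisions as a tidy DataFrame (the ``detect`` CSV layout)."""
    return pd.DataFrame(
        {
            "frame_index": [d.frame_index for d in decisions],
            "t_start": [d.t_start for d in decisions],
            "outcome": [d.outcome.value for d in decisions],
            "decided_by": [d.decided_by.value for d in decisions],
            "region": [d.dt_region.value if d.dt_region else "" for d in decisions],
            "sv_t": [d.sv_t if d.sv_t is not None else np.nan for d in decisions],
            "sv_t1": [d.sv_t1 if d.sv_t1 is not None else np.nan for d in decisions],
        }
    )


# ------------------------------------------------------------ streaming ----


class StreamingDetector:
    """Incremental frame-at-a-time detector, equivalent to batch mode.

    Frames are pushed as they complete; each push may release the decision
    for the previous frame (DT needs one frame of lookahead, PE does not).
    ``finish()`` flushes the final frame under the end-of-stream rule.
    """

    def __init__(self, config: EngineConfig | None = None, model: TrainedModel | None = None):
        self._detector = Detector(config, model)
        self._pending: AccelFrame | None = None
        self._pending_decision: TierDecision | None = None

    @property
    def counters(self) -> CallCounters:
        return self._detector.counters

    def push(self, frame: AccelFrame) -> list[TierDecision]:
        out = []
        if self._pending is not None:
            out.append(self._detector.decide(self._pending, frame))
        self._pending = frame
        return out

    def finish(self) -> list[TierDecision]:
        if self._pending is None:
            return []
        decision = self._detector.decide(self._pending, None)
        self._pending = None
        return [decision]


class DoubleBufferFeed:
    """Sample-level ingestion through two swap buffers.

    One buffer fills with incoming samples while the other, once full, is
    handed to the detector as a whole frame; ingestion therefore never
    waits on decision computation, and no sample is lost or duplicated
    (``ingested == framed + remainder``).  If the consumer lags, completed
    frames queue up (with a warning) rather than being dropped.
    """

    def __init__(self, engine: StreamingDetector, config: StreamConfig | None = None):
        self.engine = engine
        self.config = config or StreamConfig()
        self._buffers: list[list[AccelSample]] = [[], []]
        self._active = 0
        self._frame_queue: deque[AccelFrame] = deque()
        self._next_frame_index = 0
        self.ingested = 0
        self.framed = 0

    def push_sample(self, sample: AccelSample, consumer_ready: bool = True) -> list[TierDecision]:
        """Ingest one sample; returns any decisions the consumer produced."""
        n = self.config.frame_length
        buf = self._buffers[self._active]
        buf.append(sample)
        self.ingested += 1
        if len(buf) == n:
            data = np.array([[s.ax, s.ay, s.az] for s in buf])
            t = np.array([s.t for s in buf])
            self._frame_queue.append(AccelFrame(data, t, frame_index=self._next_frame_index))
            self._next_frame_index += 1
            self.framed += n
            self._buffers[self._active] = []
            self._active = 1 - self._active
            if len(self._frame_queue) > 1:
                logger.warning("detector lagging: %d frames queued", len(self._frame_queue))
        return self._drain() if consumer_ready else []

    def _drain(self) -> list[TierDecision]:
        out: list[TierDecision] = []
        while self._frame_queue:
            out.extend(self.engine.push(self._frame_queue.popleft()))
        return out

    def finish(self) -> list[TierDecision]:
        """Flush queued frames and the engine's pending final frame.

        The remainder (a partial buffer) is discarded, as in framing.
        """
        out = self._drain()
        out.extend(self.engine.finish())
        return out

    @property
    def remainder(self) -> int:
        return len(self._buffers[self._active])


# ---------------------------------------------------------- alert (EAM) ----


class AlertPhase(str, enum.Enum):
    IDLE = "IDLE"
    ALARM_PENDING = "ALARM_PENDING"
    CANCELLED = "CANCELLED"
    NOTIFIED = "NOTIFIED"


@dataclass(frozen=True)
class AlertState:
    """Alert-handling FSM: an alarm can be cancelled within a fixed window,
    after which a notification is handed to the configured sink."""

    phase: AlertPhase = AlertPhase.IDLE
    alarm_start_time: float | None = None
    cancel_window_seconds: float = 20.0


def step_alert(
    state: AlertState,
    event: str,
    t: float | None = None,
    sink: Callable[[float], None] | None = None,
) -> AlertState:
    """Advance the alert FSM by one event.

    ``event`` is ``"FALL_DETECTED"``, ``"CANCEL_PRESSED"`` or ``"TICK"``;
    ``t`` is the simulated time in seconds (required for FALL_DETECTED and
    TICK).  On notification the optional ``sink`` callable receives the
    notification time.
    """
    if event == "FALL_DETECTED":
        if t is None:
            raise ValueError("FALL_DETECTED requires a time")
        if state.phase is AlertPhase.ALARM_PENDING:
            return state  # alarm already running
        return replace(state, phase=AlertPhase.ALARM_PENDING, alarm_start_time=float(t))
    if event == "CANCEL_PRESSED":
        if state.phase is not AlertPhase.ALARM_PENDING:
            logger.info("cancel pressed with no pending alarm; ignored")
            return state
        return replace(state, phase=AlertPhase.CANCELLED)
    if event == "TICK":
        if t is None:
            raise ValueError("TICK requires a time")
        if (
            state.phase is AlertPhase.ALARM_PENDING
            and t - state.alarm_start_time >= state.cancel_window_seconds
        ):
            if sink is not None:
                sink(float(t))
            return replace(state, phase=AlertPhase.NOTIFIED)
        return state
    raise ValueError(f"unknown alert event {event!r}")
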