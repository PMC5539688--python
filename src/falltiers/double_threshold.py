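"""Double-thresholding (DT) tier.

The tier compares the signal vector magnitude (SV — the Euclidean norm of
the three axes, ≈ 1 g at rest) of the event frame, SV_t, and of the
following frame, SV_t+1, against three thresholds expressed in g:

* ``SV_t ≤ Th_low`` — slow daily activity (regions I/VI);
* ``SV_t > Th_low`` and ``SV_t+1 ≥ Th_inactivity`` — daily activity, the
  subject keeps moving afterwards (regions IV/V);
* ``SV_t > Th_high`` and ``SV_t+1 < Th_inactivity`` — harsh fall followed
  by inactivity (region III);
* otherwise (moderate impact, then inactivity) — ambiguous (region II),
  deferred to the machine-learning tier.

Per-frame SV is the maximum per-sample SV within the frame: the impact
peak determines the event's severity, and the post-frame maximum is the
strictest test of inactivity.  Boundary ties are resolved as written above
so the four regions form a true partition of the quarter-plane.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .signal_model import AccelFrame, AccelSample, StreamConfig


class DTOutcome(str, enum.Enum):
    DAILY_ACTIVITY = "DAILY_ACTIVITY"
    HARSH_FALL = "HARSH_FALL"
    AMBIGUOUS = "AMBIGUOUS"


class DTRegion(str, enum.Enum):
    I_VI = "I_VI"
    II = "II"
    III = "III"
    IV_V = "IV_V"


_REGION_OUTCOME = {
    DTRegion.I_VI: DTOutcome.DAILY_ACTIVITY,
    DTRegion.IV_V: DTOutcome.DAILY_ACTIVITY,
    DTRegion.III: DTOutcome.HARSH_FALL,
    DTRegion.II: DTOutcome.AMBIGUOUS,
}


@dataclass(frozen=True)
class DTConfig:
    """Calibrated SV thresholds, in g."""

    th_low: float = 1.5
    th_high: float = 2.4
    th_inactivity: float = 1.3

    def __post_init__(self) -> None:
        if not (0 < self.th_inactivity < self.th_low < self.th_high):
            raise ValueError(
                "thresholds must satisfy 0 < th_inactivity < th_low < th_high, got "
                f"({self.th_inactivity}, {self.th_low}, {self.th_high})"
            )


@dataclass(frozen=True)
class DTDecision:
    outcome: DTOutcome
    region: DTRegion
    sv_t: float
    sv_t1: float

    def __post_init__(self) -> None:
        if _REGION_OUTCOME[self.region] is not self.outcome:
            raise ValueError(f"outcome {self.outcome} inconsistent with region {self.region}")


def sum_vector(sample: AccelSample) -> float:
    """Signal vector magnitude sqrt(ax² + ay² + az²), in the input's units."""
    return math.sqrt(sample.ax**2 + sample.ay**2 + sample.az**2)


def frame_sv(frame: AccelFrame, config: StreamConfig | None = None) -> float:
    """Maximum per-sample SV over the frame, converted to g."""
    if len(frame) == 0:
        raise ValueError("frame_sv of an empty frame is undefined")
    config = config or StreamConfig()
    sv = np.linalg.norm(frame.data, axis=1)
    return float(sv.max() / config.gravity_ms2)


def classify_dt(sv_t: float, sv_t1: float, cfg: DTConfig | None = None) -> DTDecision:
    """Classify an (SV_t, SV_t+1) pair, both in g, into its DT region."""
    cfg = cfg or DTConfig()
    if sv_t < 0 or sv_t1 < 0:
        raise ValueError("SV values must be non-negative")
    if sv_t <= cfg.th_low:
        region = DTRegion.I_VI
    elif sv_t1 >= cfg.th_inactivity:
        region = DTRegion.IV_V
    elif sv_t > cfg.th_high:
        region = DTRegion.III
    else:
        region = DTRegion.II
    return DTDecision(_REGION_OUTCOME[region], region, sv_t=sv_t, sv_t1=sv_t1)
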