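"""Pre-elimination (PE) tier: cheap rejection of motionless periods.

A pair of successive readings is *motionless* when the L1 norm of the
per-axis differences stays strictly below a threshold,

    |x1 − x2| + |y1 − y2| + |z1 − z2| < Th_PE,

and a whole frame is eliminated only when every successive pair inside it
is motionless, so a single spike always escapes elimination and reaches the
downstream tiers.  The threshold is applied to raw readings in m/s².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import AccelFrame, AccelSample

#: Calibrated L1-difference threshold (m/s²).
DEFAULT_TH_PE = 7.0


@dataclass(frozen=True)
class PEConfig:
    th_pe: float = DEFAULT_TH_PE

    def __post_init__(self) -> None:
        if not self.th_pe > 0:
            raise ValueError("th_pe must be positive")


def pair_is_motionless(s1: AccelSample, s2: AccelSample, cfg: PEConfig | None = None) -> bool:
    """True iff the L1 difference of two successive readings is < th_pe."""
    cfg = cfg or PEConfig()
    diff = abs(s1.ax - s2.ax) + abs(s1.ay - s2.ay) + abs(s1.az - s2.az)
    return diff < cfg.th_pe


def max_pair_l1(frame: AccelFrame) -> float:
    """Largest L1 difference over the frame's successive sample pairs."""
    if len(frame) < 2:
        raise ValueError("frame must contain at least 2 samples")
    return float(np.abs(np.diff(frame.data, axis=0)).sum(axis=1).max())


def frame_is_motionless(frame: AccelFrame, cfg: PEConfig | None = None) -> bool:
    """True iff every successive pair within the frame is motionless."""
    cfg = cfg or PEConfig()
    return max_pair_l1(frame) < cfg.th_pe
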