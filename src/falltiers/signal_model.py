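"""Accelerometer stream representation, unit conventions, framing and CSV I/O.

The canonical in-memory stream container is a :class:`pandas.DataFrame` with
columns ``t, ax, ay, az`` — time in seconds and per-axis acceleration in
m/s² (the raw Android convention, where a device at rest reads a vector of
magnitude ≈ 9.81 m/s²).  Individual readings are exposed as
:class:`AccelSample` named tuples, and classification operates on
:class:`AccelFrame` windows of ``N`` consecutive samples (60 at the default
20 Hz × 3 s framing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("falltiers")

#: Standard gravity, m/s² per g.
STANDARD_GRAVITY = 9.80665

STREAM_COLUMNS = ("t", "ax", "ay", "az")


class StreamError(ValueError):
    """Raised for malformed stream files (bad header, cells, or timestamps)."""


class AccelSample(NamedTuple):
    """One tri-axial accelerometer reading.

    ``t`` is the timestamp in seconds; ``ax, ay, az`` are accelerations in
    m/s² along the device axes.
    """

    t: float
    ax: float
    ay: float
    az: float


@dataclass(frozen=True)
class StreamConfig:
    """Sampling and unit conventions of a stream.

    Parameters
    ----------
    sampling_rate_hz
        Nominal sampling rate (default 20 Hz).
    frame_seconds
        Window length used for classification (default 3 s).
    gravity_ms2
        Conversion constant between m/s² and g.
    """

    sampling_rate_hz: float = 20.0
    frame_seconds: float = 3.0
    gravity_ms2: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.frame_seconds <= 0:
            raise ValueError("sampling_rate_hz and frame_seconds must be positive")
        if self.gravity_ms2 <= 0:
            raise ValueError("gravity_ms2 must be positive")
        n = self.sampling_rate_hz * self.frame_seconds
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"sampling_rate_hz * frame_seconds must be a positive integer, got {n}"
            )

    @property
    def frame_length(self) -> int:
        """Number of samples per frame (N)."""
        return int(round(self.sampling_rate_hz * self.frame_seconds))

    @property
    def sampling_interval(self) -> float:
        """Nominal spacing between samples in seconds."""
        return 1.0 / self.sampling_rate_hz


@dataclass
class AccelFrame:
    """One fixed-length window of consecutive samples — the unit of classification.

    ``data`` is an (N, 3) float array of per-axis accelerations in m/s²;
    ``t`` the matching (N,) array of timestamps.
    """

    data: np.ndarray
    t: np.ndarray
    frame_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("frame data must be an (N, 3) array")
        if self.t.shape != (self.data.shape[0],):
            raise ValueError("timestamps must match the number of samples")
        if not np.all(np.isfinite(self.data)) or not np.all(np.isfinite(self.t)):
            raise ValueError("frame contains non-finite values")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    def samples(self) -> list[AccelSample]:
        """The frame's readings as :class:`AccelSample` tuples, in order."""
        return [AccelSample(float(t), *map(float, row)) for t, row in zip(self.t, self.data)]


def to_g(value, config: StreamConfig | None = None):
    """Convert acceleration from m/s² to g."""
    g = (config or StreamConfig()).gravity_ms2
    return value / g


def to_ms2(value, config: StreamConfig | None = None):
    """Convert acceleration from g to m/s²."""
    g = (config or StreamConfig()).gravity_ms2
    return value * g


def load_stream(path, config: StreamConfig | None = None) -> pd.DataFrame:
    """Read a ``t,ax,ay,az`` CSV stream.

    Returns the samples in file order as a DataFrame with columns
    ``t, ax, ay, az``.  Raises :class:`StreamError` naming the offending
    data row (1-based, excluding the header) for a missing column, a
    non-numeric cell, or a time step backwards.
    """
    config = config or StreamConfig()
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise StreamError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[list(STREAM_COLUMNS)]
    out = {}
    for col in STREAM_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if bad.size:
            row = int(bad[0]) + 1
            raise StreamError(
                f"{path}: non-numeric or non-finite value {df[col].iloc[bad[0]]!r} "
                f"in column {col!r} at data row {row}"
            )
        out[col] = values.to_numpy(dtype=float)
    stream = pd.DataFrame(out)
    dt = np.diff(stream["t"].to_numpy())
    if (dt < 0).any():
        row = int(np.flatnonzero(dt < 0)[0]) + 2
        raise StreamError(f"{path}: time decreases at data row {row}")
    _check_regularity(stream["t"].to_numpy(), config)
    return stream


def save_stream(stream: pd.DataFrame, path) -> None:
    """Write a stream DataFrame back to the ``t,ax,ay,az`` CSV format."""
    stream.loc[:, list(STREAM_COLUMNS)].to_csv(path, index=False)


def _check_regularity(t: np.ndarray, config: StreamConfig) -> None:
    # Gaps outside ±50% of the nominal interval only warn: framing proceeds
    # by sample count, matching fixed-rate hardware sampling.
    if t.size < 2:
        return
    dt = np.diff(t)
    nominal = config.sampling_interval
    irregular = (dt < 0.5 * nominal) | (dt > 1.5 * nominal)
    if irregular.any():
        logger.warning(
            "stream has %d/%d sample gaps outside ±50%% of the nominal %.4g s "
            "interval; framing proceeds by sample count",
            int(irregular.sum()),
            dt.size,
            nominal,
        )


def frame_stream(
    stream: pd.DataFrame | Sequence[AccelSample],
    config: StreamConfig | None = None,
    labels: Sequence[str | None] | None = None,
) -> list[AccelFrame]:
    """Block a stream into consecutive, non-overlapping N-sample frames.

    A trailing remainder shorter than one frame is dropped.  ``labels``, if
    given, assigns ``labels[i]`` to frame ``i``.
    """
    config = config or StreamConfig()
    if not isinstance(stream, pd.DataFrame):
        stream = pd.DataFrame(stream, columns=list(STREAM_COLUMNS))
    n = config.frame_length
    data = stream[["ax", "ay", "az"]].to_numpy(dtype=float)
    t = stream["t"].to_numpy(dtype=float)
    num_frames = len(stream) // n
    frames = []
    for i in range(num_frames):
        sl = slice(i * n, (i + 1) * n)
        label = labels[i] if labels is not None and i < len(labels) else None
        frames.append(AccelFrame(data[sl], t[sl], frame_index=i, label=label))
    return frames
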