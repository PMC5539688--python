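"""Synthetic 20 Hz tri-axial accelerometer traces with per-frame ground truth.

Events are generated as a signal-vector-magnitude profile ``m(t)`` (in g)
applied along a per-event random gravity direction, plus a small
perpendicular wobble and additive Gaussian sensor noise, so the
magnitude-based tiers see exactly the phenomenology they threshold on
while per-axis features face a realistic, orientation-randomized view:

* a resting device reads ≈ 1 g;
* gait (walk / run / stair climbing) is a sinusoidal SV oscillation at
  the step frequency, walking staying below the low threshold and running
  exceeding it while activity continues;
* sitting down / standing up are single smooth moderate transients,
  optionally followed by brief stillness (the ambiguous, region-II
  non-falls the ML tier exists for);
* falls are a brief free-fall dip below 1 g, a sharp impact peak, then at
  least one frame of post-impact near-stillness.  Harsh falls peak above
  the high threshold and are caught by double thresholding; slow-pace
  falls peak in the ambiguous band and must be recognized by the ML tier.

Event durations are whole frames so ground-truth labels align with the
frame grid.  All randomness flows from one seed via per-event spawned
generators, so traces are bit-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .double_threshold import DTConfig
from .features import LABEL_COLUMN, feature_table
from .selection import FALL, NON_FALL, LabeledDataset
from .signal_model import STANDARD_GRAVITY, AccelFrame, StreamConfig, frame_stream


class EventKind(str, enum.Enum):
    MOTIONLESS = "MOTIONLESS"
    WALK = "WALK"
    RUN = "RUN"
    CLIMB_UP = "CLIMB_UP"
    CLIMB_DOWN = "CLIMB_DOWN"
    SIT_DOWN = "SIT_DOWN"
    STAND_UP = "STAND_UP"
    FALL_HARSH = "FALL_HARSH"
    FALL_SLOW = "FALL_SLOW"
    FALL_FROM_WALK = "FALL_FROM_WALK"
    FALL_FROM_RUN = "FALL_FROM_RUN"
    FALL_LATERAL = "FALL_LATERAL"
    FALL_KNEES = "FALL_KNEES"


FALL_KINDS = (
    EventKind.FALL_HARSH,
    EventKind.FALL_SLOW,
    EventKind.FALL_FROM_WALK,
    EventKind.FALL_FROM_RUN,
    EventKind.FALL_LATERAL,
    EventKind.FALL_KNEES,
)

ADL_KINDS = (
    EventKind.WALK,
    EventKind.RUN,
    EventKind.CLIMB_UP,
    EventKind.CLIMB_DOWN,
    EventKind.SIT_DOWN,
    EventKind.STAND_UP,
)

# kind -> (duration in frames, impact/transient peak in g, gait frequency Hz,
#          gait SV amplitude in g); None where not applicable
_KIND_DEFAULTS: dict[EventKind, tuple[int, float | None, float | None, float | None]] = {
    EventKind.MOTIONLESS: (1, None, None, None),
    EventKind.WALK: (4, None, 2.0, 0.25),
    EventKind.RUN: (4, None, 3.0, 0.55),
    EventKind.CLIMB_UP: (4, None, 1.8, 0.35),
    EventKind.CLIMB_DOWN: (4, None, 2.0, 0.40),
    EventKind.SIT_DOWN: (2, 1.8, None, None),
    EventKind.STAND_UP: (2, 1.9, None, None),
    EventKind.FALL_HARSH: (2, 3.0, None, None),
    EventKind.FALL_SLOW: (2, 1.9, None, None),
    EventKind.FALL_FROM_WALK: (3, 2.8, 2.0, 0.25),
    EventKind.FALL_FROM_RUN: (3, 3.2, 3.0, 0.55),
    EventKind.FALL_LATERAL: (2, 2.6, None, None),
    EventKind.FALL_KNEES: (2, 2.2, None, None),
}

#: Amplitude of running's taper-out frame, chosen to keep the final gait
#: frame below Th_low while its SV still exceeds Th_inactivity.
RUN_TAPER_AMP_G = 0.40


@dataclass(frozen=True)
class EventSpec:
    """Parameters of one synthetic event.

    ``peak_g`` is the impact (falls) or transient (sit/stand) SV peak;
    ``amp_g``/``freq_hz`` the gait oscillation; ``noise_sigma`` the
    per-axis Gaussian sensor noise in m/s².  ``post_still`` controls
    whether a sit-down / stand-up is followed by brief stillness (making
    it an ambiguous region-II event) or by continued mild activity; None
    draws it at random per event.  Unset numeric fields take the kind's
    defaults.
    """

    kind: EventKind
    duration_s: float | None = None
    peak_g: float | None = None
    freq_hz: float | None = None
    amp_g: float | None = None
    noise_sigma: float = 0.1
    post_still: bool | None = None
    peak_jitter: float = 0.10  # relative per-event jitter of the SV peak
    seed: int = 0

    def resolved(self, config: StreamConfig) -> "EventSpec":
        kind = EventKind(self.kind)
        frames, peak, freq, amp = _KIND_DEFAULTS[kind]
        duration = self.duration_s if self.duration_s is not None else frames * config.frame_seconds
        n_frames = duration / config.frame_seconds
        if duration <= 0 or abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration_s must be a positive whole number of frames")
        out = replace(
            self,
            kind=kind,
            duration_s=float(duration),
            peak_g=self.peak_g if self.peak_g is not None else peak,
            freq_hz=self.freq_hz if self.freq_hz is not None else freq,
            amp_g=self.amp_g if self.amp_g is not None else amp,
        )
        if out.peak_g is not None and out.peak_g < 0:
            raise ValueError("peak_g must be non-negative")
        if out.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        return out


@dataclass
class LabeledTrace:
    """A sample stream plus per-frame ground truth aligned to the frame grid."""

    samples: pd.DataFrame  # columns t, ax, ay, az
    frame_labels: pd.DataFrame  # columns frame_index, label, kind

    def frames(self, config: StreamConfig | None = None) -> list[AccelFrame]:
        config = config or StreamConfig()
        return frame_stream(self.samples, config, labels=list(self.frame_labels["label"]))

    @property
    def n_frames(self) -> int:
        return len(self.frame_labels)


# ----------------------------------------------------- profile builders ----


def _gait_frames(n_frames: int, freq: float, amp: float, dt: float, frame_len: int,
                 phase: float, amp_last: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """SV profile of n_frames of steady gait (g); returns (m, perp)."""
    n = n_frames * frame_len
    t = np.arange(n) * dt
    a = np.full(n, amp)
    if amp_last is not None and n_frames >= 2:
        a[-frame_len:] = amp_last
    m = 1.0 + a * np.sin(2 * np.pi * freq * t + phase)
    perp = 0.3 * a * np.sin(2 * np.pi * freq * t + phase + 1.1)
    return m, perp


def _still(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.ones(n), np.zeros(n)


def _transient_frame(
    peak: float,
    frame_len: int,
    dt: float,
    rng: np.random.Generator,
    pre_level: float = 0.8,
) -> np.ndarray:
    """Postural-transition SV profile within one frame, in g.

    Sitting down (and, mirrored, standing up) briefly unweights the body
    to ``pre_level`` and ends in a sharp contact jolt to ``peak`` — the
    jolt is what makes these transitions fall-like enough to escape
    pre-elimination.  Onset and unweighting duration vary per event.
    """
    m = np.ones(frame_len)
    start = int(round(rng.uniform(0.6, 1.4) / dt))
    ease = int(round(rng.uniform(0.3, 0.5) / dt))
    i = start
    m[i : i + ease] = np.linspace(1.0, pre_level, ease, endpoint=False)
    i += ease
    m[i] = peak  # contact jolt
    m[i + 1] = 1.0 + 0.4 * (peak - 1.0)
    m[i + 2] = 1.0 + 0.1 * (peak - 1.0)
    m[i + 3 :] = 1.0
    return m


def _impact_profile(
    peak: float,
    frame_len: int,
    dt: float,
    rng: np.random.Generator,
    lead: np.ndarray | None = None,
) -> np.ndarray:
    """One frame holding free-fall dip, sharp impact and settling, in g.

    The free-fall depth and duration vary per event; ``lead`` optionally
    replaces the initial resting portion (e.g. with continuing gait for
    falls out of walking or running).
    """
    m = np.ones(frame_len)
    i_rest = int(round(1.2 / dt))  # 24 samples of context
    if lead is not None:
        k = min(len(lead), i_rest)
        m[:k] = lead[:k]
    # dip: ramp down over 0.2 s, then hold near free fall for 0.25-0.45 s
    dip = rng.uniform(0.2, 0.42)
    ramp = int(round(0.2 / dt))
    hold = int(round(rng.uniform(0.25, 0.45) / dt))
    i = i_rest
    m[i : i + ramp] = np.linspace(1.0, dip, ramp, endpoint=False)
    i += ramp
    m[i : i + hold] = dip
    i += hold
    # impact: one-sample spike to the peak, fast ringdown, then lying still
    m[i] = peak
    m[i + 1] = 1.0 + 0.45 * (peak - 1.0)
    m[i + 2] = 1.0 + 0.15 * (peak - 1.0)
    m[i + 3 :] = 1.0
    return m


def _event_profile(spec: EventSpec, config: StreamConfig, rng: np.random.Generator):
    """Return (m, perp, frame_kinds) for a resolved spec; m and perp in g."""
    n = config.frame_length
    dt = config.sampling_interval
    n_frames = int(round(spec.duration_s / config.frame_seconds))
    kind = spec.kind
    phase = rng.uniform(0, 2 * np.pi)
    peak = spec.peak_g
    if peak is not None and spec.peak_jitter > 0:
        peak = peak * (1.0 + spec.peak_jitter * rng.uniform(-1.0, 1.0))

    if kind is EventKind.MOTIONLESS:
        m, p = _still(n_frames * n)
    elif kind in (EventKind.WALK, EventKind.RUN, EventKind.CLIMB_UP, EventKind.CLIMB_DOWN):
        amp_last = RUN_TAPER_AMP_G if kind is EventKind.RUN else None
        m, p = _gait_frames(n_frames, spec.freq_hz, spec.amp_g, dt, n, phase, amp_last)
    elif kind in (EventKind.SIT_DOWN, EventKind.STAND_UP):
        if n_frames < 2:
            raise ValueError(f"{kind.value} needs at least 2 frames")
        post_still = spec.post_still
        if post_still is None:
            post_still = bool(rng.integers(2))
        m = np.ones(n_frames * n)
        m[:n] = _transient_frame(peak, n, dt, rng)
        p = np.zeros(n_frames * n)
        if not post_still:  # continued mild wiggling keeps SV above Th_inactivity
            t_post = np.arange((n_frames - 1) * n) * dt
            m[n:] = 1.0 + 0.38 * np.sin(2 * np.pi * 1.5 * t_post + phase)
    elif kind in FALL_KINDS:
        if n_frames < 2:
            raise ValueError(f"{kind.value} needs at least 2 frames (impact + stillness)")
        m = np.ones(n_frames * n)
        p = np.zeros(n_frames * n)
        if kind in (EventKind.FALL_FROM_WALK, EventKind.FALL_FROM_RUN):
            if n_frames < 3:
                raise ValueError(f"{kind.value} needs at least 3 frames")
            gait_m, gait_p = _gait_frames(n_frames - 1, spec.freq_hz, spec.amp_g, dt, n, phase)
            prefix = (n_frames - 2) * n
            m[:prefix] = gait_m[:prefix]
            p[:prefix] = gait_p[:prefix]
            m[prefix : prefix + n] = _impact_profile(peak, n, dt, rng, lead=gait_m[prefix:])
        else:
            m[:n] = _impact_profile(peak, n, dt, rng)
        # trailing frame(s): post-impact lying still (already ones)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown event kind {kind!r}")

    label = FALL if kind in FALL_KINDS else NON_FALL
    frame_kinds = [(label, kind.value)] * n_frames
    return m, p, frame_kinds


def _orientation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random gravity direction (uniform on the sphere) and a perpendicular."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    return u, v


def _render(m: np.ndarray, p: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Project SV profiles onto a random device orientation and add noise."""
    u, v = _orientation(rng)
    acc = np.outer(m, u) + np.outer(p, v)
    acc *= STANDARD_GRAVITY
    if sigma > 0:
        acc = acc + rng.normal(scale=sigma, size=acc.shape)
    return acc


def generate_event(spec: EventSpec, config: StreamConfig | None = None) -> LabeledTrace:
    """Generate one labeled event trace starting at t = 0."""
    config = config or StreamConfig()
    spec = spec.resolved(config)
    rng = np.random.default_rng(spec.seed)
    m, p, frame_kinds = _event_profile(spec, config, rng)
    acc = _render(m, p, spec.noise_sigma, rng)
    t = np.arange(len(m)) * config.sampling_interval
    samples = pd.DataFrame({"t": t, "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2]})
    frame_labels = pd.DataFrame(
        {
            "frame_index": np.arange(len(frame_kinds)),
            "label": [lab for lab, _ in frame_kinds],
            "kind": [k for _, k in frame_kinds],
        }
    )
    return LabeledTrace(samples, frame_labels)


# ------------------------------------------------------- trace assembly ----


def _concat_events(specs: list[EventSpec], config: StreamConfig, pad_frames: int = 1,
                   pad_seed: int = 0):
    """Concatenate events separated by motionless padding; returns
    (trace, manifest) with manifest rows only for the non-padding events."""
    dt = config.sampling_interval
    parts: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    manifest_rows = []
    frame_cursor = 0

    def _pad(rng_seed: int, k: int):
        nonlocal frame_cursor
        if k <= 0:
            return
        pad_spec = EventSpec(EventKind.MOTIONLESS, duration_s=k * config.frame_seconds, seed=rng_seed)
        tr = generate_event(pad_spec, config)
        parts.append(tr.samples[["ax", "ay", "az"]].to_numpy())
        labels.extend([(NON_FALL, EventKind.MOTIONLESS.value)] * k)
        frame_cursor += k

    pad_seeds = iter(
        np.random.SeedSequence([pad_seed, 0x9AD]).generate_state(len(specs) + 1) % 2**31
    )
    _pad(int(next(pad_seeds)), pad_frames)
    for event_id, spec in enumerate(specs):
        tr = generate_event(spec, config)
        n_frames = tr.n_frames
        parts.append(tr.samples[["ax", "ay", "az"]].to_numpy())
        lab = FALL if EventKind(spec.kind) in FALL_KINDS else NON_FALL
        labels.extend(zip(tr.frame_labels["label"], tr.frame_labels["kind"]))
        manifest_rows.append(
            {
                "event_id": event_id,
                "kind": EventKind(spec.kind).value,
                "label": lab,
                "start_frame": frame_cursor,
                "end_frame": frame_cursor + n_frames - 1,
            }
        )
        frame_cursor += n_frames
        _pad(int(next(pad_seeds)), pad_frames)

    acc = np.vstack(parts)
    t = np.arange(acc.shape[0]) * dt
    samples = pd.DataFrame({"t": t, "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2]})
    frame_labels = pd.DataFrame(
        {
            "frame_index": np.arange(len(labels)),
            "label": [l for l, _ in labels],
            "kind": [k for _, k in labels],
        }
    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["event_id", "kind", "label", "start_frame", "end_frame"]
    )
    return LabeledTrace(samples, frame_labels), manifest


def _spread_counts(total: int, kinds: tuple[EventKind, ...]) -> list[EventKind]:
    """Deterministic near-uniform composition over kinds."""
    out: list[EventKind] = []
    for i, kind in enumerate(kinds):
        lo = total * i // len(kinds)
        hi = total * (i + 1) // len(kinds)
        out.extend([kind] * (hi - lo))
    return out


def generate_benchmark(
    n_falls: int,
    n_adls: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    config: StreamConfig | None = None,
) -> tuple[LabeledTrace, pd.DataFrame]:
    """A labeled benchmark trace of ``n_falls`` fall and ``n_adls`` ADL events.

    Events cover all fall and ADL kinds (near-uniformly unless ``mix`` maps
    kind names to weights), are shuffled into one order, and separated by
    one frame of motionless padding.  Returns the trace and a manifest with
    one row per event (kind, label, inclusive frame span).
    """
    if n_falls < 0 or n_adls < 0:
        raise ValueError("event counts must be non-negative")
    config = config or StreamConfig()
    rng = np.random.default_rng(seed)
    if mix is None:
        kinds = _spread_counts(n_falls, FALL_KINDS) + _spread_counts(n_adls, ADL_KINDS)
    else:
        fall_kinds = [k for k in FALL_KINDS if mix.get(k.value, 0) > 0]
        adl_kinds = [k for k in ADL_KINDS if mix.get(k.value, 0) > 0]
        kinds = _weighted_counts(n_falls, fall_kinds, mix) + _weighted_counts(n_adls, adl_kinds, mix)
    order = rng.permutation(len(kinds))
    seeds = np.random.SeedSequence(seed).generate_state(len(kinds) + 1)[1:] % 2**31
    specs = [EventSpec(kinds[i], seed=int(seeds[j])) for j, i in enumerate(order)]
    return _concat_events(specs, config, pad_seed=seed)


def _weighted_counts(total: int, kinds: list[EventKind], mix: dict[str, float]) -> list[EventKind]:
    weights = np.array([mix[k.value] for k in kinds], dtype=float)
    if total and (weights.sum() <= 0 or not kinds):
        raise ValueError("mix assigns no weight to any applicable kind")
    out: list[EventKind] = []
    if not total:
        return out
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = np.argsort(-(quota - counts), kind="stable")
    for i in remainder[: total - counts.sum()]:
        counts[i] += 1
    for kind, c in zip(kinds, counts):
        out.extend([kind] * int(c))
    return out


#: Relative frequency of daily-life activity bouts, loosely following a
#: day dominated by walking with occasional stairs, runs and postural shifts.
DAILY_MIX = {
    EventKind.WALK: 0.5,
    EventKind.CLIMB_UP: 0.1,
    EventKind.CLIMB_DOWN: 0.1,
    EventKind.RUN: 0.1,
    EventKind.SIT_DOWN: 0.1,
    EventKind.STAND_UP: 0.1,
}


def generate_daily_life(
    hours: float,
    activity_fraction: float = 0.1,
    seed: int = 0,
    config: StreamConfig | None = None,
) -> LabeledTrace:
    """A long, mostly-still trace with interleaved ADL bouts.

    ``activity_fraction`` is the target fraction of frames occupied by
    activity events; the rest is motionless (device resting).  Intended
    for tier-routing and false-positive-rate studies.
    """
    if not 0 <= activity_fraction <= 1:
        raise ValueError("activity_fraction must be in [0, 1]")
    config = config or StreamConfig()
    total_frames = int(round(hours * 3600.0 / config.frame_seconds))
    rng = np.random.default_rng(seed)
    kinds = list(DAILY_MIX)
    weights = np.array(list(DAILY_MIX.values()))
    weights = weights / weights.sum()

    specs: list[EventSpec] = []
    frames_done = 0
    activity_frames = 0
    seed_stream = iter(np.random.SeedSequence(seed).generate_state(max(total_frames, 1)) % 2**31)
    while frames_done < total_frames:
        want_activity = (
            activity_fraction > 0
            and activity_frames < activity_fraction * (frames_done + 1)
        )
        if want_activity:
            kind = kinds[rng.choice(len(kinds), p=weights)]
            spec = EventSpec(kind, seed=int(next(seed_stream)))
            n_frames = _KIND_DEFAULTS[kind][0]
            activity_frames += n_frames
        else:
            spec = EventSpec(
                EventKind.MOTIONLESS,
                duration_s=config.frame_seconds,
                seed=int(next(seed_stream)),
            )
            n_frames = 1
        specs.append(spec)
        frames_done += n_frames

    trace, _ = _concat_events(specs, config, pad_frames=0, pad_seed=seed)
    # trim any overshoot from the last bout so the duration is exact
    n = config.frame_length
    trace.samples = trace.samples.iloc[: total_frames * n].reset_index(drop=True)
    trace.frame_labels = trace.frame_labels.iloc[:total_frames].reset_index(drop=True)
    return trace


# ------------------------------------------------------- training tables ----


def event_feature_table(
    trace: LabeledTrace, manifest: pd.DataFrame, config: StreamConfig | None = None
) -> pd.DataFrame:
    """One 43-feature row per manifest event, taken from the event's most
    energetic frame (maximum per-sample SV), labeled FALL / NON_FALL.

    This emulates the study design of building a labeled training table
    from recorded events.
    """
    config = config or StreamConfig()
    frames = trace.frames(config)
    sv = [float(np.linalg.norm(f.data, axis=1).max()) for f in frames]
    picked: list[AccelFrame] = []
    labels: list[str] = []
    for row in manifest.itertuples():
        span = range(row.start_frame, row.end_frame + 1)
        best = max(span, key=lambda i: sv[i])
        picked.append(frames[best])
        labels.append(row.label)
    return feature_table(picked, labels)


def training_dataset(trace: LabeledTrace, manifest: pd.DataFrame,
                     config: StreamConfig | None = None) -> LabeledDataset:
    return LabeledDataset.from_table(event_feature_table(trace, manifest, config))
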