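"""Pipeline configuration: calibrated defaults, file loading, seed fan-out.

Defaults are the deployed calibration — 20 Hz sampling, 3 s frames,
Th_PE = 7 m/s², Th_low = 1.5 g, Th_high = 2.4 g, Th_inactivity = 1.3 g,
5 selected features, and a 20 s alert-cancellation window.  A YAML (or
JSON) config file may override any key; unknown keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .double_threshold import DTConfig
from .engine import EngineConfig
from .pre_elimination import PEConfig
from .signal_model import StreamConfig

logger = logging.getLogger("falltiers")


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration files."""


@dataclass(frozen=True)
class MLConfig:
    """ML-tier settings: feature-subset size and induction parameters."""

    top_k: int = 5
    min_leaf: int = 2
    min_bucket: int = 6

    def __post_init__(self) -> None:
        if self.top_k < 1 or self.min_leaf < 1 or self.min_bucket < 1:
            raise ConfigError("ml parameters must be positive integers")


@dataclass(frozen=True)
class AlertConfig:
    cancel_window_seconds: float = 20.0

    def __post_init__(self) -> None:
        if self.cancel_window_seconds <= 0:
            raise ConfigError("alert.cancel_window_seconds must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    stream: StreamConfig = field(default_factory=StreamConfig)
    pe: PEConfig = field(default_factory=PEConfig)
    dt: DTConfig = field(default_factory=DTConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    alert: AlertConfig = field(default_factory=AlertConfig)
    seed: int = 0

    def engine_config(self) -> EngineConfig:
        return EngineConfig(stream=self.stream, pe=self.pe, dt=self.dt)

    def subseed(self, name: str) -> int:
        """Stable per-component seed derived from the global seed, so the
        generator, selection and training stages can be re-run independently."""
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(name.encode())]).generate_state(1)[0]
            % 2**31
        )


_SECTIONS = {
    "stream": StreamConfig,
    "pe": PEConfig,
    "dt": DTConfig,
    "ml": MLConfig,
    "alert": AlertConfig,
}


def _build_section(name: str, cls, overrides: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**overrides)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {name} configuration: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config: file values (if any) over calibrated defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw.update(loaded)
    if overrides:
        for section, vals in overrides.items():
            if isinstance(vals, dict):
                raw.setdefault(section, {})
                raw[section].update(vals)
            else:
                raw[section] = vals

    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    config = PipelineConfig(seed=seed, **kwargs)
    logger.info("configuration: %s", config)
    return config
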