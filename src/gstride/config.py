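"""Run configuration for the processing pipeline.

All numeric constants that influence stance detection, filtering and event
detection live here so that a processing run is fully reproducible from a
single config file.  The defaults target a generic 100 Hz MEMS foot-mounted
sensor; every value can be overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "DetectorConfig",
    "FilterConfig",
    "EventConfig",
    "IoConfig",
    "RunConfig",
    "load_config",
    "save_config",
]

GRAVITY_DEFAULT = 9.81  # m/s^2


@dataclass
class DetectorConfig:
    """Zero-velocity (stance) detector settings.

    The detector thresholds a sliding-window likelihood statistic built from
    an accelerometer deviation-from-gravity-magnitude term and an angular
    rate energy term.  ``gyro_weight`` defaults to zero because the foot
    pivots in place at loading and push-off while the sensor translation is
    still negligible; see the methods note.
    """

    window_s: float = 0.1          # sliding window length
    accel_sigma: float = 0.05      # m/s^2, accel noise scale of the statistic
    gyro_sigma: float = 0.01      # rad/s, gyro noise scale of the statistic
    accel_weight: float = 1.0
    gyro_weight: float = 0.0
    threshold: float = 10.0        # dimensionless statistic threshold
    min_stance_s: float = 0.1      # stance intervals shorter than this are removed
    min_swing_s: float = 0.2       # swing gaps shorter than this are merged

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ValueError("detector window_s must be > 0")
        if self.accel_sigma <= 0 or self.gyro_sigma <= 0:
            raise ValueError("detector noise scales must be strictly positive")
        if self.accel_weight < 0 or self.gyro_weight < 0:
            raise ValueError("detector weights must be >= 0")
        if self.accel_weight == 0 and self.gyro_weight == 0:
            raise ValueError("at least one detector term must have positive weight")
        if self.threshold <= 0:
            raise ValueError("detector threshold must be > 0")
        if self.min_stance_s < 0 or self.min_swing_s < 0:
            raise ValueError("minimum durations must be >= 0")


@dataclass
class FilterConfig:
    """Error-state Kalman filter (ZUPT) settings."""

    accel_noise: float = 0.05      # m/s^2/sample, velocity process noise source
    gyro_noise: float = 0.005      # rad/s/sample, attitude process noise source
    zupt_noise: float = 0.01       # m/s, zero-velocity measurement noise
    init_att_std: float = 0.01     # rad
    init_vel_std: float = 0.01     # m/s
    init_pos_std: float = 0.001    # m
    stance_speed_contract: float = 0.05  # m/s, post-filter stance speed bound
    estimate_gyro_bias: bool = True  # calibrate gyro bias on the initial standstill

    def validate(self) -> None:
        for name in ("accel_noise", "gyro_noise", "zupt_noise",
                     "init_att_std", "init_vel_std", "init_pos_std"):
            if getattr(self, name) <= 0:
                raise ValueError(f"filter {name} must be strictly positive")


@dataclass
class EventConfig:
    """Gait-event detection and stride plausibility settings."""

    footflat_gyro_thresh: float = 0.05  # rad/s, foot-flat sub-interval within stance
    event_window: int = 3               # samples searched around HS/TO for pitch extrema
    gct_min_s: float = 0.4              # physiological stride-duration window
    gct_max_s: float = 3.0
    still_window_s: float = 1.0         # standstill used for attitude initialisation
    still_gyro_thresh: float = 0.3      # rad/s, quasi-static gyro bound

    def validate(self) -> None:
        if self.footflat_gyro_thresh <= 0:
            raise ValueError("footflat_gyro_thresh must be > 0")
        if self.event_window < 0:
            raise ValueError("event_window must be >= 0")
        if not 0 < self.gct_min_s < self.gct_max_s:
            raise ValueError("need 0 < gct_min_s < gct_max_s")
        if self.still_window_s <= 0 or self.still_gyro_thresh <= 0:
            raise ValueError("standstill settings must be > 0")


@dataclass
class IoConfig:
    """CSV column mapping and unit conversions for raw IMU logs."""

    columns: dict[str, str] = field(default_factory=lambda: {
        "t": "t", "ax": "ax", "ay": "ay", "az": "az",
        "gx": "gx", "gy": "gy", "gz": "gz",
    })
    accel_in_g: bool = False       # convert accel from g to m/s^2 on load
    gyro_in_deg: bool = False      # convert gyro from deg/s to rad/s on load
    time_unit: str = "auto"        # "s", "ms" or "auto" (detect by magnitude)

    def validate(self) -> None:
        missing = {"t", "ax", "ay", "az", "gx", "gy", "gz"} - set(self.columns)
        if missing:
            raise ValueError(f"io column mapping missing keys: {sorted(missing)}")
        if self.time_unit not in ("s", "ms", "auto"):
            raise ValueError("time_unit must be 's', 'ms' or 'auto'")


@dataclass
class RunConfig:
    """Top-level configuration for a processing run."""

    gravity_mps2: float = GRAVITY_DEFAULT
    sample_rate_hz: float = 100.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    io: IoConfig = field(default_factory=IoConfig)

    def validate(self) -> "RunConfig":
        if self.gravity_mps2 <= 0:
            raise ValueError("gravity_mps2 must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        self.detector.validate()
        self.filter.validate()
        self.events.validate()
        self.io.validate()
        if round(self.detector.window_s * self.sample_rate_hz) < 3:
            raise ValueError("detector window must span at least 3 samples")
        return self

    def window_samples(self) -> int:
        return max(3, int(round(self.detector.window_s * self.sample_rate_hz)))


def _from_mapping(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("detector", "filter", "events", "io"):
            sub = {"detector": DetectorConfig, "filter": FilterConfig,
                   "events": EventConfig, "io": IoConfig}.get(f.name)
            value = _from_mapping(sub, value) if sub else value
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, applying optional overrides.

    Unknown keys raise ``ValueError`` so that typos never silently fall back
    to defaults.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    return _from_mapping(RunConfig, data).validate()


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
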