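"""Configuration system: the ``settings.cfg`` schema, defaults, parsing,
serialization, deployment naming, and deployment-log records.

The configuration is an INI file with four sections — ``general_settings``,
``intervalometer_settings``, ``motion_detection_settings`` and
``camera_configuration`` — covering every operating parameter of the
camera-trap engine. Enum values are parsed case-insensitively and stored
lower-case (configuration files get edited by hand in the field). Any key
absent from a file takes its packaged default; unknown keys produce a
warning and are ignored; invalid values raise :class:`SettingsError`
naming the key and the allowed values.
"""

from __future__ import annotations

import configparser
import csv
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

from .frames import TEI_SIZE

__all__ = [
    "Settings",
    "GeneralSettings",
    "IntervalometerSettings",
    "MotionSettings",
    "CameraSettings",
    "SettingsError",
    "default_settings",
    "parse_settings",
    "write_settings",
    "validate_settings",
    "deployment_name",
    "LogEntry",
    "DeploymentLog",
    "read_log",
]


class SettingsError(ValueError):
    """A configuration value is out of range or not an allowed option."""


# ---------------------------------------------------------------------------
# Typed settings groups
# ---------------------------------------------------------------------------

COLLECTION_TYPES = ("still_intervalometer", "trigger_using_red", "trigger_using_ambient")
STROBE_CHANNELS = ("red", "white")
TRIGGER_EVAL_METHODS = ("object_size", "pixel_total")
RESOLUTIONS = ("l", "m", "h")
ISO_VALUES = (100, 200, 400, 800, 1600)
STROBE_MODES = ("off", "camera", "envelope")
IMAGE_DEPTHS = ("color", "monochrome")
IMAGE_TYPES = ("jpeg", "png", "bmp")


@dataclass
class GeneralSettings:
    collection_type: str = "trigger_using_red"
    system_id: str = "pi_triggercam_001"
    initial_wait: int = 1  # minutes before acquisition starts
    low_voltage_cutoff: float = 11.0  # volts; ~11 V for 12 V battery banks
    shutdown_at_end: bool = False
    shutdown_wifi_on_collection: bool = True


@dataclass
class IntervalometerSettings:
    max_images: int = 10
    image_interval: float = 1.0  # seconds between shots
    strobe_channel: str = "red"


@dataclass
class MotionSettings:
    motion_detect_interval: int = 1  # seconds between TEI evaluations
    post_detection_rest: int = 5  # minutes of no sensing after a trigger
    max_runtime: int = 60  # minutes; limits the trigger evaluation period
    foreground_threshold: int = 8  # grey levels (0-255)
    trigger_roi: tuple[int, int, int, int] = (20, 20, 280, 200)  # left, bottom, w, h
    frame_history: int = 25  # frames kept for background modelling (20-100)
    trigger_eval_method: str = "object_size"
    min_object_size: int = 500  # pixels
    min_pixel_count: int = 10_000  # pixels


@dataclass
class CameraSettings:
    image_resolution: str = "m"  # l=(1024,768), m=(2048,1520), h=(4056,3040)
    auto_contrast: bool = False  # CLAHE on full-resolution captures
    exposure: int = 0  # microseconds; 0 = auto
    iso: int = 800
    strobe: str = "envelope"
    pre_strobe_fire: float = 0.1  # seconds of strobe lead before exposure
    strobe_duration: float = 0.5  # seconds; LED overheating guard
    image_depth: str = "monochrome"
    image_type: str = "jpeg"
    image_quality: int = 95  # 70-100 for JPEG, 0-9 for PNG


@dataclass
class Settings:
    """Typed view of every ``settings.cfg`` parameter, grouped by section."""

    general: GeneralSettings = field(default_factory=GeneralSettings)
    intervalometer: IntervalometerSettings = field(default_factory=IntervalometerSettings)
    motion: MotionSettings = field(default_factory=MotionSettings)
    camera: CameraSettings = field(default_factory=CameraSettings)

    @property
    def triggered_mode(self) -> bool:
        return self.general.collection_type.startswith("trigger")


def default_settings() -> Settings:
    """Settings populated with every packaged default value."""
    return Settings()


# ---------------------------------------------------------------------------
# Schema: one entry per key, driving parse / validate / write uniformly
# ---------------------------------------------------------------------------

def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "on", "yes", "1"):
        return True
    if t in ("false", "off", "no", "0"):
        return False
    raise ValueError(f"{text!r} is not a boolean (true/false)")


def _parse_roi(text: str) -> tuple[int, int, int, int]:
    vals = [int(v) for v in text.strip().strip("[]()").split(",")]
    if len(vals) != 4:
        raise ValueError("trigger_roi needs four integers: left, bottom, width, height")
    return tuple(vals)  # type: ignore[return-value]


def _fmt_roi(roi: tuple[int, int, int, int]) -> str:
    return "[" + ", ".join(str(v) for v in roi) + "]"


def _enum(options, numeric=False):
    def parse(text: str):
        val = int(text) if numeric else text.strip().lower()
        if val not in options:
            raise ValueError(f"must be one of {', '.join(str(o) for o in options)}")
        return val

    return parse


def _ranged_int(lo=None, hi=None):
    def parse(text: str) -> int:
        val = int(text)
        if lo is not None and val < lo:
            raise ValueError(f"must be >= {lo}")
        if hi is not None and val > hi:
            raise ValueError(f"must be <= {hi}")
        return val

    return parse


def _ranged_float(lo=None, hi=None, lo_strict=False):
    def parse(text: str) -> float:
        val = float(text)
        if lo is not None and (val < lo or (lo_strict and val == lo)):
            raise ValueError(f"must be {'>' if lo_strict else '>='} {lo}")
        if hi is not None and val > hi:
            raise ValueError(f"must be <= {hi}")
        return val

    return parse


def _check_roi(roi) -> None:
    left, bottom, width, height = roi
    tw, th = TEI_SIZE
    if width < 1 or height < 1:
        raise ValueError("trigger_roi width and height must be >= 1")
    if left < 0 or bottom < 0 or left + width > tw or bottom + height > th:
        raise ValueError(
            f"trigger_roi {_fmt_roi(roi)} must fit inside the {tw}x{th} TEI grid"
        )


# (ini section, group attribute, key) -> (parse fn, format fn)
_SCHEMA: dict[tuple[str, str, str], tuple] = {
    ("general_settings", "general", "collection_type"): (_enum(COLLECTION_TYPES), str),
    ("general_settings", "general", "system_id"): (lambda s: s.strip(), str),
    ("general_settings", "general", "initial_wait"): (_ranged_int(lo=0), str),
    ("general_settings", "general", "low_voltage_cutoff"): (_ranged_float(lo=0), str),
    ("general_settings", "general", "shutdown_at_end"): (_parse_bool, lambda v: str(v).lower()),
    ("general_settings", "general", "shutdown_wifi_on_collection"): (_parse_bool, lambda v: str(v).lower()),
    ("intervalometer_settings", "intervalometer", "max_images"): (_ranged_int(lo=1), str),
    ("intervalometer_settings", "intervalometer", "image_interval"): (_ranged_float(lo=0, lo_strict=True), str),
    ("intervalometer_settings", "intervalometer", "strobe_channel"): (_enum(STROBE_CHANNELS), str),
    ("motion_detection_settings", "motion", "motion_detect_interval"): (_ranged_int(lo=1), str),
    ("motion_detection_settings", "motion", "post_detection_rest"): (_ranged_int(lo=0), str),
    ("motion_detection_settings", "motion", "max_runtime"): (_ranged_int(lo=0), str),
    ("motion_detection_settings", "motion", "foreground_threshold"): (_ranged_int(0, 255), str),
    ("motion_detection_settings", "motion", "trigger_roi"): (_parse_roi, _fmt_roi),
    ("motion_detection_settings", "motion", "frame_history"): (_ranged_int(20, 100), str),
    ("motion_detection_settings", "motion", "trigger_eval_method"): (_enum(TRIGGER_EVAL_METHODS), str),
    ("motion_detection_settings", "motion", "min_object_size"): (_ranged_int(lo=0), str),
    ("motion_detection_settings", "motion", "min_pixel_count"): (_ranged_int(lo=0), str),
    ("camera_configuration", "camera", "image_resolution"): (_enum(RESOLUTIONS), str),
    ("camera_configuration", "camera", "auto_contrast"): (_parse_bool, lambda v: "on" if v else "off"),
    ("camera_configuration", "camera", "exposure"): (_ranged_int(lo=0), str),
    ("camera_configuration", "camera", "iso"): (_enum(ISO_VALUES, numeric=True), str),
    ("camera_configuration", "camera", "strobe"): (_enum(STROBE_MODES), str),
    ("camera_configuration", "camera", "pre_strobe_fire"): (_ranged_float(0.0, 0.5), str),
    ("camera_configuration", "camera", "strobe_duration"): (_ranged_float(0.5, 2.0), str),
    ("camera_configuration", "camera", "image_depth"): (_enum(IMAGE_DEPTHS), str),
    ("camera_configuration", "camera", "image_type"): (_enum(IMAGE_TYPES), str),
    ("camera_configuration", "camera", "image_quality"): (_ranged_int(0, 100), str),
}

_SECTIONS = ("general_settings", "intervalometer_settings",
             "motion_detection_settings", "camera_configuration")


def validate_settings(s: Settings) -> None:
    """Raise :class:`SettingsError` if any field is out of range.

    ``image_quality`` is validated against the active ``image_type``:
    70-100 for JPEG, 0-9 for PNG; BMP ignores it.
    """
    for (section, group, key), (parse, fmt) in _SCHEMA.items():
        val = getattr(getattr(s, group), key)
        try:
            parse(fmt(val) if not isinstance(val, str) else val)
        except ValueError as exc:
            raise SettingsError(f"{section}.{key}: {exc}") from None
    try:
        _check_roi(s.motion.trigger_roi)
    except ValueError as exc:
        raise SettingsError(f"motion_detection_settings.trigger_roi: {exc}") from None
    q, kind = s.camera.image_quality, s.camera.image_type
    if kind == "jpeg" and not 70 <= q <= 100:
        raise SettingsError(
            f"camera_configuration.image_quality: must be 70-100 for JPEG, got {q}"
        )
    if kind == "png" and not 0 <= q <= 9:
        raise SettingsError(
            f"camera_configuration.image_quality: must be 0-9 for PNG, got {q}"
        )


def parse_settings(text: str) -> Settings:
    """Parse ``settings.cfg`` text into a typed :class:`Settings`.

    Missing keys default; unknown keys warn and are ignored; malformed
    values raise :class:`SettingsError`. Empty text yields the defaults.
    """
    cp = configparser.ConfigParser()
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise SettingsError(f"malformed configuration file: {exc}") from None

    s = default_settings()
    known = {(sec, key): (group, parse) for (sec, group, key), (parse, _) in _SCHEMA.items()}
    quality_given = False
    for sec in cp.sections():
        if sec not in _SECTIONS:
            warnings.warn(f"ignoring unknown configuration section [{sec}]", stacklevel=2)
            continue
        for key, raw in cp.items(sec):
            entry = known.get((sec, key))
            if entry is None:
                warnings.warn(f"ignoring unknown configuration key {sec}.{key}", stacklevel=2)
                continue
            group, parse = entry
            try:
                value = parse(raw)
            except ValueError as exc:
                raise SettingsError(f"{sec}.{key}: {exc}") from None
            setattr(getattr(s, group), key, value)
            if key == "image_quality":
                quality_given = True
    # the quality scale depends on the encoder: JPEG defaults to 95, PNG to 3
    if not quality_given and s.camera.image_type == "png":
        s.camera.image_quality = 3
    validate_settings(s)
    return s


def write_settings(s: Settings) -> str:
    """Serialize a :class:`Settings` to INI text; re-parsing is the identity."""
    validate_settings(s)
    cp = configparser.ConfigParser()
    for sec in _SECTIONS:
        cp.add_section(sec)
    for (section, group, key), (_, fmt) in _SCHEMA.items():
        cp.set(section, key, fmt(getattr(getattr(s, group), key)))
    from io import StringIO

    out = StringIO()
    cp.write(out)
    return out.getvalue()


def deployment_name(t: datetime) -> str:
    """Deployment folder name for calendar time ``t``: ``DMMDDYYYY-Thhmmss``."""
    return t.strftime("D%m%d%Y-T%H%M%S")


# ---------------------------------------------------------------------------
# Deployment log
# ---------------------------------------------------------------------------

LOG_EVENTS = ("boot", "capture", "trigger_eval", "rest_start", "shutdown")
_LOG_FIELDS = ("timestamp", "event", "voltage", "free_bytes", "image_path", "diagnostics")


@dataclass
class LogEntry:
    """One deployment-log row.

    ``timestamp`` is seconds since deployment start (the simulated clock);
    serialized alongside the calendar time in ISO-8601. ``diagnostics`` is
    a free-form dict (JSON in the CSV) carrying e.g. trigger decisions.
    """

    timestamp: float
    event: str
    voltage: float | None = None
    free_bytes: int | None = None
    image_path: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event not in LOG_EVENTS:
            raise ValueError(f"unknown log event {self.event!r}; allowed: {LOG_EVENTS}")


class DeploymentLog:
    """Append-only CSV log; rows carry ISO-8601 calendar timestamps.

    Timestamps must be non-decreasing within one deployment.
    """

    def __init__(self, path: str | Path, start: datetime):
        self.path = Path(path)
        self.start = start
        self.entries: list[LogEntry] = []
        self._last_t = float("-inf")
        with open(self.path, "w", newline="") as fh:
            csv.writer(fh).writerow(("iso_time",) + _LOG_FIELDS)

    def append(self, entry: LogEntry) -> None:
        if entry.timestamp < self._last_t:
            raise ValueError(
                f"log timestamps must be non-decreasing "
                f"({entry.timestamp} after {self._last_t})"
            )
        self._last_t = entry.timestamp
        self.entries.append(entry)
        from datetime import timedelta

        iso = (self.start + timedelta(seconds=entry.timestamp)).isoformat()
        with open(self.path, "a", newline="") as fh:
            csv.writer(fh).writerow([
                iso,
                f"{entry.timestamp:.3f}",
                entry.event,
                "" if entry.voltage is None else f"{entry.voltage:.3f}",
                "" if entry.free_bytes is None else entry.free_bytes,
                entry.image_path or "",
                json.dumps(entry.diagnostics, sort_keys=True) if entry.diagnostics else "",
            ])


def read_log(path: str | Path):
    """Read a deployment log CSV back into a pandas DataFrame.

    ``diagnostics`` is decoded from JSON into dicts; ``timestamp`` is the
    seconds-since-start clock used by replay and scoring.
    """
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    df["timestamp"] = df["timestamp"].astype(float)
    df["diagnostics"] = [json.loads(d) if d else {} for d in df["diagnostics"]]
    return df
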