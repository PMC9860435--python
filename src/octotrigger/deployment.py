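"""Deployment lifecycle: boot, initial wait, mode dispatch, rest periods,
exit conditions, logging — plus the hardware-abstraction contracts and
pure simulators that make the engine runnable without a camera rig.

A *deployment* is one power-up-to-shutdown run. It gets a folder named
``DMMDDYYYY-Thhmmss`` containing a ``settings.cfg`` snapshot, a
``log.csv`` deployment log, stored full-resolution captures under
``full/`` and the evaluated TEI sequence under ``tei/`` (kept so trigger
performance can be re-derived after the deployment).

All timing is driven by the simulated clock — never real sleeps — so a
multi-day deployment replays in seconds and runs are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Protocol

import numpy as np
from scipy import ndimage

from . import mog
from .config import (
    DeploymentLog,
    LogEntry,
    Settings,
    deployment_name,
    read_log,
    write_settings,
)
from .frames import Frame, load_frame, save_frame
from .imaging import crop_roi, gaussian_blur
from .simulate import SceneRenderer, SceneSpec, TargetSpec
from .trigger import capture_full_res, evaluate_tei, strobe_schedule

__all__ = [
    "EndOfStream",
    "SimClock",
    "SimulatedCamera",
    "DirectoryCameraSource",
    "RampVoltage",
    "SimStorage",
    "RecordingStrobeDriver",
    "HardwareContract",
    "DeploymentRecord",
    "run_deployment",
    "check_exit",
    "replay_states",
    "replay_deployment",
]

STATES = ("waiting", "sensing", "resting", "capturing", "shutdown")
EXIT_REASONS = ("low_voltage", "disk_full", "max_runtime", "max_images",
                "end_of_input", "none")


class EndOfStream(Exception):
    """The frame source has no frame at the requested time."""


# ---------------------------------------------------------------------------
# Hardware contracts and simulators
# ---------------------------------------------------------------------------

class CameraSource(Protocol):
    def capture_tei(self, t: float) -> Frame: ...

    def capture_full(self, t: float, size: tuple[int, int],
                     exposure_us: int = 0, iso: int = 800) -> tuple[Frame, float]: ...


class SimClock:
    """Deterministic deployment clock: monotonic seconds + calendar time."""

    def __init__(self, start: datetime | None = None, t0: float = 0.0):
        self.start = start or datetime(2022, 7, 4, 12, 0, 0)
        self.t = float(t0)

    def now(self) -> float:
        return self.t

    def calendar(self) -> datetime:
        return self.start + timedelta(seconds=self.t)

    def advance(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("clock cannot run backwards")
        self.t += seconds


class SimulatedCamera:
    """Camera fed by the synthetic scene renderer.

    TEI requests at time ``t`` map to scene frame ``round(t / dt)``; noise
    is keyed on the frame index, so capture order does not matter. Full
    resolution requests upscale the noise-free scene render (bilinear)
    and re-add noise at the target resolution.
    """

    AUTO_EXPOSURE_S = 0.05

    def __init__(self, scene: SceneSpec, targets: list[TargetSpec] | None = None,
                 *, duration_s: float | None = None):
        self.renderer = SceneRenderer(scene, targets)
        self.scene = scene
        if duration_s is None and scene.duration_frames:
            duration_s = scene.duration_frames * scene.frame_interval_s
        self.duration_s = duration_s

    def _index(self, t: float) -> int:
        i = int(round(t / self.scene.frame_interval_s))
        if self.duration_s is not None and t >= self.duration_s:
            raise EndOfStream(f"scene ended at {self.duration_s} s (asked {t} s)")
        return i

    def capture_tei(self, t: float) -> Frame:
        f = self.renderer.render(self._index(t))
        return Frame(f.pixels, timestamp=t, tier="tei")

    def capture_full(self, t: float, size: tuple[int, int],
                     exposure_us: int = 0, iso: int = 800) -> tuple[Frame, float]:
        i = self._index(t)
        w, h = size
        clean = self.renderer.render_clean(i)
        zoomed = ndimage.zoom(
            clean, (h / clean.shape[0], w / clean.shape[1]), order=1
        )[:h, :w]
        if self.scene.noise_sd > 0:
            rng = np.random.default_rng([self.scene.seed, 3, i])
            zoomed = zoomed + rng.normal(0.0, self.scene.noise_sd, size=zoomed.shape)
        pixels = np.clip(np.rint(zoomed), 0, 255).astype(np.uint8)
        exposure_s = exposure_us / 1e6 if exposure_us > 0 else self.AUTO_EXPOSURE_S
        return Frame(pixels, timestamp=t, tier="full"), exposure_s


class DirectoryCameraSource:
    """Frames read from a directory of PNG/JPEG/BMP files, sorted by name.

    Full-resolution requests upscale the current frame (a directory
    source has no higher-resolution sensor behind it).
    """

    AUTO_EXPOSURE_S = 0.05

    def __init__(self, directory: str | Path, frame_interval_s: float = 1.0):
        exts = {".png", ".jpg", ".jpeg", ".bmp"}
        self.paths = sorted(
            p for p in Path(directory).iterdir() if p.suffix.lower() in exts
        )
        if not self.paths:
            raise ValueError(f"no image files found in {directory}")
        self.frame_interval_s = frame_interval_s

    def _frame_at(self, t: float) -> Frame:
        i = int(round(t / self.frame_interval_s))
        if i < 0 or i >= len(self.paths):
            raise EndOfStream(f"no frame at t={t} (have {len(self.paths)})")
        return load_frame(self.paths[i], timestamp=t, tier="tei")

    def capture_tei(self, t: float) -> Frame:
        return self._frame_at(t)

    def capture_full(self, t: float, size: tuple[int, int],
                     exposure_us: int = 0, iso: int = 800) -> tuple[Frame, float]:
        f = self._frame_at(t)
        w, h = size
        zoomed = ndimage.zoom(
            f.pixels.astype(float), (h / f.height, w / f.width), order=1
        )[:h, :w]
        pixels = np.clip(np.rint(zoomed), 0, 255).astype(np.uint8)
        exposure_s = exposure_us / 1e6 if exposure_us > 0 else self.AUTO_EXPOSURE_S
        return Frame(pixels, timestamp=t, tier="full"), exposure_s


class RampVoltage:
    """Linear battery-voltage model: ``v0 + slope_per_hour * hours``."""

    def __init__(self, v0: float = 12.6, slope_per_hour: float = -0.05):
        self.v0 = v0
        self.slope_per_hour = slope_per_hour

    def volts(self, t: float) -> float:
        return self.v0 + self.slope_per_hour * (t / 3600.0)


class SimStorage:
    """Byte-counting storage shim over the real filesystem."""

    def __init__(self, capacity_bytes: int = 64 * 10**9):
        self.capacity = int(capacity_bytes)
        self.used = 0

    def free_bytes(self) -> int:
        return max(0, self.capacity - self.used)

    def consume(self, path: Path) -> None:
        self.used += Path(path).stat().st_size


class RecordingStrobeDriver:
    """Records every strobe schedule it is asked to fire."""

    def __init__(self):
        self.fired = []

    def fire(self, schedule) -> None:
        self.fired.append(schedule)


@dataclass
class HardwareContract:
    """The five streams a deployment needs; pure simulators by default."""

    camera: CameraSource
    clock: SimClock = field(default_factory=SimClock)
    voltage: RampVoltage = field(default_factory=RampVoltage)
    storage: SimStorage = field(default_factory=SimStorage)
    strobe: RecordingStrobeDriver = field(default_factory=RecordingStrobeDriver)


# ---------------------------------------------------------------------------
# Deployment record and exit conditions
# ---------------------------------------------------------------------------

@dataclass
class DeploymentRecord:
    """Run state of one deployment."""

    name: str
    settings: Settings
    start: datetime
    mode: str  # "intervalometer" | "triggered"
    out_dir: Path
    images_captured: int = 0
    teis_evaluated: int = 0
    last_trigger_time: float | None = None
    state: str = "waiting"
    exit_reason: str = "none"
    sensing_elapsed: float = 0.0
    voltage_trace: list[tuple[float, float]] = field(default_factory=list)
    state_trace: list[tuple[float, str]] = field(default_factory=list)
    eval_times: list[float] = field(default_factory=list)
    trigger_times: list[float] = field(default_factory=list)
    capture_times: list[float] = field(default_factory=list)
    shutdown_requested: bool = False

    def set_state(self, t: float, state: str) -> None:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        if not self.state_trace or self.state_trace[-1][1] != state:
            self.state_trace.append((t, state))
        self.state = state

    @property
    def duration_s(self) -> float:
        if not self.state_trace:
            return 0.0
        return self.state_trace[-1][0] - self.state_trace[0][0]


def _worst_case_image_bytes(s: Settings) -> int:
    from .frames import resolution_for_tier

    w, h = resolution_for_tier(s.camera.image_resolution)
    channels = 3 if s.camera.image_depth == "color" else 1
    return w * h * channels + 1024


def check_exit(rec: DeploymentRecord, hw: HardwareContract, s: Settings) -> str | None:
    """First matching exit reason in fixed priority order, else None.

    Priority: low_voltage (strictly below the cutoff), disk_full (less
    free space than one worst-case image), max_runtime (triggered-mode
    sensing time), max_images (intervalometer mode).
    """
    volts = hw.voltage.volts(hw.clock.now())
    if volts < s.general.low_voltage_cutoff:
        return "low_voltage"
    if hw.storage.free_bytes() < _worst_case_image_bytes(s):
        return "disk_full"
    if rec.mode == "triggered" and s.motion.max_runtime > 0:
        if rec.sensing_elapsed > s.motion.max_runtime * 60.0:
            return "max_runtime"
    if rec.mode == "intervalometer":
        if rec.images_captured >= s.intervalometer.max_images:
            return "max_images"
    return None


# ---------------------------------------------------------------------------
# The state machine
# ---------------------------------------------------------------------------

def run_deployment(
    hw: HardwareContract,
    s: Settings,
    out_root: str | Path,
    *,
    save_tei: bool = True,
) -> DeploymentRecord:
    """Run one deployment to completion against the given hardware.

    Creates ``<out_root>/<DMMDDYYYY-Thhmmss>/`` with the settings
    snapshot, log, ``full/`` and ``tei/`` folders; returns the finished
    record with its exit reason.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    start_cal = hw.clock.calendar()
    name = deployment_name(start_cal)
    dep_dir = out_root / name
    dep_dir.mkdir(parents=True, exist_ok=False)
    (dep_dir / "full").mkdir()
    (dep_dir / "tei").mkdir()
    (dep_dir / "settings.cfg").write_text(write_settings(s))

    mode = "intervalometer" if s.general.collection_type == "still_intervalometer" else "triggered"
    rec = DeploymentRecord(
        name=name, settings=s, start=start_cal, mode=mode, out_dir=dep_dir
    )
    log = DeploymentLog(dep_dir / "log.csv", start_cal)

    t = hw.clock.now()
    volts = hw.voltage.volts(t)
    rec.voltage_trace.append((t, volts))
    log.append(LogEntry(
        timestamp=t, event="boot", voltage=volts,
        free_bytes=hw.storage.free_bytes(),
        diagnostics={
            "system_id": s.general.system_id,
            "mode": mode,
            "wifi_off_on_collection": s.general.shutdown_wifi_on_collection,
        },
    ))
    rec.set_state(t, "waiting")
    hw.clock.advance(s.general.initial_wait * 60.0)

    try:
        if mode == "intervalometer":
            _run_intervalometer(hw, s, rec, log)
        else:
            _run_triggered(hw, s, rec, log, save_tei=save_tei)
    except EndOfStream:
        rec.exit_reason = "end_of_input"

    t = hw.clock.now()
    rec.set_state(t, "shutdown")
    rec.shutdown_requested = s.general.shutdown_at_end
    log.append(LogEntry(
        timestamp=t, event="shutdown", voltage=hw.voltage.volts(t),
        free_bytes=hw.storage.free_bytes(),
        diagnostics={"exit_reason": rec.exit_reason,
                     "shutdown_at_end": s.general.shutdown_at_end},
    ))
    return rec


def _capture_and_log(hw, s, rec, log, seq: int) -> None:
    t = hw.clock.now()
    ext = {"jpeg": "jpg", "png": "png", "bmp": "bmp"}[s.camera.image_type]
    stamp = (rec.start + timedelta(seconds=t)).strftime("%Y%m%dT%H%M%S")
    fname = f"{stamp}_{seq:05d}.{ext}"
    frame, path, params = capture_full_res(
        hw.camera, s, when=t, out_dir=rec.out_dir / "full", filename=fname
    )
    # the camera reports the exposure it used (auto when exposure = 0),
    # which drives the strobe envelope
    sched = strobe_schedule(t, params["exposure_s"], s)
    hw.strobe.fire(sched)
    hw.storage.consume(path)
    volts = hw.voltage.volts(t)
    rec.voltage_trace.append((t, volts))
    rec.images_captured += 1
    rec.capture_times.append(t)
    log.append(LogEntry(
        timestamp=t, event="capture", voltage=volts,
        free_bytes=hw.storage.free_bytes(),
        image_path=str(Path("full") / fname),
        diagnostics={"seq": seq, "strobe": sched.mode,
                     "strobe_on": sched.on, "strobe_off": sched.off,
                     "encoder": params},
    ))


def _run_intervalometer(hw, s, rec, log) -> None:
    rec.set_state(hw.clock.now(), "capturing")
    while True:
        reason = check_exit(rec, hw, s)
        if reason is not None:
            rec.exit_reason = reason
            return
        _capture_and_log(hw, s, rec, log, seq=rec.images_captured)
        if rec.images_captured >= s.intervalometer.max_images:
            rec.exit_reason = "max_images"
            return
        hw.clock.advance(s.intervalometer.image_interval)


def _run_triggered(hw, s, rec, log, *, save_tei: bool) -> None:
    rec.set_state(hw.clock.now(), "sensing")
    interval = float(s.motion.motion_detect_interval)
    rest_s = s.motion.post_detection_rest * 60.0
    burn_in: list[Frame] = []
    model: mog.MogModel | None = None
    seq = 0
    while True:
        reason = check_exit(rec, hw, s)
        if reason is not None:
            rec.exit_reason = reason
            return
        t = hw.clock.now()
        tei = hw.camera.capture_tei(t)
        if model is None:
            processed = crop_roi(gaussian_blur(tei, 5), s.motion.trigger_roi)
            burn_in.append(processed)
            _log_tei(hw, s, rec, log, tei, seq, save_tei,
                     {"burn_in": True, "triggered": False})
            if len(burn_in) >= s.motion.frame_history:
                model = mog.init_model(burn_in, s)
                burn_in.clear()
            seq += 1
            rec.sensing_elapsed += interval
            hw.clock.advance(interval)
            continue
        decision = evaluate_tei(model, tei, s)
        _log_tei(hw, s, rec, log, tei, seq, save_tei, decision.diagnostics())
        seq += 1
        if decision.triggered:
            rec.trigger_times.append(t)
            rec.last_trigger_time = t
            _capture_and_log(hw, s, rec, log, seq=rec.images_captured)
            rec.set_state(t, "resting")
            log.append(LogEntry(
                timestamp=t, event="rest_start",
                diagnostics={"rest_minutes": s.motion.post_detection_rest},
            ))
            hw.clock.advance(rest_s)
            rec.set_state(hw.clock.now(), "sensing")
        else:
            rec.sensing_elapsed += interval
            hw.clock.advance(interval)


def _log_tei(hw, s, rec, log, tei: Frame, seq: int, save_tei: bool,
             diagnostics: dict) -> None:
    t = tei.timestamp
    path = None
    if save_tei:
        stamp = (rec.start + timedelta(seconds=t)).strftime("%Y%m%dT%H%M%S")
        fname = f"{stamp}_{seq:05d}.png"
        save_frame(tei, rec.out_dir / "tei" / fname, "png", 1)
        hw.storage.consume(rec.out_dir / "tei" / fname)
        path = str(Path("tei") / fname)
    rec.teis_evaluated += 1
    rec.eval_times.append(t)
    log.append(LogEntry(
        timestamp=t, event="trigger_eval", image_path=path,
        diagnostics=diagnostics,
    ))


# ---------------------------------------------------------------------------
# Replay: reconstruct the state sequence from the log alone
# ---------------------------------------------------------------------------

def replay_states(log_df, mode: str) -> list[tuple[float, str]]:
    """Derive the deployment state trace from log rows.

    The log alone is sufficient to replay the state sequence; this is
    the offline half of the replay test.
    """
    trace: list[tuple[float, str]] = []

    def push(t: float, state: str) -> None:
        if not trace or trace[-1][1] != state:
            trace.append((t, state))

    active = "capturing" if mode == "intervalometer" else "sensing"
    for _, row in log_df.iterrows():
        t, event = float(row["timestamp"]), row["event"]
        if event == "boot":
            push(t, "waiting")
        elif event == "trigger_eval":
            push(t, "sensing")
        elif event == "capture":
            if mode == "intervalometer":
                push(t, "capturing")
        elif event == "rest_start":
            push(t, "resting")
        elif event == "shutdown":
            push(t, "shutdown")
    return trace


def replay_deployment(dep_dir: str | Path) -> list[tuple[float, str]]:
    """Replay a stored deployment folder into its state trace."""
    dep_dir = Path(dep_dir)
    from .config import parse_settings

    s = parse_settings((dep_dir / "settings.cfg").read_text())
    mode = "intervalometer" if s.general.collection_type == "still_intervalometer" else "triggered"
    df = read_log(dep_dir / "log.csv")
    return replay_states(df, mode)
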