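"""Per-cycle triggered-acquisition pipeline.

Each sensing tick: a 320x240 monochrome trigger-evaluation image (TEI) is
blurred (5x5 Gaussian), cropped to the trigger ROI, classified against
the MOG background model at the configured foreground threshold, closed
morphologically to merge fragmented detections, and evaluated by one of
two rules:

* ``pixel_total`` — trigger iff the number of foreground pixels (on the
  post-close mask) strictly exceeds ``min_pixel_count``;
* ``object_size`` — trigger iff any 8-connected component strictly
  exceeds ``min_object_size`` pixels.

On a trigger, a full-resolution image is captured at the configured tier,
optionally CLAHE-enhanced, and encoded to disk, with the strobe driven
around the exposure envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import imaging, mog
from .config import Settings
from .frames import Frame, ForegroundMask, resolution_for_tier, save_frame

__all__ = [
    "TriggerDecision",
    "StrobeSchedule",
    "evaluate_tei",
    "decide_trigger",
    "capture_full_res",
    "strobe_schedule",
    "MORPH_KERNEL_SIDE",
]

#: Structuring-element side for the dilation+erosion merge step.
MORPH_KERNEL_SIDE = 3


@dataclass
class TriggerDecision:
    """Outcome of one TEI evaluation, with diagnostics sufficient to
    re-derive the decision offline from the stored TEI."""

    triggered: bool
    method: str  # object_size | pixel_total
    foreground_pixels: int
    component_sizes: tuple[int, ...] = ()
    largest_bbox: tuple[int, int, int, int] | None = None
    tei_timestamp: float = 0.0
    eval_time: float = 0.0
    min_object_size: int | None = None
    min_pixel_count: int | None = None
    foreground_threshold: int | None = None

    def diagnostics(self) -> dict:
        return {
            "triggered": self.triggered,
            "method": self.method,
            "foreground_pixels": self.foreground_pixels,
            "n_components": len(self.component_sizes),
            "largest_component": max(self.component_sizes, default=0),
            "largest_bbox": list(self.largest_bbox) if self.largest_bbox else None,
            "foreground_threshold": self.foreground_threshold,
        }


@dataclass
class StrobeSchedule:
    """Illumination window around one exposure."""

    mode: str  # off | camera | envelope
    channel: str = "red"
    on: float | None = None  # seconds, deployment clock
    off: float | None = None

    @property
    def duration(self) -> float:
        if self.on is None or self.off is None:
            return 0.0
        return self.off - self.on


def decide_trigger(
    mask: ForegroundMask,
    comps: imaging.ComponentSet | None,
    s: Settings,
) -> TriggerDecision:
    """Apply the configured evaluation rule to a closed foreground mask.

    Both rules use strict inequality ("exceeds"). ``comps`` must be given
    for the ``object_size`` method.
    """
    method = s.motion.trigger_eval_method
    fg = mask.popcount()
    if method == "pixel_total":
        return TriggerDecision(
            triggered=fg > s.motion.min_pixel_count,
            method=method,
            foreground_pixels=fg,
            min_pixel_count=s.motion.min_pixel_count,
            foreground_threshold=s.motion.foreground_threshold,
        )
    if method == "object_size":
        if comps is None:
            raise ValueError("object_size evaluation requires connected components")
        sizes = tuple(int(v) for v in comps.sizes)
        return TriggerDecision(
            triggered=any(sz > s.motion.min_object_size for sz in sizes),
            method=method,
            foreground_pixels=fg,
            component_sizes=sizes,
            largest_bbox=comps.largest_bbox(),
            min_object_size=s.motion.min_object_size,
            foreground_threshold=s.motion.foreground_threshold,
        )
    raise ValueError(f"unknown trigger_eval_method {method!r}")


def evaluate_tei(model: mog.MogModel, tei: Frame, s: Settings) -> TriggerDecision:
    """Run the full trigger pipeline on one TEI.

    The TEI must be 320x240; the model must match the blurred-and-cropped
    geometry (ROI width x height).
    """
    if not tei.is_tei_sized():
        raise ValueError(
            f"TEI must be 320x240 (WxH), got {tei.width}x{tei.height}"
        )
    blurred = imaging.gaussian_blur(tei, 5)
    cropped = imaging.crop_roi(blurred, s.motion.trigger_roi)
    mask = mog.update_and_classify(model, cropped, s.motion.foreground_threshold)
    closed = imaging.morph_close(mask, MORPH_KERNEL_SIDE)
    comps = None
    if s.motion.trigger_eval_method == "object_size":
        comps = imaging.connected_components(closed)
    decision = decide_trigger(closed, comps, s)
    decision.tei_timestamp = tei.timestamp
    decision.eval_time = tei.timestamp
    return decision


def strobe_schedule(
    exposure_start: float, exposure_len: float, s: Settings
) -> StrobeSchedule:
    """Strobe on/off times bracketing an exposure.

    In envelope mode the strobe leads the exposure by ``pre_strobe_fire``
    and never stays on longer than ``strobe_duration`` (LED overheating
    guard). Strobe off returns a null schedule.
    """
    if exposure_len < 0:
        raise ValueError("exposure_len must be >= 0")
    mode = s.camera.strobe
    channel = s.intervalometer.strobe_channel
    if mode == "off":
        return StrobeSchedule(mode="off", channel=channel)
    if mode == "camera":
        # camera-metered double flash is hardware-specific; schedule the
        # envelope equivalent so simulators still see an illumination window
        mode = "camera"
    on = exposure_start - s.camera.pre_strobe_fire
    off = min(exposure_start + exposure_len, on + s.camera.strobe_duration)
    return StrobeSchedule(mode=mode, channel=channel, on=on, off=off)


def capture_full_res(
    camera,
    s: Settings,
    *,
    when: float = 0.0,
    out_dir: str | Path | None = None,
    filename: str | None = None,
) -> tuple[Frame, Path | None, dict]:
    """Capture, optionally enhance, encode and store a full-resolution image.

    ``camera`` is any object with
    ``capture_full(t, size, exposure_us, iso) -> (Frame, exposure_seconds)``.
    Returns the (possibly enhanced) frame, the stored path (None when
    ``out_dir`` is None) and a diagnostics dict with the encoder
    parameters and the exposure actually used.
    """
    size = resolution_for_tier(s.camera.image_resolution)
    frame, exposure_s = camera.capture_full(
        when, size, exposure_us=s.camera.exposure, iso=s.camera.iso
    )
    if (frame.width, frame.height) != size:
        raise ValueError(
            f"camera returned {frame.width}x{frame.height}, requested {size}"
        )
    if s.camera.auto_contrast:
        frame = imaging.clahe(frame)
    path = None
    params: dict = {"exposure_s": exposure_s}
    if out_dir is not None:
        ext = {"jpeg": "jpg", "png": "png", "bmp": "bmp"}[s.camera.image_type]
        name = filename or f"capture_{when:.0f}.{ext}"
        path = Path(out_dir) / name
        params.update(
            save_frame(frame, path, s.camera.image_type, s.camera.image_quality)
        )
    return frame, path, params
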