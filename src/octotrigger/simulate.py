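"""Synthetic benthic-scene simulator with ground truth.

Generates monochrome TEI-scale frame sequences standing in for field
footage: a textured seafloor background, a slow sinusoidal luminance
drift emulating tidal-current and lighting variation, per-frame additive
Gaussian sensor noise, and moving elliptical targets of configurable
size, contrast and speed. Targets are rendered with hard edges so the
ground-truth masks are exact.

Everything is deterministic under the scene seed: frame i's noise is
drawn from a generator keyed on (seed, i), so frames can be rendered on
demand and out of order (as the simulated camera does) with identical
results.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
from scipy import ndimage

from .frames import Frame

__all__ = [
    "SceneSpec",
    "TargetSpec",
    "SceneRenderer",
    "Truth",
    "TruthWindow",
    "generate_sequence",
    "ground_truth_events",
    "load_scene_config",
]


@dataclass
class SceneSpec:
    """Scene-level parameters for the simulator.

    Amplitudes are grey levels; the background must stay inside [0, 255]
    without clipping so that target contrast is exact.
    """

    width: int = 320
    height: int = 240
    background_mean: float = 120.0
    texture_amplitude: float = 20.0
    noise_sd: float = 2.0
    drift_amplitude: float = 10.0
    drift_period_s: float = 3600.0
    frame_interval_s: float = 1.0
    duration_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_amplitude < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        lo = self.background_mean - self.texture_amplitude - self.drift_amplitude
        hi = self.background_mean + self.texture_amplitude + self.drift_amplitude
        if lo < 0 or hi > 255:
            raise ValueError(
                f"background range [{lo}, {hi}] leaves [0, 255]; "
                "reduce amplitudes or recentre background_mean"
            )


@dataclass
class TargetSpec:
    """A moving elliptical target.

    The ellipse (semi-axes ``a``, ``b`` in pixels) enters at
    ``entry_frame`` centred on ``start_center`` (x, y in bottom-up pixel
    coordinates are not used here; centres are (col, row) in the image
    grid) and moves by ``velocity`` pixels per frame. With path
    ``dwell-then-leave`` it sits still for ``dwell_frames`` frames before
    moving off.
    """

    a: float = 20.0
    b: float = 10.0
    contrast: float = 60.0  # signed grey levels relative to background
    entry_frame: int = 0
    velocity: tuple[float, float] = (2.0, 0.0)  # (dx, dy) pixels/frame
    start_center: tuple[float, float] = (160.0, 120.0)
    path: str = "linear"
    dwell_frames: int = 0

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise ValueError("ellipse semi-axes must be >= 1")
        if self.path not in ("linear", "dwell-then-leave"):
            raise ValueError(f"unknown path {self.path!r}")

    def center_at(self, frame: int) -> tuple[float, float] | None:
        """Ellipse centre at a frame index, or None before entry."""
        if frame < self.entry_frame:
            return None
        t = frame - self.entry_frame
        if self.path == "dwell-then-leave":
            t = max(0, t - self.dwell_frames)
        return (
            self.start_center[0] + self.velocity[0] * t,
            self.start_center[1] + self.velocity[1] * t,
        )

    def mask_at(self, frame: int, shape: tuple[int, int]) -> np.ndarray:
        """Exact rasterized target mask (pixel centres inside the ellipse)."""
        H, W = shape
        c = self.center_at(frame)
        out = np.zeros((H, W), dtype=bool)
        if c is None:
            return out
        cx, cy = c
        if cx + self.a < 0 or cx - self.a > W - 1 or cy + self.b < 0 or cy - self.b > H - 1:
            return out
        y, x = np.ogrid[:H, :W]
        out = ((x - cx) / self.a) ** 2 + ((y - cy) / self.b) ** 2 <= 1.0
        return out


@dataclass
class Truth:
    """Ground truth for a generated sequence."""

    present: np.ndarray  # (F,) bool: any target pixel in frame
    areas: np.ndarray  # (F, n_targets) pixel areas
    frame_interval_s: float
    masks: list[np.ndarray] | None = None  # per-frame union masks, if kept


class SceneRenderer:
    """Renders scene frames on demand, deterministically per frame index."""

    def __init__(self, scene: SceneSpec, targets: list[TargetSpec] | None = None):
        self.scene = scene
        self.targets = list(targets or [])
        rng = np.random.default_rng([scene.seed, 1])
        # smooth static texture: coarse uniform field upsampled to scene size
        coarse = rng.uniform(-1.0, 1.0, size=(max(2, scene.height // 20),
                                              max(2, scene.width // 20)))
        zoom = (scene.height / coarse.shape[0], scene.width / coarse.shape[1])
        tex = ndimage.zoom(coarse, zoom, order=1)[: scene.height, : scene.width]
        peak = np.abs(tex).max()
        if peak > 0:
            tex = tex / peak
        self.texture = scene.texture_amplitude * tex

    def drift(self, frame: int) -> float:
        s = self.scene
        if s.drift_amplitude == 0:
            return 0.0
        t = frame * s.frame_interval_s
        return s.drift_amplitude * np.sin(2 * np.pi * t / s.drift_period_s)

    def background(self, frame: int) -> np.ndarray:
        """Noise-free background (float) at a frame index."""
        return self.scene.background_mean + self.texture + self.drift(frame)

    def target_mask(self, frame: int) -> np.ndarray:
        shape = (self.scene.height, self.scene.width)
        out = np.zeros(shape, dtype=bool)
        for t in self.targets:
            out |= t.mask_at(frame, shape)
        return out

    def render_clean(self, frame: int) -> np.ndarray:
        """Noise-free render: background plus per-target contrast."""
        img = self.background(frame).copy()
        shape = (self.scene.height, self.scene.width)
        for t in self.targets:
            img = np.where(t.mask_at(frame, shape), img + t.contrast, img)
        return img

    def render(self, frame: int) -> Frame:
        """Rendered frame with per-frame sensor noise, clipped to 8 bits."""
        img = self.render_clean(frame)
        if self.scene.noise_sd > 0:
            rng = np.random.default_rng([self.scene.seed, 2, frame])
            img = img + rng.normal(0.0, self.scene.noise_sd, size=img.shape)
        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        return Frame(pixels, timestamp=frame * self.scene.frame_interval_s, tier="tei")


def generate_sequence(
    scene: SceneSpec,
    targets: list[TargetSpec] | None = None,
    *,
    keep_masks: bool = True,
) -> tuple[list[Frame], Truth]:
    """Render the full sequence with ground truth.

    ``keep_masks=False`` drops the per-frame union masks (presence flags
    and areas are always kept), which matters for long sequences.
    """
    targets = list(targets or [])
    renderer = SceneRenderer(scene, targets)
    F = scene.duration_frames
    shape = (scene.height, scene.width)
    frames: list[Frame] = []
    present = np.zeros(F, dtype=bool)
    areas = np.zeros((F, len(targets)), dtype=np.int64)
    masks: list[np.ndarray] | None = [] if keep_masks else None
    ever_seen = [False] * len(targets)
    for i in range(F):
        frames.append(renderer.render(i))
        union = np.zeros(shape, dtype=bool)
        for j, t in enumerate(targets):
            m = t.mask_at(i, shape)
            areas[i, j] = int(m.sum())
            if areas[i, j]:
                ever_seen[j] = True
            union |= m
        present[i] = bool(union.any())
        if masks is not None:
            masks.append(union)
    for j, seen in enumerate(ever_seen):
        if not seen:
            warnings.warn(
                f"target {j} never enters the frame; its truth is empty",
                stacklevel=2,
            )
    truth = Truth(
        present=present,
        areas=areas,
        frame_interval_s=scene.frame_interval_s,
        masks=masks,
    )
    return frames, truth


@dataclass
class TruthWindow:
    """A maximal interval of continuous target presence, in seconds."""

    start_s: float
    end_s: float
    matchable: bool = True


def ground_truth_events(
    truth: Truth,
    rest_minutes: float,
    detect_interval: float,
    *,
    initial_shadow_s: float = 0.0,
) -> list[TruthWindow]:
    """Collapse per-frame presence into expected trigger windows.

    A window fully inside the rest shadow cast by the previous detectable
    window is unmatchable: the engine sleeps for ``rest_minutes`` after a
    trigger, so no evaluation can land in it. ``initial_shadow_s`` lets
    the caller account for burn-in at the start of sensing.
    """
    flags = np.asarray(truth.present, dtype=bool)
    dt = truth.frame_interval_s
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[0::2], edges[1::2] - 1
    rest_s = rest_minutes * 60.0
    shadow_end = initial_shadow_s
    windows: list[TruthWindow] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        w_start, w_end = s * dt, e * dt
        if w_end < shadow_end:
            windows.append(TruthWindow(w_start, w_end, matchable=False))
            continue
        trigger_time = max(w_start, shadow_end)
        windows.append(TruthWindow(w_start, w_end, matchable=True))
        shadow_end = trigger_time + rest_s
    return windows


# ---------------------------------------------------------------------------
# Scene configuration files (for `octotrigger run --source sim:scene.cfg`)
# ---------------------------------------------------------------------------

def load_scene_config(path: str | Path) -> tuple[SceneSpec, list[TargetSpec]]:
    """Read a scene description: a [scene] section plus [target*] sections."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    scene_kwargs = {}
    if cp.has_section("scene"):
        sec = cp["scene"]
        for key in ("width", "height", "duration_frames", "seed"):
            if key in sec:
                scene_kwargs[key] = sec.getint(key)
        for key in ("background_mean", "texture_amplitude", "noise_sd",
                    "drift_amplitude", "drift_period_s", "frame_interval_s"):
            if key in sec:
                scene_kwargs[key] = sec.getfloat(key)
    scene = SceneSpec(**scene_kwargs)
    targets = []
    for name in cp.sections():
        if not name.startswith("target"):
            continue
        sec = cp[name]
        kwargs = {}
        for key in ("a", "b", "contrast"):
            if key in sec:
                kwargs[key] = sec.getfloat(key)
        for key in ("entry_frame", "dwell_frames"):
            if key in sec:
                kwargs[key] = sec.getint(key)
        if "path" in sec:
            kwargs["path"] = sec.get("path")
        for key in ("velocity", "start_center"):
            if key in sec:
                parts = [float(v) for v in sec.get(key).strip("[]()").split(",")]
                kwargs[key] = (parts[0], parts[1])
        targets.append(TargetSpec(**kwargs))
    return scene, targets
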