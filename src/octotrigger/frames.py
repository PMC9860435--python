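"""Frame and mask containers plus greyscale image I/O.

A *frame* is a 2-D grid of 8-bit grey levels. Trigger-evaluation images
(TEIs) are always 320x240 (width x height); full-resolution captures use
one of the named resolution tiers of the camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: TEI geometry as (width, height).
TEI_SIZE = (320, 240)

#: Full-resolution tiers (width, height), keyed by the one-letter tier name.
RESOLUTION_TIERS = {
    "l": (1024, 768),
    "m": (2048, 1520),
    "h": (4056, 3040),
}

# ITU-R BT.601 luminance weights, used when a colour array must be
# collapsed to the single 8-bit channel the trigger path operates on.
_LUMA = np.array([0.299, 0.587, 0.114])


def resolution_for_tier(tier: str) -> tuple[int, int]:
    """Return (width, height) for a resolution tier letter (case-insensitive)."""
    try:
        return RESOLUTION_TIERS[tier.lower()]
    except KeyError:
        raise ValueError(
            f"unknown image_resolution {tier!r}; allowed: L, M, H"
        ) from None


def to_luminance(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W) or (H, W, 3) uint8 array to (H, W) uint8 luminance."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        y = arr[..., :3].astype(np.float64) @ _LUMA
        return np.clip(np.rint(y), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")


@dataclass
class Frame:
    """A timestamped monochrome frame.

    Parameters
    ----------
    pixels:
        (H, W) uint8 array of grey levels.
    timestamp:
        Seconds since deployment start.
    tier:
        ``"tei"`` for 320x240 trigger-evaluation images, or ``"full"``.
    """

    pixels: np.ndarray
    timestamp: float = 0.0
    tier: str = "tei"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"frame pixels must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("frame pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_tei_sized(self) -> bool:
        return (self.width, self.height) == TEI_SIZE


@dataclass
class ForegroundMask:
    """Binary foreground mask aligned to a (possibly ROI-cropped) frame.

    ``origin`` is the (left, bottom) offset of the mask within its parent
    frame, in the bottom-left pixel coordinates used by the trigger ROI.
    """

    bits: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.bits = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def popcount(self) -> int:
        """Number of foreground pixels."""
        return int(self.bits.sum())


def load_frame(path: str | Path, timestamp: float = 0.0, tier: str = "tei") -> Frame:
    """Read a PNG/JPEG/BMP file as a monochrome frame.

    Colour images are converted to luminance; the trigger path is 8-bit
    greyscale throughout.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    return Frame(to_luminance(arr), timestamp=timestamp, tier=tier)


def save_frame(
    frame: Frame,
    path: str | Path,
    image_type: str = "png",
    image_quality: int = 95,
) -> dict:
    """Encode and write a frame; returns the encoder parameters used.

    ``image_quality`` is the JPEG quality (70-100) or the PNG compression
    level (0-9); it is ignored for BMP.
    """
    kind = image_type.lower()
    im = Image.fromarray(frame.pixels, mode="L")
    path = Path(path)
    if kind == "jpeg":
        params = {"format": "JPEG", "quality": int(image_quality)}
        im.save(path, format="JPEG", quality=int(image_quality))
    elif kind == "png":
        params = {"format": "PNG", "compress_level": int(image_quality)}
        im.save(path, format="PNG", compress_level=int(image_quality))
    elif kind == "bmp":
        params = {"format": "BMP"}
        im.save(path, format="BMP")
    else:
        raise ValueError(f"unknown image_type {image_type!r}; allowed: JPEG, PNG, BMP")
    return params
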