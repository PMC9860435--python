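"""From-scratch 2-D image operators used by the trigger pipeline.

All operators are deterministic and pure numpy: separable Gaussian blur,
bottom-left ROI crop, binary morphological closing, 8-connected component
labelling, and contrast-limited adaptive histogram equalization (CLAHE).

Coordinate convention: frames are stored top-left row-major, but the
trigger ROI is specified with a bottom-left origin (left, bottom, width,
height) on the 320x240 TEI grid; :func:`crop_roi` performs the conversion
``row = H - bottom - height``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .frames import Frame, ForegroundMask

__all__ = [
    "gaussian_kernel1d",
    "gaussian_blur",
    "crop_roi",
    "morph_close",
    "connected_components",
    "ComponentSet",
    "clahe",
]


# ---------------------------------------------------------------------------
# Gaussian blur
# ---------------------------------------------------------------------------

def gaussian_kernel1d(kernel_side: int) -> np.ndarray:
    """Normalized 1-D Gaussian kernel for an odd window of ``kernel_side``.

    sigma follows the convention common to imaging toolkits,
    ``0.3*((k-1)/2 - 1) + 0.8``, which gives sigma = 1.1 for the default
    5x5 window.
    """
    if kernel_side < 1 or kernel_side % 2 == 0:
        raise ValueError(f"kernel_side must be odd and >= 1, got {kernel_side}")
    if kernel_side == 1:
        return np.array([1.0])
    sigma = 0.3 * ((kernel_side - 1) / 2 - 1) + 0.8
    x = np.arange(kernel_side) - (kernel_side - 1) / 2
    g = np.exp(-(x**2) / (2 * sigma**2))
    return g / g.sum()


def _convolve_axis(arr: np.ndarray, kern: np.ndarray, axis: int) -> np.ndarray:
    p = len(kern) // 2
    pad = [(0, 0), (0, 0)]
    pad[axis] = (p, p)
    ap = np.pad(arr, pad, mode="reflect")
    out = np.zeros(arr.shape, dtype=np.float64)
    for i, kv in enumerate(kern):
        sl = [slice(None), slice(None)]
        sl[axis] = slice(i, i + arr.shape[axis])
        out += kv * ap[tuple(sl)]
    return out


def gaussian_blur(f: Frame, kernel_side: int = 5) -> Frame:
    """Separable Gaussian low-pass filter with reflected borders.

    The result is rounded back to 8-bit grey levels. ``kernel_side`` must
    be odd; 1 is the identity.
    """
    kern = gaussian_kernel1d(kernel_side)
    if kernel_side == 1:
        return Frame(f.pixels.copy(), timestamp=f.timestamp, tier=f.tier)
    out = _convolve_axis(f.pixels.astype(np.float64), kern, axis=0)
    out = _convolve_axis(out, kern, axis=1)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return Frame(out, timestamp=f.timestamp, tier=f.tier)


# ---------------------------------------------------------------------------
# ROI crop
# ---------------------------------------------------------------------------

def crop_roi(f: Frame, roi: tuple[int, int, int, int]) -> Frame:
    """Crop ``(left, bottom, width, height)`` out of a frame.

    The ROI uses a bottom-left origin; rows are converted to the internal
    top-left ordering. The ROI must lie fully inside the frame.
    """
    left, bottom, width, height = (int(v) for v in roi)
    H, W = f.pixels.shape
    if width < 1 or height < 1:
        raise ValueError(f"ROI width/height must be >= 1, got {roi}")
    if left < 0 or bottom < 0 or left + width > W or bottom + height > H:
        raise ValueError(f"ROI {roi} exceeds frame bounds {W}x{H}")
    top = H - bottom - height
    return Frame(
        f.pixels[top : top + height, left : left + width].copy(),
        timestamp=f.timestamp,
        tier=f.tier,
    )


# ---------------------------------------------------------------------------
# Morphological closing
# ---------------------------------------------------------------------------

def _window_reduce(bits: np.ndarray, k: int, reduce) -> np.ndarray:
    # square structuring elements separate into a row pass and a column pass
    H, W = bits.shape
    rows = reduce(sliding_window_view(bits, k, axis=0), axis=-1)
    return reduce(sliding_window_view(rows, k, axis=1), axis=-1)


def morph_close(m: ForegroundMask, kernel_side: int = 3) -> ForegroundMask:
    """Dilation then erosion with a square structuring element.

    Merges fragmented detections of a single target. The mask is treated
    as embedded in an infinite zero background, which makes the operation
    exactly idempotent. ``kernel_side`` 1 is the identity.
    """
    k = int(kernel_side)
    if k < 1:
        raise ValueError(f"kernel_side must be >= 1, got {kernel_side}")
    if k == 1:
        return ForegroundMask(m.bits.copy(), origin=m.origin)
    # pad by k-1 so dilation support outside the frame is represented;
    # a valid-window max then a valid-window min land exactly back on the
    # original geometry with correctly paired dilation/erosion origins
    big = np.pad(m.bits, k - 1, mode="constant", constant_values=0)
    dil = _window_reduce(big, k, np.max)
    ero = _window_reduce(dil, k, np.min)
    return ForegroundMask(ero.astype(np.uint8), origin=m.origin)


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """8-connected components of a binary mask.

    ``labels`` holds 0 for background and 1..n for components, numbered in
    row-major order of first appearance. ``bboxes`` rows are
    (min_row, min_col, max_row, max_col), inclusive.
    """

    labels: np.ndarray
    sizes: np.ndarray
    bboxes: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    def largest_bbox(self):
        if self.n_components == 0:
            return None
        return tuple(int(v) for v in self.bboxes[int(np.argmax(self.sizes))])


class _DSU:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def connected_components(m: ForegroundMask) -> ComponentSet:
    """Label maximal 8-connected foreground regions.

    Uses row run-length encoding with union-find across adjacent rows,
    which keeps the per-TEI cost proportional to the number of runs
    rather than the number of pixels.
    """
    bits = m.bits
    H, W = bits.shape
    # runs[r] = list of (start_col, end_col_inclusive, run_id)
    run_rows: list[list[tuple[int, int, int]]] = []
    n_runs = 0
    padded = np.zeros(W + 2, dtype=np.int16)
    for r in range(H):
        row = bits[r]
        if not row.any():
            run_rows.append([])
            continue
        padded[1:-1] = row
        edges = np.flatnonzero(np.diff(padded))
        starts, ends = edges[0::2], edges[1::2] - 1
        runs = []
        for s, e in zip(starts.tolist(), ends.tolist()):
            runs.append((s, e, n_runs))
            n_runs += 1
        run_rows.append(runs)

    dsu = _DSU(n_runs)
    for r in range(1, H):
        cur, prev = run_rows[r], run_rows[r - 1]
        if not cur or not prev:
            continue
        j = 0
        for s, e, rid in cur:
            while j < len(prev) and prev[j][1] < s - 1:
                j += 1
            k = j
            while k < len(prev) and prev[k][0] <= e + 1:
                dsu.union(rid, prev[k][2])
                k += 1
            if k > j:
                j = k - 1  # last overlapping run may also touch the next run

    # contiguous labels in order of first appearance (root run id is minimal)
    root_to_label: dict[int, int] = {}
    labels = np.zeros((H, W), dtype=np.int32)
    sizes: list[int] = []
    bboxes: list[list[int]] = []
    for r, runs in enumerate(run_rows):
        for s, e, rid in runs:
            root = dsu.find(rid)
            lab = root_to_label.get(root)
            if lab is None:
                lab = len(sizes) + 1
                root_to_label[root] = lab
                sizes.append(0)
                bboxes.append([r, s, r, e])
            labels[r, s : e + 1] = lab
            sizes[lab - 1] += e - s + 1
            bb = bboxes[lab - 1]
            bb[0] = min(bb[0], r)
            bb[1] = min(bb[1], s)
            bb[2] = max(bb[2], r)
            bb[3] = max(bb[3], e)
    return ComponentSet(
        labels=labels,
        sizes=np.asarray(sizes, dtype=np.int64),
        bboxes=np.asarray(bboxes, dtype=np.int64).reshape(-1, 4),
    )


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def clahe(f: Frame, clip_limit: float = 2.0, tiles: tuple[int, int] = (8, 8)) -> Frame:
    """Contrast-limited adaptive histogram equalization.

    The frame is divided into ``tiles`` (rows, cols); each tile's histogram
    is clipped at ``clip_limit`` times the uniform bin height, the excess
    is redistributed evenly, and per-tile equalization mappings are blended
    with bilinear interpolation. The frame must be at least one pixel per
    tile.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    tr, tc = int(tiles[0]), int(tiles[1])
    if tr < 1 or tc < 1:
        raise ValueError("tiles must be >= (1, 1)")
    H, W = f.pixels.shape
    if H < tr or W < tc:
        raise ValueError(f"frame {H}x{W} smaller than tile grid {tr}x{tc}")

    th = -(-H // tr)  # ceil tile height
    tw = -(-W // tc)
    Hp, Wp = th * tr, tw * tc
    img = np.pad(f.pixels, ((0, Hp - H), (0, Wp - W)), mode="reflect")

    area = th * tw
    limit = max(1, int(clip_limit * area / 256))
    luts = np.empty((tr, tc, 256), dtype=np.uint8)
    scale = 255.0 / area
    for i in range(tr):
        for j in range(tc):
            tile = img[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.int64)
            excess = int(np.maximum(hist - limit, 0).sum())
            hist = np.minimum(hist, limit)
            hist += excess // 256
            rem = excess % 256
            if rem:  # spread the remainder at an even stride across bins
                step = max(256 // rem, 1)
                idx = np.arange(0, 256, step)[:rem]
                hist[idx] += 1
            cdf = np.cumsum(hist)
            luts[i, j] = np.clip(np.rint(cdf * scale), 0, 255).astype(np.uint8)

    # bilinear blend of the four surrounding tile mappings
    ty = (np.arange(Hp) + 0.5) / th - 0.5
    tx = (np.arange(Wp) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(ty), 0, tr - 1).astype(int)
    x0 = np.clip(np.floor(tx), 0, tc - 1).astype(int)
    y1 = np.clip(y0 + 1, 0, tr - 1)
    x1 = np.clip(x0 + 1, 0, tc - 1)
    wy = np.clip(ty - np.floor(ty), 0.0, 1.0)
    wx = np.clip(tx - np.floor(tx), 0.0, 1.0)
    wy[ty < 0] = 0.0
    wy[ty > tr - 1] = 1.0
    wx[tx < 0] = 0.0
    wx[tx > tc - 1] = 1.0

    v = img.astype(int)
    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    WY = wy[:, None]
    WX = wx[None, :]
    out = (
        (1 - WY) * (1 - WX) * luts[Y0, X0, v]
        + (1 - WY) * WX * luts[Y0, X1, v]
        + WY * (1 - WX) * luts[Y1, X0, v]
        + WY * WX * luts[Y1, X1, v]
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)[:H, :W]
    return Frame(out, timestamp=f.timestamp, tier=f.tier)
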