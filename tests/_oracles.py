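"""Independent oracles used by the test suite.

These deliberately share no code with the package implementation: the
blur oracle is a naive nested-loop 2-D convolution with mirrored
indexing, and the component oracle is a breadth-first flood fill.
"""

import numpy as np

from octotrigger.imaging import gaussian_kernel1d


def brute_force_blur(pixels: np.ndarray, k: int) -> np.ndarray:
    """Direct 2-D convolution with reflected (edge-excluding) borders."""
    kern1 = gaussian_kernel1d(k)
    kern = np.outer(kern1, kern1)
    H, W = pixels.shape
    p = k // 2

    def reflect(i, n):
        # mirror without repeating the edge sample: -1 -> 1, n -> n-2
        while i < 0 or i >= n:
            if i < 0:
                i = -i
            if i >= n:
                i = 2 * (n - 1) - i
        return i

    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            acc = 0.0
            for dr in range(-p, p + 1):
                for dc in range(-p, p + 1):
                    acc += (
                        kern[dr + p, dc + p]
                        * pixels[reflect(r + dr, H), reflect(c + dc, W)]
                    )
            out[r, c] = acc
    return np.clip(np.rint(out), 0, 255)


def flood_fill_components(bits: np.ndarray):
    """BFS flood fill, 8-connected; returns (labels, sizes)."""
    H, W = bits.shape
    labels = np.zeros((H, W), dtype=int)
    sizes = []
    nxt = 0
    for r in range(H):
        for c in range(W):
            if bits[r, c] and not labels[r, c]:
                nxt += 1
                queue = [(r, c)]
                labels[r, c] = nxt
                n = 0
                while queue:
                    y, x = queue.pop()
                    n += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < H and 0 <= xx < W
                                and bits[yy, xx] and not labels[yy, xx]
                            ):
                                labels[yy, xx] = nxt
                                queue.append((yy, xx))
                sizes.append(n)
    return labels, np.array(sizes, dtype=int)
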