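"""Imaging operators against independent oracles.

The blur oracle is a direct 2-D convolution with reflected indexing; the
connected-components oracle is a breadth-first flood fill; closing is
cross-checked against scipy morphology on a zero-embedded domain and
CLAHE behaviourally against scikit-image.
"""

import numpy as np
import pytest
from scipy import ndimage as ndi

from octotrigger.frames import Frame, ForegroundMask
from octotrigger.imaging import (
    clahe,
    connected_components,
    crop_roi,
    gaussian_blur,
    gaussian_kernel1d,
    morph_close,
)


from _oracles import brute_force_blur, flood_fill_components  # noqa: E402


# ---------------------------------------------------------------------------
# Gaussian blur
# ---------------------------------------------------------------------------

def test_blur_preserves_constant_frames():
    f = Frame(np.full((20, 30), 7, dtype=np.uint8))
    assert np.array_equal(gaussian_blur(f, 5).pixels, f.pixels)


def test_blur_kernel_side_one_is_identity():
    rng = np.random.default_rng(0)
    f = Frame(rng.integers(0, 256, (10, 10), dtype=np.uint8))
    assert np.array_equal(gaussian_blur(f, 1).pixels, f.pixels)


def test_blur_rejects_even_kernel():
    with pytest.raises(ValueError):
        gaussian_blur(Frame(np.zeros((4, 4), dtype=np.uint8)), 4)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("k", [3, 5])
def test_blur_matches_brute_force_convolution(seed, k):
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    got = gaussian_blur(Frame(pixels), k).pixels.astype(float)
    want = brute_force_blur(pixels, k)
    assert np.abs(got - want).max() <= 1  # rounding slack


def test_blur_is_shift_equivariant_away_from_borders():
    rng = np.random.default_rng(3)
    base = rng.integers(0, 256, (24, 24), dtype=np.uint8)
    shifted = np.roll(base, (2, 3), axis=(0, 1))
    a = gaussian_blur(Frame(base), 5).pixels
    b = gaussian_blur(Frame(shifted), 5).pixels
    assert np.array_equal(
        np.roll(a, (2, 3), axis=(0, 1))[6:-6, 6:-6], b[6:-6, 6:-6]
    )


# ---------------------------------------------------------------------------
# ROI crop
# ---------------------------------------------------------------------------

def test_default_roi_crop_geometry():
    f = Frame(np.zeros((240, 320), dtype=np.uint8))
    c = crop_roi(f, (20, 20, 280, 200))
    assert c.pixels.shape == (200, 280)


def test_full_frame_crop_is_identity():
    rng = np.random.default_rng(4)
    f = Frame(rng.integers(0, 256, (240, 320), dtype=np.uint8))
    assert np.array_equal(crop_roi(f, (0, 0, 320, 240)).pixels, f.pixels)


def test_out_of_bounds_roi_raises():
    f = Frame(np.zeros((240, 320), dtype=np.uint8))
    with pytest.raises(ValueError):
        crop_roi(f, (300, 0, 40, 40))


def test_crop_converts_bottom_left_origin():
    pixels = np.zeros((240, 320), dtype=np.uint8)
    pixels[239, 0] = 99  # bottom-left pixel in top-left storage
    c = crop_roi(Frame(pixels), (0, 0, 10, 10))
    assert c.pixels[9, 0] == 99


# ---------------------------------------------------------------------------
# Morphological closing
# ---------------------------------------------------------------------------

def test_close_merges_one_pixel_gap():
    bits = np.zeros((5, 9), dtype=np.uint8)
    bits[1:4, 1:4] = 1
    bits[1:4, 5:8] = 1  # two 3x3 blobs, 1-px gap at column 4
    closed = morph_close(ForegroundMask(bits), 3)
    comps = connected_components(closed)
    assert comps.n_components == 1
    assert closed.bits[1:4, 4].all()  # the gap column is filled


def test_close_fixed_points():
    zero = ForegroundMask(np.zeros((8, 8), dtype=np.uint8))
    one = ForegroundMask(np.ones((8, 8), dtype=np.uint8))
    assert morph_close(zero, 3).popcount() == 0
    assert morph_close(one, 3).popcount() == 64


@pytest.mark.parametrize("k", [2, 3, 5])
def test_close_is_idempotent(k):
    rng = np.random.default_rng(5)
    for _ in range(25):
        bits = (rng.random((30, 30)) < 0.3).astype(np.uint8)
        once = morph_close(ForegroundMask(bits), k)
        twice = morph_close(once, k)
        assert np.array_equal(once.bits, twice.bits)


def test_close_matches_scipy_on_zero_embedded_domain():
    rng = np.random.default_rng(6)
    for _ in range(25):
        bits = (rng.random((40, 40)) < 0.3).astype(np.uint8)
        got = morph_close(ForegroundMask(bits), 3).bits
        big = np.pad(bits, 2)
        ref = ndi.binary_closing(big, structure=np.ones((3, 3)))[2:-2, 2:-2]
        assert np.array_equal(got, ref.astype(np.uint8))


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def test_empty_mask_has_zero_components():
    comps = connected_components(ForegroundMask(np.zeros((10, 10), dtype=np.uint8)))
    assert comps.n_components == 0
    assert comps.largest_bbox() is None


def test_solid_rectangle_single_component():
    bits = np.zeros((40, 40), dtype=np.uint8)
    bits[5:25, 10:35] = 1  # 20 rows x 25 cols
    comps = connected_components(ForegroundMask(bits))
    assert comps.n_components == 1
    assert comps.sizes[0] == 500
    assert comps.largest_bbox() == (5, 10, 24, 34)


def test_components_match_flood_fill_oracle():
    rng = np.random.default_rng(7)
    for trial in range(200):
        density = rng.uniform(0.1, 0.7)
        bits = (rng.random((32, 32)) < density).astype(np.uint8)
        comps = connected_components(ForegroundMask(bits))
        labels, sizes = flood_fill_components(bits)
        assert comps.n_components == len(sizes), f"trial {trial}"
        assert sorted(comps.sizes) == sorted(sizes), f"trial {trial}"
        # same partition: label grids agree up to renaming
        for lab in range(1, comps.n_components + 1):
            region = comps.labels == lab
            oracle_labels = np.unique(labels[region])
            assert len(oracle_labels) == 1, f"trial {trial}"


def test_component_sizes_sum_to_popcount_and_transpose_invariance():
    rng = np.random.default_rng(8)
    bits = (rng.random((20, 30)) < 0.4).astype(np.uint8)
    comps = connected_components(ForegroundMask(bits))
    assert comps.sizes.sum() == bits.sum()
    comps_t = connected_components(ForegroundMask(bits.T))
    assert sorted(comps.sizes) == sorted(comps_t.sizes)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def test_clahe_constant_frame_stays_constant():
    f = Frame(np.full((128, 128), 100, dtype=np.uint8))
    out = clahe(f, 2.0, (4, 4))
    assert len(np.unique(out.pixels)) == 1


def test_clahe_output_stays_in_range():
    rng = np.random.default_rng(9)
    f = Frame(rng.integers(0, 256, (64, 96), dtype=np.uint8))
    out = clahe(f, 3.0, (4, 4)).pixels
    assert out.min() >= 0 and out.max() <= 255 and out.dtype == np.uint8


def test_clahe_rejects_frame_smaller_than_tile_grid():
    with pytest.raises(ValueError):
        clahe(Frame(np.zeros((4, 4), dtype=np.uint8)), 2.0, (8, 8))


def test_clahe_expands_low_contrast_separation():
    """A two-level 100/110 frame must come out at least as separated;
    scikit-image's CLAHE on the same frame confirms the direction."""
    from skimage import exposure

    two = np.full((128, 128), 100, dtype=np.uint8)
    two[:, 64:] = 110
    out = clahe(Frame(two), 8.0, (4, 4)).pixels
    sep_in = 10.0
    sep_out = float(out[:, 80:].mean() - out[:, :48].mean())
    assert sep_out >= sep_in
    ref = exposure.equalize_adapthist(two, kernel_size=32, clip_limit=0.03)
    sep_ref = float((ref[:, 80:].mean() - ref[:, :48].mean()) * 255)
    assert sep_ref >= sep_in  # the reference agrees contrast should not shrink


def test_operators_are_deterministic():
    rng = np.random.default_rng(10)
    pixels = rng.integers(0, 256, (60, 80), dtype=np.uint8)
    f = Frame(pixels)
    assert np.array_equal(gaussian_blur(f, 5).pixels, gaussian_blur(f, 5).pixels)
    assert np.array_equal(clahe(f).pixels, clahe(f).pixels)
    bits = (rng.random((60, 80)) < 0.4).astype(np.uint8)
    m = ForegroundMask(bits)
    assert np.array_equal(morph_close(m).bits, morph_close(m).bits)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings as hyp_settings, strategies as st
from hypothesis.extra.numpy import arrays


@hyp_settings(max_examples=60, derandomize=True, deadline=None)
@given(arrays(np.uint8, (12, 15), elements=st.integers(0, 1)))
def test_close_idempotence_and_component_accounting_property(bits):
    """For arbitrary masks: closing is idempotent, never removes
    foreground, and component sizes always sum to the mask popcount."""
    m = ForegroundMask(bits)
    closed = morph_close(m, 3)
    assert np.array_equal(closed.bits, morph_close(closed, 3).bits)
    assert (closed.bits >= bits).all()  # closing is extensive
    comps = connected_components(closed)
    assert comps.sizes.sum() == closed.popcount()
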