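"""Alignment recovery, exact histogram specification, block-mean downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organelleseg.preprocess import (align_translational, downsample_xy,
                                     exact_histogram_specification,
                                     pixel_rank_order, specify_stack)
from organelleseg.types import GrayscaleStack

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Alignment

def test_identical_slices_align_to_zero():
    sl = RNG.integers(0, 256, (32, 32)).astype(np.uint8)
    stack = np.stack([sl, sl, sl])
    aligned, offsets = align_translational(stack, max_shift=4)
    assert offsets == [(0, 0), (0, 0), (0, 0)]
    assert np.array_equal(aligned, stack)


def test_single_known_shift_recovered():
    base = RNG.integers(0, 256, (40, 40)).astype(np.uint8)
    shifted = np.roll(base, (-2, 3), axis=(0, 1))
    _, offsets = align_translational(np.stack([base, shifted]), max_shift=5)
    assert offsets == [(0, 0), (2, -3)]


def test_cumulative_offsets_compose():
    base = RNG.integers(0, 256, (40, 40)).astype(np.uint8)
    s1 = np.roll(base, (1, 0), axis=(0, 1))
    s2 = np.roll(base, (2, 0), axis=(0, 1))
    _, offsets = align_translational(np.stack([base, s1, s2]), max_shift=5)
    assert offsets == [(0, 0), (-1, 0), (-2, 0)]


@given(dy=st.integers(-5, 5), dx=st.integers(-5, 5), seed=st.integers(0, 50))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_integer_shift_exact_recovery(dy, dx, seed):
    base = np.random.default_rng(seed).integers(0, 256, (48, 48)).astype(np.uint8)
    shifted = np.roll(base, (dy, dx), axis=(0, 1))
    _, offsets = align_translational(np.stack([base, shifted]), max_shift=5)
    assert offsets[1] == (-dy, -dx)


def test_single_slice_is_noop():
    sl = RNG.integers(0, 256, (1, 8, 8)).astype(np.uint8)
    aligned, offsets = align_translational(sl, max_shift=3)
    assert offsets == [] and np.array_equal(aligned, sl)


def test_flat_slice_warns_and_zero_shift():
    base = RNG.integers(0, 256, (16, 16)).astype(np.uint8)
    flat = np.full((16, 16), 100, np.uint8)
    with pytest.warns(UserWarning, match="flat"):
        _, offsets = align_translational(np.stack([base, flat]), max_shift=3)
    assert offsets[1] == (0, 0)


def test_border_fill_uses_median():
    base = np.full((10, 10), 7, np.uint8)
    base[0, 0] = 200
    shifted = np.roll(base, (3, 0), axis=(0, 1))
    aligned, offsets = align_translational(np.stack([base, shifted]), max_shift=4)
    assert offsets[1] == (-3, 0)
    assert (aligned[1, -3:] == 7).all()  # vacated rows filled with median


# ---------------------------------------------------------------------------
# Exact histogram specification

def _sort_and_assign_oracle(img, target):
    """Independent oracle: explicit per-pixel key sort then assignment."""
    h, w = img.shape
    from scipy import ndimage
    f = img.astype(float)
    kernels = []
    c3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], float)
    f3 = np.ones((3, 3))
    c5 = np.zeros((5, 5)); c5[2, :] = 1; c5[:, 2] = 1
    f5 = np.ones((5, 5)); f7 = np.ones((7, 7))
    means = [ndimage.convolve(f, k / k.sum(), mode="reflect")
             for k in (c3, f3, c5, f5, f7)]
    entries = []
    for i in range(h):
        for j in range(w):
            entries.append(((f[i, j], *[m[i, j] for m in means], i * w + j),
                            i * w + j))
    entries.sort()
    values = np.repeat(np.arange(256, dtype=np.uint8), target)
    out = np.empty(h * w, np.uint8)
    for rank, (_, flat) in enumerate(entries):
        out[flat] = values[rank]
    return out.reshape(h, w)


def test_toy_image_matches_sort_and_assign_oracle():
    img = np.array([[3, 3, 1, 0], [3, 2, 2, 1], [0, 0, 3, 2], [1, 1, 2, 0]],
                   dtype=np.uint8)
    target = np.zeros(256, np.int64)
    target[[10, 50, 100, 200]] = 4
    out = exact_histogram_specification(img, target)
    assert np.array_equal(out, _sort_and_assign_oracle(img, target))


def test_self_specification_is_identity_histogram():
    img = RNG.integers(0, 256, (16, 16)).astype(np.uint8)
    own = np.bincount(img.ravel(), minlength=256)
    out = exact_histogram_specification(img, own)
    assert np.array_equal(np.bincount(out.ravel(), minlength=256), own)


def test_uniform_target_exact():
    img = RNG.integers(0, 256, (16, 16)).astype(np.uint8)
    out = exact_histogram_specification(img, np.ones(256, np.int64))
    assert np.array_equal(np.bincount(out.ravel(), minlength=256),
                          np.ones(256, np.int64))


@given(seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_output_histogram_always_equals_target(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
    raw = rng.multinomial(img.size, np.full(256, 1 / 256))
    out = exact_histogram_specification(img, raw)
    assert np.array_equal(np.bincount(out.ravel(), minlength=256), raw)
    # double application with the same target is idempotent
    out2 = exact_histogram_specification(out, raw)
    assert np.array_equal(out, out2)


def test_histogram_sum_mismatch_rejected():
    img = np.zeros((4, 4), np.uint8)
    bad = np.zeros(256, np.int64)
    bad[0] = 15
    with pytest.raises(ValueError, match="sums to"):
        exact_histogram_specification(img, bad)


def test_rank_preservation():
    img = RNG.integers(0, 256, (10, 10)).astype(np.uint8)
    target = np.bincount(RNG.integers(0, 256, 100), minlength=256)
    out = exact_histogram_specification(img, target)
    order = pixel_rank_order(img)
    ranked_out = out.ravel()[order]
    assert (np.diff(ranked_out.astype(int)) >= 0).all()


def test_specify_stack_matches_first_slice():
    a = RNG.integers(0, 200, (16, 16)).astype(np.uint8)
    b = np.clip(a.astype(int) + 40, 0, 255).astype(np.uint8)
    out = specify_stack(np.stack([a, b]))
    assert np.array_equal(out[0], a)
    assert np.array_equal(np.bincount(out[1].ravel(), minlength=256),
                          np.bincount(a.ravel(), minlength=256))


# ---------------------------------------------------------------------------
# Downsampling

def test_factor_one_is_identity():
    vol = RNG.integers(0, 256, (2, 8, 8)).astype(np.uint8)
    assert np.array_equal(downsample_xy(vol, 1), vol)


def test_hand_computed_block_means():
    sl = np.array([[10, 10, 20, 20], [10, 10, 20, 20],
                   [30, 30, 40, 40], [30, 30, 40, 40]], np.uint8)
    out = downsample_xy(sl[None], 2)
    assert np.array_equal(out[0], np.array([[10, 20], [30, 40]]))


def test_shapes_floor_and_pixel_size_scaling():
    stack = GrayscaleStack(RNG.integers(0, 256, (2, 33, 65)).astype(np.uint8),
                           pixel_size_xy=3.899)
    out = downsample_xy(stack, 2)
    assert out.voxels.shape == (2, 16, 32)
    assert out.pixel_size_xy == pytest.approx(7.798)


def test_total_intensity_conserved_within_rounding():
    vol = RNG.integers(0, 256, (1, 30, 30)).astype(np.uint8)
    out = downsample_xy(vol, 3)
    n_blocks = out.size
    assert abs(out.astype(float).sum() - vol.astype(float).sum() / 9) <= 0.5 * n_blocks


def test_factor_exceeding_dimensions_rejected():
    with pytest.raises(ValueError):
        downsample_xy(np.zeros((1, 4, 4), np.uint8), 5)
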