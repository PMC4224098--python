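"""Slice alignment, exact histogram specification, lateral downsampling.

SBEM stacks drift laterally between cuts and their per-slice brightness
wanders with beam/staining conditions.  The preprocessing stage therefore
(1) translationally aligns consecutive slices by cross-correlation,
(2) forces every slice's histogram to exactly match the first slice's, and
(3) optionally block-mean downsamples in XY.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .types import GrayscaleStack, as_slices

__all__ = [
    "align_translational",
    "exact_histogram_specification",
    "specify_stack",
    "downsample_xy",
]


# ---------------------------------------------------------------------------
# Translational alignment

def _best_shift(ref: np.ndarray, mov: np.ndarray, max_shift: int):
    """Integer (dy, dx) within +-max_shift maximizing the circular
    cross-correlation of the mean-subtracted slices.

    Ties are broken toward the smallest L2-norm shift, then lexicographically.
    """
    a = ref.astype(np.float64) - ref.mean()
    b = mov.astype(np.float64) - mov.mean()
    if a.std() == 0 or b.std() == 0:
        warnings.warn("flat slice encountered during alignment; zero shift used")
        return (0, 0)
    # corr(dy, dx) = sum_p ref(p) * mov(p - (dy, dx)): shifting mov by (dy, dx)
    corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    shifts = [(dy, dx)
              for dy in range(-max_shift, max_shift + 1)
              for dx in range(-max_shift, max_shift + 1)]
    vals = np.array([corr[dy % a.shape[0], dx % a.shape[1]] for dy, dx in shifts])
    best = vals.max()
    cands = [s for s, v in zip(shifts, vals) if np.isclose(v, best, rtol=0, atol=1e-9 * abs(best) + 1e-12)]
    cands.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s))
    return cands[0]


def _apply_shift(slc: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a slice by (dy, dx), filling vacated borders with its median."""
    fill = np.median(slc)
    out = np.roll(slc, (dy, dx), axis=(0, 1))
    if dy > 0:
        out[:dy] = fill
    elif dy < 0:
        out[dy:] = fill
    if dx > 0:
        out[:, :dx] = fill
    elif dx < 0:
        out[:, dx:] = fill
    return out


def align_translational(stack, max_shift: int = 10):
    """Cumulatively align each slice to the previous aligned slice.

    Returns ``(aligned_stack, offsets)`` where ``offsets[z] = (dy, dx)`` is
    the cumulative correction applied to slice z (slice 0 is the reference
    with offset (0, 0)).  Output shape is unchanged; vacated borders are
    filled with the slice median.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    vol = as_slices(stack)
    if vol.shape[0] < 2:
        out = vol.copy()
        return _rewrap(stack, out), []
    aligned = np.empty_like(vol)
    aligned[0] = vol[0]
    offsets = [(0, 0)]
    for z in range(1, vol.shape[0]):
        dy, dx = _best_shift(aligned[z - 1], vol[z], max_shift)
        aligned[z] = _apply_shift(vol[z], dy, dx)
        offsets.append((dy, dx))
    return _rewrap(stack, aligned), offsets


def _rewrap(template, voxels):
    if isinstance(template, GrayscaleStack):
        return GrayscaleStack(voxels, pixel_size_xy=template.pixel_size_xy,
                              slice_thickness=template.slice_thickness,
                              provenance=template.provenance)
    return voxels


# ---------------------------------------------------------------------------
# Exact histogram specification

# Auxiliary local-mean filters imposing a strict ordering on equal-intensity
# pixels: growing neighborhoods, cross before full, per Coltuc-style exact
# specification.
_CROSS3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], float)
_FULL3 = np.ones((3, 3))
_CROSS5 = np.zeros((5, 5)); _CROSS5[2, :] = 1; _CROSS5[:, 2] = 1
_FULL5 = np.ones((5, 5))
_FULL7 = np.ones((7, 7))
_ORDER_KERNELS = [_CROSS3, _FULL3, _CROSS5, _FULL5, _FULL7]


def _ordering_keys(img: np.ndarray):
    """Return the stack of tie-breaker keys, coarsest-priority first."""
    f = img.astype(np.float64)
    keys = [f]
    for k in _ORDER_KERNELS:
        keys.append(ndimage.convolve(f, k / k.sum(), mode="reflect"))
    return keys


def pixel_rank_order(img: np.ndarray) -> np.ndarray:
    """Strict total order of pixels: intensity, then successive local means,
    then raster index.  Returns flat indices from darkest to brightest."""
    keys = _ordering_keys(img)
    flat = [k.ravel() for k in keys]
    raster = np.arange(img.size)
    # np.lexsort: last key is the primary sort key
    return np.lexsort((raster, *flat[::-1]))


def exact_histogram_specification(image: np.ndarray, target_histogram) -> np.ndarray:
    """Force the image's histogram to equal ``target_histogram`` bin-for-bin.

    Pixels are ranked under the strict total order and the sorted multiset of
    target intensities is assigned in rank order, so the output histogram is
    exactly the target and rank order is preserved.
    """
    img = np.asarray(image)
    target = np.asarray(target_histogram, dtype=np.int64)
    if target.shape != (256,):
        raise ValueError("target histogram must have 256 bins")
    if target.sum() != img.size:
        raise ValueError(
            f"target histogram sums to {target.sum()}, image has {img.size} pixels")
    order = pixel_rank_order(img)
    values = np.repeat(np.arange(256, dtype=np.uint8), target)
    out = np.empty(img.size, dtype=np.uint8)
    out[order] = values
    return out.reshape(img.shape)


def specify_stack(stack):
    """Match every slice's histogram exactly to that of the first slice."""
    vol = as_slices(stack)
    out = vol.copy()
    target = np.bincount(vol[0].ravel(), minlength=256)
    for z in range(1, vol.shape[0]):
        out[z] = exact_histogram_specification(vol[z], target)
    return _rewrap(stack, out)


# ---------------------------------------------------------------------------
# Downsampling

def downsample_xy(stack, factor: int):
    """Block-mean downsample in XY by an integer factor.

    Output pixel = rounded mean of its factor x factor source block;
    H' = floor(H/factor), W' = floor(W/factor); Z unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    vol = as_slices(stack)
    z, h, w = vol.shape
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds slice dimensions {h}x{w}")
    if factor == 1:
        return _rewrap_scaled(stack, vol.copy(), 1)
    h2, w2 = h // factor, w // factor
    trimmed = vol[:, :h2 * factor, :w2 * factor].astype(np.float64)
    blocks = trimmed.reshape(z, h2, factor, w2, factor).mean(axis=(2, 4))
    out = np.rint(blocks).astype(vol.dtype)
    return _rewrap_scaled(stack, out, factor)


def _rewrap_scaled(template, voxels, factor):
    if isinstance(template, GrayscaleStack):
        ps = template.pixel_size_xy * factor if template.pixel_size_xy else None
        return GrayscaleStack(voxels, pixel_size_xy=ps,
                              slice_thickness=template.slice_thickness,
                              provenance=template.provenance)
    return voxels
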