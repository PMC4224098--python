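"""Thresholders vs brute-force criterion scans, shrinking, active contours."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import ndimage

from organelleseg.binarize import (binarize_probability_map, chan_vese_energy,
                                   evolve_active_contours, histogram256,
                                   maximum_entropy_criterion,
                                   minimum_error_criterion,
                                   morphological_shrink, optimal_threshold_sweep,
                                   otsu_multilevel, threshold_maximum_entropy,
                                   threshold_minimum_error, threshold_otsu_single,
                                   top_level_mask)
from organelleseg.binarize import _optimal_cuts, _bin_threshold


# ---------------------------------------------------------------------------
# Brute-force oracles

def brute_otsu_cuts(hist, G):
    """Exhaustive between-class variance maximization over all cut tuples."""
    p = hist / hist.sum()
    centers = (np.arange(256) + 0.5) / 256
    best, arg = -1.0, None
    for cuts in itertools.combinations(range(255), G):
        bounds = [-1] + list(cuts) + [255]
        v = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            w = p[a + 1:b + 1].sum()
            if w > 0:
                mu = (p[a + 1:b + 1] * centers[a + 1:b + 1]).sum()
                v += mu * mu / w
        if v > best + 1e-15:
            best, arg = v, cuts
    return list(arg)


def _random_histogram(seed):
    rng = np.random.default_rng(seed)
    hist = rng.integers(0, 100, 256)
    hist[rng.integers(0, 256, size=3)] += rng.integers(200, 800, size=3)
    return hist


@pytest.mark.parametrize("G", [1, 2])
def test_multilevel_otsu_equals_exhaustive_search(G):
    for seed in range(25):
        hist = _random_histogram(seed)
        assert _optimal_cuts(hist, G) == brute_otsu_cuts(hist, G), seed


def test_three_level_otsu_equals_exhaustive_search():
    hist = _random_histogram(123)
    assert _optimal_cuts(hist, 3) == brute_otsu_cuts(hist, 3)


def test_g1_reduces_to_single_otsu():
    rng = np.random.default_rng(17)
    vals = rng.random(4000)
    lv = otsu_multilevel(vals, 1)
    single = threshold_otsu_single(vals)
    assert np.array_equal(top_level_mask(lv), single)


def test_bimodal_threshold_between_peaks():
    vals = np.concatenate([np.full(500, 0.1), np.full(500, 0.9)])
    lv = otsu_multilevel(vals, 1)
    assert 0.1 < lv.thresholds[0] < 0.9
    assert (top_level_mask(lv) == (vals > 0.5)).all()


def test_three_equal_values_labelled_0_1_2():
    vals = np.repeat([0.0, 0.5, 1.0], 100)
    lv = otsu_multilevel(vals, 2)
    assert set(lv.values[:100]) == {0}
    assert set(lv.values[100:200]) == {1}
    assert set(lv.values[200:]) == {2}


def test_constant_map_has_no_threshold():
    with pytest.raises(ValueError, match="constant"):
        otsu_multilevel(np.full(100, 0.5), 2)


def test_minimum_error_and_max_entropy_match_brute_scans():
    for seed in (11, 12, 13):
        rng = np.random.default_rng(seed)
        vals = np.clip(np.concatenate([rng.normal(0.3, 0.08, 3000),
                                       rng.normal(0.75, 0.05, 1500)]), 0, 1)
        hist = histogram256(vals)
        J = minimum_error_criterion(hist)
        b_me = int(np.argmin(J))
        assert np.array_equal(threshold_minimum_error(vals),
                              (vals >= _bin_threshold(b_me)).astype(np.uint8))
        H = maximum_entropy_criterion(hist)
        b_en = int(np.argmax(H))
        assert np.array_equal(threshold_maximum_entropy(vals),
                              (vals >= _bin_threshold(b_en)).astype(np.uint8))


def test_separated_modes_all_thresholders_between():
    """Each thresholder's cut falls strictly between the two mode centers."""
    rng = np.random.default_rng(1)
    vals = np.clip(np.concatenate([rng.normal(0.15, 0.04, 4000),
                                   rng.normal(0.85, 0.04, 2000)]), 0, 1)
    for fn in (threshold_minimum_error, threshold_maximum_entropy,
               threshold_otsu_single):
        mask = fn(vals).astype(bool)
        assert mask.any() and not mask.all()
        implied_threshold = vals[mask].min()
        assert 0.15 < implied_threshold < 0.85
        # pixels at the mode centers are classified with their mode
        assert not mask[np.abs(vals - 0.15) < 0.01].any()
        assert mask[np.abs(vals - 0.85) < 0.01].all()


def test_otsu_single_on_binary_map_selects_ones():
    vals = np.array([0.0, 0.0, 1.0, 1.0, 0.0])
    assert np.array_equal(threshold_otsu_single(vals),
                          np.array([0, 0, 1, 1, 0], np.uint8))


# ---------------------------------------------------------------------------
# Level map / top mask

def test_top_level_mask_indexing():
    from organelleseg.binarize import LevelMap
    lm = LevelMap(values=np.array([[0, 1, 2], [2, 0, 1], [0, 0, 0]]),
                  thresholds=(0.3, 0.6), G=2)
    assert np.array_equal(top_level_mask(lm),
                          np.array([[0, 0, 1], [1, 0, 0], [0, 0, 0]], np.uint8))


# ---------------------------------------------------------------------------
# Morphological shrinking

def test_single_pixel_survives_two_iterations():
    m = np.zeros((5, 5), np.uint8)
    m[2, 2] = 1
    assert np.array_equal(morphological_shrink(m, 2), m)


def test_square_shrinks_without_losing_component():
    m = np.zeros((9, 9), np.uint8)
    m[2:7, 2:7] = 1
    out = morphological_shrink(m, 2)
    assert out.sum() < m.sum() and out.sum() >= 1
    assert (out <= m).all()
    _, n = ndimage.label(out, structure=np.ones((3, 3)))
    assert n == 1


def test_empty_mask_stays_empty():
    assert not morphological_shrink(np.zeros((6, 6), np.uint8), 2).any()


def test_component_count_preserved_on_random_masks():
    rng = np.random.default_rng(8)
    s8 = np.ones((3, 3))
    for _ in range(10):
        m = (ndimage.gaussian_filter(rng.random((40, 40)), 2) > 0.55)
        _, n_before = ndimage.label(m, structure=s8)
        out = morphological_shrink(m.astype(np.uint8), 2)
        _, n_after = ndimage.label(out, structure=s8)
        assert n_after == n_before
        assert (out <= m.astype(np.uint8)).all()


def test_ring_survives_shrinking():
    yy, xx = np.mgrid[0:15, 0:15]
    d = np.hypot(yy - 7, xx - 7)
    ring = ((d <= 6) & (d >= 4)).astype(np.uint8)
    out = morphological_shrink(ring, 2)
    _, n = ndimage.label(out, structure=np.ones((3, 3)))
    assert n == 1 and out.sum() >= 8  # still a loop, not a point


# ---------------------------------------------------------------------------
# Active contours

def _disk(shape=(64, 64), center=(32, 32), r=18):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (np.hypot(yy - center[0], xx - center[1]) <= r).astype(np.uint8)


def test_crisp_binary_map_recovered_exactly():
    disk = _disk()
    init = ndimage.binary_erosion(disk, iterations=4).astype(np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = evolve_active_contours(disk.astype(float), init, alpha=100, lam=0)
    assert np.array_equal(seg, disk)


def test_blurred_disk_matches_midpoint_threshold_oracle():
    disk = _disk().astype(float)
    blur = ndimage.gaussian_filter(disk, 2.0)
    blur = (blur - blur.min()) / (blur.max() - blur.min())
    init = morphological_shrink(top_level_mask(otsu_multilevel(blur, 2)), 2)
    seg = evolve_active_contours(blur, init, alpha=100, lam=0)
    c1 = blur[seg > 0].mean()
    c2 = blur[seg == 0].mean()
    oracle = blur >= (c1 + c2) / 2
    mismatch = oracle ^ (seg > 0)
    boundary = ndimage.binary_dilation(oracle) ^ ndimage.binary_erosion(oracle)
    assert (mismatch & ~ndimage.binary_dilation(boundary)).sum() == 0


def test_energy_non_increasing_per_iteration():
    disk = _disk().astype(float)
    blur = ndimage.gaussian_filter(disk, 2.0)
    blur = (blur - blur.min()) / (blur.max() - blur.min())
    init = ndimage.binary_erosion(disk > 0, iterations=4).astype(np.uint8)
    for lam in (0, 4):
        seg, energies = evolve_active_contours(blur, init, alpha=60, lam=lam,
                                               return_energy=True)
        deltas = np.diff(energies)
        assert (deltas <= 1e-6).all()


def test_weak_distractor_removed_from_segmentation(blob_probability_map):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = binarize_probability_map(blob_probability_map, G=2, alpha=100, lam=0)
    assert seg[:45, :45].sum() > 100     # strong blob segmented
    assert seg[45:, 45:].sum() == 0      # weak (~0.4) distractor excluded


def test_empty_init_gives_empty_segmentation():
    m = np.random.default_rng(0).random((20, 20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = evolve_active_contours(m, np.zeros((20, 20), np.uint8),
                                     alpha=60, lam=0)
    assert not seg.any()


def test_increasing_g_never_grows_foreground(blob_probability_map):
    areas = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for G in (1, 2, 3, 4):
            seg = binarize_probability_map(blob_probability_map, G=G,
                                           alpha=100, lam=0)
            areas.append(int(seg.sum()))
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_binary_map_binarization_idempotent():
    disk = _disk()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = binarize_probability_map(disk.astype(float), G=1, alpha=100, lam=0)
        seg2 = binarize_probability_map(seg.astype(float), G=1, alpha=100, lam=0)
    assert np.array_equal(seg, disk)
    assert np.array_equal(seg2, seg)


def test_constant_map_yields_empty_seg_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        seg = binarize_probability_map(np.zeros((10, 10)), G=2, alpha=100, lam=0)
    assert not seg.any()


# ---------------------------------------------------------------------------
# Supervised sweep

def test_perfect_map_sweep():
    truth = np.array([0, 0, 1, 1], np.uint8)
    vals = truth.astype(float)
    t, f = optimal_threshold_sweep(vals, truth)
    assert f == 1.0 and t == pytest.approx(1 / 255)


def test_sweep_equals_enumeration_oracle():
    vals = np.array([0.2, 0.4, 0.6, 0.8])
    truth = np.array([0, 0, 1, 1], np.uint8)
    t, f = optimal_threshold_sweep(vals, truth)
    # enumeration over all cuts of the sorted values
    best = 0.0
    for cut in [0.0, 0.3, 0.5, 0.7, 0.9]:
        seg = vals >= cut
        tp = (seg & (truth == 1)).sum()
        fp = (seg & (truth == 0)).sum()
        fn = ((~seg) & (truth == 1)).sum()
        best = max(best, 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0)
    assert f == pytest.approx(best) == 1.0
    assert 0.4 < t <= 0.6


def test_sweep_requires_nonempty_truth():
    with pytest.raises(ValueError, match="empty"):
        optimal_threshold_sweep(np.array([0.1, 0.9]), np.zeros(2, np.uint8))
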