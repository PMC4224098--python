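"""Unsupervised binarization of probability maps.

The central post-processing idea: threshold the normalized probability map
with multi-level Otsu (G thresholds -> G+1 classes), keep only the top
class as conservative initial positions, shrink it morphologically, then
evolve region-based (Chan-Vese-type) active contours on the probability map
from each initial component.  Comparison single-threshold binarizers
(Kittler-Illingworth minimum error, Kapur maximum entropy, single-level
Otsu) and the supervised F-maximizing threshold sweep are also provided.

All thresholders operate on a 256-uniform-bin histogram of the map over
[0, 1]; ties are broken toward the smallest threshold (vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, ProbabilityMap

__all__ = [
    "LevelMap", "histogram256", "otsu_multilevel", "top_level_mask",
    "morphological_shrink", "evolve_active_contours", "binarize_probability_map",
    "threshold_minimum_error", "threshold_maximum_entropy", "threshold_otsu_single",
    "optimal_threshold_sweep", "chan_vese_energy",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def _map_values(pmap, require_normalized=True) -> np.ndarray:
    if isinstance(pmap, ProbabilityMap):
        if require_normalized and not pmap.normalized:
            raise ValueError("probability map must be normalized to [0, 1]")
        return np.asarray(pmap.values, dtype=np.float64)
    v = np.asarray(pmap, dtype=np.float64)
    if require_normalized and v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    return v


def histogram256(values: np.ndarray) -> np.ndarray:
    """256 uniform bins on [0, 1]; bin b covers [b/256, (b+1)/256)."""
    idx = np.minimum((np.asarray(values, float).ravel() * 256).astype(np.int64), 255)
    return np.bincount(idx, minlength=256)


def _bin_threshold(b: int) -> float:
    """Threshold value separating bins <= b from bins > b."""
    return (b + 1) / 256.0


# ---------------------------------------------------------------------------
# Otsu (single and multi-level)

def _class_term_matrix(hist):
    """T[a, b] = w_k * mu_k^2 for the class spanning bins a..b inclusive.

    Maximizing the sum of these terms over a partition is equivalent to
    maximizing the between-class variance.
    """
    p = hist.astype(np.float64) / hist.sum()
    centers = (np.arange(256) + 0.5) / 256.0
    w = np.concatenate([[0.0], np.cumsum(p)])
    mu = np.concatenate([[0.0], np.cumsum(p * centers)])
    wk = w[None, 1:] - w[:-1, None]      # wk[a, b] = w[b+1] - w[a]
    mk = mu[None, 1:] - mu[:-1, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(wk > 0, mk * mk / np.maximum(wk, 1e-300), 0.0)
    return np.triu(T)


def otsu_multilevel(pmap, G: int):
    """Multi-level Otsu: G thresholds maximizing between-class variance.

    Exact search (dynamic programming over bin cut points, equivalent to
    exhaustive enumeration); ties broken toward the lexicographically
    smallest threshold vector.  Returns a LevelMap with classes 0..G, class 0
    approximating background.
    """
    if not 1 <= G <= 8:
        raise ValueError("G must be in 1..8")
    vals = _map_values(pmap)
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("constant map: no threshold exists")
    hist = histogram256(vals)
    cuts = _optimal_cuts(hist, G)
    thresholds = [_bin_threshold(c) for c in cuts]
    labels = np.zeros(vals.shape, dtype=np.uint8)
    for t in thresholds:
        labels += (vals >= t).astype(np.uint8)
    return LevelMap(values=labels, thresholds=tuple(thresholds), G=G)


def _optimal_cuts(hist, G):
    """Optimal G ascending cut bins; class g spans bins (c_{g-1}, c_g].

    Exact dynamic program over all cut placements (equivalent to exhaustive
    enumeration).  Forward reconstruction with first-argmax selection yields
    the lexicographically smallest optimal cut vector.
    """
    T = _class_term_matrix(hist)
    nb = 256
    # best[k][s] = max achievable over bins s..255 split into k classes
    best = np.full((G + 2, nb), -np.inf)
    best[1] = T[:, nb - 1]
    for k in range(2, G + 2):
        # first class of the remainder spans s..c, then k-1 classes from c+1
        for s in range(nb - k + 1):
            cand = T[s, s:nb - k + 1] + best[k - 1][s + 1:nb - k + 2]
            best[k][s] = cand.max()
    cuts = []
    s = 0
    for k in range(G + 1, 1, -1):
        cand = T[s, s:nb - k + 1] + best[k - 1][s + 1:nb - k + 2]
        c = s + int(np.nonzero(cand >= best[k][s] - 1e-12)[0][0])
        cuts.append(c)
        s = c + 1
    return cuts


@dataclass
class LevelMap:
    """Integer class labels 0..G with the G ascending cut thresholds."""

    values: np.ndarray
    thresholds: tuple
    G: int

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.max(initial=0) > self.G:
            raise ValueError("labels exceed G")


def top_level_mask(levels: LevelMap) -> np.ndarray:
    """Initial-position mask K: pixels in the top (G-th) class."""
    return (levels.values == levels.G).astype(np.uint8)


# ---------------------------------------------------------------------------
# Morphological shrinking

def _build_shrink_lut():
    """LUT over the 8-neighbor bitmask: True if the center pixel is deletable.

    Deletable = has >= 1 foreground neighbor and exactly one 0->1 transition
    in the circular neighbor sequence (local 8-connectivity preserved; rings
    and isolated points are never deleted).
    """
    lut = np.zeros(256, dtype=bool)
    for code in range(256):
        nb = [(code >> k) & 1 for k in range(8)]  # p2..p9 circular order
        b = sum(nb)
        a = sum(1 for k in range(8) if nb[k] == 0 and nb[(k + 1) % 8] == 1)
        lut[code] = (b >= 1) and (a == 1)
    return lut


_SHRINK_LUT = _build_shrink_lut()
# circular neighbor order: N, NE, E, SE, S, SW, W, NW as (dy, dx)
_NEIGHBORS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _neighbor_code(mask, y, x):
    h, w = mask.shape
    code = 0
    for k, (dy, dx) in enumerate(_NEIGHBORS):
        yy, xx = y + dy, x + dx
        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
            code |= 1 << k
    return code


def morphological_shrink(mask, iterations: int = 2) -> np.ndarray:
    """Connectivity-preserving shrink: peel boundary pixels without ever
    deleting an 8-connected component (a single-pixel component survives).

    Each iteration visits the iteration-start boundary pixels in raster order
    and deletes those the lookup table marks as locally simple.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    m = (np.asarray(mask) != 0)
    if m.ndim != 2:
        raise ValueError("morphological_shrink operates on a single 2D mask")
    m = m.copy()
    for _ in range(iterations):
        interior = ndimage.binary_erosion(m, structure=_S8, border_value=0)
        boundary = np.argwhere(m & ~interior)
        changed = False
        for y, x in boundary:
            if _SHRINK_LUT[_neighbor_code(m, y, x)]:
                m[y, x] = False
                changed = True
        if not changed:
            break
    return m.astype(np.uint8)


# ---------------------------------------------------------------------------
# Active contours (region-based, two-phase)

def _median_smooth(region: np.ndarray, passes: int) -> np.ndarray:
    """3x3 binary median passes: a morphological curvature-flow surrogate."""
    r = region
    for _ in range(passes):
        counts = ndimage.uniform_filter(r.astype(np.float32), size=3, mode="constant")
        r = counts > 0.5
    return r


def chan_vese_energy(values, region, lam: float) -> float:
    """Two-phase piecewise-constant energy with a length term weighted by lam."""
    inside = region.astype(bool)
    v = np.asarray(values, float)
    e = 0.0
    if inside.any():
        c1 = v[inside].mean()
        e += ((v[inside] - c1) ** 2).sum()
    if (~inside).any():
        c2 = v[~inside].mean()
        e += ((v[~inside] - c2) ** 2).sum()
    # perimeter: count 4-adjacent fg/bg pairs
    per = (np.abs(np.diff(inside.astype(np.int8), axis=0)).sum()
           + np.abs(np.diff(inside.astype(np.int8), axis=1)).sum())
    return e + lam * per


def evolve_active_contours(pmap, init, alpha: int, lam: float,
                           return_energy: bool = False):
    """Evolve a two-phase piecewise-constant contour model on the map.

    Each 8-connected component of ``init`` seeds an independent evolution
    restricted to its basin (the Voronoi cell of the component under
    Euclidean distance), so separate seeds cannot silently merge.  Per
    iteration: update the inside/outside means c1, c2 of every basin, move
    each basin pixel to the region whose mean is closer in the squared
    sense, then apply ``lam`` passes of 3x3 binary median smoothing
    (``lam = 0`` disables smoothing).  Components may grow, shrink or vanish.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if alpha < 50:
        warnings.warn("alpha should be at least 50")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    vals = _map_values(pmap)
    if vals.ndim != 2:
        raise ValueError("evolve_active_contours operates on a single slice")
    init_m = (np.asarray(init.values if isinstance(init, BinaryMask) else init) != 0)
    if init_m.shape != vals.shape:
        raise ValueError("init mask must match the map domain")
    energies = []
    if not init_m.any():
        out = np.zeros(vals.shape, np.uint8)
        return (out, energies) if return_energy else out

    seeds, n = ndimage.label(init_m, structure=_S8)
    # Voronoi basins of the initial components
    _, (iy, ix) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
    basin = seeds[iy, ix]

    region = init_m.copy()
    lam_passes = int(round(lam))
    flat_basin = basin.ravel()
    flat_vals = vals.ravel()
    for _ in range(alpha):
        flat_region = region.ravel()
        # per-basin inside/outside means via bincount
        cnt_in = np.bincount(flat_basin, weights=flat_region, minlength=n + 1)
        sum_in = np.bincount(flat_basin, weights=flat_vals * flat_region,
                             minlength=n + 1)
        cnt_all = np.bincount(flat_basin, minlength=n + 1)
        sum_all = np.bincount(flat_basin, weights=flat_vals, minlength=n + 1)
        cnt_out = cnt_all - cnt_in
        sum_out = sum_all - sum_in
        with np.errstate(invalid="ignore", divide="ignore"):
            c1 = np.where(cnt_in > 0, sum_in / np.maximum(cnt_in, 1), np.nan)
            c2 = np.where(cnt_out > 0, sum_out / np.maximum(cnt_out, 1), np.nan)
        d1 = (vals - c1[basin]) ** 2
        d2 = (vals - c2[basin]) ** 2
        # dead components (empty inside) stay dead; full basins stay full
        d1 = np.where(np.isnan(d1), np.inf, d1)
        d2 = np.where(np.isnan(d2), np.inf, d2)
        new_region = d1 < d2
        if lam_passes:
            new_region = _median_smooth(new_region, lam_passes)
        if return_energy:
            energies.append(chan_vese_energy(vals, new_region, lam))
        if np.array_equal(new_region, region):
            region = new_region
            break
        region = new_region
    out = region.astype(np.uint8)
    return (out, energies) if return_energy else out


# ---------------------------------------------------------------------------
# Composition

def binarize_probability_map(pmap, G: int, alpha: int, lam: float,
                             shrink_iterations: int = 2) -> np.ndarray:
    """Full unsupervised binarization of one normalized probability map:
    multi-level Otsu -> top-class mask -> morphological shrink -> active
    contours.  A constant (e.g. all-background) map yields an empty
    segmentation with a warning rather than an error."""
    vals = _map_values(pmap)
    if vals.size == 0 or vals.max() == vals.min():
        warnings.warn("constant probability map: returning empty segmentation")
        return np.zeros(vals.shape, np.uint8)
    levels = otsu_multilevel(vals, G)
    init = top_level_mask(levels)
    init = morphological_shrink(init, shrink_iterations)
    return evolve_active_contours(vals, init, alpha=alpha, lam=lam)


# ---------------------------------------------------------------------------
# Comparison thresholders

def _threshold_to_mask(vals, t):
    return (vals >= t).astype(np.uint8)


def _check_nonconstant(vals):
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("constant map: no threshold exists")


def threshold_otsu_single(pmap) -> np.ndarray:
    """Single-level Otsu: between-class variance maximizer (smallest tie)."""
    vals = _map_values(pmap)
    _check_nonconstant(vals)
    b = _optimal_cuts(histogram256(vals), 1)[0]
    return _threshold_to_mask(vals, _bin_threshold(b))


def minimum_error_criterion(hist: np.ndarray) -> np.ndarray:
    """Kittler-Illingworth J(t) for cuts after bins 0..254 (lower is better).

    Two-Gaussian mixture fit per side; cuts leaving an empty or
    zero-variance side are assigned +inf.
    """
    p = hist.astype(np.float64) / hist.sum()
    centers = (np.arange(256) + 0.5) / 256.0
    w = np.cumsum(p)
    m = np.cumsum(p * centers)
    s = np.cumsum(p * centers ** 2)
    J = np.full(255, np.inf)
    for b in range(255):
        w1 = w[b]; w2 = 1.0 - w1
        if w1 <= 0 or w2 <= 0:
            continue
        mu1 = m[b] / w1
        mu2 = (m[-1] - m[b]) / w2
        var1 = s[b] / w1 - mu1 ** 2
        var2 = (s[-1] - s[b]) / w2 - mu2 ** 2
        if var1 <= 0 or var2 <= 0:
            continue
        J[b] = 1.0 + w1 * np.log(var1) + w2 * np.log(var2) \
            - 2.0 * (w1 * np.log(w1) + w2 * np.log(w2))
    return J


def threshold_minimum_error(pmap) -> np.ndarray:
    vals = _map_values(pmap)
    _check_nonconstant(vals)
    J = minimum_error_criterion(histogram256(vals))
    if not np.isfinite(J).any():
        raise ValueError("minimum-error criterion undefined for this histogram")
    b = int(np.argmin(J))
    return _threshold_to_mask(vals, _bin_threshold(b))


def maximum_entropy_criterion(hist: np.ndarray) -> np.ndarray:
    """Kapur criterion: H_background + H_foreground for cuts after bins 0..254."""
    p = hist.astype(np.float64) / hist.sum()
    w = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    H = np.full(255, -np.inf)
    for b in range(255):
        w1 = w[b]; w2 = 1.0 - w1
        if w1 <= 0 or w2 <= 0:
            continue
        h1 = np.log(w1) - cum_plogp[b] / w1
        h2 = np.log(w2) - (cum_plogp[-1] - cum_plogp[b]) / w2
        H[b] = h1 + h2
    return H


def threshold_maximum_entropy(pmap) -> np.ndarray:
    vals = _map_values(pmap)
    _check_nonconstant(vals)
    H = maximum_entropy_criterion(histogram256(vals))
    b = int(np.argmax(H))
    return _threshold_to_mask(vals, _bin_threshold(b))


# ---------------------------------------------------------------------------
# Supervised sweep

def optimal_threshold_sweep(pmap, truth, step: float = 1.0 / 255.0):
    """Sweep thresholds {0, step, ..., 1}; return (smallest argmax, best F).

    Foreground at threshold t is ``map >= t``; F is computed against the
    (nonempty) ground truth.
    """
    vals = _map_values(pmap)
    t_arr = (np.asarray(truth.values if isinstance(truth, BinaryMask) else truth) != 0)
    if not t_arr.any():
        raise ValueError("ground truth is empty: F undefined")
    thresholds = np.arange(0.0, 1.0 + step / 2, step)
    best_t, best_f = 0.0, -1.0
    npos = int(t_arr.sum())
    flat = vals.ravel()
    tf = t_arr.ravel()
    for t in thresholds:
        seg = flat >= t
        tp = int(np.count_nonzero(seg & tf))
        fp = int(np.count_nonzero(seg & ~tf))
        denom = 2 * tp + fp + (npos - tp)
        f = 2 * tp / denom if denom else 0.0
        if f > best_f + 1e-15:
            best_t, best_f = float(t), f
    return best_t, best_f
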