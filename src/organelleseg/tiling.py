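"""Tiled probability-map inference: plan an m x n tile grid with overlap U,
classify each tile independently, stitch with the max rule, normalize.

Overlap pixels take the maximum over all contributing tiles, then the full
stitched slice is min-max normalized to [0, 1] (a constant stitched map
becomes all zeros).  Slices are processed independently, so stacks can be
distributed one slice per worker with results identical to serial runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import joblib

from .chm import CHMModel, apply_chm
from .types import ConfigWarning, ProbabilityMap, as_slices

__all__ = ["TileGrid", "plan_tiles", "classify_slice", "classify_stack",
           "stitch_max", "normalize_map"]


@dataclass
class TileGrid:
    """m x n half-open rectangles (y0, y1, x0, x1) covering an H x W slice."""

    H: int
    W: int
    m: int
    n: int
    U: int
    rects: list

    def __iter__(self):
        return iter(self.rects)


def _axis_cells(size, k, U):
    """Half-open 1D intervals: ceil(size/k)-sized cells, interior edges
    expanded by floor(U/2)/ceil(U/2); the last cell absorbs the remainder."""
    cell = -(-size // k)
    bounds = [min(i * cell, size) for i in range(k + 1)]
    lo_pad, hi_pad = U // 2, U - U // 2
    out = []
    for i in range(k):
        a = bounds[i] - (lo_pad if i > 0 else 0)
        b = bounds[i + 1] + (hi_pad if i + 1 < k else 0)
        out.append((max(a, 0), min(b, size)))
    return out


def plan_tiles(H: int, W: int, m: int, n: int, U: int) -> TileGrid:
    """Plan the m x n tile grid with exactly-U interior overlaps."""
    if m > H or n > W:
        raise ValueError("more tiles than pixels along an axis")
    max_u = min(H // m, W // n)
    if U >= max_u and (m > 1 or n > 1):
        raise ValueError(f"overlap U = {U} too large for {m}x{n} tiling of "
                         f"{H}x{W} (must be < {max_u})")
    side = min(-(-H // m), -(-W // n))
    if (m > 1 or n > 1) and not (0.02 * side <= U <= 0.10 * side):
        warnings.warn(f"U = {U} outside 2-10% of the tile side {side}",
                      ConfigWarning, stacklevel=2)
    rows = _axis_cells(H, m, U if m > 1 else 0)
    cols = _axis_cells(W, n, U if n > 1 else 0)
    rects = [(y0, y1, x0, x1) for (y0, y1) in rows for (x0, x1) in cols]
    return TileGrid(H=H, W=W, m=m, n=n, U=U, rects=rects)


def _tile_classifier(model):
    if isinstance(model, CHMModel):
        return lambda tile: np.asarray(apply_chm(model, tile).values)
    if callable(model):
        return lambda tile: np.asarray(model(tile), dtype=np.float64)
    raise TypeError("model must be a CHMModel or a callable tile -> map")


def stitch_max(H, W, rects, tile_maps) -> np.ndarray:
    """Max-rule stitching: overlap pixels take the largest contribution."""
    out = np.full((H, W), -np.inf)
    for (y0, y1, x0, x1), tm in zip(rects, tile_maps):
        np.maximum(out[y0:y1, x0:x1], tm, out=out[y0:y1, x0:x1])
    return out


def normalize_map(values: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); a constant map becomes all zeros."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values, dtype=np.float64)
    return (values - lo) / (hi - lo)


def classify_slice(model, image, grid: TileGrid) -> ProbabilityMap:
    """Classify one slice tile-by-tile, stitch with max, then normalize."""
    img = np.asarray(image)
    if img.shape != (grid.H, grid.W):
        raise ValueError(f"grid planned for {(grid.H, grid.W)}, image is {img.shape}")
    clf = _tile_classifier(model)
    maps = []
    for k, (y0, y1, x0, x1) in enumerate(grid.rects):
        try:
            tm = clf(img[y0:y1, x0:x1])
        except Exception as exc:
            raise RuntimeError(f"classifier failed on tile {k} "
                               f"[{y0}:{y1}, {x0}:{x1}]: {exc}") from exc
        if tm.shape != (y1 - y0, x1 - x0):
            raise RuntimeError(f"tile {k}: classifier returned shape {tm.shape}")
        maps.append(tm)
    stitched = stitch_max(grid.H, grid.W, grid.rects, maps)
    return ProbabilityMap(normalize_map(stitched), normalized=True)


def classify_stack(model, stack, m: int, n: int, U: int,
                   n_workers: int = 1) -> ProbabilityMap:
    """Classify every slice independently; slice order preserved.

    ``n_workers > 1`` distributes slices over processes; results are
    identical to the serial run by construction.
    """
    vol = as_slices(stack)
    z, h, w = vol.shape
    grid = plan_tiles(h, w, m, n, U)
    if n_workers > 1:
        results = joblib.Parallel(n_jobs=n_workers)(
            joblib.delayed(_classify_one)(model, vol[i], grid, i)
            for i in range(z))
    else:
        results = [_classify_one(model, vol[i], grid, i) for i in range(z)]
    errors = [r for r in results if isinstance(r, tuple)]
    if errors:
        raise RuntimeError("; ".join(f"slice {i}: {msg}" for i, msg in errors))
    return ProbabilityMap(np.stack(results), normalized=True)


def _classify_one(model, sl, grid, index):
    try:
        return np.asarray(classify_slice(model, sl, grid).values)
    except Exception as exc:  # noqa: BLE001 - reported with slice index
        return (index, str(exc))
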