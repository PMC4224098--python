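"""3D connected-component objects from per-slice segmentations.

Per-slice masks are assembled into a label volume whose separate 3D
connected components become distinct objects (default 26-connectivity,
which tolerates residual slice-to-slice jitter), with an object table of
voxel counts, bounding boxes, centroids and physical volumes.  A simple
size-exclusion filter removes objects outside a plausible size range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import as_slices

__all__ = ["LabelVolume", "connected_components_3d", "size_filter",
           "export_contours", "trace_boundaries"]


@dataclass
class LabelVolume:
    """Z x H x W integer labels (0 = background, objects 1..K) plus a table."""

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size_xy: float | None = None
    slice_thickness: float | None = None

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))


_TABLE_COLS = ["label", "voxels", "volume_um3", "z0", "z1", "y0", "y1",
               "x0", "x1", "cz", "cy", "cx"]


def _build_table(labels, pixel_size_xy, slice_thickness):
    k = int(labels.max(initial=0))
    rows = []
    if k:
        counts = np.bincount(labels.ravel(), minlength=k + 1)
        objects = ndimage.find_objects(labels)
        coms = ndimage.center_of_mass(labels > 0, labels, index=range(1, k + 1))
        for lab in range(1, k + 1):
            sl = objects[lab - 1]
            vox = int(counts[lab])
            if pixel_size_xy and slice_thickness:
                vol = vox * pixel_size_xy ** 2 * slice_thickness / 1e9  # nm3 -> um3
            else:
                vol = float("nan")
            cz, cy, cx = coms[lab - 1]
            rows.append([lab, vox, vol, sl[0].start, sl[0].stop,
                         sl[1].start, sl[1].stop, sl[2].start, sl[2].stop,
                         cz, cy, cx])
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def connected_components_3d(segs, connectivity: int = 26,
                            pixel_size_xy: float | None = None,
                            slice_thickness: float | None = None) -> LabelVolume:
    """Label separate 3D connected components in raster-scan discovery order."""
    vol = as_slices(segs) != 0
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    if hasattr(segs, "pixel_size_xy"):
        pixel_size_xy = pixel_size_xy or segs.pixel_size_xy
        slice_thickness = slice_thickness or segs.slice_thickness
    labels, k = ndimage.label(vol, structure=structure)
    labels = _relabel_raster_order(labels, k)
    if k and not (pixel_size_xy and slice_thickness):
        warnings.warn("missing pixel-size metadata: volumes reported in voxels only")
    return LabelVolume(labels, _build_table(labels, pixel_size_xy, slice_thickness),
                       pixel_size_xy, slice_thickness)


def _relabel_raster_order(labels, k):
    """Renumber labels by first occurrence in flattened raster order."""
    if k == 0:
        return labels.astype(np.int32)
    flat = labels.ravel()
    nz = np.nonzero(flat)[0]
    seen = flat[nz]
    _, first_idx = np.unique(seen, return_index=True)
    order = seen[np.sort(first_idx)]  # old labels in discovery order
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[order] = np.arange(1, k + 1, dtype=np.int32)
    return remap[labels]


def size_filter(vol: LabelVolume, min_voxels: int = 0,
                max_voxels: float = np.inf) -> LabelVolume:
    """Drop objects outside [min_voxels, max_voxels]; labels re-compacted.

    Idempotent under repeated application with the same bounds; removed
    objects are logged via a warning.
    """
    if not 0 <= min_voxels <= max_voxels:
        raise ValueError("need 0 <= min_voxels <= max_voxels")
    counts = np.bincount(vol.labels.ravel(), minlength=vol.n_objects + 1)
    keep = [lab for lab in range(1, vol.n_objects + 1)
            if min_voxels <= counts[lab] <= max_voxels]
    removed = [lab for lab in range(1, vol.n_objects + 1) if lab not in keep]
    if removed:
        warnings.warn(f"size filter removed objects {removed} "
                      f"(sizes {[int(counts[r]) for r in removed]})")
    remap = np.zeros(vol.n_objects + 1, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        remap[lab] = new
    labels = remap[vol.labels]
    return LabelVolume(labels,
                       _build_table(labels, vol.pixel_size_xy, vol.slice_thickness),
                       vol.pixel_size_xy, vol.slice_thickness)


# ---------------------------------------------------------------------------
# Contour export

def trace_boundaries(mask: np.ndarray, simplify: bool = True):
    """Outer rectilinear boundary polygons of a 2D mask.

    Vertices are pixel-corner coordinates (y, x); a single pixel at (0, 0)
    yields the unit square (0,0)-(0,1)-(1,1)-(1,0).  Holes are omitted.
    """
    m = np.asarray(mask) != 0
    ys, xs = np.nonzero(m)
    h, w = m.shape
    # directed boundary edges with interior on the left -> outer loops come
    # out with positive signed area (y-down coordinates); holes negative.
    multi = {}
    for y, x in zip(ys.tolist(), xs.tolist()):
        sides = []
        if y == 0 or not m[y - 1, x]:
            sides.append(((y, x), (y, x + 1)))
        if x + 1 >= w or not m[y, x + 1]:
            sides.append(((y, x + 1), (y + 1, x + 1)))
        if y + 1 >= h or not m[y + 1, x]:
            sides.append(((y + 1, x + 1), (y + 1, x)))
        if x == 0 or not m[y, x - 1]:
            sides.append(((y + 1, x), (y, x)))
        for a, b in sides:
            multi.setdefault(a, []).append(b)
    polygons = []
    while multi:
        start = min(multi)
        prev = None
        cur = start
        poly = [cur]
        while True:
            outs = multi[cur]
            if len(outs) == 1 or prev is None:
                nxt = outs[0]
            else:
                # saddle: prefer the sharpest left turn relative to incoming
                dy, dx = cur[0] - prev[0], cur[1] - prev[1]
                def turn(b):
                    ny, nx_ = b[0] - cur[0], b[1] - cur[1]
                    return dx * ny - dy * nx_  # cross product, y-down
                outs.sort(key=turn)
                nxt = outs[0]
            outs.remove(nxt)
            if not outs:
                del multi[cur]
            prev, cur = cur, nxt
            if cur == start:
                break
            poly.append(cur)
        if _signed_area(poly) > 0:  # outer loops only
            polygons.append(_merge_collinear(poly) if simplify else poly)
    return polygons


def _signed_area(poly):
    a = 0.0
    n = len(poly)
    for i in range(n):
        y1, x1 = poly[i]
        y2, x2 = poly[(i + 1) % n]
        a += x1 * y2 - x2 * y1
    return a / 2.0


def _merge_collinear(poly):
    out = []
    n = len(poly)
    for i in range(n):
        p0, p1, p2 = poly[i - 1], poly[i], poly[(i + 1) % n]
        if (p1[0] - p0[0]) * (p2[1] - p1[1]) != (p1[1] - p0[1]) * (p2[0] - p1[0]):
            out.append(p1)
    return out


def export_contours(vol: LabelVolume, path):
    """Write per-object, per-slice outer boundary polygons as JSON lines."""
    path = Path(path)
    lines = []
    labels = vol.labels
    for lab in range(1, vol.n_objects + 1):
        obj = labels == lab
        for z in range(labels.shape[0]):
            if not obj[z].any():
                continue
            for poly in trace_boundaries(obj[z]):
                lines.append(json.dumps(
                    {"object": lab, "z": z,
                     "vertices": [[int(y), int(x)] for y, x in poly]}))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
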