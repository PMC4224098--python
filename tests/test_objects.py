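"""3D connected components, size filtering, boundary-contour export."""

import json

import numpy as np
import pytest

from organelleseg.objects import (connected_components_3d, export_contours,
                                  size_filter, trace_boundaries)


def test_blob_spanning_slices_is_one_object():
    vol = np.zeros((3, 6, 6), np.uint8)
    vol[:, 2:4, 2:4] = 1
    lv = connected_components_3d(vol)
    assert lv.n_objects == 1
    assert lv.table.iloc[0]["voxels"] == 12


def test_adjacent_slice_overlap_merges_but_distance_separates():
    vol = np.zeros((2, 10, 10), np.uint8)
    vol[0, 1:3, 1:3] = 1
    vol[1, 2:4, 2:4] = 1   # overlaps in (y, x) -> one 26-connected object
    assert connected_components_3d(vol).n_objects == 1
    vol2 = np.zeros((2, 10, 10), np.uint8)
    vol2[0, 1:3, 1:3] = 1
    vol2[1, 6:8, 6:8] = 1  # far apart -> two objects
    assert connected_components_3d(vol2).n_objects == 2


def test_diagonal_contact_6_vs_26_connectivity():
    vol = np.zeros((2, 4, 4), np.uint8)
    vol[0, 1, 1] = 1
    vol[1, 2, 2] = 1
    assert connected_components_3d(vol, connectivity=26).n_objects == 1
    assert connected_components_3d(vol, connectivity=6).n_objects == 2


def test_empty_stack_zero_objects():
    lv = connected_components_3d(np.zeros((2, 4, 4), np.uint8))
    assert lv.n_objects == 0 and len(lv.table) == 0


def test_raster_discovery_order_and_translation_invariance():
    vol = np.zeros((1, 10, 10), np.uint8)
    vol[0, 1, 1] = 1          # discovered first
    vol[0, 5, 5] = 1          # discovered second
    lv = connected_components_3d(vol)
    assert lv.labels[0, 1, 1] == 1 and lv.labels[0, 5, 5] == 2
    shifted = np.roll(vol, 2, axis=2)
    lv2 = connected_components_3d(shifted)
    assert np.array_equal(np.roll(lv.labels, 2, axis=2), lv2.labels)


def test_physical_volume_and_metadata_warning():
    vol = np.zeros((1, 4, 4), np.uint8)
    vol[0, 0, 0] = 1
    lv = connected_components_3d(vol, pixel_size_xy=100.0, slice_thickness=100.0)
    assert lv.table.iloc[0]["volume_um3"] == pytest.approx(1e6 / 1e9)
    with pytest.warns(UserWarning, match="metadata"):
        lv2 = connected_components_3d(vol)
    assert np.isnan(lv2.table.iloc[0]["volume_um3"])


def test_voxel_counts_sum_to_foreground():
    rng = np.random.default_rng(4)
    vol = (rng.random((4, 20, 20)) > 0.8).astype(np.uint8)
    lv = connected_components_3d(vol)
    assert lv.table["voxels"].sum() == vol.sum()


def test_size_filter_behaviour_and_idempotence():
    vol = np.zeros((1, 30, 30), np.uint8)
    vol[0, 1:2, 1:6] = 1              # 5 voxels
    vol[0, 10:30, 5:30] = 1           # 500 voxels
    lv = connected_components_3d(vol)
    ident = size_filter(lv, 0, np.inf)
    assert ident.n_objects == lv.n_objects
    with pytest.warns(UserWarning, match="removed"):
        kept = size_filter(lv, min_voxels=10)
    assert kept.n_objects == 1
    assert kept.table.iloc[0]["voxels"] == 500
    again = size_filter(kept, min_voxels=10)
    assert np.array_equal(again.labels, kept.labels)


def test_size_filter_can_empty_volume():
    vol = np.zeros((1, 5, 5), np.uint8)
    vol[0, 2, 2] = 1
    lv = connected_components_3d(vol)
    with pytest.warns(UserWarning):
        out = size_filter(lv, min_voxels=10)
    assert out.n_objects == 0 and not out.labels.any()


def test_single_pixel_boundary_square():
    m = np.zeros((3, 3), np.uint8)
    m[1, 1] = 1
    polys = trace_boundaries(m)
    assert polys == [[(1, 1), (1, 2), (2, 2), (2, 1)]]


def test_square_boundary_matches_rasterization_oracle():
    from shapely.geometry import Polygon, Point
    m = np.zeros((8, 8), np.uint8)
    m[2:5, 3:6] = 1
    polys = trace_boundaries(m, simplify=True)
    assert len(polys) == 1 and len(polys[0]) == 4
    poly = Polygon([(x, y) for y, x in polys[0]])
    assert poly.area == pytest.approx(m.sum())
    # every foreground pixel center inside, every background center outside
    for y in range(8):
        for x in range(8):
            assert poly.contains(Point(x + 0.5, y + 0.5)) == bool(m[y, x])


def test_unsimplified_square_has_12_vertices():
    m = np.zeros((8, 8), np.uint8)
    m[2:5, 3:6] = 1
    polys = trace_boundaries(m, simplify=False)
    assert len(polys[0]) == 12


def test_irregular_shape_polygon_area_equals_pixels():
    from shapely.geometry import Polygon
    rng = np.random.default_rng(9)
    from scipy import ndimage
    m = (ndimage.gaussian_filter(rng.random((20, 20)), 2) > 0.5)
    lbl, n = ndimage.label(m, structure=np.ones((3, 3)))
    for lab in range(1, n + 1):
        comp = (lbl == lab).astype(np.uint8)
        area = sum(abs(Polygon([(x, y) for y, x in p]).area)
                   for p in trace_boundaries(comp))
        # outer boundaries only: polygon area >= pixel count (holes included)
        assert area >= comp.sum()


def test_export_contours_json_lines(tmp_path):
    vol = np.zeros((2, 6, 6), np.uint8)
    vol[0, 1:3, 1:3] = 1
    vol[1, 1:3, 1:3] = 1
    lv = connected_components_3d(vol)
    p = export_contours(lv, tmp_path / "contours.jsonl")
    lines = [json.loads(line) for line in p.read_text().splitlines()]
    assert len(lines) == 2
    assert {l["z"] for l in lines} == {0, 1}
    assert all(l["object"] == 1 for l in lines)


def test_export_contours_empty_volume(tmp_path):
    lv = connected_components_3d(np.zeros((1, 4, 4), np.uint8))
    p = export_contours(lv, tmp_path / "c.jsonl")
    assert p.read_text() == ""
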