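"""Acquisition and annotation workload arithmetic for SBEM stacks.

Used to size segmentation campaigns: the physical volume of a stack from
its raster dimensions, and the extrapolated wall-clock cost of manually
annotating every tile of it at a measured minutes-per-tile rate.
"""

from __future__ import annotations

__all__ = ["stack_volume_um3", "manual_segmentation_years",
           "MINUTES_PER_YEAR"]

MINUTES_PER_YEAR = 525_600.0  # 365 d


def stack_volume_um3(nx: int, ny: int, nz: int, pixel_size_nm: float,
                     slice_thickness_nm: float) -> float:
    """Physical stack volume in cubic micrometers."""
    vol_nm3 = nx * pixel_size_nm * ny * pixel_size_nm * nz * slice_thickness_nm
    return vol_nm3 / 1e9


def manual_segmentation_years(nx: int, ny: int, nz: int,
                              tile_px: int, minutes_per_tile: float) -> float:
    """Years to manually annotate every tile_px x tile_px tile of the stack.

    Tiles are counted per slice at the stack's native pixel size and
    multiplied by the number of slices and the per-tile annotation rate.
    """
    tiles_per_slice = (nx / tile_px) * (ny / tile_px)
    total_minutes = tiles_per_slice * nz * minutes_per_tile
    return total_minutes / MINUTES_PER_YEAR
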