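"""Deterministic EM-like phantom stacks with exact ground truth.

The generator emulates the inputs the workflow was designed for: anisotropic
SBEM-style stacks (fine XY, coarse Z) of cytoplasm-like textured background
containing organelle cross-sections of several phenotypes, plus confounding
structures (myelin-like rings, Golgi-like stripe stacks) that appear in the
image but never in the ground-truth masks.  Organelles are 3D ellipsoids
rasterized per slice so consecutive slices correlate.  Per-slice intensity
drift and integer inter-slice jitter can be applied last to exercise the
preprocessing stage.

Intensity design (8-bit): background ~150 with low-contrast mottle; the
"textured" phenotype has a stripe texture whose mean matches the background
(separable by texture, not brightness, and therefore sensitive to
downsampling); the "smooth" phenotype is uniformly dark (separable at any
scale).  Both carry a dark boundary membrane.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import GrayscaleStack, SeedPoint

__all__ = ["OrganellePhenotype", "PhantomSpec", "generate_phantom",
           "make_fixture_suite", "unit_spec", "integration_spec"]


@dataclass(frozen=True)
class OrganellePhenotype:
    name: str
    count: int
    radius_range: tuple          # lateral semi-axis range, px
    eccentricity_range: tuple = (0.7, 1.0)   # ry/rx
    texture: str = "striped"     # striped | granular | uniform-dark | smooth-bright
    boundary_darkness: float = 70.0
    interior_level: float = 148.0
    stripe_amplitude: float = 45.0
    stripe_period: float = 6.0


@dataclass
class PhantomSpec:
    Z: int = 10
    H: int = 256
    W: int = 256
    pixel_size_xy: float = 7.8    # nm/pixel
    slice_thickness: float = 30.0  # nm; ~4x anisotropy, the regime 2D-only
                                   # per-slice processing targets
    phenotypes: list = field(default_factory=list)
    n_myelin: int = 0
    n_golgi: int = 0
    background_level: float = 150.0
    background_mottle: float = 14.0
    noise_sigma: float = 6.0
    drift_amplitude: float = 0.0   # per-slice additive intensity drift
    jitter_amplitude: int = 0      # integer per-slice translation, px
    rng_seed: int = 0


def _smooth_noise(rng, shape, sigma, amplitude):
    n = rng.standard_normal(shape)
    n = ndimage.gaussian_filter(n, sigma)
    s = n.std()
    return n / s * amplitude if s > 0 else n


def _occupy_box(occupied, cz_lo, cz_hi, cy, cx, ry, rx):
    Z, H, W = occupied.shape
    return (slice(max(int(cz_lo), 0), min(int(cz_hi) + 1, Z)),
            slice(max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, H)),
            slice(max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, W)))


def _place_instances(rng, spec, phen, occupied):
    """Sample non-overlapping 3D ellipsoids; error after bounded retries."""
    placed = []
    margin = 2
    for _ in range(phen.count):
        for attempt in range(200):
            rx = rng.uniform(*phen.radius_range)
            ry = rx * rng.uniform(*phen.eccentricity_range)
            rz = max(1.0, rx * spec.pixel_size_xy / spec.slice_thickness)
            cz = rng.uniform(0, spec.Z - 1)
            # rotated-ellipse extent can reach rx (major axis) in any direction
            cy = rng.uniform(rx + margin, spec.H - rx - margin)
            cx = rng.uniform(rx + margin, spec.W - rx - margin)
            box = _occupy_box(occupied, cz - rz - 1, cz + rz + 1, cy, cx, rx, rx)
            if occupied[box].any():
                continue
            occupied[box] = True
            placed.append(dict(cz=cz, cy=cy, cx=cx, rz=rz, ry=ry, rx=rx,
                               theta=rng.uniform(0, np.pi)))
            break
        else:
            raise RuntimeError(f"could not place phenotype {phen.name!r} "
                               "after bounded retries")
    return placed


def _ellipsoid_cross_section(inst, z, H, W):
    """Boolean mask of the instance's cross-section on slice z (or None)."""
    dz = (z - inst["cz"]) / inst["rz"]
    if abs(dz) >= 1.0:
        return None
    shrink = np.sqrt(1.0 - dz * dz)
    ry, rx = inst["ry"] * shrink, inst["rx"] * shrink
    if min(ry, rx) < 1.0:
        return None
    yy, xx = np.mgrid[0:H, 0:W]
    ct, st = np.cos(inst["theta"]), np.sin(inst["theta"])
    u = (xx - inst["cx"]) * ct + (yy - inst["cy"]) * st
    v = -(xx - inst["cx"]) * st + (yy - inst["cy"]) * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _stripes(shape, period, theta, phase=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    u = xx * np.cos(theta) + yy * np.sin(theta)
    return np.sin(2 * np.pi * u / period + phase)


def _paint_interior(img, cross, phen, inst, rng_phase):
    interior = ndimage.binary_erosion(cross, iterations=2)
    boundary = cross & ~interior
    if phen.texture == "striped":
        tex = (phen.interior_level
               + phen.stripe_amplitude * _stripes(img.shape, phen.stripe_period,
                                                  inst["theta"] + np.pi / 2,
                                                  rng_phase))
        img[interior] = tex[interior]
    elif phen.texture == "granular":
        img[interior] = phen.interior_level
    elif phen.texture == "uniform-dark":
        img[interior] = phen.interior_level
    elif phen.texture == "smooth-bright":
        img[interior] = 210.0
    else:
        raise ValueError(f"unknown texture {phen.texture!r}")
    img[boundary] = phen.boundary_darkness


def generate_phantom(spec: PhantomSpec):
    """Generate ``(GrayscaleStack, {phenotype: mask volume}, seeds)``.

    Ground-truth masks are exact and mutually disjoint; distractors appear
    only in the image.  Same seed -> bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    Z, H, W = spec.Z, spec.H, spec.W
    # volumetric background mottle: smooth in XY and correlated across
    # slices, as cytoplasmic structure persists over the cutting increment
    mottle = rng.standard_normal((Z, H, W))
    mottle = ndimage.gaussian_filter(mottle, (1.5, 3.0, 3.0))
    s = mottle.std()
    if s > 0:
        mottle *= spec.background_mottle / s
    img = spec.background_level + mottle

    occupied = np.zeros((Z, H, W), dtype=bool)
    masks = {}
    seeds = []
    instances = {}
    for phen in spec.phenotypes:
        instances[phen.name] = _place_instances(rng, spec, phen, occupied)
        masks[phen.name] = np.zeros((Z, H, W), dtype=np.uint8)

    for phen in spec.phenotypes:
        for inst in instances[phen.name]:
            phase = rng.uniform(0, 2 * np.pi)
            zc = int(round(inst["cz"]))
            seeds.append(SeedPoint(x=int(round(inst["cx"])),
                                   y=int(round(inst["cy"])),
                                   z=min(max(zc, 0), Z - 1)))
            for z in range(Z):
                cross = _ellipsoid_cross_section(inst, z, H, W)
                if cross is None or not cross.any():
                    continue
                _paint_interior(img[z], cross, phen, inst, phase)
                masks[phen.name][z][cross] = 1

    # distractors: in the image, never in the masks
    for _ in range(spec.n_myelin):
        _draw_myelin(rng, img, occupied, spec)
    for _ in range(spec.n_golgi):
        _draw_golgi(rng, img, occupied, spec)

    img += rng.standard_normal(img.shape) * spec.noise_sigma

    if spec.drift_amplitude:
        drift = rng.uniform(-spec.drift_amplitude, spec.drift_amplitude, size=Z)
        img += drift[:, None, None]

    if spec.jitter_amplitude:
        j = spec.jitter_amplitude
        for z in range(1, Z):
            dy = int(rng.integers(-j, j + 1))
            dx = int(rng.integers(-j, j + 1))
            img[z] = np.roll(img[z], (dy, dx), axis=(0, 1))
            for mvol in masks.values():
                mvol[z] = np.roll(mvol[z], (dy, dx), axis=(0, 1))

    stack = GrayscaleStack(np.clip(np.rint(img), 0, 255).astype(np.uint8),
                           pixel_size_xy=spec.pixel_size_xy,
                           slice_thickness=spec.slice_thickness,
                           provenance=f"phantom seed={spec.rng_seed}")
    return stack, masks, seeds


def _draw_myelin(rng, img, occupied, spec):
    """Dark annulus, a myelinated-axon look-alike."""
    Z, H, W = img.shape
    for _ in range(100):
        r = rng.uniform(8, 16)
        cy = rng.uniform(r + 2, H - r - 2)
        cx = rng.uniform(r + 2, W - r - 2)
        z0 = int(rng.integers(0, Z))
        span = range(max(0, z0 - 2), min(Z, z0 + 3))
        box = _occupy_box(occupied, span.start, span.stop - 1, cy, cx, r, r)
        if occupied[box].any():
            continue
        occupied[box] = True
        yy, xx = np.mgrid[0:H, 0:W]
        d = np.hypot(yy - cy, xx - cx)
        ring = (d <= r) & (d >= r - 3.5)
        lumen = d < r - 3.5
        for z in span:
            img[z][ring] = 45.0
            img[z][lumen] = 165.0
        return
    raise RuntimeError("could not place myelin distractor")


def _draw_golgi(rng, img, occupied, spec):
    """Short stack of parallel dark lamellae with a stripe texture very
    close to the textured phenotype's interior."""
    Z, H, W = img.shape
    for _ in range(100):
        ly = rng.uniform(10, 16)   # half-height
        lx = rng.uniform(18, 28)   # half-width
        cy = rng.uniform(ly + 2, H - ly - 2)
        cx = rng.uniform(lx + 2, W - lx - 2)
        theta = rng.uniform(0, np.pi)
        z0 = int(rng.integers(0, Z))
        span = range(max(0, z0 - 1), min(Z, z0 + 2))
        r_occ = max(lx, ly)
        box = _occupy_box(occupied, span.start, span.stop - 1, cy, cx, r_occ, r_occ)
        if occupied[box].any():
            continue
        occupied[box] = True
        yy, xx = np.mgrid[0:H, 0:W]
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        region = (np.abs(u) <= lx) & (np.abs(v) <= ly)
        tex = 148.0 + 45.0 * _stripes(img[0].shape, 6.0, theta + np.pi / 2,
                                      rng.uniform(0, 2 * np.pi))
        for z in span:
            img[z][region] = tex[region]
        return
    raise RuntimeError("could not place golgi distractor")


# ---------------------------------------------------------------------------
# Fixture suites

def _textured_phenotype(radius_range):
    return OrganellePhenotype(
        name="textured", count=0, radius_range=radius_range,
        texture="striped", interior_level=148.0, stripe_amplitude=45.0,
        stripe_period=6.0, boundary_darkness=70.0)


def _smooth_phenotype(radius_range):
    return OrganellePhenotype(
        name="smooth", count=0, radius_range=radius_range,
        texture="uniform-dark", interior_level=85.0, boundary_darkness=65.0)


import dataclasses as _dc


def unit_spec(seed: int = 7, distractors: bool = True) -> PhantomSpec:
    """Small suite: 10 slices of 140x140, one 128x128 tile per slice."""
    return PhantomSpec(
        Z=10, H=140, W=140,
        phenotypes=[
            _dc.replace(_textured_phenotype((8.0, 13.0)), count=6),
            _dc.replace(_smooth_phenotype((13.0, 18.0)), count=2),
        ],
        n_myelin=1 if distractors else 0,
        n_golgi=1 if distractors else 0,
        rng_seed=seed)


def integration_spec(seed: int = 7, distractors: bool = True) -> PhantomSpec:
    """Integration suite geometry: 20 slices, three 256x256 tiles per slice
    (60 tiles), emulating the N = 90 / Q = R = 500 design at reduced size."""
    return PhantomSpec(
        Z=20, H=280, W=840,
        phenotypes=[
            _dc.replace(_textured_phenotype((10.0, 20.0)), count=50),
            _dc.replace(_smooth_phenotype((22.0, 34.0)), count=12),
        ],
        n_myelin=8 if distractors else 0,
        n_golgi=8 if distractors else 0,
        rng_seed=seed)


def _tile_seeds(spec, tiles_per_slice, Q):
    """Fixed tile-center seeds: tiles_per_slice side-by-side per slice."""
    seeds = []
    for z in range(spec.Z):
        for t in range(tiles_per_slice):
            cx = (spec.W // tiles_per_slice) * t + (spec.W // tiles_per_slice) // 2
            seeds.append(SeedPoint(x=cx, y=spec.H // 2, z=z))
    return seeds


def make_fixture_suite(scale: str = "unit", seed: int = 7, out_dir=None,
                       distractors: bool = True):
    """Build the on-disk (or in-memory) fixture suite.

    unit: 10 tiles of 128x128; integration: 60 tiles of 256x256 across 20
    slices.  Returns a dict with the stack, per-phenotype masks, tile seeds,
    tile size and manifest (seeds and content hashes).
    """
    from .training import extract_tiles, rasterize_labels

    if scale == "unit":
        spec, Q, per_slice = unit_spec(seed, distractors), 128, 1
    elif scale == "integration":
        spec, Q, per_slice = integration_spec(seed, distractors), 256, 3
    else:
        raise ValueError("scale must be 'unit' or 'integration'")
    stack, masks, _ = generate_phantom(spec)
    tile_seeds = _tile_seeds(spec, per_slice, Q)
    images = extract_tiles(stack, tile_seeds, Q, Q)
    labels = {name: rasterize_labels(m, tile_seeds, Q, Q)
              for name, m in masks.items()}
    manifest = {
        "scale": scale, "rng_seed": seed, "tile_size": Q,
        "n_tiles": len(tile_seeds),
        "hashes": {
            "images": hashlib.sha256(images.tobytes()).hexdigest(),
            **{f"labels/{k}": hashlib.sha256(v.tobytes()).hexdigest()
               for k, v in labels.items()},
        },
    }
    suite = dict(spec=spec, stack=stack, masks=masks, seeds=tile_seeds,
                 images=images, labels=labels, tile_size=Q, manifest=manifest)
    if out_dir is not None:
        from . import io as _io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_stack(stack, out / "stack.tif")
        _io.write_stack(np.stack(images), out / "tiles.tif")
        for name, lab in labels.items():
            _io.write_stack(lab * np.uint8(255), out / f"labels_{name}.tif")
        for name, m in masks.items():
            _io.write_stack(m * np.uint8(255), out / f"truth_{name}.tif")
        _io.write_seeds_csv(tile_seeds, out / "seeds.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return suite
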