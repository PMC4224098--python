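"""Stack readers/writers, model serialization and configuration files.

Supported volume formats: multi-page TIFF, directories of PNG/TIFF slices
(lexicographic Z order), and MRC mode 0 (8-bit) with the standard 1024-byte
header.  Masks are stored as 0/255 8-bit; probability maps as 32-bit float
TIFF (or rescaled 8-bit for PNG/MRC).
"""

from __future__ import annotations

import pickle
import struct
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio import v3 as iio

from .types import BinaryMask, GrayscaleStack, PipelineConfig, ProbabilityMap, SeedPoint, as_slices

__all__ = [
    "read_stack", "write_stack", "save_model", "load_model",
    "read_config", "write_config", "read_seeds_csv", "write_seeds_csv",
    "read_mrc", "write_mrc",
]

MODEL_FORMAT_VERSION = 1

# IMOD header convention: imodStamp at byte 152, imodFlags at 156;
# flag bit 0 set means mode-0 bytes are signed.
_IMOD_STAMP = 1146047817


# ---------------------------------------------------------------------------
# MRC mode 0

def write_mrc(path, volume: np.ndarray, pixel_size_xy: float | None = None,
              slice_thickness: float | None = None, signed: bool = False):
    """Write a (Z, H, W) uint8 volume as a little-endian MRC mode-0 file."""
    vol = np.ascontiguousarray(volume)
    if vol.dtype != np.uint8:
        raise ValueError("MRC mode 0 output requires uint8 data")
    nz, ny, nx = vol.shape
    psx = float(pixel_size_xy or 1.0)
    psz = float(slice_thickness or psx)
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # nx, ny, nz
    struct.pack_into("<i", header, 12, 0)                    # mode 0
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * psx / 10.0,     # cell in A
                     ny * psx / 10.0, nz * psz / 10.0)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # mapc/r/s
    dmin, dmax = float(vol.min()), float(vol.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(vol.mean()))
    struct.pack_into("<2i", header, 152, _IMOD_STAMP, 1 if signed else 0)
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                    # little-endian stamp
    out = vol if not signed else (vol.astype(np.int16) - 128).astype(np.int8)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(out.tobytes())


def read_mrc(path):
    """Read an MRC mode-0 file; returns (uint8 volume, pixel_size_xy_nm, dz_nm).

    Both signed and unsigned byte conventions are accepted, selected by the
    IMOD flag in the header and defaulting to unsigned.
    """
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise IOError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        if mode != 0:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 0)")
        xlen, = struct.unpack_from("<f", header, 40)
        zlen, = struct.unpack_from("<f", header, 48)
        stamp, flags = struct.unpack_from("<2i", header, 152)
        nsymbt, = struct.unpack_from("<i", header, 92)
        fh.seek(1024 + max(nsymbt, 0))
        raw = fh.read(nx * ny * nz)
    if len(raw) != nx * ny * nz:
        raise IOError(f"{path}: truncated MRC data section")
    vol = np.frombuffer(raw, dtype=np.uint8).reshape(nz, ny, nx).copy()
    if stamp == _IMOD_STAMP and (flags & 1):
        vol = (vol.view(np.int8).astype(np.int16) + 128).astype(np.uint8)
    psx = xlen * 10.0 / nx if nx and xlen > 0 else None
    psz = zlen * 10.0 / nz if nz and zlen > 0 else None
    return vol, psx, psz


# ---------------------------------------------------------------------------
# Generic stacks

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    if path.is_dir():
        return "png-dir"
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".mrc", ".rec", ".st"):
        return "mrc"
    raise ValueError(f"cannot infer stack format for {path}")


def read_stack(path, format: str | None = None, *, pixel_size_xy=None,
               slice_thickness=None) -> GrayscaleStack:
    """Read an 8-bit grayscale stack; slices ordered by ascending Z.

    Z order is file order for multi-page TIFF and lexicographic file-name
    order for slice directories.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        vol = tifffile.imread(str(path))
        vol = np.asarray(vol)
        if vol.ndim == 2:
            vol = vol[None]
    elif fmt == "png-dir":
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise IOError(f"no slice images found in {path}")
        slices = []
        shape = None
        for f in files:
            try:
                img = np.asarray(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - name the slice
                raise IOError(f"unreadable slice {f}: {exc}") from exc
            if img.ndim == 3:  # collapse grayscale-encoded RGB
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"mixed slice shapes: {f} is {img.shape}, expected {shape}")
            slices.append(img)
        vol = np.stack(slices)
    elif fmt == "mrc":
        vol, psx, psz = read_mrc(path)
        pixel_size_xy = pixel_size_xy or psx
        slice_thickness = slice_thickness or psz
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return GrayscaleStack(vol.astype(np.uint8), pixel_size_xy=pixel_size_xy,
                          slice_thickness=slice_thickness,
                          provenance=f"{fmt}:{path.name}")


def write_stack(stack, path, format: str | None = None):
    """Write a stack, mask stack or probability-map stack to disk.

    Masks go out as 0/255 8-bit.  Probability maps are written as 32-bit
    float TIFF; for 8-bit formats (PNG/MRC) they are rescaled to 0..255.
    """
    path = Path(path)
    if isinstance(stack, BinaryMask):
        vol = as_slices(stack) * np.uint8(255)
        meta = (None, None)
    elif isinstance(stack, ProbabilityMap):
        vol = as_slices(stack).astype(np.float32)
        meta = (None, None)
    elif isinstance(stack, GrayscaleStack):
        vol = stack.voxels
        meta = (stack.pixel_size_xy, stack.slice_thickness)
    else:
        vol = np.asarray(stack)
        if vol.ndim == 2:
            vol = vol[None]
        meta = (None, None)
    if vol.size == 0 or vol.shape[0] == 0:
        raise ValueError("refusing to write an empty stack")
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        tifffile.imwrite(str(path), vol)
    elif fmt == "png-dir":
        path.mkdir(parents=True, exist_ok=True)
        out = vol
        if out.dtype != np.uint8:
            out = _to_uint8(out)
        digits = max(3, len(str(len(out) - 1)))
        for z, sl in enumerate(out):
            iio.imwrite(path / f"s{z:0{digits}d}.png", sl)
    elif fmt == "mrc":
        out = vol if vol.dtype == np.uint8 else _to_uint8(vol)
        write_mrc(path, out, pixel_size_xy=meta[0], slice_thickness=meta[1])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _to_uint8(vol: np.ndarray) -> np.ndarray:
    v = vol.astype(np.float64)
    lo, hi = v.min(), v.max()
    if hi > lo:
        v = (v - lo) / (hi - lo)
    else:
        v = np.zeros_like(v)
    return np.rint(v * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Model serialization

def save_model(model, path):
    """Serialize a trained cascade model with a format-version field.

    The byte stream is canonicalized (one pickle round-trip) so that
    saving an identical model always produces an identical file, including
    after load_model.
    """
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    raw = pickle.dumps(payload, protocol=4)
    canonical = pickle.dumps(pickle.loads(raw), protocol=4)
    Path(path).write_bytes(canonical)
    return path


def load_model(path):
    data = Path(path).read_bytes()
    try:
        payload = pickle.loads(data)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: corrupt or truncated model file: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not an organelleseg model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})")
    return payload["model"]


# ---------------------------------------------------------------------------
# Config and seed files

def write_config(configs, path):
    """Write one or more PipelineConfigs as a YAML file, one section per target."""
    if isinstance(configs, PipelineConfig):
        configs = {configs.organelle_tag or "default": configs}
    doc = {}
    for tag, cfg in configs.items():
        doc[tag] = {
            "N": cfg.N, "Q": cfg.Q, "R": cfg.R, "S": cfg.S, "L": cfg.L,
            "m": cfg.m, "n": cfg.n, "U": cfg.U, "G": cfg.G,
            "alpha": cfg.alpha, "lambda": cfg.lam,
            "downsample_factor": cfg.downsample_factor,
            "rng_seed": cfg.rng_seed,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_config(path) -> dict:
    """Read a per-organelle config file -> {tag: PipelineConfig}."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of organelle sections")
    out = {}
    for tag, section in doc.items():
        kw = dict(section)
        if "lambda" in kw:
            kw["lam"] = kw.pop("lambda")
        out[tag] = PipelineConfig(organelle_tag=tag, **kw)
    return out


def write_seeds_csv(seeds, path):
    lines = ["x,y,z"] + [f"{s.x},{s.y},{s.z}" for s in seeds]
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_seeds_csv(path):
    seeds = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or (i == 0 and line.lower().startswith("x")):
            continue
        x, y, z = (int(v) for v in line.split(","))
        seeds.append(SeedPoint(x=x, y=y, z=z))
    return seeds
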