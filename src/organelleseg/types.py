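"""Domain containers for EM segmentation volumes.

Conventions used throughout the package:

* Volumes are ``(Z, H, W)`` numpy arrays; single slices are ``(H, W)``.
* Coordinates are 0-based ``(z, y, x)`` with ``y`` increasing downward.
* All rectangles are half-open ``[y0, y1) x [x0, x1)``.
* Binary masks are ``{0, 1}`` uint8 in memory and 0/255 on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayscaleStack",
    "ProbabilityMap",
    "BinaryMask",
    "SeedPoint",
    "PipelineConfig",
    "MetricsReport",
    "ConfigWarning",
    "as_slices",
]


class ConfigWarning(UserWarning):
    """Raised (as a warning) for suspicious but legal parameter values."""


def _as_volume(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3:
        raise ValueError(f"expected 2D slice or 3D stack, got shape {a.shape}")
    return a


def as_slices(obj) -> np.ndarray:
    """Coerce a stack container or ndarray to a (Z, H, W) array view."""
    if isinstance(obj, (GrayscaleStack, BinaryMask, ProbabilityMap)):
        return _as_volume(obj.values if hasattr(obj, "values") else obj.voxels)
    return _as_volume(obj)


@dataclass
class GrayscaleStack:
    """An ordered Z x H x W stack of 8-bit EM slices.

    ``pixel_size_xy`` is the lateral sampling in nm/pixel and
    ``slice_thickness`` the cutting increment delta in nm; SBEM stacks are
    typically strongly anisotropic (delta several times the pixel size).
    """

    voxels: np.ndarray
    pixel_size_xy: float | None = None
    slice_thickness: float | None = None
    provenance: str = ""

    def __post_init__(self):
        v = _as_volume(self.voxels)
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise ValueError("grayscale intensities must lie in [0, 255]")
            v = v.astype(np.uint8)
        if any(s < 1 for s in v.shape):
            raise ValueError("empty stack")
        self.voxels = v

    @property
    def shape(self):
        return self.voxels.shape

    def __len__(self):
        return self.voxels.shape[0]


@dataclass
class ProbabilityMap:
    """Per-pixel organelle probability, one slice (H, W) or a stack.

    When ``normalized`` the values span [0, 1] with min 0 and max 1 unless
    the map is constant (then all zeros, by convention).
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim not in (2, 3):
            raise ValueError("probability map must be 2D or 3D")
        if self.normalized:
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("normalized map must lie in [0, 1]")
        self.values = v

    @property
    def shape(self):
        return self.values.shape


@dataclass
class BinaryMask:
    """A {0, 1} mask congruent with its paired image."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        self.values = (v != 0).astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class SeedPoint:
    """Voxel coordinate of an organelle instance: x = column, y = row, z = slice."""

    x: int
    y: int
    z: int

    def in_bounds(self, shape) -> bool:
        z, h, w = shape
        return 0 <= self.z < z and 0 <= self.y < h and 0 <= self.x < w


# Table-style per-organelle parameter defaults used by the binarizer.
ORGANELLE_DEFAULTS = {
    "mitochondria": dict(G=3, alpha=80, lam=7, U=50),
    "lysosomes": dict(G=2, alpha=200, lam=4, U=50),
    "nuclei": dict(G=2, alpha=300, lam=8, U=20),
    "nucleoli": dict(G=2, alpha=90, lam=10, U=50),
}


@dataclass
class PipelineConfig:
    """Full parameter set for one organelle target.

    N: number of training tiles; Q, R: tile height/width; S, L: cascade
    stages and levels; m, n: inference tile-array shape; U: tile overlap in
    pixels; G: gray levels for multi-level Otsu; alpha: active-contour
    iterations; lam: smoothing factor (lambda); downsample_factor: lateral
    downsampling applied before everything else.
    """

    N: int = 50
    Q: int = 500
    R: int = 500
    S: int = 2
    L: int = 2
    m: int = 2
    n: int = 2
    U: int = 50
    G: int = 2
    alpha: int = 100
    lam: float = 0.0
    downsample_factor: int = 1
    rng_seed: int = 0
    organelle_tag: str = ""

    def __post_init__(self):
        for name in ("N", "Q", "R", "S", "L", "m", "n", "U", "G", "alpha",
                     "downsample_factor"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            setattr(self, name, int(v))
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        self.validate()

    def validate(self):
        if self.S == 1:
            warnings.warn("S = 1: the number of stages should be greater than one",
                          ConfigWarning, stacklevel=2)
        if self.alpha < 50:
            warnings.warn("alpha should be at least 50", ConfigWarning, stacklevel=2)
        side = min(self.Q, self.R)
        if not (0.02 * side <= self.U <= 0.10 * side):
            warnings.warn(
                f"U = {self.U} outside 2-10% of min(Q, R) = {side}",
                ConfigWarning, stacklevel=2)
        if self.lam > 8:
            warnings.warn("lambda above the usual 0-8 range", ConfigWarning,
                          stacklevel=2)


@dataclass
class MetricsReport:
    """Confusion counts and the derived pixelwise metrics.

    Undefined ratios (zero denominators) are reported as NaN and listed in
    ``undefined`` rather than silently set to 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    tpr: float = field(init=False)
    fpr: float = field(init=False)
    precision: float = field(init=False)
    accuracy: float = field(init=False)
    f_value: float = field(init=False)
    jaccard: float = field(init=False)
    undefined: tuple = field(init=False, default=())

    def __post_init__(self):
        tp, fp, tn, fn = (int(self.TP), int(self.FP), int(self.TN), int(self.FN))
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if tp + fp + tn + fn == 0:
            raise ValueError("all confusion counts are zero")
        undef = []

        def ratio(num, den, name):
            if den == 0:
                undef.append(name)
                return float("nan")
            return num / den

        self.tpr = ratio(tp, tp + fn, "tpr")
        self.fpr = ratio(fp, fp + tn, "fpr")
        self.precision = ratio(tp, tp + fp, "precision")
        self.accuracy = (tp + tn) / (tp + fp + tn + fn)
        self.f_value = ratio(2 * tp, 2 * tp + fp + fn, "f_value")
        self.jaccard = ratio(tp, tp + fp + fn, "jaccard")
        self.undefined = tuple(undef)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "tpr": self.tpr, "fpr": self.fpr, "precision": self.precision,
            "accuracy": self.accuracy, "f_value": self.f_value,
            "jaccard": self.jaccard,
        }
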