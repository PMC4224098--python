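"""Per-pixel feature bank for the cascaded pixel classifier.

Features per pixel (translation-covariant, reflect-padded borders):
raw intensity; Gaussian-smoothed intensity at sigma {1, 2, 4} px; gradient
magnitude at sigma {1, 2}; Laplacian of Gaussian at sigma {1, 2}; local
mean and standard deviation in 5x5 and 9x9 windows; and the 25 raw
intensity samples of the 5x5 neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["FeatureBank", "compute_features"]


@dataclass(frozen=True)
class FeatureBank:
    gaussian_sigmas: tuple = (1.0, 2.0, 4.0)
    gradient_sigmas: tuple = (1.0, 2.0)
    laplacian_sigmas: tuple = (1.0, 2.0)
    window_sizes: tuple = (5, 9)
    neighborhood: int = 5

    @property
    def n_features(self) -> int:
        return (1 + len(self.gaussian_sigmas) + len(self.gradient_sigmas)
                + len(self.laplacian_sigmas) + 2 * len(self.window_sizes)
                + self.neighborhood ** 2)


def compute_features(image: np.ndarray, config: FeatureBank | None = None) -> np.ndarray:
    """Feature array of shape (H, W, n_features), float32, deterministic."""
    cfg = config or FeatureBank()
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("compute_features expects a nonempty 2D slice")
    feats = [img]
    for s in cfg.gaussian_sigmas:
        feats.append(ndimage.gaussian_filter(img, s, mode="reflect"))
    for s in cfg.gradient_sigmas:
        gy = ndimage.gaussian_filter(img, s, order=(1, 0), mode="reflect")
        gx = ndimage.gaussian_filter(img, s, order=(0, 1), mode="reflect")
        feats.append(np.hypot(gy, gx))
    for s in cfg.laplacian_sigmas:
        feats.append(ndimage.gaussian_laplace(img, s, mode="reflect"))
    for w in cfg.window_sizes:
        mean = ndimage.uniform_filter(img, w, mode="reflect")
        sq = ndimage.uniform_filter(img * img, w, mode="reflect")
        feats.append(mean)
        feats.append(np.sqrt(np.maximum(sq - mean * mean, 0.0)))
    k = cfg.neighborhood // 2
    padded = np.pad(img, k, mode="reflect")
    h, w_ = img.shape
    for dy in range(-k, k + 1):
        for dx in range(-k, k + 1):
            feats.append(padded[k + dy:k + dy + h, k + dx:k + dx + w_])
    return np.stack(feats, axis=-1).astype(np.float32)
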