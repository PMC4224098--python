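"""Training tile/label extraction around user-chosen seed points.

A training set is N tiles of Q x R pixels, each centered on a seed point
P_i = (x_i, y_i, z_i) placed on an organelle instance, paired with binary
labels cut from the same windows of a ground-truth mask volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SeedPoint, as_slices

__all__ = ["TrainingSet", "extract_tiles", "rasterize_labels",
           "split_train_test", "propose_seeds", "tile_window"]


@dataclass
class TrainingSet:
    """N congruent (Q, R) image tiles with binary label tiles."""

    images: np.ndarray          # (N, Q, R) uint8
    labels: np.ndarray          # (N, Q, R) {0, 1}
    seeds: list = field(default_factory=list)
    organelle_tag: str = ""

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = (np.asarray(self.labels) != 0).astype(np.uint8)
        if self.images.shape != self.labels.shape:
            raise ValueError("images and labels must be congruent")

    def __len__(self):
        return self.images.shape[0]

    def subset(self, idx):
        idx = np.asarray(idx)
        return TrainingSet(self.images[idx], self.labels[idx],
                           [self.seeds[i] for i in idx] if self.seeds else [],
                           self.organelle_tag)


def tile_window(seed: SeedPoint, Q: int, R: int):
    """Half-open (y0, y1, x0, x1) of the Q x R window centered on the seed.

    For even Q (or R) the seed sits at tile index floor(Q/2).
    """
    y0 = seed.y - Q // 2
    x0 = seed.x - R // 2
    return y0, y0 + Q, x0, x0 + R


def _check_bounds(seeds, Q, R, shape):
    z, h, w = shape
    bad = []
    for s in seeds:
        y0, y1, x0, x1 = tile_window(s, Q, R)
        if not (0 <= s.z < z and y0 >= 0 and x0 >= 0 and y1 <= h and x1 <= w):
            bad.append(s)
    if bad:
        raise ValueError(f"tiles out of bounds for seeds: {bad}")


def extract_tiles(stack, seeds, Q: int, R: int) -> np.ndarray:
    """Cut the Q x R window centered on each seed from its slice."""
    vol = as_slices(stack)
    _check_bounds(seeds, Q, R, vol.shape)
    tiles = np.empty((len(seeds), Q, R), dtype=vol.dtype)
    for i, s in enumerate(seeds):
        y0, y1, x0, x1 = tile_window(s, Q, R)
        tiles[i] = vol[s.z, y0:y1, x0:x1]
    return tiles


def rasterize_labels(mask_stack, seeds, Q: int, R: int) -> np.ndarray:
    """Cut label tiles from a mask volume; values binarized to {0, 1}."""
    vol = as_slices(mask_stack)
    tiles = extract_tiles(vol, seeds, Q, R)
    return (tiles != 0).astype(np.uint8)


def split_train_test(tset: TrainingSet, n_train: int, rng_seed: int = 0):
    """Random disjoint train/test partition, reproducible under rng_seed."""
    n = len(tset)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return tset.subset(np.sort(perm[:n_train])), tset.subset(np.sort(perm[n_train:]))


def propose_seeds(mask_stack, Q: int, R: int, n: int, rng_seed: int = 0):
    """Propose n seed points on foreground, stratified across the Z range.

    Convenience for phantom experiments; real seeds are chosen by the
    experimenter for wide spatial coverage.
    """
    vol = as_slices(mask_stack)
    z, h, w = vol.shape
    rng = np.random.default_rng(rng_seed)
    seeds = []
    zs = np.array_split(np.arange(z), min(n, z))
    gi = 0
    while len(seeds) < n:
        group = zs[gi % len(zs)]
        gi += 1
        for _ in range(200):
            zz = int(rng.choice(group))
            ys, xs = np.nonzero(vol[zz])
            if ys.size == 0:
                continue
            k = int(rng.integers(ys.size))
            s = SeedPoint(x=int(xs[k]), y=int(ys[k]), z=zz)
            y0, y1, x0, x1 = tile_window(s, Q, R)
            if y0 >= 0 and x0 >= 0 and y1 <= h and x1 <= w:
                seeds.append(s)
                break
        else:
            raise RuntimeError("could not place a seed with an in-bounds tile")
    return seeds
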