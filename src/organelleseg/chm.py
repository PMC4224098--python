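"""Cascaded hierarchical pixel classification.

The cascade has S stages; each stage runs a bottom-up pass over L+1
resolution levels (level 0 = native, each further level downsampled by 2)
followed by a top-down combiner:

* level 0 learner: image features (+ the previous stage's output map as
  context when the stage index > 1);
* level l learner (1..L): features of the 2^l-downsampled tile plus the
  downsampled output maps of levels 0..l-1;
* top-down combiner: native-resolution features plus the bilinearly
  upsampled output maps of all levels 0..L.

Each stage's combiner map is the stage output and feeds the next stage; the
final model output is the last stage's combiner probability map.  The base
learner is pluggable; the default is a seeded extremely-randomized-trees
ensemble trained on a class-balanced pixel subsample, which keeps training
tractable at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import downscale_local_mean, resize
from sklearn.ensemble import ExtraTreesClassifier

from .features import FeatureBank, compute_features
from .types import ProbabilityMap

__all__ = ["CHMModel", "train_chm", "apply_chm"]

MAX_PIXELS_PER_LEARNER = 200_000


class _ConstantLearner:
    """Fallback learner when a level sees only one class."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba_pos(self, X):
        return np.full(X.shape[0], self.p, dtype=np.float32)


class _TreeLearner:
    def __init__(self, seed: int, n_estimators: int, max_depth: int):
        self.clf = ExtraTreesClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            min_samples_leaf=5, random_state=seed, n_jobs=1)

    def fit(self, X, y):
        self.clf.fit(X, y)
        return self

    def predict_proba_pos(self, X):
        return self.clf.predict_proba(X)[:, 1].astype(np.float32)


@dataclass
class CHMModel:
    """Trained cascade C_{S,L}: one learner per (stage, level) plus one
    top-down combiner per stage; S*(L+1) + S learners in total."""

    S: int
    L: int
    learners: dict
    feature_config: FeatureBank
    pixel_size_xy: float | None = None
    organelle_tag: str = ""
    constant_output: float | None = None  # degenerate-label fallback

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def _downsample(img: np.ndarray, times: int) -> np.ndarray:
    """Repeated factor-2 block-mean pyramid (odd trailing row/col dropped)."""
    out = np.asarray(img, dtype=np.float32)
    for _ in range(times):
        h, w = out.shape
        out = downscale_local_mean(out[:h - h % 2, :w - w % 2], (2, 2))
        out = out.astype(np.float32)
    return out


def _resize_to(m: np.ndarray, shape) -> np.ndarray:
    if m.shape == tuple(shape):
        return m.astype(np.float32)
    return resize(m.astype(np.float32), shape, order=1, mode="reflect",
                  anti_aliasing=False, preserve_range=True).astype(np.float32)


def _level_arrays(tiles, level):
    return [_downsample(t, level) for t in tiles]


def _assemble_features(img, context_maps, cfg):
    """Stack image features with context probability maps (resampled)."""
    f = compute_features(img, cfg)
    if context_maps:
        ctx = [_resize_to(c, img.shape)[..., None] for c in context_maps]
        f = np.concatenate([f] + ctx, axis=-1)
    return f


def _subsample(X, y, cap, rng):
    """Class-balanced subsample of at most ``cap`` rows."""
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    per = min(cap // 2, pos.size, neg.size)
    if per == 0:
        return None
    take_p = rng.choice(pos, size=per, replace=False)
    take_n = rng.choice(neg, size=per, replace=False)
    idx = np.sort(np.concatenate([take_p, take_n]))
    return X[idx], y[idx]


def _fit_learner(feat_list, lab_list, seed, params, cap=MAX_PIXELS_PER_LEARNER):
    """Fit one base learner on per-tile features with balanced subsampling."""
    n_tiles = len(feat_list)
    rng = np.random.default_rng(seed)
    per_tile = max(cap // max(n_tiles, 1), 2)
    Xs, ys = [], []
    for f, lab in zip(feat_list, lab_list):
        X = f.reshape(-1, f.shape[-1])
        y = lab.ravel()
        sub = _subsample(X, y, per_tile, rng)
        if sub is not None:
            Xs.append(sub[0])
            ys.append(sub[1])
    if not Xs:
        # single-class data at this level: constant learner
        p = float(np.mean([lab.mean() for lab in lab_list]) > 0.5)
        return _ConstantLearner(p)
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    return _TreeLearner(int(seed) % (2**31 - 1), *params).fit(X, y)


def _predict_map(learner, feat) -> np.ndarray:
    h, w, nf = feat.shape
    return learner.predict_proba_pos(feat.reshape(-1, nf)).reshape(h, w)


def _label_at_level(lab, level):
    return (_downsample(lab.astype(np.float32), level) >= 0.5).astype(np.uint8)


def train_chm(train, S: int, L: int, rng_seed: int = 0, *,
              feature_config: FeatureBank | None = None,
              n_estimators: int = 30, max_depth: int = 12) -> CHMModel:
    """Train the cascade on a TrainingSet; deterministic under rng_seed."""
    from .training import TrainingSet  # local import avoids cycle at import time
    if not isinstance(train, TrainingSet):
        raise TypeError("train must be a TrainingSet")
    if len(train) < 2:
        raise ValueError("need at least 2 training tiles")
    if S < 1 or L < 1:
        raise ValueError("S and L must be >= 1")
    if S == 1:
        warnings.warn("the number of stages chosen should be greater than one")
    q, r = train.images.shape[1:]
    if min(q, r) < 2 ** L:
        raise ValueError(f"tiles must be at least 2^L = {2**L} pixels per side")
    cfg = feature_config or FeatureBank()
    params = (n_estimators, max_depth)

    labels_native = [lab for lab in train.labels]
    if len(np.unique(train.labels)) < 2:
        p = float(train.labels.mean() > 0.5)
        warnings.warn("degenerate labels (single class): constant model returned")
        return CHMModel(S=S, L=L, learners={}, feature_config=cfg,
                        organelle_tag=train.organelle_tag, constant_output=p)

    tiles = [img for img in train.images]
    seedseq = np.random.SeedSequence(rng_seed)
    learner_seeds = iter(seedseq.generate_state(S * (L + 2) + 8))

    learners = {}
    stage_output = None  # list of native-res maps from the previous stage
    for s in range(1, S + 1):
        level_maps = []  # level_maps[l][i]: map of tile i at level-l resolution
        for l in range(0, L + 1):
            imgs_l = _level_arrays(tiles, l)
            labs_l = [_label_at_level(lab, l) for lab in labels_native]
            feats = []
            for i, im in enumerate(imgs_l):
                ctx = [level_maps[j][i] for j in range(l)]
                if l == 0 and s > 1:
                    ctx = [stage_output[i]] + ctx
                feats.append(_assemble_features(im, ctx, cfg))
            seed = int(next(learner_seeds))
            learner = _fit_learner(feats, labs_l, seed, params)
            learners[(s, "bu", l)] = learner
            level_maps.append([_predict_map(learner, f) for f in feats])
        # top-down combiner at native resolution
        feats = []
        for i, im in enumerate(tiles):
            ctx = [level_maps[l][i] for l in range(L + 1)]
            feats.append(_assemble_features(np.asarray(im, np.float32), ctx, cfg))
        seed = int(next(learner_seeds))
        combiner = _fit_learner(feats, labels_native, seed, params)
        learners[(s, "td")] = combiner
        stage_output = [_predict_map(combiner, f) for f in feats]

    return CHMModel(S=S, L=L, learners=learners, feature_config=cfg,
                    organelle_tag=train.organelle_tag)


def apply_chm(model: CHMModel, image: np.ndarray) -> ProbabilityMap:
    """Apply the trained cascade to one grayscale slice at native resolution.

    Output values lie in [0, 1]; the map is NOT min-max normalized (that
    happens after tile stitching).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("apply_chm expects a single 2D slice")
    if min(img.shape) < 2 ** model.L:
        raise ValueError(f"image smaller than 2^L = {2**model.L} pixels")
    if model.constant_output is not None:
        return ProbabilityMap(np.full(img.shape, model.constant_output), False)
    cfg = model.feature_config
    stage_map = None
    for s in range(1, model.S + 1):
        level_maps = []
        for l in range(0, model.L + 1):
            im_l = _downsample(img, l)
            ctx = [ _resize_to(level_maps[j], im_l.shape) for j in range(l) ]
            if l == 0 and s > 1:
                ctx = [stage_map] + ctx
            feat = _assemble_features(im_l, ctx, cfg)
            level_maps.append(_predict_map(model.learners[(s, "bu", l)], feat))
        ctx = [_resize_to(level_maps[l], img.shape) for l in range(model.L + 1)]
        feat = _assemble_features(np.asarray(img, np.float32), ctx, cfg)
        stage_map = _predict_map(model.learners[(s, "td")], feat)
    return ProbabilityMap(np.clip(stage_map, 0.0, 1.0), normalized=False)
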