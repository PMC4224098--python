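"""End-to-end orchestration: preprocess -> train -> classify -> binarize ->
evaluate -> 3D objects, with deterministic outputs and a provenance manifest.

Slice-level work units are independent (no cross-slice coupling exists in
the per-slice algorithm), so worker count and scheduling never change the
result.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import joblib

from . import __version__
from .types import PipelineConfig, ProbabilityMap, as_slices
from .training import TrainingSet, split_train_test
from .chm import train_chm, apply_chm
from .tiling import classify_stack
from .binarize import binarize_probability_map
from .evaluate import stack_metrics
from .objects import connected_components_3d, size_filter
from .preprocess import downsample_xy

__all__ = ["PipelineResult", "run_pipeline", "binarize_stack",
           "downsampling_experiment"]


@dataclass
class PipelineResult:
    model: object = None
    probability_maps: np.ndarray | None = None
    segmentations: np.ndarray | None = None
    label_volume: object = None
    report: object = None
    manifest: dict = field(default_factory=dict)


def _hash_array(a) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def binarize_stack(maps, G, alpha, lam, n_workers: int = 1) -> np.ndarray:
    """Binarize each slice of a normalized probability-map stack."""
    vol = np.asarray(maps.values if isinstance(maps, ProbabilityMap) else maps)
    if vol.ndim == 2:
        vol = vol[None]
    if n_workers > 1:
        segs = joblib.Parallel(n_jobs=n_workers)(
            joblib.delayed(binarize_probability_map)(vol[z], G, alpha, lam)
            for z in range(vol.shape[0]))
    else:
        segs = [binarize_probability_map(vol[z], G, alpha, lam)
                for z in range(vol.shape[0])]
    return np.stack(segs)


def run_pipeline(config: PipelineConfig, train_set: TrainingSet,
                 test_images, test_truth=None, *, model=None,
                 n_workers: int = 1, out_dir=None,
                 min_object_voxels: int = 0) -> PipelineResult:
    """Train (unless a model is given), classify, binarize, evaluate,
    extract 3D objects.  Fully deterministic under config.rng_seed."""
    test_vol = as_slices(test_images)
    if model is None:
        model = train_chm(train_set, S=config.S, L=config.L,
                          rng_seed=config.rng_seed)
    maps = classify_stack(model, test_vol, m=config.m, n=config.n, U=config.U,
                          n_workers=n_workers)
    segs = binarize_stack(maps, G=config.G, alpha=config.alpha, lam=config.lam,
                          n_workers=n_workers)
    report = None
    if test_truth is not None:
        report = stack_metrics(segs, test_truth)
    label_vol = connected_components_3d(segs)
    if min_object_voxels:
        label_vol = size_filter(label_vol, min_voxels=min_object_voxels)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in asdict(config).items()},
        "rng_seed": config.rng_seed,
        "hashes": {
            "probability_maps": _hash_array(np.asarray(maps.values)),
            "segmentations": _hash_array(segs),
        },
    }
    result = PipelineResult(model=model, probability_maps=np.asarray(maps.values),
                            segmentations=segs, label_volume=label_vol,
                            report=report, manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path):
    from . import io as _io
    out.mkdir(parents=True, exist_ok=True)
    _io.write_stack(ProbabilityMap(result.probability_maps, normalized=True),
                    out / "probability_maps.tif")
    _io.write_stack(result.segmentations * np.uint8(255), out / "segmentations.tif")
    if result.report is not None:
        (out / "metrics.json").write_text(
            json.dumps(result.report.as_dict(), indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def downsampling_experiment(train_set: TrainingSet, test_images, test_truth,
                            factors, *, S: int = 2, L: int = 2, G: int = 2,
                            alpha: int = 100, lam: float = 0.0,
                            rng_seed: int = 0) -> dict:
    """Retrain and re-evaluate at each lateral downsampling factor.

    For every factor: block-mean downsample training tiles/labels and test
    images/truth, train an S-stage/L-level cascade, classify (single-tile
    inference), binarize with (G, alpha, lam), and report pooled metrics.
    Per-factor failures are recorded and the run continues.
    """
    results = {}
    test_vol = as_slices(test_images)
    truth_vol = as_slices(test_truth)
    for f in factors:
        try:
            if f == 1:
                tr_i, tr_l = train_set.images, train_set.labels
                te_i, te_t = test_vol, truth_vol
            else:
                tr_i = as_slices(downsample_xy(train_set.images, f))
                tr_l = (as_slices(downsample_xy(train_set.labels.astype(np.uint8)
                                                * 255, f)) >= 128).astype(np.uint8)
                te_i = as_slices(downsample_xy(test_vol, f))
                te_t = (as_slices(downsample_xy(truth_vol.astype(np.uint8) * 255,
                                                f)) >= 128).astype(np.uint8)
            ts = TrainingSet(tr_i, tr_l, organelle_tag=train_set.organelle_tag)
            model = train_chm(ts, S=S, L=L, rng_seed=rng_seed)
            maps = classify_stack(model, te_i, m=1, n=1, U=0)
            segs = binarize_stack(maps, G=G, alpha=alpha, lam=lam)
            results[f] = stack_metrics(segs, te_t)
        except Exception as exc:  # noqa: BLE001 - collect and continue
            results[f] = exc
    return results
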