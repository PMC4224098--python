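# Methods

This note documents the models, conventions and numerical choices behind
`organelleseg`, and what the synthetic test bed does and does not show.

## Data model and conventions

Stacks are `(Z, H, W)` arrays of 8-bit intensities with lateral pixel size
(nm/pixel) and slice thickness δ (nm) as metadata; SBEM data are strongly
anisotropic (δ is typically several times the pixel size), which is why
every processing step below is strictly 2D per slice. Coordinates are
0-based `(z, y, x)`, y increasing downward; all rectangles are half-open.
Masks are `{0,1}` in memory and 0/255 on disk. MRC output is mode 0,
little-endian, with the unsigned-byte convention recorded via the IMOD
stamp/flag header fields; both signed and unsigned mode-0 inputs are read,
defaulting to unsigned.

## Preprocessing

**Alignment.** Consecutive slices are aligned translationally only (no
rotation/affine): the correction for slice z maximizes the circular
cross-correlation of the mean-subtracted slice against the *aligned* slice
z−1, searched at integer shifts within ±`max_shift` (default 10 px);
corrections are therefore cumulative with slice 0 as reference. Ties are
broken toward the smallest L2-norm shift, then lexicographically. Vacated
borders are filled with the slice median rather than zeros so that the
subsequent histogram operations are not biased by an artificial black
border. A flat (zero-variance) slice contributes a zero shift and a
warning.

**Exact histogram specification.** Every slice's histogram is forced to
equal the first slice's bin-for-bin. Pixels are ranked under a strict
total order — intensity, then five auxiliary local means of growing
support (3×3 cross, 3×3 full, 5×5 cross, 5×5 full, 7×7 full), then raster
index — and the sorted multiset of target intensities is assigned in rank
order. The strict order makes the result exact and rank-preserving;
because the output histogram equals the target, re-applying the transform
with the same target is the identity.

**Downsampling.** Lateral downsampling by integer factor f maps each
f×f block to its rounded mean (`H' = floor(H/f)`), multiplying the pixel
size by f. Block means were chosen over decimation to avoid aliasing
without introducing a resampling-kernel choice.

## Cascaded hierarchical pixel classification

The classifier `C_{S,L}` has S stages; each stage runs a bottom-up pass
over levels 0..L (level 0 native, each further level block-mean
downsampled by 2) and a top-down combiner:

* level 0: per-pixel image features (+ the previous stage's output map as
  an extra feature when the stage index exceeds 1);
* level l: features of the 2^l-downsampled tile plus the output maps of
  levels 0..l−1 resampled to that level;
* combiner: native-resolution features plus the bilinearly upsampled maps
  of all levels; its probability map is the stage output.

The per-pixel feature bank (37 features) holds the raw intensity, Gaussian
smoothings (σ = 1, 2, 4 px), gradient magnitudes (σ = 1, 2), Laplacians of
Gaussian (σ = 1, 2), local mean and standard deviation in 5×5 and 9×9
windows, and the 25 raw samples of the 5×5 neighborhood, all computed with
reflect padding (translation-covariant up to borders).

The base learner is pluggable. The default is an extremely-randomized-trees
ensemble (30 trees, depth ≤ 12, min leaf 5, seeded, single-threaded)
trained per (stage, level) on a class-balanced subsample of at most 200,000
pixels drawn with a per-tile quota from a seed fanned out deterministically
from the top-level seed. This learner was chosen for desk-scale
tractability and determinism; the cascade topology, not the learner, is the
load-bearing design, and per-pixel outputs are not expected to match any
particular reference training run. If a level sees a single class (e.g. a
tiny structure vanishing at a coarse level), a constant-probability learner
stands in; fully degenerate labels yield a constant model with a warning.
Context maps passed between levels and stages are probabilities in [0,1],
resampled bilinearly. Two stages are recommended; a single stage draws a
warning.

Model files are version-tagged pickles whose byte stream is canonicalized
by one serialization round-trip, so identical models (including a model
that was saved, loaded and saved again) produce identical files.

## Tiled inference

A slice is covered by an m×n grid: base cells of `ceil(H/m) × ceil(W/n)`
pixels, with each interior edge expanded by `floor(U/2)` / `ceil(U/2)` so
adjacent tiles overlap by exactly U pixels (border tiles never extend past
the image; the last row/column absorbs the remainder). U should be roughly
2–10% of the training-tile side; the planner warns outside that band
relative to its own cell size, and the configuration validator checks U
against min(Q, R). Overlap pixels take the maximum over contributing
tiles, and the stitched map is min-max normalized once per slice — after
stitching, not per tile — with the convention that a constant stitched map
normalizes to all zeros. Slices are processed independently, so
multi-worker runs are bit-identical to serial runs by construction.

## Binarization

**Multi-level Otsu.** "G gray levels" means G thresholds producing G+1
classes labeled 0..G, class 0 approximating background; the kept class for
initialization is exactly class G. Thresholds maximize the between-class
variance of a 256-uniform-bin histogram on [0,1]; the search is an exact
dynamic program over cut positions (equivalent to exhaustive enumeration),
with ties resolved toward the lexicographically smallest threshold vector.
A bin cut after bin b corresponds to the threshold (b+1)/256, and
thresholding is inclusive (`value ≥ t`). Constant maps have no threshold
and raise an error from the thresholders; the full binarization pipeline
instead returns an empty segmentation with a warning, because an
all-background slice is legitimate input.

**Morphological shrinking.** Implemented as a lookup-table operator, not
plain erosion: each iteration visits the iteration-start boundary pixels in
raster order and deletes a pixel only if its 8-neighborhood has at least
one foreground pixel and exactly one 0→1 transition in circular order.
This peels components toward points without ever deleting one (a
single-pixel component is retained, a one-pixel-wide ring survives as a
ring), which is what guarantees that every true detection still seeds a
contour after two iterations.

**Active contours.** A two-phase piecewise-constant (Chan–Vese-type) model
evolved directly on the probability map. Each 8-connected component of the
initialization evolves independently, restricted to its basin — the
Voronoi cell of the component under Euclidean distance — so separate seeds
cannot merge silently. Per iteration: the inside/outside means c1, c2 of
each basin are updated, every basin pixel moves to the region whose mean is
closer in the squared sense (equivalently, thresholding the basin at
(c1+c2)/2), and λ passes of a 3×3 binary median filter are applied as a
morphological curvature-flow surrogate; λ = 0 disables smoothing and is
the right choice at large pixel sizes. Components may grow, shrink or
vanish. With λ = 0 the iteration is exact coordinate descent on the
two-phase energy, so the energy (with the boundary-length term weighted by
λ) is non-increasing; with the median surrogate this monotonicity is not
guaranteed analytically but holds on the disk fixtures used in the tests.
α should be at least 50 (warning below); λ is usually in 0–8, and larger
values draw a warning but are accepted.

Raising G removes weak detections (distractors such as myelin rings or
Golgi stacks whose probability plateaus sit below the top Otsu class) at
the cost of weak true positives; this is the central
true-positive/false-positive dial of the workflow.

## Evaluation

Confusion counts are pixelwise; stack metrics pool counts over all slices
before deriving rates (micro-averaging), which is how one value per test
stack is reported. Undefined ratios are NaN with an explicit flag, never
silently zero. ROC curves are computed over pooled pixels with one point
per distinct threshold, endpoints (0,0) and (1,1) included. The identities
F = 2PR/(P+R) and J = F/(2−F) are maintained to 1e-12.

## 3D objects

Per-slice segmentations are labeled in 3D with 26-connectivity by default
(tolerant of residual slice-to-slice jitter; 6-connectivity by flag),
renumbered in raster-scan discovery order. The object table carries voxel
counts, bounding boxes, centroids and physical volumes
(voxels · pixel_size² · δ, reported in µm³; voxels only, with a warning,
when metadata is missing). The size-exclusion filter removes objects
outside a voxel-count range, re-compacts labels, and is idempotent.
Contours are exported per object and slice as outer rectilinear
pixel-boundary polygons (holes omitted, collinear vertices merged on
request) in JSON-lines form.

## Synthetic phantoms

The generator emulates the features of the target data that the workflow
actually exercises: 3D ellipsoidal organelles rasterized per slice (so
consecutive slices correlate, with axial extent scaled by pixel_size/δ ≈
1/4 to mimic SBEM anisotropy), a volumetric cytoplasm-like background
(smooth 3D mottle plus per-pixel noise), dark boundary membranes, and two
distractor classes drawn only into the image: dark myelin-like annuli and
Golgi-like stripe stacks whose texture matches the striped phenotype.
Intensity design: background 150 ± 14 mottle with σ = 6 pixel noise; the
"textured" phenotype's stripe texture (period 6 px, amplitude 45) has the
*same mean as the background*, so it is separable by texture, not
brightness — and therefore degrades under lateral downsampling, while the
"smooth" phenotype (uniform 85) stays separable at any scale. This is the
mechanism behind the downsampling experiment's expected ordering. Per-slice
intensity drift and integer inter-slice jitter (applied last) exercise the
preprocessing stage; ground truth is exact, per-phenotype and mutually
disjoint.

Fixture scales: `unit` = 10 tiles of 128×128 from a 10×140×140 stack;
`integration` = 60 tiles of 256×256 from a 20×280×840 stack (three tiles
per slice), a reduced version of a 90-tile / 500×500 design, split 40/20
for training/held-out evaluation. These sizes were chosen so the full
train-classify-binarize-evaluate loop runs in minutes on one CPU.

**What passing phantom tests does and does not show.** The phantoms have
controllable, fairly clean class separability; held-out F ≈ 0.99 on them
validates the pipeline's contracts (shapes, determinism, stitching,
initialization, contour convergence, metric arithmetic), not real-EM
accuracy, where staining variability, membrane ambiguity and annotation
noise dominate. Conversely, behaviors that are intrinsic to the method do
transfer: per-slice min-max normalization amplifies classifier noise on
slices with no organelles at all, so an all-background slice yields sparse
speckle rather than an exactly empty mask — the size-exclusion filter
(with a threshold below the smallest plausible organelle volume) removes
it. Real deployments should keep that filter on.

## Degenerate inputs and numerical details

* Histograms for all thresholders: 256 uniform bins on [0,1]; all
  thresholder ties go to the smallest threshold.
* The supervised sweep evaluates F at thresholds {0, 1/255, …, 1} with
  inclusive thresholding and returns the smallest arg-max.
* Alignment of a single-slice stack is a no-op with an empty offset list.
* Empty initialization for the contours returns an empty segmentation
  (valid); a non-normalized map is an error.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence`; training, phantom generation and pipeline
  runs are bit-reproducible, and worker count never changes results.

## Known limitations

* Translational alignment only; rotational drift is out of scope.
* The contour model is strictly 2D and two-phase; overlapping organelle
  classes need separate runs per target.
* λ is an iteration count for a median-filter surrogate, not a PDE
  coefficient; its numeric values are not comparable to curvature weights
  in level-set implementations.
* The default learner trades accuracy ceiling for tractability; swapping
  in a stronger ensemble is a one-line change at training time.
* Physical volumes assume constant pixel size and slice thickness across
  the stack.
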