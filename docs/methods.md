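# Methods

This note records the models, algorithms, parameter choices, and known
limitations behind `pollenset`, at the level of detail a maintainer or
reviewer needs to judge what the package does and what its tests do and do
not demonstrate.

## Extended depth-of-field fusion

**Transform.** The fusion backend is a 2-D dual-tree complex wavelet
transform built from PyWavelets filter banks (`pollenset._dtcwt`). Four
parallel real separable DWTs ("trees") are run, one per combination of a
primary (*a*) and secondary (*b*) filter tree along rows and columns:

* level 1 uses the LeGall 5/3 biorthogonal pair (`bior2.2`) for both trees;
  tree *b* is realized by advancing the input one sample along its axis
  before analysis — the classic odd/even-sampling construction giving the
  trees complementary sampling phases;
* levels ≥ 2 use the 8-tap near-symmetric orthonormal `sym4` filter for
  tree *a* and its time reverse for tree *b*, approximating the half-sample
  delay that makes the tree pair analytic.

The complex magnitude at a position is read off as the root-sum-square of
the four trees' coefficients — the combined energy of the two conjugate
oriented subbands. This quantity is approximately shift invariant, which is
the property that matters for comparing sharpness across planes: a grain
edge that lands between sample positions in one plane's decimated grid
still produces a stable magnitude. Exact quarter-sample (Q-shift) filter
pairs would improve analyticity further; the reversed-`sym4` pair is an
engineering approximation whose per-tree perfect reconstruction is exact
(verified to ~1e-12 under periodized boundaries), so fusion fidelity is not
affected — only the degree of shift invariance of the selection statistic.

**Fusion rule.** Every plane (per channel for RGB — channel-wise fusion
preserves stain color, on which the downstream RGB filter depends) is
decomposed to `levels` = 4 levels (grains ~200 px across span several
octaves). At each level/orientation/position the plane with maximal complex
magnitude contributes its coefficients in all four trees; the selection map
is smoothed by a 3×3 majority vote (default on) to suppress impulse
artifacts. Lowpass bands are combined by the mean across planes (default;
smooth backgrounds, avoids blotching) or by following the coarsest-band
selection (`max_energy`). Inversion averages the four tree reconstructions
after undoing the level-1 shifts; output is clipped to [0, 255]. Images are
edge-padded to a multiple of 2^levels and cropped back.

**Baseline.** `fuse_laplacian` is a standard Laplacian-pyramid fusion with
max-|coefficient| selection and mean top level. Its expand step is the same
bilinear operator in analysis and synthesis, so reconstruction telescopes
exactly and the identical-slice identity holds to the integer rounding.

**Focus measure.** `focus_measure` is the local variance of the Laplacian
response (window default 9 px, on luminance). It is used as a test
comparator and by the synthetic generator's sharpest-plane guarantee, not
inside the fusion rule itself.

## Tiling and geometry

All coordinates are 0-based and half-open with x = column; conversions to
COCO `[x, y, w, h]` happen only in dataset I/O. Tile grids stride by
`patch_size − overlap`; the last row/column is anchored to the image edge
(duplicates deduped) so no slide area is unobservable. Assembly uses
non-overlapping tiles (overlap 0); detection at inference may use
overlapping tiles (e.g. overlap = patch/2) so grains straddling seams are
seen whole by some tile, with one global NMS pass merging seam duplicates.

## One-shot detection

The `OneShotDetector` contract is: deterministic, tile-local boxes, scores
≥ threshold. The built-in `NccDetector` slides the luminance exemplar over
the luminance tile at scales {0.8, 1.0, 1.25} (±25% size variation; no
rotation search, grains being near-isotropic), takes 3×3 local maxima of
the normalized cross-correlation with r ≥ 2·threshold − 1, and scores each
box (r+1)/2 so thresholds are numerically comparable with learned-detector
confidences. Greedy NMS (IoU 0.5, lexicographic tie-breaks) dedupes within
and across tiles. The default threshold 0.8 (r ≥ 0.6) is a deliberate
precision-first convention: initial detections should be clean, with
recall recovered later by the refinement stage. Learned
open-vocabulary detectors integrate as adapters behind the same contract;
no model inference ships with the package.

## Refinement

**RGB statistical filter.** Each box is summarized by its mean RGB vector
m_i (pixel centers inside box ∩ image); μ is the mean of {m_i} and
d_i = ‖m_i − μ‖₂. A box is removed iff d_i > k·σ, strictly, with k = 1
by default — strictness makes the degenerate all-identical case remove
nothing. Two spread estimates are implemented:

* `channel` (default): σ = ‖per-channel population SD of {m_i}‖ — the size
  of the color cloud itself;
* `distance`: σ = population SD of the scalar distances {d_i}.

The distance variant is the more literal reading of a scalar "1σ" rule, but
for a roughly isotropic color cloud d_i is chi-distributed with mean ≈
1.6σ_c and SD ≈ 0.7σ_c, so *every* box exceeds one SD of the distances and
the filter degenerates to "remove all" precisely when the input is clean;
it behaves as intended only when genuine outliers inflate the spread. The
channel variant removes ~30–50% on the synthetic benchmark — outliers and
the boxes with the most background contamination — and is therefore the
default. Both are config-selectable; the planted-outlier recovery case
behaves identically under both. Filtering is skipped below `min_boxes` = 3
inputs, where a spread estimate is meaningless. Per-box summarization (one
keep/discard decision per box) is the chosen granularity; a pixel-level
comparison would need a separate aggregation rule to reach a box decision.

**Tightening.** Within each kept box expanded by 1.5×, the background color
is estimated from the window's 2-px border ring, the foreground mask is
Otsu-thresholded on the RGB distance-to-background map, and the box snaps
to the largest connected component. Fallback to the input box when the mask
is empty or the component is under 10% of the box area (pure-background
boxes pass through unchanged).

**Recovery.** The slide is re-scanned at a relaxed threshold (default 0.6,
i.e. r ≥ 0.2 for the NCC detector); candidates overlapping any kept box
with IoU ≥ 0.3 are discarded. Recovered boxes are then also tightened, and
the concatenated refined set passes one final NMS: the relaxed NCC pass
produces side peaks at ring-period offsets around textured grains, and
tightening snaps those satellites onto their grain where NMS collapses
them. The stage counts (initial / filtered / refined) recorded per slide
follow the standard reporting pattern: filtered ≤ initial always, and
refined may exceed initial via recovery.

A learned refiner can replace the tighten+rescan pair behind the `Refiner`
contract; the adapter metadata fields (25 epochs, batch 32, learning rate
0.001) are carried in `RefineConfig` so adapter runs are reproducible, but
no training code ships.

## Dataset assembly

Label inheritance requires `SlideImage.species` to be set and refuses mixed
slides. COCO output uses lexicographic category ids, bbox floats rounded to
2 decimals (sub-pixel precision is irrelevant at 200-px grains; round trips
are lossless at that precision), and carries score/stage/detector_id as
extra annotation fields so one schema serves training data and predictions.
Internal holdout splits withhold a whole number of tile strides anchored at
the far slide edge (the train side keeps any partial-stride remainder);
each region is tiled independently, so no tile straddles the boundary. The
default holdout fraction is 0.2. Manifests record the full resolved config,
seed, stage counts, and a config hash; no timestamps, so identical runs are
byte-identical.

## Evaluation protocol

AP is the 101-point interpolated area under the precision envelope at a
given IoU threshold; AP(0.50:0.95) averages thresholds 0.50 to 0.95 in
steps of 0.05; AR is recall under a per-image cap of 100 detections. With
class-aware scoring (default), metrics are macro means over classes with at
least one ground truth; a class with detections but no ground truth scores
AP 0, and the empty-vs-empty case is reported as missing and excluded from
means rather than scored 0 (absent taxa should not dilute macro averages).
Matching is greedy in descending score with lexicographic tie-breaks; each
ground truth matches at most one detection.

The containment rule drops ground truths whose box has < `min_containment`
(default 0.8, inclusive) of its area inside every tile. The CLI evaluate
command applies the same rule to predictions by default
(`--no-containment-dets` disables): a detector running on non-overlapping
tiles both misses boundary grains (recall side) and emits truncated boxes
for them (precision side), and the fairness argument covers both. Box area
is the containment denominator (for box annotations, the box and the
annotated area coincide).

Confusion matrices use class-agnostic matching — class-aware matching could
never populate off-diagonals — with unmatched ground truths tallied in a
separate `missed` vector outside the normalized rows. `fold_mean_stderr`
is the reporting helper for mean ± SE over repeated evaluation folds.

The test suite pins the implementation to an independent brute-force oracle
(enumerate score thresholds, re-match from scratch at each, integrate the
envelope) to 1e-9 over 200 random instances. Both sides share the exact
recall grid `arange(101)/100` and an ε = 1e-12 inclusive comparison; test
instances use distinct scores, under which threshold enumeration and
prefix cumulation provably coincide.

## Synthetic slide generator

The generator emulates the statistical structure the pipeline assumes:
round grains (radius 80–120 px, i.e. ~200 px diameter at a 40×-like
sampling) with species-specific stain color, concentric exine-like ring
modulation, a darker rim, multiplicative speckle, and up to four darker
aperture notches; a pale background with Gaussian noise; unannotated debris
(gray-brown blobs and random-walk fibers) that exists to exercise the RGB
filter and confidence thresholding; per-grain focal depth and a defocus
z-stack where each grain is composited with blur σ = `blur_sigma_per_plane`
× |depth − plane| over a background blurred at half rate relative to the
mean grain depth (the adhesive surface grains sit on — this makes the
single-plane and zero-blur cases reproduce the reference exactly and
guarantees each grain is sharpest at the plane nearest its depth, by
construction). Ground-truth boxes are the exact bounding boxes of each
grain's rendered alpha support. One RNG stream per scene, drawn in
documented order, makes every output byte-reproducible from (spec, seed).

The standard benchmark (`make_fixture`) renders 2 species × 12 grains per
pure slide on a 1554² canvas (a 3×3 grid of 518-px tiles), plus a mixed
slide and one held-out grain per species cropped as the exemplar. The
*easy* preset has disjoint grains, no debris, noise SD 3; *hard* allows box
IoU up to 0.2, adds debris, noise SD 6, stronger color jitter, and a stain
shift between slides emulating cross-region domain shifts.

**What passing tests do not show.** Synthetic grains are crisp procedural
disks on clean backgrounds: NCC correlations are far higher, and Otsu
tightening far cleaner, than on real fuchsine-stained material with
collapsed grains, touching clusters, air bubbles, and uneven illumination.
Near-perfect AP on the benchmark validates the pipeline's plumbing and
geometry, not field-grade detection accuracy; on real slides the one-shot
stage would be a learned detector behind the adapter contract, and the
filter/refinement margins would be materially tighter.

## Numerical choices and degenerate inputs

* Fusion tolerance "equals within ±1 intensity" means max-abs pixel
  difference ≤ 1 after uint8 rounding.
* NCC correlation is clipped to [−1, 1] before score mapping (floating
  error can exceed 1 on exact matches); constant templates or tiles yield
  no detections rather than NaNs.
* All tie-breaks (NMS order, matching order, selection argmax, majority
  vote) resolve lexicographically / lowest-index, so every code path is
  deterministic without randomness.
* Histogram matching uses a mid-mass quantile convention (a value's
  quantile = mass strictly below + half its own mass): constant images map
  to the reference's median-mass level, pure intensity offsets invert
  exactly, and rank order is preserved per channel.
* `box_mean_rgb` clips overhanging boxes to the raster and errors on empty
  intersection; `tighten_box` falls back to its input instead of erroring.
* Problem sizes in tests and the acceptance script (1554² slides, 3-plane
  stacks, ≤ 200-instance oracle sweeps) were chosen as the smallest sizes
  at which every contract is exercised with multi-tile geometry.

## Known limitations

* No registration of misaligned z-planes (scanner output is assumed
  co-registered) and no stain-vector (Macenko) deconvolution — histogram
  matching is the only normalization shipped.
* Plain rasters only; no pyramidal WSI container support.
* The NCC detector searches scale but not rotation or shape; strongly
  aspherical or collapsed grains need a learned detector adapter.
* The RGB filter is color-only; feature-space outlier clustering is out of
  scope.
* Fold averaging across region splits is a reporting helper; the package
  does not orchestrate cross-validation itself.
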