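"""Stage-2 annotation cleanup: RGB outlier removal, tightening, and recovery.

On a pure-species slide every true grain shares one stain appearance, so a
detection whose mean color sits far from the slide's class mean is very
likely debris or background.  The filter summarizes each box by its mean RGB
vector, measures Euclidean distances to the class mean, and discards boxes
whose distance exceeds ``k`` standard deviations (k = 1 by default).

The subsequent refinement stage has a fixed contract — remove residual false
positives, tighten boxes to the grain support, and recover grains the
high-threshold initial pass missed — realized here by a classical
tighten-and-rescan pair; learned refiners plug in behind the
:class:`Refiner` contract and replace that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .oneshot import (
    Detection,
    DetectorConfig,
    Exemplar,
    OneShotDetector,
    detect_slide,
    nms,
)
from .slides import Box, SlideImage, TilingConfig, iou

__all__ = [
    "FilterConfig",
    "FilterResult",
    "RefineConfig",
    "Refiner",
    "StageCounts",
    "box_mean_rgb",
    "rgb_outlier_filter",
    "tighten_box",
    "rescan_recover",
    "refine_annotations",
]


@dataclass(frozen=True)
class FilterConfig:
    """RGB statistical filter parameters.

    ``k`` multiplies the standard deviation of the distance distribution
    (the field convention is the 1-sigma rule, k = 1).  ``min_boxes`` guards
    the degenerate case: a spread estimated from fewer samples is
    meaningless, so filtering is skipped below it.

    ``sigma_mode`` selects the spread estimate.  ``'channel'`` (default)
    takes the Euclidean norm of the per-channel standard deviations of the
    box mean colors — a measure of the color cloud's own size.
    ``'distance'`` takes the standard deviation of the scalar distances
    {d_i}.  The distance spread of a roughly isotropic color cloud is much
    smaller than its mean (d_i is chi-like), so on clean slides the
    'distance' rule at k=1 removes nearly every box; it behaves as intended
    only when genuine outliers inflate the spread.  'channel' reproduces the
    intended outlier-only behavior in both regimes.
    """

    k: float = 1.0
    min_boxes: int = 3
    sigma_mode: Literal["channel", "distance"] = "channel"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.sigma_mode not in ("distance", "channel"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")


@dataclass
class FilterResult:
    """Partition of the input detections plus the filter's statistics."""

    kept: list[Detection]
    removed: list[Detection]
    class_mean_rgb: np.ndarray
    sigma: float
    distances: np.ndarray


@dataclass(frozen=True)
class RefineConfig:
    """Refinement-stage parameters.

    ``expand_factor`` scales each kept box before foreground estimation so a
    slightly-off box still sees the whole grain; ``relaxed_threshold`` is the
    lowered confidence used by the recovery re-scan; ``recover_max_iou``
    bounds the overlap a recovered box may have with any kept box.  The
    ``adapter_*`` fields are pass-through metadata recorded for learned
    refiner adapters (training epochs / batch size / learning rate) so
    adapter runs are reproducible; no training happens in-package.
    """

    expand_factor: float = 1.5
    relaxed_threshold: float = 0.6
    recover_max_iou: float = 0.3
    adapter_epochs: int = 25
    adapter_batch_size: int = 32
    adapter_learning_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.expand_factor < 1.0:
            raise ValueError("expand_factor must be >= 1")
        if not (0.0 <= self.relaxed_threshold <= 1.0):
            raise ValueError("relaxed_threshold must lie in [0, 1]")


@runtime_checkable
class Refiner(Protocol):
    """Contract for pluggable refiners (e.g. a briefly fine-tuned detector).

    Must be deterministic given fixed inputs; output boxes lie within the
    slide bounds and carry ``stage='refined'``.
    """

    def refine(
        self,
        slide: SlideImage,
        filtered: Sequence[Detection],
        exemplar: Exemplar,
        config: RefineConfig,
    ) -> list[Detection]: ...


@dataclass(frozen=True)
class StageCounts:
    """Annotation counts after each pipeline stage."""

    initial: int
    filtered: int
    refined: int


def box_mean_rgb(image: np.ndarray, box: Box) -> np.ndarray:
    """Channel-wise mean color over the pixels whose centers fall in the box.

    Boxes overhanging the raster are clipped to it; an empty intersection is
    an error.
    """
    h, w = image.shape[:2]
    x0 = max(int(np.ceil(box.x_min - 0.5)), 0)
    y0 = max(int(np.ceil(box.y_min - 0.5)), 0)
    x1 = min(int(np.ceil(box.x_max - 0.5)), w)
    y1 = min(int(np.ceil(box.y_max - 0.5)), h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("box does not intersect the image")
    patch = image[y0:y1, x0:x1]
    if patch.ndim == 2:
        m = float(patch.mean())
        return np.array([m, m, m])
    return patch.reshape(-1, patch.shape[-1]).mean(axis=0).astype(np.float64)


def rgb_outlier_filter(
    dets: Sequence[Detection],
    image: np.ndarray,
    config: FilterConfig = FilterConfig(),
) -> FilterResult:
    """Discard detections whose mean color is a >k-sigma outlier.

    Per box i: m_i = mean RGB; mu = mean of {m_i}; d_i = ||m_i - mu||;
    sigma is the population standard deviation of {d_i} (``sigma_mode
    'distance'``, the default) or the norm of the per-channel population
    standard deviations of {m_i} (``'channel'``).  A box is removed iff
    d_i > k*sigma, strictly, so an all-identical input removes nothing.
    With fewer than ``min_boxes`` inputs all boxes are kept and sigma
    reported as 0.
    """
    if len(dets) == 0:
        raise ValueError("rgb_outlier_filter needs at least one detection")
    means = np.stack([box_mean_rgb(image, d.box) for d in dets])
    mu = means.mean(axis=0)
    distances = np.linalg.norm(means - mu, axis=1)
    if len(dets) < config.min_boxes:
        kept = [replace(d, stage="filtered") for d in dets]
        return FilterResult(kept, [], mu, 0.0, distances)
    if config.sigma_mode == "distance":
        sigma = float(distances.std())  # population sd of the scalar distances
    else:
        sigma = float(np.linalg.norm(means.std(axis=0)))
    kept, removed = [], []
    for d, dist in zip(dets, distances):
        if dist > config.k * sigma:
            removed.append(d)
        else:
            kept.append(replace(d, stage="filtered"))
    return FilterResult(kept, removed, mu, sigma, distances)


def _expand_clip(box: Box, factor: float, w: int, h: int) -> Box:
    cx, cy = box.center
    hw, hh = 0.5 * box.width * factor, 0.5 * box.height * factor
    return Box(
        x_min=max(cx - hw, 0.0),
        y_min=max(cy - hh, 0.0),
        x_max=min(cx + hw, float(w)),
        y_max=min(cy + hh, float(h)),
    )


def tighten_box(
    image: np.ndarray, box: Box, config: RefineConfig = RefineConfig()
) -> Box:
    """Shrink (or grow) a box to the grain it contains.

    Within the ``expand_factor``-scaled box, the background color is
    estimated from the expanded box's 2-px border ring; the foreground mask
    is Otsu-thresholded on the RGB distance-to-background map, and the
    bounding box of the largest connected foreground component is returned.
    Falls back to the input box when no credible foreground is found (empty
    mask or largest component under 10% of the box area).
    """
    h, w = image.shape[:2]
    ebox = _expand_clip(box, config.expand_factor, w, h)
    x0, y0 = int(np.floor(ebox.x_min)), int(np.floor(ebox.y_min))
    x1, y1 = int(np.ceil(ebox.x_max)), int(np.ceil(ebox.y_max))
    patch = image[y0:y1, x0:x1].astype(np.float64)
    if patch.ndim == 2:
        patch = patch[..., None]
    if patch.shape[0] < 5 or patch.shape[1] < 5:
        return box
    ring = np.concatenate(
        [
            patch[:2].reshape(-1, patch.shape[-1]),
            patch[-2:].reshape(-1, patch.shape[-1]),
            patch[:, :2].reshape(-1, patch.shape[-1]),
            patch[:, -2:].reshape(-1, patch.shape[-1]),
        ]
    )
    background = ring.mean(axis=0)
    dist = np.linalg.norm(patch - background, axis=-1)
    if np.ptp(dist) < 1e-9:
        return box
    mask = dist > threshold_otsu(dist)
    if not mask.any():
        return box
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < 0.1 * box.area:
        return box
    ys, xs = np.nonzero(labels == largest)
    return replace(
        box,
        x_min=float(x0 + xs.min()),
        y_min=float(y0 + ys.min()),
        x_max=float(x0 + xs.max() + 1),
        y_max=float(y0 + ys.max() + 1),
    )


def rescan_recover(
    slide: SlideImage,
    exemplar: Exemplar,
    kept: Sequence[Detection],
    tiling: TilingConfig = TilingConfig(),
    detector_config: DetectorConfig = DetectorConfig(),
    refine_config: RefineConfig = RefineConfig(),
    detector: Optional[OneShotDetector] = None,
) -> list[Detection]:
    """Recover grains missed by the high-threshold initial pass.

    Re-runs slide detection at ``relaxed_threshold`` and returns only
    detections overlapping every kept box below ``recover_max_iou``,
    stage-tagged ``refined``.
    """
    relaxed = replace(detector_config, score_threshold=refine_config.relaxed_threshold)
    rescan = detect_slide(slide, exemplar, tiling, relaxed, detector)
    recovered = []
    for d in rescan:
        if all(iou(d.box, k.box) < refine_config.recover_max_iou for k in kept):
            recovered.append(replace(d, stage="refined"))
    return recovered


def refine_annotations(
    slide: SlideImage,
    initial: Sequence[Detection],
    exemplar: Exemplar,
    tiling: TilingConfig = TilingConfig(),
    detector_config: DetectorConfig = DetectorConfig(),
    filter_config: FilterConfig = FilterConfig(),
    refine_config: RefineConfig = RefineConfig(),
    detector: Optional[OneShotDetector] = None,
    refiner: Optional[Refiner] = None,
) -> tuple[list[Detection], StageCounts, FilterResult | None]:
    """Two-step refinement: statistical filtering, then tighten + recover.

    Returns the refined detections, the per-stage counts, and the filter
    diagnostics (None when ``initial`` is empty).  When a :class:`Refiner`
    adapter is supplied it replaces the classical tighten/re-scan pair.
    """
    if len(initial) == 0:
        return [], StageCounts(0, 0, 0), None
    fres = rgb_outlier_filter(initial, slide.raster, filter_config)
    if refiner is not None:
        refined = list(
            refiner.refine(slide, fres.kept, exemplar, refine_config)
        )
    else:
        tightened = [
            replace(d, stage="refined", box=tighten_box(slide.raster, d.box, refine_config))
            for d in fres.kept
        ]
        recovered = rescan_recover(
            slide, exemplar, tightened, tiling, detector_config, refine_config, detector
        )
        # tighten recovered boxes too: off-center re-scan hits snap onto
        # their grain, and the final NMS pass then collapses duplicates
        recovered = [
            replace(d, box=tighten_box(slide.raster, d.box, refine_config))
            for d in recovered
        ]
        refined = nms(tightened + recovered, detector_config.nms_iou)
    counts = StageCounts(
        initial=len(initial), filtered=len(fres.kept), refined=len(refined)
    )
    return refined, counts, fres
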