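"""One-shot exemplar detection: contract, classical NCC detector, and NMS.

The annotation pipeline is bootstrapped by a one-shot detector: given a single
cropped exemplar grain, it proposes boxes for visually similar grains on every
tile of a slide.  In production that role is played by a learned
open-vocabulary model behind the :class:`OneShotDetector` contract; the
built-in :class:`NccDetector` is a deterministic multi-scale normalized
cross-correlation matcher that satisfies the same contract at desk scale,
so the whole pipeline is runnable and testable without GPU inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import resize

from .slides import Box, SlideImage, TileRect, TilingConfig, iou, tile_grid, to_global

__all__ = [
    "Exemplar",
    "Detection",
    "DetectorConfig",
    "OneShotDetector",
    "NccDetector",
    "ncc_detect",
    "nms",
    "detect_slide",
    "read_exemplar",
]

STAGES = ("initial", "filtered", "refined")


@dataclass(frozen=True)
class Exemplar:
    """A single cropped grain used to prompt one-shot detection.

    Its species label propagates to every detection on a pure-species slide.
    """

    crop: np.ndarray
    species: str
    exemplar_id: str = "exemplar-0"

    def __post_init__(self) -> None:
        if self.crop.ndim not in (2, 3) or min(self.crop.shape[:2]) < 3:
            raise ValueError("exemplar crop must be a small 2-D/RGB raster")
        if not self.species:
            raise ValueError("exemplar species must be non-empty")


@dataclass(frozen=True)
class Detection:
    """A scored, labeled box with stage provenance.

    ``box`` is tile-local or global depending on context; ``tile_origin``
    records the producing tile, ``stage`` the pipeline step that emitted it.
    """

    box: Box
    score: float
    label: str
    tile_origin: tuple[int, int] = (0, 0)
    stage: str = "initial"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")


@dataclass(frozen=True)
class DetectorConfig:
    """One-shot detection parameters.

    ``score_threshold`` is deliberately high (0.8) so the initial stage
    favors precision; the refinement stage re-scans at a relaxed threshold.
    ``scales`` covers ~±25% grain size variation; rotation is not searched
    (grains are near-isotropic).
    """

    score_threshold: float = 0.8
    scales: tuple[float, ...] = (0.8, 1.0, 1.25)
    nms_iou: float = 0.5
    max_per_tile: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must lie in [0, 1]")
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and positive")
        if not (0.0 <= self.nms_iou <= 1.0):
            raise ValueError("nms_iou must lie in [0, 1]")


@runtime_checkable
class OneShotDetector(Protocol):
    """Behavioral contract for one-shot detectors.

    ``detect`` returns tile-local detections with boxes inside the tile and
    scores >= the configured threshold, deterministically for fixed inputs.
    Adapters wrapping learned models plug in here.
    """

    def detect(
        self, tile: np.ndarray, exemplar: Exemplar, config: DetectorConfig
    ) -> list[Detection]: ...


_LUMA = np.array([0.299, 0.587, 0.114])


def _luminance(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image.astype(np.float64)
    return image.astype(np.float64) @ _LUMA


def _det_sort_key(d: Detection):
    return (-d.score, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)


def nms(dets: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited in descending score (ties broken lexicographically
    by box corners); one is kept iff its IoU with every already-kept
    detection is below ``iou_threshold``.  Kept order is preserved.
    """
    kept: list[Detection] = []
    for d in sorted(dets, key=_det_sort_key):
        if all(iou(d.box, k.box) < iou_threshold for k in kept):
            kept.append(d)
    return kept


def ncc_detect(
    tile: np.ndarray, exemplar: Exemplar, config: DetectorConfig = DetectorConfig()
) -> list[Detection]:
    """Multi-scale normalized cross-correlation detection on one tile.

    For each scale the luminance exemplar is slid over the luminance tile;
    3x3-neighborhood local maxima with correlation r >= 2*threshold - 1
    become boxes of the scaled exemplar size centered on the maximum, scored
    (r+1)/2 so thresholds are comparable with learned-detector confidences.
    Results are pooled over scales and deduplicated by NMS.
    """
    tile_lum = _luminance(tile)
    ex_lum = _luminance(exemplar.crop)
    th, tw = tile_lum.shape
    r_min = 2.0 * config.score_threshold - 1.0

    candidates: list[Detection] = []
    any_scale = False
    for scale in config.scales:
        eh = max(3, int(round(ex_lum.shape[0] * scale)))
        ew = max(3, int(round(ex_lum.shape[1] * scale)))
        if eh > th or ew > tw:
            continue  # exemplar larger than tile at this scale
        any_scale = True
        templ = resize(
            ex_lum, (eh, ew), order=1, anti_aliasing=scale < 1.0, preserve_range=True
        )
        if templ.std() == 0.0:
            continue
        corr = match_template(tile_lum, templ, pad_input=False)
        corr = np.clip(np.nan_to_num(corr, nan=-1.0), -1.0, 1.0)
        local_max = corr == ndimage.maximum_filter(corr, size=3, mode="constant", cval=-2.0)
        peaks = np.argwhere(local_max & (corr >= r_min))
        for y, x in peaks:
            r = float(corr[y, x])
            box = Box(
                x_min=float(x),
                y_min=float(y),
                x_max=float(min(x + ew, tw)),
                y_max=float(min(y + eh, th)),
            )
            candidates.append(
                Detection(box=box, score=(r + 1.0) / 2.0, label=exemplar.species)
            )
    if not any_scale:
        raise ValueError("exemplar larger than tile at every scale")
    kept = nms(candidates, config.nms_iou)
    return kept[: config.max_per_tile]


@dataclass(frozen=True)
class NccDetector:
    """Built-in classical detector satisfying the OneShotDetector contract."""

    def detect(
        self, tile: np.ndarray, exemplar: Exemplar, config: DetectorConfig
    ) -> list[Detection]:
        return ncc_detect(tile, exemplar, config)


def detect_slide(
    slide: SlideImage,
    exemplar: Exemplar,
    tiling: TilingConfig = TilingConfig(),
    config: DetectorConfig = DetectorConfig(),
    detector: Optional[OneShotDetector] = None,
) -> list[Detection]:
    """Run one-shot detection over every tile of a slide.

    Boxes are mapped to global slide coordinates and a final cross-tile NMS
    pass merges duplicates arising from anchored-tile overlap.  All output
    detections carry ``stage='initial'``.
    """
    detector = detector or NccDetector()
    raster = slide.raster
    if slide.region_of_interest is not None:
        roi = slide.region_of_interest
        raster = roi.crop(raster)
    all_dets: list[Detection] = []
    for tile in tile_grid(raster.shape[1], raster.shape[0], tiling):
        try:
            local = detector.detect(tile.crop(raster), exemplar, config)
        except ValueError as exc:
            raise ValueError(
                f"detector failed on tile ({tile.x}, {tile.y}) of "
                f"slide {slide.slide_id!r}: {exc}"
            ) from exc
        for d in local:
            all_dets.append(
                replace(
                    d,
                    box=to_global(d.box, tile),
                    tile_origin=(tile.x, tile.y),
                    stage="initial",
                )
            )
    merged = nms(all_dets, config.nms_iou)
    if slide.region_of_interest is not None:
        roi = slide.region_of_interest
        merged = [
            replace(d, box=d.box.translate(roi.x, roi.y),
                    tile_origin=(d.tile_origin[0] + roi.x, d.tile_origin[1] + roi.y))
            for d in merged
        ]
    return merged


def read_exemplar(path: str | Path, species: str, exemplar_id: Optional[str] = None) -> Exemplar:
    """Load an exemplar crop from PNG/TIFF."""
    path = Path(path)
    crop = np.asarray(iio.imread(path))
    if crop.ndim == 3 and crop.shape[2] == 4:
        crop = crop[:, :, :3]
    return Exemplar(crop=crop, species=species, exemplar_id=exemplar_id or path.stem)
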