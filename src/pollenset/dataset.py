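"""Labeled-dataset assembly: label inheritance, splits, COCO I/O, reports.

Because every slide entering the pipeline is a pure-species reference slide,
one exemplar's species label can be inherited by every detection on that
slide, turning raw detector output into a fully labeled dataset.  This module
owns that bookkeeping plus the standard COCO-detection interchange format and
the internal/external region split (a spatially distinct slide region is
withheld for internal testing).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .oneshot import Detection, STAGES
from .refine import StageCounts
from .slides import Box, SlideImage, TileRect, TilingConfig

__all__ = [
    "AnnotationRecord",
    "StageCountRow",
    "RegionSplit",
    "DatasetManifest",
    "inherit_labels",
    "split_regions",
    "write_coco",
    "read_coco",
    "stage_report",
]

_BOX_DECIMALS = 2


@dataclass(frozen=True)
class AnnotationRecord:
    """A labeled box tied to a slide, species, pipeline stage and detector."""

    slide_id: str
    box: Box
    species: str
    stage: str = "refined"
    score: float = 1.0
    detector_id: str = "ncc"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.stage not in STAGES and self.stage != "ground_truth":
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class StageCountRow:
    """Per (slide, species) annotation counts at the three pipeline stages."""

    slide_id: str
    species: str
    initial: int
    filtered: int
    refined: int

    def __post_init__(self) -> None:
        if self.filtered > self.initial:
            raise ValueError("filtered count cannot exceed initial count")
        if min(self.initial, self.filtered, self.refined) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RegionSplit:
    """Disjoint train/test regions covering a slide (or its ROI)."""

    train_region: TileRect
    test_region: TileRect
    axis: Literal["horizontal", "vertical"]
    holdout_fraction: float


def inherit_labels(
    dets: Sequence[Detection],
    slide: SlideImage,
    detector_id: str = "ncc",
) -> list[AnnotationRecord]:
    """Copy a pure-species slide's label onto every detection.

    Mixed slides (``slide.species`` unset) must not be auto-labeled and
    raise instead.
    """
    if not slide.species:
        raise ValueError(
            f"slide {slide.slide_id!r} has no species label; "
            "label inheritance applies only to pure-species slides"
        )
    return [
        AnnotationRecord(
            slide_id=slide.slide_id,
            box=d.box,
            species=slide.species,
            stage=d.stage,
            score=d.score,
            detector_id=detector_id,
        )
        for d in dets
    ]


def split_regions(
    slide: SlideImage,
    holdout_fraction: float = 0.2,
    axis: Literal["horizontal", "vertical"] = "vertical",
    tiling: TilingConfig = TilingConfig(),
) -> RegionSplit:
    """Withhold a spatially distinct region of the slide for internal testing.

    The split boundary sits at ``floor(dim * (1 - holdout_fraction))``
    snapped to the tile stride so no tile straddles it; the holdout is a
    whole number of strides anchored at the far edge, the train side keeps
    any partial-stride remainder.  ``axis='vertical'`` splits along x.
    """
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be horizontal or vertical, got {axis!r}")
    roi = slide.region_of_interest or TileRect(0, 0, slide.width, slide.height)
    dim = roi.width if axis == "vertical" else roi.height
    stride = tiling.stride
    holdout_strides = int(np.ceil(dim * holdout_fraction)) // stride
    if holdout_strides < 1:
        raise ValueError(
            f"holdout fraction {holdout_fraction} leaves no room for a full "
            f"{stride}-px tile along {axis} dim {dim}"
        )
    boundary = dim - holdout_strides * stride
    if boundary < 1:
        raise ValueError("holdout fraction leaves no training region")
    if axis == "vertical":
        train = TileRect(roi.x, roi.y, boundary, roi.height)
        test = TileRect(roi.x + boundary, roi.y, dim - boundary, roi.height)
    else:
        train = TileRect(roi.x, roi.y, roi.width, boundary)
        test = TileRect(roi.x, roi.y + boundary, roi.width, dim - boundary)
    return RegionSplit(train, test, axis, holdout_fraction)


def _category_ids(species: Sequence[str]) -> dict[str, int]:
    return {name: i + 1 for i, name in enumerate(sorted(set(species)))}


def write_coco(
    records: Sequence[AnnotationRecord],
    slides: Sequence[SlideImage],
    path: str | Path,
) -> None:
    """Write annotation records as COCO detection JSON.

    Category ids are assigned lexicographically by species name (stable
    across runs); bbox is ``[x, y, w, h]`` rounded to 2 decimals; scores and
    stage provenance ride along in extra annotation fields.
    """
    slide_ids = {s.slide_id: i + 1 for i, s in enumerate(slides)}
    cats = _category_ids([r.species for r in records])
    images = [
        {
            "id": slide_ids[s.slide_id],
            "file_name": f"{s.slide_id}.png",
            "width": s.width,
            "height": s.height,
        }
        for s in slides
    ]
    categories = [{"id": i, "name": name} for name, i in sorted(cats.items(), key=lambda kv: kv[1])]
    annotations = []
    for k, r in enumerate(records):
        if r.slide_id not in slide_ids:
            raise ValueError(f"record references unknown slide {r.slide_id!r}")
        x = round(r.box.x_min, _BOX_DECIMALS)
        y = round(r.box.y_min, _BOX_DECIMALS)
        w = round(r.box.x_max - r.box.x_min, _BOX_DECIMALS)
        h = round(r.box.y_max - r.box.y_min, _BOX_DECIMALS)
        annotations.append(
            {
                "id": k + 1,
                "image_id": slide_ids[r.slide_id],
                "category_id": cats[r.species],
                "bbox": [x, y, w, h],
                "area": round(w * h, 2 * _BOX_DECIMALS),
                "iscrowd": 0,
                "score": round(r.score, 6),
                "stage": r.stage,
                "detector_id": r.detector_id,
            }
        )
    payload = {"images": images, "categories": categories, "annotations": annotations}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_coco(path: str | Path) -> tuple[list[AnnotationRecord], list[dict]]:
    """Read COCO detection JSON back into records plus image metadata.

    Exact inverse of :func:`write_coco` at the declared precision.  Raises
    with the offending location on malformed input.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON: {exc}") from exc
    for key in ("images", "categories", "annotations"):
        if key not in payload:
            raise ValueError(f"{path}: missing COCO key {key!r}")
    cat_names = {c["id"]: c["name"] for c in payload["categories"]}
    image_ids = {im["id"]: im for im in payload["images"]}
    records = []
    for ann in payload["annotations"]:
        if ann["category_id"] not in cat_names:
            raise ValueError(
                f"{path}: annotation id {ann.get('id')} references unknown "
                f"category id {ann['category_id']}"
            )
        if ann["image_id"] not in image_ids:
            raise ValueError(
                f"{path}: annotation id {ann.get('id')} references unknown "
                f"image id {ann['image_id']}"
            )
        x, y, w, h = ann["bbox"]
        records.append(
            AnnotationRecord(
                slide_id=Path(image_ids[ann["image_id"]]["file_name"]).stem,
                box=Box(x, y, x + w, y + h),
                species=cat_names[ann["category_id"]],
                stage=ann.get("stage", "refined"),
                score=float(ann.get("score", 1.0)),
                detector_id=ann.get("detector_id", "unknown"),
            )
        )
    return records, payload["images"]


def stage_report(rows: Sequence[StageCountRow]) -> tuple[str, list[dict]]:
    """Tabulate per-slide/species counts at the three pipeline stages.

    Returns a TSV text table and the equivalent JSON-ready list; rows keep
    input order.  Percent removed = filtering losses relative to the initial
    count; recovered = boxes the refinement stage added back beyond the
    filtered count (clamped at 0).
    """
    header = [
        "slide_id", "species", "initial", "filtered", "refined",
        "pct_removed", "recovered",
    ]
    lines = ["\t".join(header)]
    table = []
    for r in rows:
        pct_removed = (
            100.0 * (r.initial - r.filtered) / r.initial if r.initial else 0.0
        )
        recovered = max(r.refined - r.filtered, 0)
        entry = {
            "slide_id": r.slide_id,
            "species": r.species,
            "initial": r.initial,
            "filtered": r.filtered,
            "refined": r.refined,
            "pct_removed": round(pct_removed, 1),
            "recovered": recovered,
        }
        table.append(entry)
        lines.append("\t".join(str(entry[k]) for k in header))
    return "\n".join(lines) + "\n", table


@dataclass
class DatasetManifest:
    """Reproducibility record written beside every assembled dataset."""

    slides: list[str]
    species: list[str]
    patch_size: int
    config: dict
    seed: int
    stage_counts: list[dict] = field(default_factory=list)
    creation_log: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(
            {"config": self.config, "seed": self.seed, "patch_size": self.patch_size},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["config_hash"] = self.config_hash
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
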