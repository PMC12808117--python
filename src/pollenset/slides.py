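"""Slide rasters, tiling geometry, and box arithmetic.

All coordinates in this package are 0-based and half-open: a box or tile
occupies columns ``[x_min, x_max)`` and rows ``[y_min, y_max)``, with ``x``
indexing columns and ``y`` indexing rows.  Conversions to other conventions
(e.g. COCO's ``[x, y, w, h]``) happen only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Box",
    "TileRect",
    "TilingConfig",
    "SlideImage",
    "tile_grid",
    "to_global",
    "to_local",
    "iou",
    "containment_fraction",
    "read_slide",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel units, half-open, positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"box must have positive area, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def corners(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def translate(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )


@dataclass(frozen=True)
class TileRect:
    """Integer tile rectangle ``[x, x+width) x [y, y+height)``."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("tile origin must be non-negative")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tile dimensions must be positive")

    def as_box(self) -> Box:
        return Box(self.x, self.y, self.x + self.width, self.y + self.height)

    def crop(self, raster: np.ndarray) -> np.ndarray:
        return raster[self.y : self.y + self.height, self.x : self.x + self.width]


@dataclass(frozen=True)
class TilingConfig:
    """Grid parameters: ``patch_size`` square tiles with optional ``overlap``.

    Non-overlapping grids (overlap 0) are used for training-set assembly;
    inference may use overlapping tiles to improve coverage at tile seams.
    """

    patch_size: int = 518
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not (0 <= self.overlap < self.patch_size):
            raise ValueError("overlap must satisfy 0 <= overlap < patch_size")

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap


@dataclass
class SlideImage:
    """A slide raster with optional pure-species metadata.

    ``species`` is set only for pure-species reference slides, where every
    grain on the slide shares one taxon; label inheritance requires it.
    """

    raster: np.ndarray
    slide_id: str
    species: Optional[str] = None
    microns_per_pixel: Optional[float] = None
    region_of_interest: Optional[TileRect] = None

    def __post_init__(self) -> None:
        if self.raster.ndim not in (2, 3):
            raise ValueError("slide raster must be 2-D gray or 3-D RGB")
        if self.raster.shape[0] < 1 or self.raster.shape[1] < 1:
            raise ValueError("slide raster must be non-empty")

    @property
    def height(self) -> int:
        return int(self.raster.shape[0])

    @property
    def width(self) -> int:
        return int(self.raster.shape[1])


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    """Origins along one axis: multiples of stride, tail anchored to the edge."""
    if dim <= patch:
        return [0]
    origins = list(range(0, dim - patch + 1, stride))
    tail = dim - patch
    if origins[-1] != tail:
        origins.append(tail)
    return origins


def tile_grid(width: int, height: int, config: TilingConfig) -> list[TileRect]:
    """Tile a ``width x height`` raster into a covering grid of TileRects.

    Origins sit at multiples of ``stride = patch_size - overlap``; the final
    row/column is anchored to the image edge so the union of tiles covers the
    raster exactly; anchored duplicates are removed.  Tiles on rasters smaller
    than the patch are clipped to the raster.  Row-major order.
    """
    if width < 1 or height < 1:
        raise ValueError("raster dimensions must be >= 1")
    patch, stride = config.patch_size, config.stride
    xs = _axis_origins(width, patch, stride)
    ys = _axis_origins(height, patch, stride)
    tiles = []
    for y in ys:
        for x in xs:
            tiles.append(
                TileRect(x, y, min(patch, width - x), min(patch, height - y))
            )
    return tiles


def to_global(box: Box, tile: TileRect) -> Box:
    """Map a tile-local box into slide coordinates."""
    return box.translate(tile.x, tile.y)


def to_local(box: Box, tile: TileRect) -> Box:
    """Map a slide-coordinate box into tile-local coordinates (exact inverse)."""
    return box.translate(-tile.x, -tile.y)


def _intersection_area(a: Box, b: Box) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    inter = _intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def containment_fraction(box: Box, rect: TileRect) -> float:
    """Fraction of ``box``'s area lying inside ``rect`` (in [0, 1])."""
    return _intersection_area(box, rect.as_box()) / box.area


def read_slide(
    path: str | Path,
    slide_id: Optional[str] = None,
    species: Optional[str] = None,
) -> SlideImage:
    """Load a plain raster (TIFF/PNG) as a SlideImage."""
    path = Path(path)
    raster = np.asarray(iio.imread(path))
    if raster.ndim == 3 and raster.shape[2] == 4:  # drop alpha
        raster = raster[:, :, :3]
    return SlideImage(
        raster=raster, slide_id=slide_id or path.stem, species=species
    )
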