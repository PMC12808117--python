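"""Extended depth-of-field fusion of z-stacks and photometric normalization.

Bright-field slide scanners capture each field at several focal depths; a
grain's equatorial optical section is sharp in one plane and blurred in the
others.  Fusion merges the stack into a single extended-focus raster by
keeping, at every position and scale, the transform coefficients of the
sharpest plane.  Two fusion backends are provided: the dual-tree complex
wavelet transform (shift-tolerant, directional; the default) and a classical
Laplacian pyramid baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from ._dtcwt import (
    DETAIL_KEYS,
    TREES,
    DtcwtPyramid,
    detail_magnitude,
    dtcwt_forward,
    dtcwt_inverse,
)

__all__ = [
    "ZStack",
    "FusionConfig",
    "focus_measure",
    "fuse_dtcwt",
    "fuse_laplacian",
    "match_histograms",
    "rmse",
    "read_zstack",
    "write_raster",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ZStack:
    """An ordered set of co-registered focal planes of one field.

    Slice order corresponds to monotone focal depth; all slices share
    height/width/channel count.  Values are 8-bit (0-255) rasters.
    """

    slices: list[np.ndarray]
    z_spacing_um: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a ZStack needs at least one slice")
        shape = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.shape != shape:
                raise ValueError(
                    f"slice {i} shape {s.shape} differs from slice 0 shape {shape}"
                )
        if self.z_spacing_um is not None and self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple:
        return self.slices[0].shape


@dataclass(frozen=True)
class FusionConfig:
    """Free parameters of DTCWT fusion.

    ``levels`` is the decomposition depth (grains spanning ~200 px need
    several octaves; default 4).  ``lowpass_rule`` combines the coarse
    residual bands: ``mean`` averages planes (smooth background, avoids
    blotching), ``max_energy`` follows the plane with the strongest coarse
    detail.  ``consistency_filter`` applies a 3x3 majority vote to each
    selection map to suppress impulse artifacts.
    """

    levels: int = 4
    lowpass_rule: Literal["mean", "max_energy"] = "mean"
    consistency_filter: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.lowpass_rule not in ("mean", "max_energy"):
            raise ValueError(f"unknown lowpass_rule {self.lowpass_rule!r}")


def _luminance(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image.astype(np.float64)
    return image.astype(np.float64) @ _LUMA


def focus_measure(image: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-pixel sharpness: local variance of the Laplacian response.

    Computed on luminance for RGB input; ``window`` is the odd side length of
    the local averaging window.  Constant regions score exactly zero.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(image.shape[0], image.shape[1]):
        raise ValueError("window larger than image")
    lap = ndimage.laplace(_luminance(image))
    mean = ndimage.uniform_filter(lap, size=window)
    mean_sq = ndimage.uniform_filter(lap * lap, size=window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def _majority_smooth(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """3x3 majority vote on an integer label map (ties -> lowest label)."""
    votes = np.stack(
        [
            ndimage.uniform_filter((labels == s).astype(np.float64), size=3)
            for s in range(n_labels)
        ]
    )
    return np.argmax(votes, axis=0)


def _check_stack(stack: ZStack) -> None:
    if len(stack) < 1:
        raise ValueError("empty stack")


def _fuse_dtcwt_channel(planes: list[np.ndarray], config: FusionConfig) -> np.ndarray:
    pyrs = [dtcwt_forward(p, config.levels) for p in planes]
    fused = DtcwtPyramid(
        shape=pyrs[0].shape,
        levels=config.levels,
        lowpass={},
        details=[{t: {} for t in TREES} for _ in range(config.levels)],
    )
    n = len(planes)
    coarse_sel = None
    for j in range(config.levels):
        for key in DETAIL_KEYS:
            mags = np.stack([detail_magnitude(p, j, key) for p in pyrs])
            sel = np.argmax(mags, axis=0)
            if config.consistency_filter and n > 1:
                sel = _majority_smooth(sel, n)
            if j == config.levels - 1:
                coarse_sel = sel  # reused by the max_energy lowpass rule
            for tree in TREES:
                stacked = np.stack([p.details[j][tree][key] for p in pyrs])
                fused.details[j][tree][key] = np.take_along_axis(
                    stacked, sel[None], axis=0
                )[0]
    for tree in TREES:
        lows = np.stack([p.lowpass[tree] for p in pyrs])
        if config.lowpass_rule == "mean" or n == 1:
            fused.lowpass[tree] = lows.mean(axis=0)
        else:  # max_energy: follow the plane selected in the coarsest band
            fused.lowpass[tree] = np.take_along_axis(lows, coarse_sel[None], axis=0)[0]
    return dtcwt_inverse(fused)


def fuse_dtcwt(stack: ZStack, config: FusionConfig = FusionConfig()) -> np.ndarray:
    """Fuse a z-stack into one extended-focus raster via the DTCWT.

    Every slice is decomposed to ``config.levels`` dual-tree levels; at each
    highpass coefficient the slice with maximal complex magnitude wins
    (optionally majority-smoothed per selection map); lowpass bands are
    combined by ``config.lowpass_rule``.  RGB is fused channel-wise to
    preserve stain color.  Output is clipped to [0, 255] uint8.
    """
    _check_stack(stack)
    shape = stack.shape
    if (1 << config.levels) > min(shape[0], shape[1]):
        raise ValueError("2**levels exceeds the smallest slice dimension")
    arrs = [s.astype(np.float64) for s in stack.slices]
    if arrs[0].ndim == 2:
        out = _fuse_dtcwt_channel(arrs, config)
    else:
        out = np.stack(
            [
                _fuse_dtcwt_channel([a[..., c] for a in arrs], config)
                for c in range(arrs[0].shape[-1])
            ],
            axis=-1,
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _reduce(image: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(image, sigma=1.0, mode="nearest")[::2, ::2]


def _expand(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    yi = np.clip(np.arange(shape[0]) / 2.0, 0, image.shape[0] - 1)
    xi = np.clip(np.arange(shape[1]) / 2.0, 0, image.shape[1] - 1)
    return ndimage.map_coordinates(
        image, np.meshgrid(yi, xi, indexing="ij"), order=1, mode="nearest"
    )


def _laplacian_pyramid(image: np.ndarray, levels: int):
    gauss = [image]
    for _ in range(levels):
        gauss.append(_reduce(gauss[-1]))
    laps = [
        gauss[j] - _expand(gauss[j + 1], gauss[j].shape) for j in range(levels)
    ]
    return laps, gauss[-1]


def _fuse_laplacian_channel(planes: list[np.ndarray], levels: int) -> np.ndarray:
    pyrs = [_laplacian_pyramid(p, levels) for p in planes]
    fused_laps = []
    for j in range(levels):
        stacked = np.stack([laps[j] for laps, _ in pyrs])
        sel = np.argmax(np.abs(stacked), axis=0)
        fused_laps.append(np.take_along_axis(stacked, sel[None], axis=0)[0])
    top = np.stack([top for _, top in pyrs]).mean(axis=0)
    out = top
    for j in range(levels - 1, -1, -1):
        out = fused_laps[j] + _expand(out, fused_laps[j].shape)
    return out


def fuse_laplacian(stack: ZStack, levels: int = 4) -> np.ndarray:
    """Laplacian-pyramid focus fusion baseline (max-absolute selection)."""
    _check_stack(stack)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if (1 << levels) > min(stack.shape[0], stack.shape[1]):
        raise ValueError("2**levels exceeds the smallest slice dimension")
    arrs = [s.astype(np.float64) for s in stack.slices]
    if arrs[0].ndim == 2:
        out = _fuse_laplacian_channel(arrs, levels)
    else:
        out = np.stack(
            [
                _fuse_laplacian_channel([a[..., c] for a in arrs], levels)
                for c in range(arrs[0].shape[-1])
            ],
            axis=-1,
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _midpoint_quantiles(channel: np.ndarray):
    values, counts = np.unique(channel, return_counts=True)
    cum = np.cumsum(counts)
    quantiles = (cum - 0.5 * counts) / channel.size
    return values.astype(np.float64), quantiles


def _match_channel(channel: np.ndarray, reference: np.ndarray) -> np.ndarray:
    src_vals, src_q = _midpoint_quantiles(channel)
    ref_vals, ref_q = _midpoint_quantiles(reference)
    mapped = np.interp(src_q, ref_q, ref_vals)
    lookup = dict(zip(src_vals.tolist(), mapped.tolist()))
    flat = np.array([lookup[v] for v in channel.ravel().tolist()])
    return flat.reshape(channel.shape)


def match_histograms(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-channel monotone CDF matching of ``image`` onto ``reference``.

    A mid-mass quantile convention is used (a pixel value's quantile is the
    mass strictly below it plus half its own mass), so a constant image maps
    to the reference's median-mass level and pure intensity offsets invert
    exactly.  Pixel rank order is preserved within each channel.  Intended as
    a light stain-normalization step between slides from different scanners.
    """
    if (image.ndim != reference.ndim) or (
        image.ndim == 3 and image.shape[-1] != reference.shape[-1]
    ):
        raise ValueError("image and reference must have the same channel count")
    if image.ndim == 2:
        out = _match_channel(image, reference)
    else:
        out = np.stack(
            [
                _match_channel(image[..., c], reference[..., c])
                for c in range(image.shape[-1])
            ],
            axis=-1,
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square intensity error between two equal-shaped rasters."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.sqrt(np.mean(d * d)))


def read_zstack(path: str | Path) -> ZStack:
    """Read a z-stack from a multi-page TIFF or a directory of plane images.

    Directory planes are ordered by filename; all planes must share shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no plane images found in {path}")
        return ZStack(slices=[np.asarray(iio.imread(f)) for f in files])
    data = tifffile.imread(path)
    if data.ndim == 2 or (data.ndim == 3 and data.shape[-1] in (3, 4)):
        return ZStack(slices=[data[..., :3] if data.ndim == 3 else data])
    return ZStack(slices=[data[i][..., :3] if data[i].ndim == 3 else data[i]
                          for i in range(data.shape[0])])


def write_raster(path: str | Path, raster: np.ndarray) -> None:
    """Write a raster as TIFF or PNG depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)
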