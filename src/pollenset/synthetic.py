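"""Deterministic synthetic slide generator with exact ground truth.

Pure-species reference slides of the kind the pipeline consumes are not
publicly deposited, so this module renders statistically similar stand-ins:
round, textured grains (~200 px diameter at 40x-like sampling) on a pale
background, with species-specific stain color and exine-like texture
(concentric ring modulation, speckle, darker aperture notches), unannotated
debris, per-grain focal depth, and a defocus z-stack with depth-dependent
Gaussian blur.  Every output is a pure function of (spec, seed): one
pseudo-random stream per scene, drawn from in documented order (background,
debris, then per grain: radius, color jitter, placement, texture, depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .dataset import AnnotationRecord, write_coco
from .imaging import ZStack, write_raster
from .oneshot import Exemplar
from .slides import Box, SlideImage, iou

__all__ = [
    "SpeciesAppearance",
    "SceneSpec",
    "GrainInstance",
    "SyntheticSlide",
    "render_grain",
    "render_scene",
    "defocus_stack",
    "make_fixture",
    "FixtureSet",
]


@dataclass(frozen=True)
class SpeciesAppearance:
    """Procedural appearance parameters of one taxon.

    ``radius_px`` spans 80-120 by default, i.e. ~200 px grain diameter;
    ``ring_count`` / ``speckle_density`` / ``aperture_count`` shape the
    exine-like texture; colors are 8-bit RGB.
    """

    name: str
    radius_px: tuple[int, int] = (80, 120)
    base_rgb: tuple[float, float, float] = (188, 96, 130)
    rgb_jitter_sd: float = 6.0
    ring_count: int = 4
    speckle_density: float = 0.08
    aperture_count: int = 3

    def __post_init__(self) -> None:
        if self.radius_px[1] < self.radius_px[0] or self.radius_px[0] < 3:
            raise ValueError("radius_px must satisfy 3 <= min <= max")
        if any(not (0 <= c <= 255) for c in self.base_rgb):
            raise ValueError("base_rgb channels must lie in [0, 255]")
        if not (0.0 <= self.speckle_density <= 1.0):
            raise ValueError("speckle_density must lie in [0, 1]")
        if not (0 <= self.aperture_count <= 4):
            raise ValueError("aperture_count must lie in 0..4")


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of one synthetic slide scene."""

    canvas: tuple[int, int] = (1554, 1554)  # (width, height)
    species_mix: tuple[tuple[SpeciesAppearance, int], ...] = ()
    max_pair_iou: float = 0.0
    debris_count: int = 0
    background_rgb: tuple[float, float, float] = (232, 226, 218)
    noise_sd: float = 3.0
    z_planes: int = 3
    depth_assignment: Optional[tuple[float, ...]] = None
    blur_sigma_per_plane: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        if self.blur_sigma_per_plane < 0:
            raise ValueError("blur_sigma_per_plane must be >= 0")
        if any(count < 0 for _, count in self.species_mix):
            raise ValueError("species counts must be >= 0")


@dataclass
class GrainInstance:
    """One rendered grain: sprite, alpha support, placement, and depth."""

    sprite: np.ndarray
    alpha: np.ndarray
    x0: int
    y0: int
    depth: float
    species: str

    @property
    def box(self) -> Box:
        ys, xs = np.nonzero(self.alpha > 0)
        return Box(
            x_min=float(self.x0 + xs.min()),
            y_min=float(self.y0 + ys.min()),
            x_max=float(self.x0 + xs.max() + 1),
            y_max=float(self.y0 + ys.max() + 1),
        )


@dataclass
class SyntheticSlide:
    """Rendered scene: all-in-focus reference, z-stack, and ground truth."""

    slide_id: str
    reference: np.ndarray
    background: np.ndarray  # reference minus grains (incl. debris + noise)
    grains: list[GrainInstance]
    gts: list[AnnotationRecord]
    stack: Optional[ZStack] = None
    species: Optional[str] = None

    @property
    def depths(self) -> list[float]:
        return [g.depth for g in self.grains]

    def as_slide_image(self, use_stack_fusion: Optional[np.ndarray] = None) -> SlideImage:
        raster = self.reference if use_stack_fusion is None else use_stack_fusion
        return SlideImage(raster=raster, slide_id=self.slide_id, species=self.species)


def render_grain(
    appearance: SpeciesAppearance, radius: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one procedural grain sprite and its alpha support mask.

    The sprite is a filled disk with concentric ring modulation, a darker
    exine rim, multiplicative speckle, and up to four darker circular
    aperture notches; color is the species base plus one per-grain jitter
    draw.  Deterministic for a fixed rng state.
    """
    side = 2 * radius + 3
    c = radius + 1
    yy, xx = np.mgrid[0:side, 0:side]
    dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    alpha = dist <= radius

    color = np.asarray(appearance.base_rgb, dtype=np.float64) + rng.normal(
        0.0, appearance.rgb_jitter_sd, size=3
    )
    factor = 1.0 + 0.12 * np.cos(
        2.0 * np.pi * appearance.ring_count * dist / max(radius, 1)
    )
    factor *= 1.0 - 0.30 * np.exp(-np.maximum(radius - dist, 0.0) / 4.0)  # rim
    speckle = rng.random(size=(side, side)) < appearance.speckle_density
    factor = np.where(speckle, factor * 0.72, factor)
    for _ in range(appearance.aperture_count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ar = 0.62 * radius
        ay, ax = c + ar * np.sin(ang), c + ar * np.cos(ang)
        ad = np.sqrt((yy - ay) ** 2 + (xx - ax) ** 2)
        factor = np.where(ad <= 0.18 * radius, factor * 0.55, factor)
    sprite = np.clip(color[None, None, :] * factor[..., None], 0, 255)
    sprite = np.where(alpha[..., None], sprite, 0.0)
    return sprite, alpha.astype(np.float64)


def _render_debris(canvas: np.ndarray, rng: np.random.Generator) -> None:
    """Paint one unannotated debris object (gray-brown blob or fiber) in place."""
    h, w = canvas.shape[:2]
    kind = rng.random()
    color = np.array([120.0, 108.0, 92.0]) + rng.normal(0, 12, size=3)
    if kind < 0.5:  # irregular blob
        r = int(rng.integers(12, 35))
        cy, cx = int(rng.integers(r, h - r)), int(rng.integers(r, w - r))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        wobble = 1.0 + 0.35 * np.sin(3.0 * np.arctan2(yy, xx) + rng.uniform(0, 6.28))
        mask = np.sqrt(yy**2 + xx**2) <= r * 0.8 * wobble
        patch = canvas[cy - r : cy + r + 1, cx - r : cx + r + 1]
        patch[mask] = np.clip(color, 0, 255)
    else:  # fiber: random walk polyline
        n = int(rng.integers(60, 160))
        y, x = rng.uniform(10, h - 10), rng.uniform(10, w - 10)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(n):
            ang += rng.normal(0, 0.25)
            y = float(np.clip(y + 2.0 * np.sin(ang), 1, h - 2))
            x = float(np.clip(x + 2.0 * np.cos(ang), 1, w - 2))
            canvas[int(y) - 1 : int(y) + 2, int(x) - 1 : int(x) + 2] = np.clip(
                color, 0, 255
            )


def render_scene(spec: SceneSpec, slide_id: str = "synthetic") -> SyntheticSlide:
    """Render a full scene: background, debris, grains, and tight ground truth.

    Grain placement uses rejection sampling honoring ``max_pair_iou`` between
    ground-truth boxes (1000 attempts per grain, then an error naming the
    grain index).  Debris is never annotated.  The all-in-focus reference and
    the grain-free background composite are both returned; the z-stack is
    produced separately by :func:`defocus_stack`.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.canvas
    background = np.clip(
        np.asarray(spec.background_rgb)[None, None, :]
        + rng.normal(0.0, spec.noise_sd, size=(h, w, 3)),
        0,
        255,
    )
    for _ in range(spec.debris_count):
        _render_debris(background, rng)

    grains: list[GrainInstance] = []
    boxes: list[Box] = []
    species_names = [app.name for app, _ in spec.species_mix]
    pure_species = species_names[0] if len(set(species_names)) == 1 else None
    grain_index = 0
    depths = spec.depth_assignment
    for app, count in spec.species_mix:
        for _ in range(count):
            radius = int(rng.integers(app.radius_px[0], app.radius_px[1] + 1))
            sprite, alpha = render_grain(app, radius, rng)
            side = sprite.shape[0]
            if side > min(w, h):
                raise ValueError(
                    f"grain {grain_index}: sprite side {side} exceeds canvas"
                )
            placed = False
            for _attempt in range(1000):
                x0 = int(rng.integers(0, w - side + 1))
                y0 = int(rng.integers(0, h - side + 1))
                cand = GrainInstance(sprite, alpha, x0, y0, 0.0, app.name)
                cand_box = cand.box
                if all(iou(cand_box, b) <= spec.max_pair_iou for b in boxes):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place grain {grain_index} after 1000 attempts "
                    f"(canvas too small for the requested mix)"
                )
            if depths is not None:
                depth = float(depths[grain_index])
            else:
                depth = float(rng.integers(0, spec.z_planes))
            grain = GrainInstance(sprite, alpha, x0, y0, depth, app.name)
            grains.append(grain)
            boxes.append(grain.box)
            grain_index += 1

    reference = background.copy()
    for g in grains:
        region = reference[g.y0 : g.y0 + g.sprite.shape[0], g.x0 : g.x0 + g.sprite.shape[1]]
        a = g.alpha[..., None]
        region[:] = a * g.sprite + (1.0 - a) * region
    reference = np.clip(np.rint(reference), 0, 255).astype(np.uint8)
    background = np.clip(np.rint(background), 0, 255).astype(np.uint8)

    gts = [
        AnnotationRecord(
            slide_id=slide_id,
            box=g.box,
            species=g.species,
            stage="ground_truth",
            score=1.0,
            detector_id="synthetic",
        )
        for g in grains
    ]
    return SyntheticSlide(
        slide_id=slide_id,
        reference=reference,
        background=background,
        grains=grains,
        gts=gts,
        species=pure_species,
    )


def defocus_stack(slide: SyntheticSlide, spec: SceneSpec) -> ZStack:
    """Synthesize the z-stack for a rendered scene.

    Plane ``p`` composites each grain blurred with Gaussian sigma =
    ``blur_sigma_per_plane * |depth - p|`` over the background blurred with
    ``blur_sigma_per_plane * 0.5 * |p - depth_bg|``, where ``depth_bg`` is
    the mean grain depth (the adhesive surface the grains sit on).  Each
    grain is therefore sharpest at the plane nearest its depth, exactly.
    """
    sigma = spec.blur_sigma_per_plane
    depth_bg = float(np.mean(slide.depths)) if slide.grains else 0.5 * (spec.z_planes - 1)
    planes = []
    for p in range(spec.z_planes):
        s_bg = sigma * 0.5 * abs(p - depth_bg)
        base = slide.background.astype(np.float64)
        if s_bg > 0:
            base = ndimage.gaussian_filter(base, sigma=(s_bg, s_bg, 0))
        for g in slide.grains:
            s_g = sigma * abs(g.depth - p)
            sprite, alpha = g.sprite, g.alpha
            if s_g > 0:
                sprite = ndimage.gaussian_filter(sprite, sigma=(s_g, s_g, 0))
                alpha = ndimage.gaussian_filter(alpha, sigma=s_g)
            region = base[
                g.y0 : g.y0 + sprite.shape[0], g.x0 : g.x0 + sprite.shape[1]
            ]
            a = alpha[..., None]
            region[:] = a * sprite + (1.0 - a) * region
        planes.append(np.clip(np.rint(base), 0, 255).astype(np.uint8))
    stack = ZStack(slices=planes)
    slide.stack = stack
    return stack


_EASY_SPECIES = (
    SpeciesAppearance(name="ambrosia", base_rgb=(188, 96, 130), ring_count=4,
                      aperture_count=3, speckle_density=0.06),
    SpeciesAppearance(name="betula", base_rgb=(172, 138, 88), ring_count=6,
                      aperture_count=2, speckle_density=0.10),
)


@dataclass
class FixtureSet:
    """A bundle of synthetic slides, exemplars, and specs for pipeline runs."""

    preset: str
    seed: int
    pure_slides: list[SyntheticSlide]
    mixed_slide: SyntheticSlide
    exemplars: dict[str, Exemplar]
    specs: dict[str, SceneSpec]

    def all_gts(self) -> list[AnnotationRecord]:
        gts = []
        for s in self.pure_slides:
            gts.extend(s.gts)
        gts.extend(self.mixed_slide.gts)
        return gts

    def write(self, outdir: str | Path) -> None:
        """Write references, z-stack planes, exemplars, and COCO ground truth."""
        outdir = Path(outdir)
        (outdir / "slides").mkdir(parents=True, exist_ok=True)
        (outdir / "exemplars").mkdir(exist_ok=True)
        (outdir / "annotations").mkdir(exist_ok=True)
        slides = []
        for s in self.pure_slides + [self.mixed_slide]:
            write_raster(outdir / "slides" / f"{s.slide_id}.png", s.reference)
            if s.stack is not None:
                import tifffile

                tifffile.imwrite(
                    outdir / "slides" / f"{s.slide_id}_stack.tif",
                    np.stack(s.stack.slices),
                )
            slides.append(s.as_slide_image())
        for name, ex in self.exemplars.items():
            write_raster(outdir / "exemplars" / f"{name}.png", ex.crop)
        write_coco(self.all_gts(), slides, outdir / "annotations" / "ground_truth.json")


def _cut_exemplar(app: SpeciesAppearance, spec: SceneSpec, seed: int) -> Exemplar:
    """Render a held-out grain on background and crop it as the exemplar."""
    ex_spec = replace(
        spec,
        canvas=(2 * app.radius_px[1] + 40, 2 * app.radius_px[1] + 40),
        species_mix=((app, 1),),
        debris_count=0,
        seed=seed,
    )
    scene = render_scene(ex_spec, slide_id=f"exemplar_{app.name}")
    b = scene.gts[0].box
    pad = 4
    x0, y0 = max(int(b.x_min) - pad, 0), max(int(b.y_min) - pad, 0)
    x1 = min(int(b.x_max) + pad, scene.reference.shape[1])
    y1 = min(int(b.y_max) + pad, scene.reference.shape[0])
    crop = scene.reference[y0:y1, x0:x1]
    return Exemplar(crop=crop, species=app.name, exemplar_id=f"{app.name}-exemplar")


def make_fixture(
    preset: Literal["easy", "hard"] = "easy",
    seed: int = 0,
    grains_per_species: int = 12,
    with_stacks: bool = True,
) -> FixtureSet:
    """Build the standard two-species benchmark fixture.

    ``easy``: well-separated grains, no debris, mild noise.  ``hard``:
    box overlaps up to IoU 0.2, debris, stronger noise, and a stain shift
    between slides (emulating cross-region domain shifts).  Deterministic
    for fixed (preset, seed).
    """
    if preset not in ("easy", "hard"):
        raise ValueError(f"unknown preset {preset!r}")
    hard = preset == "hard"
    species = _EASY_SPECIES
    if hard:
        species = tuple(
            replace(app, rgb_jitter_sd=10.0, speckle_density=app.speckle_density + 0.05)
            for app in species
        )
    base = SceneSpec(
        canvas=(1554, 1554),
        max_pair_iou=0.2 if hard else 0.0,
        debris_count=6 if hard else 0,
        noise_sd=6.0 if hard else 3.0,
        z_planes=3,
        blur_sigma_per_plane=3.0,
    )
    pure_slides = []
    specs: dict[str, SceneSpec] = {}
    for i, app in enumerate(species):
        if hard and i == 1:  # stain shift between slides
            app = replace(
                app,
                base_rgb=tuple(np.clip(np.asarray(app.base_rgb) + (12, -8, 6), 0, 255)),
            )
        spec = replace(
            base, species_mix=((app, grains_per_species),), seed=seed * 101 + i
        )
        slide = render_scene(spec, slide_id=f"{preset}_{app.name}")
        if with_stacks:
            defocus_stack(slide, spec)
        pure_slides.append(slide)
        specs[slide.slide_id] = spec
    mixed_spec = replace(
        base,
        species_mix=tuple((app, max(grains_per_species // 2, 1)) for app in species),
        seed=seed * 101 + 7,
    )
    mixed = render_scene(mixed_spec, slide_id=f"{preset}_mixed")
    if with_stacks:
        defocus_stack(mixed, mixed_spec)
    specs[mixed.slide_id] = mixed_spec
    exemplars = {
        app.name: _cut_exemplar(app, base, seed * 101 + 50 + i)
        for i, app in enumerate(species)
    }
    return FixtureSet(
        preset=preset,
        seed=seed,
        pure_slides=pure_slides,
        mixed_slide=mixed,
        exemplars=exemplars,
        specs=specs,
    )
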