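"""RGB statistical filtering, box tightening, and missed-grain recovery."""

import dataclasses

import numpy as np
import pytest

from pollenset.oneshot import Detection, DetectorConfig, Exemplar
from pollenset.refine import (
    FilterConfig,
    RefineConfig,
    box_mean_rgb,
    refine_annotations,
    rescan_recover,
    rgb_outlier_filter,
    tighten_box,
)
from pollenset.slides import Box, SlideImage, TilingConfig, iou
from pollenset.synthetic import SceneSpec, SpeciesAppearance, render_scene


def det(x0, y0, x1, y1, score=0.9):
    return Detection(box=Box(x0, y0, x1, y1), score=score, label="x")


class TestBoxMeanRgb:
    def test_uniform_region(self):
        img = np.zeros((50, 50, 3), np.uint8)
        img[10:30, 10:30] = (200, 30, 30)
        assert np.allclose(box_mean_rgb(img, Box(10, 10, 30, 30)), (200, 30, 30))

    def test_half_black_half_white(self):
        img = np.zeros((20, 40, 3), np.uint8)
        img[:, 20:] = 255
        assert np.allclose(box_mean_rgb(img, Box(0, 0, 40, 20)), 127.5)

    def test_overhanging_box_uses_clipped_region_only(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(30, 30, 3)).astype(np.uint8)
        overhang = box_mean_rgb(img, Box(20, 20, 50, 50))
        manual = img[20:, 20:].reshape(-1, 3).mean(axis=0)
        assert np.allclose(overhang, manual)

    def test_disjoint_box_rejected(self):
        with pytest.raises(ValueError):
            box_mean_rgb(np.zeros((10, 10, 3), np.uint8), Box(50, 50, 60, 60))


def brute_force_filter(colors, k):
    """Independent 1-sigma rule: distances to the mean color, population sd."""
    colors = np.asarray(colors, dtype=float)
    mu = colors.mean(axis=0)
    d = np.sqrt(((colors - mu) ** 2).sum(axis=1))
    sigma = np.sqrt(((d - d.mean()) ** 2).mean())
    return d, sigma, [i for i in range(len(d)) if d[i] > k * sigma]


class TestRgbOutlierFilter:
    def make_colored_boxes(self, colors):
        img = np.zeros((60, 40 * len(colors), 3), np.uint8)
        dets = []
        for i, c in enumerate(colors):
            x = 40 * i
            img[10:50, x + 5 : x + 35] = c
            dets.append(det(x + 5, 10, x + 35, 50))
        return img, dets

    def test_identical_colors_remove_nothing(self):
        img, dets = self.make_colored_boxes([(120, 80, 60)] * 6)
        res = rgb_outlier_filter(dets, img, FilterConfig(sigma_mode="distance"))
        assert res.sigma == 0.0
        assert len(res.removed) == 0 and len(res.kept) == 6

    @pytest.mark.parametrize("mode", ["distance", "channel"])
    def test_planted_outlier_is_the_only_removal(self, mode):
        colors = [(200, 50, 50)] * 19 + [(50, 200, 50)]
        img, dets = self.make_colored_boxes(colors)
        res = rgb_outlier_filter(dets, img, FilterConfig(k=1.0, sigma_mode=mode))
        assert len(res.removed) == 1
        assert res.removed[0] == dets[19]
        assert len(res.kept) == 19

    def test_distances_and_sigma_match_brute_force_oracle(self):
        colors = [(200, 50, 50)] * 19 + [(50, 200, 50)]
        img, dets = self.make_colored_boxes(colors)
        res = rgb_outlier_filter(dets, img, FilterConfig(k=1.0, sigma_mode="distance"))
        d, sigma, removed_idx = brute_force_filter(colors, k=1.0)
        assert np.allclose(res.distances, d, atol=1e-9)
        assert res.sigma == pytest.approx(sigma, abs=1e-9)
        assert removed_idx == [19]

    def test_huge_k_removes_nothing(self):
        colors = [(200, 50, 50)] * 10 + [(50, 200, 50)] * 5
        img, dets = self.make_colored_boxes(colors)
        res = rgb_outlier_filter(dets, img, FilterConfig(k=1e6))
        assert res.removed == []

    def test_partition_is_exact(self):
        rng = np.random.default_rng(11)
        colors = [tuple(rng.integers(0, 255, 3)) for _ in range(12)]
        img, dets = self.make_colored_boxes(colors)
        res = rgb_outlier_filter(dets, img)
        assert len(res.kept) + len(res.removed) == len(dets)
        kept_boxes = {d.box for d in res.kept}
        removed_boxes = {d.box for d in res.removed}
        assert kept_boxes.isdisjoint(removed_boxes)
        assert kept_boxes | removed_boxes == {d.box for d in dets}

    def test_intensity_shift_equivariance(self):
        colors = [(90, 60, 120)] * 8 + [(30, 180, 40)] * 2
        img, dets = self.make_colored_boxes(colors)
        shifted = np.clip(img.astype(int) + 17, 0, 255).astype(np.uint8)
        res_a = rgb_outlier_filter(dets, img)
        res_b = rgb_outlier_filter(dets, shifted)
        assert np.allclose(res_a.distances, res_b.distances, atol=1e-9)
        assert [d.box for d in res_a.kept] == [d.box for d in res_b.kept]

    def test_below_min_boxes_skips_filtering(self):
        img, dets = self.make_colored_boxes([(200, 50, 50), (50, 200, 50)])
        res = rgb_outlier_filter(dets, img, FilterConfig(min_boxes=3))
        assert len(res.kept) == 2 and res.sigma == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rgb_outlier_filter([], np.zeros((10, 10, 3), np.uint8))


def disk_image(radius=40, center=(100, 100), size=(200, 200)):
    img = np.full((*size, 3), 230, np.uint8)
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[mask] = (150, 60, 90)
    return img, mask


class TestTightenBox:
    def test_loose_box_shrinks_to_disk_extent(self):
        img, mask = disk_image()
        ys, xs = np.nonzero(mask)
        loose = Box(xs.min() - 30, ys.min() - 30, xs.max() + 31, ys.max() + 31)
        tight = tighten_box(img, loose)
        assert abs(tight.x_min - xs.min()) <= 2
        assert abs(tight.y_min - ys.min()) <= 2
        assert abs(tight.x_max - (xs.max() + 1)) <= 2
        assert abs(tight.y_max - (ys.max() + 1)) <= 2

    def test_already_tight_box_stable(self):
        img, mask = disk_image()
        ys, xs = np.nonzero(mask)
        tight_in = Box(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        out = tighten_box(img, tight_in)
        for got, want in zip(out.corners(), tight_in.corners()):
            assert abs(got - want) <= 2

    def test_pure_background_box_unchanged(self):
        img = np.full((120, 120, 3), 228, np.uint8)
        box = Box(20, 20, 70, 70)
        assert tighten_box(img, box) == box

    def test_result_within_expanded_box(self):
        img, _ = disk_image()
        box = Box(55, 55, 150, 150)
        cfg = RefineConfig(expand_factor=1.5)
        out = tighten_box(img, box, cfg)
        cx, cy = box.center
        assert out.x_min >= cx - 0.75 * box.width - 1
        assert out.x_max <= cx + 0.75 * box.width + 1
        assert out.y_min >= cy - 0.75 * box.height - 1
        assert out.y_max <= cy + 0.75 * box.height + 1


@pytest.fixture(scope="module")
def ten_grain_scene():
    app = SpeciesAppearance(name="sp", radius_px=(40, 40))
    spec = SceneSpec(canvas=(900, 900), species_mix=((app, 10),), noise_sd=2.0, seed=21)
    scene = render_scene(spec, slide_id="ten")
    ex_spec = dataclasses.replace(spec, canvas=(120, 120), species_mix=((app, 1),), seed=5)
    exs = render_scene(ex_spec)
    b = exs.gts[0].box
    crop = exs.reference[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)]
    return scene, Exemplar(crop=crop, species="sp")


class TestRescanRecover:
    def test_recovers_missed_grains(self, ten_grain_scene):
        scene, exemplar = ten_grain_scene
        slide = scene.as_slide_image()
        kept = [
            Detection(box=g.box, score=0.95, label="sp", stage="filtered")
            for g in scene.gts[:8]
        ]
        rec = rescan_recover(slide, exemplar, kept, TilingConfig(518, 259))
        missed = scene.gts[8:]
        assert any(
            max(iou(r.box, m.box) for m in missed) >= 0.5 for r in rec
        )
        assert all(r.stage == "refined" for r in rec)

    def test_everything_kept_means_empty_recovery(self, ten_grain_scene):
        scene, exemplar = ten_grain_scene
        slide = scene.as_slide_image()
        kept = [
            Detection(box=g.box, score=0.95, label="sp", stage="filtered")
            for g in scene.gts
        ]
        rec = rescan_recover(
            slide, exemplar, kept, TilingConfig(518, 259),
            refine_config=RefineConfig(relaxed_threshold=0.8),
        )
        assert rec == []

    def test_recovered_disjoint_from_kept(self, ten_grain_scene):
        scene, exemplar = ten_grain_scene
        slide = scene.as_slide_image()
        kept = [
            Detection(box=g.box, score=0.95, label="sp", stage="filtered")
            for g in scene.gts[:5]
        ]
        cfg = RefineConfig(recover_max_iou=0.3)
        for r in rescan_recover(slide, exemplar, kept, TilingConfig(518, 259), refine_config=cfg):
            assert all(iou(r.box, k.box) < cfg.recover_max_iou for k in kept)


class TestRefineAnnotations:
    def test_empty_initial_gives_zero_counts(self, ten_grain_scene):
        scene, exemplar = ten_grain_scene
        refined, counts, fres = refine_annotations(
            scene.as_slide_image(), [], exemplar
        )
        assert refined == [] and (counts.initial, counts.filtered, counts.refined) == (0, 0, 0)
        assert fres is None

    def test_identity_refiner_returns_filtered_set(self, ten_grain_scene):
        scene, exemplar = ten_grain_scene

        class IdentityRefiner:
            def refine(self, slide, filtered, exemplar, config):
                return [dataclasses.replace(d, stage="refined") for d in filtered]

        initial = [
            Detection(box=g.box, score=0.9, label="sp") for g in scene.gts
        ]
        refined, counts, _ = refine_annotations(
            scene.as_slide_image(), initial, exemplar, refiner=IdentityRefiner()
        )
        assert counts.refined == counts.filtered == len(refined)

    def test_stage_pattern_filtered_le_initial_le_refined_possible(self, ten_grain_scene):
        # planted color outliers are filtered out; recovery may add grains
        # back, so refined >= filtered is the expected pattern
        scene, exemplar = ten_grain_scene
        slide = scene.as_slide_image()
        outlier = Detection(box=Box(5, 5, 60, 60), score=0.85, label="sp")
        initial = [
            Detection(box=g.box, score=0.9, label="sp") for g in scene.gts[:8]
        ] + [outlier]
        refined, counts, fres = refine_annotations(
            slide, initial, exemplar, tiling=TilingConfig(518, 259)
        )
        assert counts.filtered <= counts.initial
        assert counts.refined >= counts.filtered
        assert all(d.stage == "refined" for d in refined)
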