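"""Detection metrics vs an independent brute-force precision-recall oracle."""

import numpy as np
import pytest

from pollenset.dataset import AnnotationRecord
from pollenset.evaluation import (
    EvalConfig,
    average_precision,
    average_recall,
    confusion_matrix,
    evaluate,
    filter_gt_by_containment,
    fold_mean_stderr,
    match_detections,
)
from pollenset.slides import Box, TileRect, TilingConfig, tile_grid


def rec(x0, y0, x1, y1, species="a", score=1.0, slide="s1", stage="refined"):
    return AnnotationRecord(
        slide_id=slide, box=Box(x0, y0, x1, y1), species=species,
        stage=stage, score=score,
    )


def gt(x0, y0, x1, y1, species="a", slide="s1"):
    return rec(x0, y0, x1, y1, species, 1.0, slide, stage="ground_truth")


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate score thresholds, apply the matching
# definition directly at each, and integrate the precision envelope.
# ---------------------------------------------------------------------------

def _oracle_greedy_match(dets, gts, iou_thr):
    """Direct transcription of the matching definition."""

    def _iou(a, b):
        w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
        h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
        if w <= 0 or h <= 0:
            return 0.0
        inter = w * h
        return inter / (
            (a.x_max - a.x_min) * (a.y_max - a.y_min)
            + (b.x_max - b.x_min) * (b.y_max - b.y_min)
            - inter
        )

    gts = sorted(gts, key=lambda r: (r.slide_id, r.box.x_min, r.box.y_min,
                                     r.box.x_max, r.box.y_max, r.species))
    taken = set()
    n_tp = 0
    for d in sorted(dets, key=lambda r: (-r.score, r.slide_id, r.box.x_min,
                                         r.box.y_min, r.box.x_max, r.box.y_max)):
        best, best_v = None, 0.0
        for j, g in enumerate(gts):
            if j in taken or g.slide_id != d.slide_id:
                continue
            v = _iou(d.box, g.box)
            if v >= iou_thr and v > best_v:
                best, best_v = j, v
        if best is not None:
            taken.add(best)
            n_tp += 1
    return n_tp


def oracle_ap(dets, gts, iou_thr):
    if len(gts) == 0:
        return None if len(dets) == 0 else 0.0
    if len(dets) == 0:
        return 0.0
    points = []  # (recall, precision) at every distinct score threshold
    for t in sorted({d.score for d in dets}, reverse=True):
        subset = [d for d in dets if d.score >= t]
        n_tp = _oracle_greedy_match(subset, gts, iou_thr)
        points.append((n_tp / len(gts), n_tp / len(subset)))
    grid = np.arange(101) / 100.0
    sampled = []
    for r in grid:
        ps = [p for (rr, p) in points if rr >= r - 1e-12]
        sampled.append(max(ps) if ps else 0.0)
    return float(np.mean(sampled))


def oracle_ar(dets, gts, iou_thrs, cap):
    if len(gts) == 0:
        return None
    per_image = {}
    for d in sorted(dets, key=lambda r: (-r.score, r.slide_id, r.box.x_min,
                                         r.box.y_min, r.box.x_max, r.box.y_max)):
        per_image.setdefault(d.slide_id, [])
        if len(per_image[d.slide_id]) < cap:
            per_image[d.slide_id].append(d)
    capped = [d for ds in per_image.values() for d in ds]
    recalls = [
        _oracle_greedy_match(capped, gts, t) / len(gts) for t in iou_thrs
    ]
    return float(np.mean(recalls))


def random_instance(rng, slide="s1"):
    n_gt = int(rng.integers(0, 9))
    n_det = int(rng.integers(0, 9))
    gts = []
    for _ in range(n_gt):
        x, y = rng.uniform(0, 80, 2)
        w, h = rng.uniform(5, 30, 2)
        gts.append(gt(x, y, x + w, y + h, slide=slide))
    scores = rng.permutation(np.linspace(0.05, 0.99, 40))[:n_det]
    dets = []
    for s in scores:
        if gts and rng.random() < 0.7:  # perturb a gt box
            g = gts[int(rng.integers(0, len(gts)))]
            dx, dy = rng.uniform(-8, 8, 2)
            dets.append(
                rec(g.box.x_min + dx, g.box.y_min + dy,
                    g.box.x_max + dx, g.box.y_max + dy,
                    score=float(s), slide=slide)
            )
        else:
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 30, 2)
            dets.append(rec(x, y, x + w, y + h, score=float(s), slide=slide))
    return dets, gts


class TestMatching:
    def test_good_overlap_is_tp(self):
        m = match_detections([rec(0, 0, 10, 10, score=0.9)], [gt(0, 3, 10, 13)], 0.5)
        assert m.det_match == [0] and m.gt_matched == [True]

    def test_poor_overlap_is_fp_and_missed_gt(self):
        m = match_detections([rec(0, 0, 10, 10, score=0.9)], [gt(0, 6, 10, 16)], 0.5)
        assert m.det_match == [None] and m.gt_matched == [False]

    def test_one_gt_claims_only_best_scoring_detection(self):
        dets = [rec(0, 0, 10, 10, score=0.9), rec(0, 1, 10, 11, score=0.8)]
        m = match_detections(dets, [gt(0, 0, 10, 10)], 0.5)
        assert m.det_match[0] == 0 and m.det_match[1] is None


class TestAveragePrecision:
    def test_perfect_detection(self):
        gts = [gt(0, 0, 10, 10), gt(50, 50, 70, 70)]
        dets = [rec(0, 0, 10, 10, score=0.9), rec(50, 50, 70, 70, score=0.8)]
        assert average_precision(dets, gts, 0.5) == 1.0

    def test_no_detections(self):
        assert average_precision([], [gt(0, 0, 10, 10)], 0.5) == 0.0

    def test_no_gt_with_detections_scores_zero(self):
        assert average_precision([rec(0, 0, 10, 10, score=0.9)], [], 0.5) == 0.0

    def test_empty_vs_empty_is_undefined(self):
        assert average_precision([], [], 0.5) is None

    def test_worked_case_high_scoring_fp_halves_ap(self):
        # FP at score 0.9, TP at 0.8 on the single gt: the precision
        # envelope at recall 1 is 1/2, so 101-point AP = 0.5
        gts = [gt(0, 0, 10, 10)]
        dets = [rec(50, 50, 60, 60, score=0.9), rec(0, 0, 10, 10, score=0.8)]
        ap = average_precision(dets, gts, 0.5)
        assert ap == pytest.approx(0.5, abs=1e-12)
        assert ap == pytest.approx(oracle_ap(dets, gts, 0.5), abs=1e-12)


class TestAverageRecall:
    def test_all_matched(self):
        gts = [gt(0, 0, 10, 10), gt(50, 50, 70, 70)]
        dets = [rec(0, 0, 10, 10, score=0.9), rec(50, 50, 70, 70, score=0.8)]
        assert average_recall(dets, gts, 0.5) == 1.0

    def test_three_of_four(self):
        gts = [gt(100 * i, 0, 100 * i + 10, 10) for i in range(4)]
        dets = [
            rec(100 * i, 0, 100 * i + 10, 10, score=0.9 - 0.1 * i) for i in range(3)
        ]
        assert average_recall(dets, gts, 0.5) == 0.75

    def test_detection_cap_applied_before_matching(self):
        gts = [gt(0, 0, 10, 10), gt(50, 50, 70, 70)]
        dets = [rec(0, 0, 10, 10, score=0.9), rec(50, 50, 70, 70, score=0.8)]
        assert average_recall(dets, gts, 0.5, max_detections=1) == 0.5


class TestOracleEquivalence:
    def test_ap_and_ar_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        thresholds = np.round(np.arange(0.50, 0.96, 0.05), 2)
        checked = 0
        for _ in range(200):
            dets, gts = random_instance(rng)
            for t in thresholds:
                got_ap = average_precision(dets, gts, t, class_aware=False)
                want_ap = oracle_ap(dets, gts, t)
                if want_ap is None:
                    assert got_ap is None
                else:
                    assert got_ap == pytest.approx(want_ap, abs=1e-9)
            got_ar = average_recall(dets, gts, thresholds, 100, class_aware=False)
            want_ar = oracle_ar(dets, gts, thresholds, 100)
            if want_ar is None:
                assert got_ar is None
            else:
                assert got_ar == pytest.approx(want_ar, abs=1e-9)
            checked += 1
        assert checked == 200

    def test_monotone_in_iou_threshold(self):
        rng = np.random.default_rng(42)
        thresholds = np.round(np.arange(0.50, 0.96, 0.05), 2)
        for _ in range(20):
            dets, gts = random_instance(rng)
            if not gts:
                continue
            aps = [average_precision(dets, gts, t, class_aware=False) for t in thresholds]
            ars = [average_recall(dets, gts, t, class_aware=False) for t in thresholds]
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(ars, ars[1:]))


class TestEvaluate:
    def test_perfect_predictions_score_one_everywhere(self):
        gts = [gt(0, 0, 20, 20), gt(50, 50, 80, 80, species="b")]
        dets = [
            rec(0, 0, 20, 20, score=0.9),
            rec(50, 50, 80, 80, species="b", score=0.9),
        ]
        s = evaluate(dets, gts)
        assert s.ap == s.ap50 == s.ap75 == 1.0
        assert s.ar == s.ar50 == s.ar75 == 1.0

    def test_shrunken_boxes_fall_below_half_iou(self):
        # shrinking to 70% per side about the center gives iou 0.49 exactly
        gts = [gt(0, 0, 100, 100), gt(200, 200, 300, 300)]
        dets = []
        for g in gts:
            cx, cy = g.box.center
            w, h = g.box.width * 0.7, g.box.height * 0.7
            dets.append(
                rec(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, score=0.9)
            )
        from pollenset.slides import iou as iou_fn

        assert iou_fn(dets[0].box, gts[0].box) == pytest.approx(0.49)
        s = evaluate(dets, gts)
        assert s.ap50 == 0.0

    def test_single_threshold_bounds_range_average(self):
        rng = np.random.default_rng(17)
        dets, gts = random_instance(rng)
        while not gts:
            dets, gts = random_instance(rng)
        s = evaluate(dets, gts, EvalConfig(class_aware=False))
        assert s.ap50 >= s.ap - 1e-12
        assert s.ar50 >= s.ar - 1e-12


class TestContainmentRule:
    def test_exact_080_kept_inclusive(self):
        tiles = [TileRect(0, 0, 8, 20)]
        g = gt(0, 0, 10, 10)
        assert filter_gt_by_containment([g], tiles, 0.8) == [g]

    def test_corner_straddler_dropped(self):
        # grain sits across a tile corner: at most ~55% in its best tile
        tiles = tile_grid(200, 200, TilingConfig(100, 0))
        g = gt(85, 85, 125, 125)  # 40x40 across the (100,100) corner
        best = max(
            (min(t.x + t.width, 125) - max(t.x, 85)) * (min(t.y + t.height, 125) - max(t.y, 85))
            / 1600
            for t in tiles
        )
        assert best < 0.8
        assert filter_gt_by_containment([g], tiles, 0.8) == []

    def test_zero_threshold_is_identity(self):
        tiles = [TileRect(0, 0, 10, 10)]
        gts = [gt(500, 500, 520, 520), gt(0, 0, 5, 5)]
        assert filter_gt_by_containment(gts, tiles, 0.0) == gts


class TestConfusionMatrix:
    def test_all_correct_is_identity(self):
        gts = [gt(0, 0, 10, 10, "a"), gt(50, 50, 60, 60, "b")]
        dets = [rec(0, 0, 10, 10, "a", 0.9), rec(50, 50, 60, 60, "b", 0.8)]
        cm = confusion_matrix(dets, gts, 0.5)
        assert cm.classes == ["a", "b"]
        assert np.allclose(cm.matrix, np.eye(2))
        assert (cm.matrix[cm.support > 0].sum(axis=1) == pytest.approx(1.0))

    def test_half_confused_row(self):
        gts = [gt(100 * i, 0, 100 * i + 10, 10, "a") for i in range(4)]
        dets = [
            rec(0, 0, 10, 10, "a", 0.9),
            rec(100, 0, 110, 10, "a", 0.9),
            rec(200, 0, 210, 10, "b", 0.9),
            rec(300, 0, 310, 10, "b", 0.9),
        ]
        cm = confusion_matrix(dets, gts, 0.5)
        row_a = cm.matrix[cm.classes.index("a")]
        assert np.allclose(row_a, [0.5, 0.5])

    def test_no_matches_leaves_zero_rows_and_missed_counts(self):
        gts = [gt(0, 0, 10, 10, "a")]
        dets = [rec(500, 500, 510, 510, "b", 0.9)]
        cm = confusion_matrix(dets, gts, 0.5)
        assert cm.matrix.sum() == 0.0
        assert cm.missed[cm.classes.index("a")] == 1


def test_fold_mean_stderr():
    mean, se = fold_mean_stderr([0.8, 0.9, 1.0])
    assert mean == pytest.approx(0.9)
    assert se == pytest.approx(0.1 / np.sqrt(3))
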