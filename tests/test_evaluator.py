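"""Evaluation protocol: point matching, PR curves, AUC, count curves."""

import math

import numpy as np
import pytest

import trapgrid as tg
from trapgrid.evaluator import MatchConfig


def det(x, y, cls="DSM", conf=0.9, image_id="im0"):
    return tg.Detection(x=float(x), y=float(y), pred_class=cls,
                        confidence=float(conf), image_id=image_id)


def gt(cx, cy, label="DSM", half=5):
    return tg.BBox(int(cx - half), int(cy - half), int(cx + half),
                   int(cy + half), label)


# --------------------------------------------------------------------------
# Independent brute-force matcher: a direct transcription of the rule —
# descending confidence, nearest ground-truth centroid, one-to-one claims
# --------------------------------------------------------------------------

def match_oracle(dets, gts, dist_thr, class_mode, conf_thr):
    fly = [(i, b) for i, b in enumerate(gts) if b.label in ("DSF", "DSM")]
    order = sorted([i for i, d in enumerate(dets)
                    if d.confidence >= conf_thr],
                   key=lambda i: (-dets[i].confidence, i))
    claimed = set()
    tp = fp = 0
    for i in order:
        d = dets[i]
        best_j, best_dist = None, None
        for j, (_, b) in enumerate(fly):
            cx, cy = tg.box_centroid(b)
            dist = math.dist((d.x, d.y), (cx, cy))
            if best_dist is None or dist < best_dist:
                best_j, best_dist = j, dist
        if best_j is None or best_dist > dist_thr:
            fp += 1
            continue
        if best_j in claimed:
            fp += 1
            continue
        gt_label = fly[best_j][1].label
        if class_mode == "both" or d.pred_class == gt_label:
            claimed.add(best_j)
            tp += 1
        else:
            fp += 1
    return tp, fp, len(fly) - tp


def random_instance(rng):
    dets = [det(rng.uniform(0, 200), rng.uniform(0, 200),
                ("DSF", "DSM")[int(rng.integers(2))],
                round(float(rng.random()), 2))
            for _ in range(rng.integers(0, 11))]
    gts = [gt(rng.uniform(10, 190), rng.uniform(10, 190),
              ("DSF", "DSM", "BC")[int(rng.integers(3))])
           for _ in range(rng.integers(0, 11))]
    return dets, gts


class TestMatchDetections:
    def test_direct_match(self):
        r = tg.match_detections([det(100, 100)], [gt(105, 108)],
                                MatchConfig(50, "per_class"))
        assert (r.tp, r.fp, r.fn) == (1, 0, 0)
        assert r.pairs == [(0, 0)]

    def test_class_mismatch_rule(self):
        dets = [det(100, 100, "DSM")]
        gts = [gt(105, 108, "DSF")]
        per = tg.match_detections(dets, gts, MatchConfig(50, "per_class"))
        assert (per.tp, per.fp, per.fn) == (0, 1, 1)
        both = tg.match_detections(dets, gts, MatchConfig(50, "both"))
        assert (both.tp, both.fp, both.fn) == (1, 0, 0)

    def test_double_claim_is_false_positive(self):
        dets = [det(100, 100, conf=0.9), det(103, 100, conf=0.8)]
        r = tg.match_detections(dets, [gt(100, 102)],
                                MatchConfig(50, "per_class"))
        assert (r.tp, r.fp, r.fn) == (1, 1, 0)
        assert r.pairs == [(0, 0)]  # higher confidence wins the claim

    def test_distance_threshold_exclusive(self):
        r = tg.match_detections([det(0, 0)], [gt(0, 60)], MatchConfig(50))
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_nearest_neighbour_taken_literally(self):
        # nearest GT is the wrong class: FP, even though a correct-class
        # GT sits within threshold slightly farther away
        dets = [det(100, 100, "DSM")]
        gts = [gt(100, 110, "DSF"), gt(100, 120, "DSM")]
        r = tg.match_detections(dets, gts, MatchConfig(50, "per_class"))
        assert (r.tp, r.fp, r.fn) == (0, 1, 2)

    def test_bycatch_excluded_but_tallied(self):
        dets = [det(100, 100, conf=0.9)]
        gts = [gt(100, 105, "BC")]
        r = tg.match_detections(dets, gts, MatchConfig(50, "both"))
        assert (r.tp, r.fp, r.fn) == (0, 1, 0)  # BC is not a target
        assert r.fp_on_bycatch == 1

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(200)
        for _ in range(200):
            dets, gts = random_instance(rng)
            mode = ("per_class", "both")[int(rng.integers(2))]
            thr = float(rng.choice([20.0, 50.0]))
            conf_thr = round(float(rng.random()), 2)
            r = tg.match_detections(dets, gts, MatchConfig(thr, mode), conf_thr)
            assert (r.tp, r.fp, r.fn) == match_oracle(dets, gts, thr, mode,
                                                      conf_thr)

    def test_one_to_one_pairs(self):
        rng = np.random.default_rng(201)
        for _ in range(50):
            dets, gts = random_instance(rng)
            r = tg.match_detections(dets, gts, MatchConfig(50, "both"))
            det_ids = [p[0] for p in r.pairs]
            gt_ids = [p[1] for p in r.pairs]
            assert len(det_ids) == len(set(det_ids))
            assert len(gt_ids) == len(set(gt_ids))


class TestPrCurve:
    def test_perfect_detector(self):
        gts = [gt(50, 50), gt(150, 50), gt(50, 150)]
        dets = [det(*tg.box_centroid(b), conf=1.0) for b in gts]
        curve = tg.pr_curve(dets, gts, MatchConfig(50, "per_class"))
        assert np.all(curve.precision == 1.0)
        assert np.all(curve.recall == 1.0)
        assert curve.auc == pytest.approx(1.0)

    def test_no_detections(self):
        curve = tg.pr_curve([], [gt(50, 50)], MatchConfig(50))
        assert np.all(curve.recall == 0.0)
        assert curve.auc == 0.0

    def test_equations_on_constructed_counts(self):
        # five targets, three hit, one stray: Tp=3 Fp=1 Fn=2
        gts = [gt(100 * i + 50, 50) for i in range(5)]
        dets = [det(*tg.box_centroid(b), conf=0.9) for b in gts[:3]]
        dets.append(det(450, 450, conf=0.9))
        curve = tg.pr_curve(dets, gts, MatchConfig(50, "per_class"))
        assert curve.precision[0] == pytest.approx(0.75)
        assert curve.recall[0] == pytest.approx(0.60)

    def test_hand_computed_trapezoidal_auc(self):
        """4 detections vs 3 targets, worked by hand: the threshold sweep
        visits (R, P) = (1/3, 1), (1/3, 1/2), (2/3, 2/3), (2/3, 1/2) and the
        anchored trapezoid area is 1/3 + (1/3)(1/2 + 2/3)/2 = 19/36."""
        gts = [gt(5, 5, "DSF"), gt(105, 5, "DSF"), gt(205, 5, "DSF")]
        dets = [det(5, 5, "DSF", 0.9), det(7, 5, "DSF", 0.8),
                det(105, 5, "DSF", 0.6), det(400, 5, "DSF", 0.4)]
        curve = tg.pr_curve(dets, gts, MatchConfig(50, "per_class"))
        assert curve.auc == pytest.approx(19 / 36)

    def test_zero_ground_truth_errors(self):
        with pytest.raises(ValueError):
            tg.pr_curve([det(1, 1)], [], MatchConfig(50))

    def test_recall_monotone_in_threshold(self):
        rng = np.random.default_rng(202)
        for _ in range(20):
            dets, gts = random_instance(rng)
            if not any(b.label in ("DSF", "DSM") for b in gts):
                continue
            curve = tg.pr_curve(dets, gts, MatchConfig(50, "both"))
            # thresholds descend, so recall must be non-decreasing
            assert np.all(np.diff(curve.recall) >= 0)


class TestCountCurves:
    def test_threshold_above_all_confidences(self):
        gts = [gt(50, 50), gt(150, 150)]
        dets = [det(50, 50, conf=0.7)]
        df = tg.count_curves(dets, gts, MatchConfig(50), [1.01])
        assert (df.tp[0], df.fp[0], df.fn[0]) == (0, 0, 2)

    def test_threshold_zero_conserves_detections(self):
        rng = np.random.default_rng(203)
        dets, gts = random_instance(rng)
        df = tg.count_curves(dets, gts, MatchConfig(50), [0.0])
        assert df.tp[0] + df.fp[0] == len(dets)

    def test_conservation_and_monotonicity(self):
        rng = np.random.default_rng(204)
        grid = np.linspace(0, 1, 11)
        for _ in range(20):
            dets, gts = random_instance(rng)
            n_fly = sum(1 for b in gts if b.label in ("DSF", "DSM"))
            df = tg.count_curves(dets, gts, MatchConfig(50, "both"), grid)
            for _, row in df.iterrows():
                assert row.tp + row.fn == n_fly
                n_kept = sum(1 for d in dets if d.confidence >= row.threshold)
                assert row.tp + row.fp == n_kept
            assert np.all(np.diff(df.tp) <= 0)
            assert np.all(np.diff(df.fn) >= 0)


class TestEvaluateDetections:
    def _toy(self):
        ann = tg.AnnotatedImage("im0", 300, 300,
                                [gt(50, 50, "DSF"), gt(150, 150, "DSM")])
        dets = {"im0": [det(50, 50, "DSF", 0.9), det(150, 150, "DSM", 0.8)]}
        return dets, [ann]

    def test_summary_rows(self):
        dets, anns = self._toy()
        result = tg.evaluate_detections(dets, anns, MatchConfig(50))
        assert list(result.summary()["sex"]) == \
               ["Female (DSF)", "Male (DSM)", "Both"]
        assert list(result.summary()["auc"]) == [1.0, 1.0, 1.0]

    def test_replicating_images_leaves_ratios_unchanged(self):
        dets, anns = self._toy()
        base = tg.evaluate_detections(dets, anns, MatchConfig(50))
        ann2 = tg.AnnotatedImage("im1", 300, 300, list(anns[0].boxes))
        dets2 = dict(dets)
        dets2["im1"] = [tg.Detection(d.x, d.y, d.pred_class, d.confidence,
                                     "im1") for d in dets["im0"]]
        doubled = tg.evaluate_detections(dets2, anns + [ann2], MatchConfig(50))
        for key in ("DSF", "DSM", "Both"):
            np.testing.assert_allclose(doubled.curves[key].precision,
                                       base.curves[key].precision)
            np.testing.assert_allclose(doubled.curves[key].recall,
                                       base.curves[key].recall)

    def test_detections_cannot_match_across_images(self):
        ann0 = tg.AnnotatedImage("im0", 300, 300,
                                 [gt(50, 50, "DSM"), gt(150, 50, "DSF")])
        ann1 = tg.AnnotatedImage("im1", 300, 300,
                                 [gt(250, 250, "DSM"), gt(250, 50, "DSF")])
        # detection in im1 at im0's target position: must be an FP
        dets = {"im1": [det(50, 50, "DSM", 0.9, "im1")]}
        result = tg.evaluate_detections(dets, [ann0, ann1], MatchConfig(50))
        assert result.curves["Both"].recall.max() == 0.0
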