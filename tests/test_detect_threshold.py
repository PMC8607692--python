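"""Threshold detector, box merging and detection evaluation."""

import numpy as np
import pytest

import sparkline as sl
from sparkline.detect.boxes import SparkDetection, box_iou, nms
from sparkline.detect.threshold import smooth_boxcar
from sparkline.linescan import DegenerateInputError
from sparkline.simulate import SparkSpec

DX, DT = 0.14, 2.5


def _one_spark_image(amp, noise_sigma=0.1, seed=0):
    spec = SparkSpec(x0=10.0, t0=200.0, amp=amp, sigma_x=0.849,
                     tau_rise=5.0, tau_decay=20.0)
    img, boxes = sl.generate_image([spec], noise_sigma, (128, 400), DX, DT,
                                   seed=seed)
    return img, boxes[0]


class TestDetectThreshold:
    def test_bright_spark_detected_with_peak_in_truth_box(self):
        img, truth = _one_spark_image(amp=0.5)  # 5 sigma
        bg = sl.estimate_background(img)
        dets = sl.detect_threshold(img, bg)
        assert len(dets) == 1
        px, pt = dets[0].peak_xy
        assert truth[0] <= px < truth[1] and truth[2] <= pt < truth[3]
        assert dets[0].score == 1.0 and dets[0].source == "threshold"

    def test_subthreshold_spark_missed(self):
        # peak F/F0 = 1 + 3 sigma < mu + 3.8 sigma: the classical blind spot
        img, _ = _one_spark_image(amp=0.3)
        bg = sl.estimate_background(img)
        assert sl.detect_threshold(img, bg) == []

    def test_detection_monotone_in_cri(self):
        ds = sl.generate_detection_set(n_images=2, sparks_per_image=6,
                                       amp_range_sigma=(3, 8), seed=33)
        for cell in ds.cells:
            bg = sl.estimate_background(cell.image)
            strict = sl.detect_threshold(cell.image, bg, cri=4.5)
            loose = sl.detect_threshold(cell.image, bg, cri=3.8)
            for d in strict:  # every strict peak lies inside some loose box
                assert any(
                    l.box[0] <= d.peak_xy[0] < l.box[1]
                    and l.box[2] <= d.peak_xy[1] < l.box[3]
                    for l in loose
                )

    def test_every_peak_exceeds_threshold_on_smoothed_image(self):
        ds = sl.generate_detection_set(n_images=2, sparks_per_image=5,
                                       amp_range_sigma=(4, 8), seed=13)
        for cell in ds.cells:
            bg = sl.estimate_background(cell.image)
            sm = smooth_boxcar(cell.image.data)
            for d in sl.detect_threshold(cell.image, bg):
                assert sm[d.peak_xy] > bg.mu + 3.8 * bg.sigma

    def test_rejects_raw_image_and_degenerate_background(self, noise_image):
        raw = sl.LineScanImage(noise_image.data * 100, dx=DX, dt=DT)
        bg = sl.estimate_background(noise_image)
        with pytest.raises(ValueError, match="normalized"):
            sl.detect_threshold(raw, bg)
        bg.sigma = 0.0
        with pytest.raises(DegenerateInputError):
            sl.detect_threshold(noise_image, bg)


class TestMergeOverlaps:
    def _det(self, box, score=1.0):
        peak = (box[0], box[2])
        return SparkDetection(box=box, score=score, source="threshold",
                              peak_xy=peak)

    def test_identical_boxes_merge_to_one(self):
        d = self._det((10, 20, 30, 40))
        out = sl.merge_overlaps([d, d])
        assert len(out) == 1 and out[0].box == (10, 20, 30, 40)

    def test_disjoint_boxes_unchanged(self):
        a, b = self._det((0, 5, 0, 5)), self._det((20, 25, 20, 25))
        assert len(sl.merge_overlaps([a, b])) == 2

    def test_chain_merges_transitively_like_brute_force(self):
        # three boxes, each overlapping the next at IoU ~0.5: transitive
        # closure -> a single union box
        boxes = [(0, 10, 0, 12), (0, 10, 6, 18), (0, 10, 12, 24)]
        dets = [self._det(b) for b in boxes]
        out = sl.merge_overlaps(dets, iou_min=0.3)
        assert len(out) == _brute_force_n_groups(boxes, 0.3)
        assert out[0].box == (0, 10, 0, 24)

    def test_idempotent(self, rng):
        boxes = [
            tuple(sorted(rng.integers(0, 30, 2))[:2]) + tuple(sorted(rng.integers(0, 30, 2))[:2])
            for _ in range(30)
        ]
        dets = [self._det((b[0], b[1] + 1, b[2], b[3] + 1)) for b in boxes]
        once = sl.merge_overlaps(dets)
        twice = sl.merge_overlaps(once)
        assert [d.box for d in once] == [d.box for d in twice]


def _brute_force_n_groups(boxes, iou_min):
    """Independent transitive-closure oracle over the IoU graph."""
    n = len(boxes)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(box_iou(boxes[a], boxes[b]) >= iou_min
                       for a in groups[i] for b in groups[j]):
                    groups[i] |= groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return len(groups)


class TestEvaluateDetections:
    def _det(self, box, score=1.0):
        return SparkDetection(box=box, score=score, source="nn",
                              peak_xy=((box[0] + box[1]) // 2, (box[2] + box[3]) // 2))

    def test_perfect_detector(self):
        truth = [(0, 10, 0, 10), (20, 30, 20, 30)]
        m = sl.evaluate_detections([self._det(b) for b in truth], truth)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_duplicated_detections_halve_precision(self):
        truth = [(0, 10, 0, 10), (20, 30, 20, 30)]
        dets = [self._det(b) for b in truth for _ in range(2)]
        m = sl.evaluate_detections(dets, truth)
        assert m.recall == 1.0 and m.precision == 0.5

    def test_empty_conventions(self):
        assert sl.evaluate_detections([], []).precision == 1.0
        m = sl.evaluate_detections([], [(0, 5, 0, 5)] * 10)
        assert m.recall == 0.0 and m.precision == 1.0

    def test_amplitude_bin_bookkeeping(self):
        truth = [(0, 10, 0, 10), (20, 30, 20, 30), (40, 50, 40, 50)]
        dets = [self._det(truth[0]), self._det(truth[2])]
        m = sl.evaluate_detections(dets, truth, amps_sigma=[1.5, 3.0, 6.0])
        assert m.bin_recall["[1,2)"] == 1.0
        assert m.bin_recall["[2,3.8)"] == 0.0
        assert m.bin_recall["[5,inf)"] == 1.0


class TestNMS:
    def test_nms_idempotent_and_keeps_highest_score(self, rng):
        dets = []
        for _ in range(40):
            x0, t0 = rng.integers(0, 40, 2)
            w, h = rng.integers(5, 15, 2)
            dets.append(SparkDetection(
                box=(int(x0), int(x0 + w), int(t0), int(t0 + h)),
                score=float(rng.uniform(0.1, 1.0)), source="nn",
                peak_xy=(int(x0), int(t0))))
        once = nms(dets, 0.3)
        assert nms(once, 0.3) == once
        assert once[0].score == max(d.score for d in dets)
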