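"""Detections, box arithmetic, NMS, merging, and detector evaluation.

Boxes are half-open ``(x_start, x_end, t_start, t_end)`` in pixel/line
units, space axis first.  A detection "hits" a truth box when the
box-vs-box IoU reaches ``iou_min`` OR the detection's peak falls inside the
truth box — small spark boxes make strict IoU brittle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class SparkDetection:
    """One detected spark: a space-time box with a confidence score."""

    box: Box
    score: float
    source: str                      # "threshold" | "nn"
    peak_xy: tuple[int, int]         # (x, t) of max F/F0 within the box

    def __post_init__(self):
        x0, x1, t0, t1 = self.box
        if not (x1 > x0 and t1 > t0):
            raise ValueError(f"empty box {self.box}")
        px, pt = self.peak_xy
        if not (x0 <= px < x1 and t0 <= pt < t1):
            raise ValueError(f"peak {self.peak_xy} outside box {self.box}")


def box_area(b: Box) -> int:
    return (b[1] - b[0]) * (b[3] - b[2])


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open boxes."""
    ix = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    it = max(0, min(a[3], b[3]) - max(a[2], b[2]))
    inter = ix * it
    if inter == 0:
        return 0.0
    return inter / (box_area(a) + box_area(b) - inter)


def box_union(a: Box, b: Box) -> Box:
    return (min(a[0], b[0]), max(a[1], b[1]), min(a[2], b[2]), max(a[3], b[3]))


def merge_overlaps(dets: list[SparkDetection], iou_min: float = 0.3) -> list[SparkDetection]:
    """Merge detections whose pairwise IoU reaches ``iou_min``.

    Merging is transitive (union-find over the overlap graph) and the result
    is re-merged until stable, so the operation is idempotent.  A merged
    detection keeps the highest score and the peak of its best member.
    """
    if not 0 < iou_min <= 1:
        raise ValueError("iou_min must be in (0, 1]")
    dets = list(dets)
    while True:
        merged = _merge_pass(dets, iou_min)
        if len(merged) == len(dets):
            return merged
        dets = merged


def _merge_pass(dets, iou_min):
    n = len(dets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if box_iou(dets[i].box, dets[j].box) >= iou_min:
                parent[find(i)] = find(j)
    groups: dict[int, list[SparkDetection]] = {}
    for i, d in enumerate(dets):
        groups.setdefault(find(i), []).append(d)
    out = []
    for members in groups.values():
        best = max(members, key=lambda d: d.score)
        box = members[0].box
        for m in members[1:]:
            box = box_union(box, m.box)
        out.append(SparkDetection(box=box, score=best.score,
                                  source=best.source, peak_xy=best.peak_xy))
    out.sort(key=lambda d: -d.score)
    return out


def nms(dets: list[SparkDetection], iou_thresh: float = 0.3) -> list[SparkDetection]:
    """Greedy non-maximum suppression, highest score first. Idempotent."""
    order = sorted(dets, key=lambda d: -d.score)
    kept: list[SparkDetection] = []
    for d in order:
        if all(box_iou(d.box, k.box) < iou_thresh for k in kept):
            kept.append(d)
    return kept


def is_hit(det: SparkDetection, truth: Box, iou_min: float = 0.3) -> bool:
    """Hit rule: IoU >= iou_min OR detection peak inside the truth box."""
    if box_iou(det.box, truth) >= iou_min:
        return True
    px, pt = det.peak_xy
    return truth[0] <= px < truth[1] and truth[2] <= pt < truth[3]


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    n_true_positive: int
    n_false_positive: int
    n_truth: int
    matches: list[tuple[int, int]]          # (detection index, truth index)
    bin_recall: dict[str, float]            # per-amplitude-bin recall
    bin_counts: dict[str, int]

#: amplitude bins in units of the background noise sigma; 3.8 is the
#: traditional detection threshold, so the [2, 3.8) bin holds sub-threshold
#: events
AMPLITUDE_BINS = ((1.0, 2.0), (2.0, 3.8), (3.8, 5.0), (5.0, np.inf))


def evaluate_detections(
    dets: list[SparkDetection],
    truth: list[Box],
    amps_sigma: list[float] | None = None,
    iou_min: float = 0.3,
) -> DetectionMetrics:
    """One-to-one greedy matching by detection score.

    ``amps_sigma`` are per-truth amplitudes in noise-sigma units for the
    per-bin recall breakdown.  Empty truth with empty detections counts as
    perfect by convention.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched_truth: set[int] = set()
    matches = []
    for di in order:
        best_j, best_iou = None, -1.0
        for j, tb in enumerate(truth):
            if j in matched_truth or not is_hit(dets[di], tb, iou_min):
                continue
            iou = box_iou(dets[di].box, tb)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            matched_truth.add(best_j)
            matches.append((di, best_j))
    tp = len(matches)
    fp = len(dets) - tp
    precision = tp / len(dets) if dets else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    bin_recall, bin_counts = {}, {}
    if amps_sigma is not None:
        hit = np.zeros(len(truth), dtype=bool)
        hit[list(matched_truth)] = True
        amps = np.asarray(amps_sigma)
        for lo, hi in AMPLITUDE_BINS:
            key = f"[{lo:g},{hi:g})"
            sel = (amps >= lo) & (amps < hi)
            bin_counts[key] = int(sel.sum())
            bin_recall[key] = float(hit[sel].mean()) if sel.any() else float("nan")
    return DetectionMetrics(
        precision=precision, recall=recall, f1=f1,
        n_true_positive=tp, n_false_positive=fp, n_truth=len(truth),
        matches=matches, bin_recall=bin_recall, bin_counts=bin_counts,
    )
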