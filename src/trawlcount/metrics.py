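"""Counting-performance metrics and matching of counted tracks to truth.

Every counted track is labelled true positive (TP) if it overlaps a
ground-truth trajectory, otherwise false positive (FP); ground-truth
objects never matched are false negatives (FN). Two scalar summaries:

    correct count rate = 100 * TP / GT            (percent)
    F-score            = TP / (TP + 0.5 * (FP + FN))

The F-score is algebraically the harmonic mean of precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BoundingBox, iou
from .counting import CountEvent


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given tally."""


@dataclass(frozen=True)
class CountingTally:
    TP: int
    FP: int
    FN: int
    GT: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.GT) < 0:
            raise ValueError("tally entries must be non-negative")
        if self.TP > self.GT:
            raise ValueError("TP cannot exceed GT")


@dataclass(frozen=True)
class FpsSummary:
    min: float
    mean: float
    max: float


def correct_count_rate(t: CountingTally) -> float:
    """Percentage of ground-truth catch items correctly counted."""
    if t.GT == 0:
        raise UndefinedMetricError("correct count rate undefined for GT = 0")
    return 100.0 * t.TP / t.GT


def f_score(t: CountingTally) -> float:
    """Counting F-score in [0, 1]; penalizes FP and FN equally."""
    denom = t.TP + 0.5 * (t.FP + t.FN)
    if denom == 0:
        raise UndefinedMetricError("F-score undefined for an all-zero tally")
    return t.TP / denom


def fps_summary(values: list[float]) -> FpsSummary:
    """Min/mean/max of the per-processed-frame effective FPS values."""
    if not values:
        raise ValueError("fps_summary requires at least one value")
    return FpsSummary(min(values), sum(values) / len(values), max(values))


def match_counts_to_gt(
    events: list[CountEvent],
    track_histories: dict[int, list[tuple[int, BoundingBox]]],
    gt_trajectories: list[list[tuple[int, BoundingBox]]],
    spatio_iou_min: float = 0.5,
) -> CountingTally:
    """Greedy one-to-one spatiotemporal matching -> TP/FP/FN tally.

    A counted track is a candidate match for a ground-truth object if on at
    least one shared frame their boxes overlap with IoU >= spatio_iou_min;
    candidate pairs are committed in order of descending best overlap.
    TP + FN = GT by construction.
    """
    counted_ids = [e.track_id for e in events]
    gt_n = len(gt_trajectories)
    # best single-frame IoU per (counted track, gt object)
    candidates: list[tuple[float, int, int]] = []
    for ti, tid in enumerate(counted_ids):
        frames = {f: b for f, b in track_histories.get(tid, [])}
        for gi, traj in enumerate(gt_trajectories):
            best = 0.0
            for f, gbox in traj:
                tbox = frames.get(f)
                if tbox is not None:
                    best = max(best, iou(tbox, gbox))
            if best >= spatio_iou_min:
                candidates.append((best, ti, gi))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_tracks: set[int] = set()
    used_gt: set[int] = set()
    tp = 0
    for _, ti, gi in candidates:
        if ti in used_tracks or gi in used_gt:
            continue
        used_tracks.add(ti)
        used_gt.add(gi)
        tp += 1
    fp = len(counted_ids) - tp
    fn = gt_n - tp
    return CountingTally(TP=tp, FP=fp, FN=fn, GT=gt_n)
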