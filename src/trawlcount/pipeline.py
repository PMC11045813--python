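"""Pipeline orchestration: scheduler -> detector -> tracker -> counter.

The primary execution mode replays pre-computed detections (from a CSV file
or a synthetic scene); an external-adapter hook accepts any object exposing
``detect(frame_index) -> list[BoundingBox]`` under the same one-frame-at-a-
time contract a batch-of-1 detector would honor. No neural runtime is
bundled.

Counts are a pure function of the detection stream, the configuration, and
the schedule; wall-clock timing only enters the effective-FPS figures.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Protocol

from .core import BoundingBox, FrameDetections, VideoMeta, filter_by_confidence
from .counting import CounterConfig, CountEvent, LineCounter
from .metrics import (
    CountingTally,
    FpsSummary,
    correct_count_rate,
    f_score,
    fps_summary,
    match_counts_to_gt,
)
from .scheduling import MODES, FrameScheduler, effective_fps
from .sort import SortTracker, TrackerConfig


class DetectorSource(Protocol):
    """Anything that yields detections for one frame at a time."""

    def detect(self, frame_index: int) -> list[BoundingBox]: ...


class ReplaySource:
    """Replays a pre-computed per-frame detection stream."""

    def __init__(self, frames: list[FrameDetections]):
        self._by_index = {f.frame_index: f.detections for f in frames}
        self.n_frames = max(self._by_index, default=-1) + 1

    def detect(self, frame_index: int) -> list[BoundingBox]:
        return self._by_index.get(frame_index, [])


class AdapterSource:
    """Wraps an external detector callable under the batch-of-1 contract."""

    def __init__(self, fn: Callable[[int], list[BoundingBox]]):
        self._fn = fn

    def detect(self, frame_index: int) -> list[BoundingBox]:
        return list(self._fn(frame_index))


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    meta: VideoMeta
    skip_mode: str
    confidence_threshold: float
    count: int
    events: list[CountEvent]
    frames_processed: int
    frames_with_detections: int
    frames_skipped: int
    fps: FpsSummary
    fps_per_frame: list[float]
    real_time: bool
    track_histories: dict[int, list[tuple[int, BoundingBox]]]
    tally: CountingTally | None = None
    metrics: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable summary (per-frame FPS list included)."""
        d = {
            "meta": asdict(self.meta),
            "skip_mode": self.skip_mode,
            "confidence_threshold": self.confidence_threshold,
            "count": self.count,
            "events": [asdict(e) for e in self.events],
            "frames_processed": self.frames_processed,
            "frames_with_detections": self.frames_with_detections,
            "frames_skipped": self.frames_skipped,
            "fps": asdict(self.fps) if self.fps else None,
            "fps_per_frame": [round(v, 2) for v in self.fps_per_frame],
            "real_time": self.real_time,
        }
        if self.tally is not None:
            d["tally"] = asdict(self.tally)
        if self.metrics:
            d["metrics"] = {k: round(v, 2) for k, v in self.metrics.items()}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(
    source: DetectorSource,
    meta: VideoMeta,
    tracker_cfg: TrackerConfig | None = None,
    counter_cfg: CounterConfig | None = None,
    skip_mode: str = "none",
    confidence_threshold: float = 0.5,
    verbose: bool = False,
) -> RunReport:
    """Run the full counting pipeline over ``meta.n_frames`` native frames.

    Per frame: the scheduler decides process/skip; processed frames are
    detected, confidence-filtered, tracked, checked against the counting
    line, and fed back to the (adaptive) scheduler. The effective FPS of a
    processed frame is its measured reciprocal processing time times one
    plus the number of frames skipped immediately before it.
    """
    if skip_mode not in MODES:
        raise ValueError(f"skip_mode must be one of {MODES}")
    if meta.n_frames <= 0:
        raise ValueError("meta.n_frames must be positive")
    tracker = SortTracker(tracker_cfg)
    counter = LineCounter(meta, counter_cfg)
    scheduler = FrameScheduler(skip_mode)
    fps_values: list[float] = []
    frames_with_detections = 0

    for frame_index in range(meta.n_frames):
        if not scheduler.decide(frame_index):
            continue
        t0 = time.perf_counter()
        raw = source.detect(frame_index)
        dets = filter_by_confidence(raw, confidence_threshold)
        confirmed = tracker.step(FrameDetections(frame_index, dets))
        new_events = counter.update(frame_index, confirmed)
        elapsed = max(time.perf_counter() - t0, 1e-9)
        fps_values.append(
            effective_fps(elapsed, scheduler.state.skipped_before_current)
        )
        if dets:
            frames_with_detections += 1
        scheduler.record_detection(bool(dets))
        if verbose:
            print(
                f"frame {frame_index}: {len(dets)} det, "
                f"{len(confirmed)} confirmed tracks, {len(new_events)} new events"
            )

    histories = {tid: list(h) for tid, h in counter.histories.items()}
    summary = fps_summary(fps_values)
    return RunReport(
        meta=meta,
        skip_mode=skip_mode,
        confidence_threshold=confidence_threshold,
        count=counter.count,
        events=list(counter.events),
        frames_processed=scheduler.state.frames_processed,
        frames_with_detections=frames_with_detections,
        frames_skipped=scheduler.state.frames_skipped,
        fps=summary,
        fps_per_frame=fps_values,
        real_time=summary.mean >= meta.native_fps,
        track_histories=histories,
    )


def evaluate(
    report: RunReport,
    gt_trajectories: list[list[tuple[int, "BoundingBox"]]],
    spatio_iou_min: float = 0.5,
) -> RunReport:
    """Attach a TP/FP/FN tally and counting metrics to a run report."""
    if not gt_trajectories:
        raise ValueError("ground truth is empty; metrics undefined")
    tally = match_counts_to_gt(
        report.events, report.track_histories, gt_trajectories, spatio_iou_min
    )
    report.tally = tally
    report.metrics = {
        "correct_count_rate": correct_count_rate(tally),
        "f_score": f_score(tally),
    }
    return report
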