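"""Frame-skipping schedulers and effective-FPS bookkeeping.

Five modes decide which native frames the detector/tracker sees:

- ``none``     — process every frame;
- ``fs1``      — skip every third frame  (period 3: P P S);
- ``fs2``      — skip every second frame (period 2: P S);
- ``fs3``      — skip every second and third frames (period 3: P S S);
- ``adaptive`` — content-driven: after a processed frame with no target
  detections, skip the next two frames and process the third; after a
  frame *with* detections, process the next two frames. The check repeats
  on every processed frame until the end of the video.

Frame 0 is always processed, in every mode.

The effective throughput of a processed frame is the reciprocal of its
processing time multiplied by one more than the number of frames skipped
immediately before it — skipping one frame doubles the effective FPS of
the next processed frame, and so on. A run is real-time when the mean
effective FPS is at or above the video's native frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

MODES = ("none", "fs1", "fs2", "fs3", "adaptive")

# periodic masks anchored at frame 0; True = process
_FIXED_PATTERNS = {
    "none": (True,),
    "fs1": (True, True, False),
    "fs2": (True, False),
    "fs3": (True, False, False),
}


@dataclass
class ScheduleState:
    mode: str
    forced_remaining: int = 0  # upcoming frames committed to processing
    frames_processed: int = 0
    frames_skipped: int = 0
    skipped_before_current: int = 0

    @property
    def frames_seen(self) -> int:
        return self.frames_processed + self.frames_skipped


def fixed_decision(mode: str, frame_index: int) -> bool:
    """Process/skip decision of the periodic modes at a 0-based index."""
    if mode not in _FIXED_PATTERNS:
        raise ValueError(
            f"fixed_decision handles modes {sorted(_FIXED_PATTERNS)}, got {mode!r}"
        )
    pattern = _FIXED_PATTERNS[mode]
    return pattern[frame_index % len(pattern)]


def adaptive_after(state: ScheduleState, detections_present: bool) -> ScheduleState:
    """Adaptive rule, applied once per processed frame after detection.

    Detections present -> commit to processing the next two frames
    (max-merged with any outstanding commitment); empty frame -> no
    commitment, so the skip-two-process-one cadence resumes.
    """
    if detections_present:
        state.forced_remaining = max(state.forced_remaining, 2)
    return state


def effective_fps(frame_time: float, skipped_before: int) -> float:
    """Effective FPS of one processed frame: (1 + skipped_before) / time."""
    if frame_time <= 0:
        raise ValueError("frame_time must be positive")
    if skipped_before < 0:
        raise ValueError("skipped_before must be non-negative")
    return (1 + skipped_before) / frame_time


class FrameScheduler:
    """Sequential process/skip decisions with tallies for one video run.

    Drive it frame by frame: call :meth:`decide` for every native frame in
    order; after each *processed* frame, call :meth:`record_detection` with
    whether any target was detected (only the adaptive mode reacts).
    """

    def __init__(self, mode: str = "none"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.state = ScheduleState(mode=mode)
        self._skips_since_processed = 0
        self._started = False

    @property
    def mode(self) -> str:
        return self.state.mode

    def decide(self, frame_index: int) -> bool:
        """Decide for the next frame in sequence; updates tallies."""
        if frame_index != self.state.frames_seen:
            raise ValueError(
                f"frames must be offered in order: expected index "
                f"{self.state.frames_seen}, got {frame_index}"
            )
        if self.mode == "adaptive":
            process = self._adaptive_decision()
        else:
            process = fixed_decision(self.mode, frame_index)
        if process:
            self.state.frames_processed += 1
            self.state.skipped_before_current = self._skips_since_processed
            self._skips_since_processed = 0
            self._started = True
        else:
            self.state.frames_skipped += 1
            self._skips_since_processed += 1
        return process

    def _adaptive_decision(self) -> bool:
        if not self._started:
            return True
        if self.state.forced_remaining > 0:
            self.state.forced_remaining -= 1
            return True
        # idle cadence: skip two, process the third
        return self._skips_since_processed >= 2

    def record_detection(self, detections_present: bool) -> None:
        """Report the detection outcome of the frame just processed."""
        if self.mode == "adaptive":
            adaptive_after(self.state, detections_present)


def schedule_mask(
    mode: str, n_frames: int, detections_present: list[bool] | None = None
) -> list[bool]:
    """Full process/skip mask for ``n_frames`` frames.

    For the adaptive mode ``detections_present[i]`` tells whether frame i
    would contain detections if processed (skipped frames are never
    inspected, matching the online behaviour).
    """
    sched = FrameScheduler(mode)
    mask = []
    for i in range(n_frames):
        process = sched.decide(i)
        mask.append(process)
        if process:
            present = bool(detections_present[i]) if detections_present else False
            sched.record_detection(present)
    return mask
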