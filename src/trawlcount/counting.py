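"""Line-crossing catch counting.

A horizontal counting line sits at 4/5 of the frame height (measured from
the top; y increases downward). A confirmed track is accepted as a catch —
once, ever — when any enabled condition first holds:

i.   bottom_cross — the bottom edge of its box crosses the line,
ii.  center_cross — the center of its box crosses the line,
iii. tall_box     — its box height exceeds 2/3 of the frame height
                    (a target so close to the camera that it fills the
                    frame never cleanly crosses the line).

"Crosses" means an observed above-to-below transition between two
consecutive processed observations of the track; the boundary is inclusive
on the below side. Animals drifting above the line (or swimming back out of
the trawl) are therefore never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import BoundingBox, VideoMeta
from .sort import Track

CONDITION_BOTTOM_CROSS = "bottom_cross"
CONDITION_CENTER_CROSS = "center_cross"
CONDITION_TALL_BOX = "tall_box"
ALL_CONDITIONS = frozenset(
    {CONDITION_BOTTOM_CROSS, CONDITION_CENTER_CROSS, CONDITION_TALL_BOX}
)


@dataclass(frozen=True)
class CounterConfig:
    line_fraction: float = 4.0 / 5.0
    height_fraction: float = 2.0 / 3.0
    enabled_conditions: frozenset[str] = ALL_CONDITIONS
    #: count a track whose first-ever observation is already past the line
    #: (no transition was observed); off by default.
    count_on_first_sight_below: bool = False
    #: evaluate conditions on Kalman-predicted boxes of coasting tracks;
    #: off by default — only observed boxes count, to avoid ghost counts.
    count_on_predicted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.line_fraction < 1.0:
            raise ValueError("line_fraction must lie in (0, 1)")
        if not 0.0 < self.height_fraction <= 1.0:
            raise ValueError("height_fraction must lie in (0, 1]")
        if not self.enabled_conditions:
            raise ValueError("at least one condition must be enabled")
        unknown = set(self.enabled_conditions) - ALL_CONDITIONS
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


@dataclass(frozen=True)
class CountEvent:
    """The once-per-track record that a track was accepted as a catch."""

    track_id: int
    frame_index: int
    condition: str


def line_y(meta: VideoMeta, cfg: CounterConfig | None = None) -> float:
    """y coordinate of the counting line: line_fraction x frame height."""
    cfg = cfg or CounterConfig()
    return cfg.line_fraction * meta.frame_height


def condition_bottom_cross(
    prev: BoundingBox, cur: BoundingBox, line: float
) -> bool:
    """Condition i: box bottom crossed the line between two observations."""
    return prev.bottom() < line <= cur.bottom()


def condition_center_cross(
    prev: BoundingBox, cur: BoundingBox, line: float
) -> bool:
    """Condition ii: box center crossed the line between two observations."""
    return prev.center_y() < line <= cur.center_y()


def condition_tall_box(
    cur: BoundingBox, meta: VideoMeta, cfg: CounterConfig | None = None
) -> bool:
    """Condition iii: box height strictly exceeds height_fraction x H."""
    cfg = cfg or CounterConfig()
    return cur.height > cfg.height_fraction * meta.frame_height


class LineCounter:
    """Stateful per-run counter; call update once per processed frame."""

    def __init__(self, meta: VideoMeta, cfg: CounterConfig | None = None):
        self.meta = meta
        self.cfg = cfg or CounterConfig()
        self.line = line_y(meta, self.cfg)
        self.events: list[CountEvent] = []
        #: observation history of each counted track, kept alive past the
        #: track's own lifetime so counts can be matched to ground truth
        self.histories: dict[int, list[tuple[int, BoundingBox]]] = {}
        self._counted: set[int] = set()

    @property
    def count(self) -> int:
        return len(self.events)

    def update(self, frame_index: int, confirmed_tracks: list[Track]) -> list[CountEvent]:
        """Evaluate the enabled conditions; returns any new CountEvents.

        A track fires at most one event per run; conditions are checked in
        the order i, ii, iii and the first that holds is recorded.
        """
        new_events = []
        for track in confirmed_tracks:
            if track.track_id in self._counted or not track.history:
                continue
            if track.time_since_update > 0:
                if not self.cfg.count_on_predicted:
                    continue
                cur = track.state.to_box()
            else:
                cur = track.last_box()
            prev = track.history[-2][1] if len(track.history) >= 2 else None
            condition = self._first_condition(prev, cur)
            if condition is not None:
                event = CountEvent(track.track_id, frame_index, condition)
                self.events.append(event)
                self.histories[track.track_id] = track.history
                self._counted.add(track.track_id)
                new_events.append(event)
        return new_events

    def _first_condition(
        self, prev: BoundingBox | None, cur: BoundingBox
    ) -> str | None:
        enabled = self.cfg.enabled_conditions
        if prev is not None:
            if CONDITION_BOTTOM_CROSS in enabled and condition_bottom_cross(
                prev, cur, self.line
            ):
                return CONDITION_BOTTOM_CROSS
            if CONDITION_CENTER_CROSS in enabled and condition_center_cross(
                prev, cur, self.line
            ):
                return CONDITION_CENTER_CROSS
        elif self.cfg.count_on_first_sight_below:
            if CONDITION_BOTTOM_CROSS in enabled and cur.bottom() >= self.line:
                return CONDITION_BOTTOM_CROSS
            if CONDITION_CENTER_CROSS in enabled and cur.center_y() >= self.line:
                return CONDITION_CENTER_CROSS
        if CONDITION_TALL_BOX in enabled and condition_tall_box(
            cur, self.meta, self.cfg
        ):
            return CONDITION_TALL_BOX
        return None
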