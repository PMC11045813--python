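"""Shared geometric and video domain types.

Coordinates are continuous, 0-based, origin at the top-left corner with y
increasing downward — the convention of the MOT-Challenge CSV dialect used
for detection replay. Boxes are stored as (x_left, y_top, width, height) in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidBoxError(ValueError):
    """Raised when a bounding box has non-positive width or height."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates with a detector confidence."""

    x_left: float
    y_top: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidBoxError(
                f"box width and height must be positive, got "
                f"{self.width}x{self.height}"
            )

    @property
    def x_right(self) -> float:
        return self.x_left + self.width

    def bottom(self) -> float:
        return self.y_top + self.height

    def center_x(self) -> float:
        return self.x_left + self.width / 2.0

    def center_y(self) -> float:
        return self.y_top + self.height / 2.0

    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class VideoMeta:
    """Frame geometry and rate of a video stream.

    The default profile matches the in-trawl camera setting this package
    targets: 1280x720 pixels at 60 frames per second.
    """

    frame_width: int = 1280
    frame_height: int = 720
    native_fps: float = 60.0
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.native_fps <= 0:
            raise ValueError("native_fps must be positive")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")

    @property
    def duration(self) -> float:
        """Video duration in seconds."""
        return self.n_frames / self.native_fps


@dataclass
class FrameDetections:
    """All detections reported for one frame (0-based index)."""

    frame_index: int
    detections: list[BoundingBox] = field(default_factory=list)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1].

    Used both as the association affinity in the SORT step and as the
    spatial-overlap measure when matching counted tracks to ground truth.
    """
    ix = min(a.x_right, b.x_right) - max(a.x_left, b.x_left)
    iy = min(a.bottom(), b.bottom()) - max(a.y_top, b.y_top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area() + b.area() - inter)


def filter_by_confidence(
    dets: list[BoundingBox], threshold: float = 0.5
) -> list[BoundingBox]:
    """Keep detections whose confidence is at or above ``threshold``.

    Order-preserving; the boundary is inclusive (a detection exactly at the
    threshold is kept), the usual detector convention. Default 0.5.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [d for d in dets if d.confidence >= threshold]
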