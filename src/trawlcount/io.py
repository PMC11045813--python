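"""MOT-Challenge-style CSV I/O for detections and ground-truth tracks.

On disk a row is ``frame,id,x,y,w,h,conf`` with 1-based frame indices (the
MOT convention); in memory everything is 0-based. The id column is ignored
when reading plain detections and carries the object identity when reading
or writing ground truth.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .core import BoundingBox, FrameDetections, InvalidBoxError
from .synthetic import GroundTruthObject, Scene

_COLUMNS = ("frame", "id", "x", "y", "w", "h", "conf")


class DetectionsParseError(ValueError):
    """A malformed row in a detections/GT CSV; carries the line number."""


def _parse_row(row: list[str], lineno: int) -> tuple[int, int, BoundingBox]:
    try:
        frame = int(float(row[0]))
        obj_id = int(float(row[1]))
        x, y, w, h, conf = (float(v) for v in row[2:7])
    except (ValueError, IndexError) as exc:
        raise DetectionsParseError(f"line {lineno}: malformed row {row!r}") from exc
    if frame < 1:
        raise DetectionsParseError(f"line {lineno}: frame indices are 1-based on disk")
    try:
        box = BoundingBox(x, y, w, h, conf)
    except InvalidBoxError as exc:
        raise DetectionsParseError(f"line {lineno}: {exc}") from exc
    return frame - 1, obj_id, box


def _read_rows(path: str | Path):
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].strip().startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "frame":
                continue  # optional header
            yield _parse_row(row, lineno)


def read_detections_csv(
    path: str | Path, n_frames: int | None = None
) -> list[FrameDetections]:
    """Read per-frame detections, grouped and sorted by frame.

    Frames absent from the file are empty. ``n_frames`` pads the stream to
    a known video length; by default the last frame seen sets the length.
    """
    by_frame: dict[int, list[BoundingBox]] = {}
    for frame, _obj_id, box in _read_rows(path):
        by_frame.setdefault(frame, []).append(box)
    total = n_frames if n_frames is not None else (max(by_frame) + 1 if by_frame else 0)
    return [FrameDetections(i, by_frame.get(i, [])) for i in range(total)]


def write_detections_csv(path: str | Path, frames: list[FrameDetections]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for frame in frames:
            for box in frame.detections:
                writer.writerow(
                    [
                        frame.frame_index + 1,
                        -1,
                        f"{box.x_left:.3f}",
                        f"{box.y_top:.3f}",
                        f"{box.width:.3f}",
                        f"{box.height:.3f}",
                        f"{box.confidence:.4f}",
                    ]
                )


def read_gt_csv(path: str | Path) -> list[list[tuple[int, BoundingBox]]]:
    """Read ground-truth trajectories, one list of (frame, box) per object."""
    by_object: dict[int, list[tuple[int, BoundingBox]]] = {}
    for frame, obj_id, box in _read_rows(path):
        by_object.setdefault(obj_id, []).append((frame, box))
    return [sorted(traj) for _, traj in sorted(by_object.items())]


def write_gt_csv(path: str | Path, objects: list[GroundTruthObject]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for obj in objects:
            for frame, box in obj.trajectory:
                writer.writerow(
                    [
                        frame + 1,
                        obj.object_id,
                        f"{box.x_left:.3f}",
                        f"{box.y_top:.3f}",
                        f"{box.width:.3f}",
                        f"{box.height:.3f}",
                        "1.0000",
                    ]
                )


def write_scene(scene: Scene, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a synthetic scene's detections and GT; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det_path = out / "detections.csv"
    gt_path = out / "gt.csv"
    write_detections_csv(det_path, scene.frames)
    write_gt_csv(gt_path, scene.objects)
    return det_path, gt_path
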