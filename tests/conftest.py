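import numpy as np
import pytest

from trawlcount import BoundingBox, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_box(rng, frame_w=1280, frame_h=720, integer=False):
    """A random valid box inside the frame."""
    w = rng.uniform(5, frame_w / 3)
    h = rng.uniform(5, frame_h / 3)
    x = rng.uniform(0, frame_w - w)
    y = rng.uniform(0, frame_h - h)
    if integer:
        x, y, w, h = (float(int(v)) for v in (x, y, w, h))
        w, h = max(w, 1.0), max(h, 1.0)
    return BoundingBox(x, y, w, h, confidence=float(rng.uniform(0, 1)))


def rasterized_iou(a: BoundingBox, b: BoundingBox, step: float = 1.0) -> float:
    """Brute-force IoU oracle: count lattice-cell membership.

    Samples a regular lattice of cell centers covering both boxes and
    counts cells inside a, b, and both. Exact for boxes whose corners lie
    on the lattice; otherwise accurate to O(step/box size).
    """
    x0 = min(a.x_left, b.x_left)
    x1 = max(a.x_right, b.x_right)
    y0 = min(a.y_top, b.y_top)
    y1 = max(a.bottom(), b.bottom())
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    def inside(box):
        return (
            (X >= box.x_left)
            & (X < box.x_right)
            & (Y >= box.y_top)
            & (Y < box.bottom())
        )

    in_a, in_b = inside(a), inside(b)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union


@pytest.fixture
def clean_scene():
    """Zero-noise 5-object scene: detections equal ground truth exactly."""
    cfg = SceneConfig(
        duration=30.0,
        n_objects=5,
        miss_prob=0.0,
        fp_rate=0.0,
        loc_noise_sd=0.0,
        speed_sd=0.0,
        seed=42,
    )
    return generate_scene(cfg)
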