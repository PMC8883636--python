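"""First detection stage in the pixel-features point cloud.

Candidate 3D boxes (anchors) share the interest region's 2D footprint and
differ only along the grayscale axis: centers slide over [0, 255] with a fixed
stride and each center carries one anchor per scale.  The points inside each
anchor are subsampled to a fixed count, normalized to the anchor's frame and
classified by the point-set network; surviving anchors go through
non-maximum suppression with 3D IoU, which keeps a single proposal per
candidate class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Box3D, ConfigError, EmptyCloudError, PixelCloud, clip_box
from .nn import PointSetClassifier

__all__ = [
    "AnchorGrid",
    "ScoredBox3D",
    "TrainConfig",
    "ClassificationDataset",
    "BACKGROUND",
    "generate_anchors",
    "sample_points",
    "normalize_points",
    "classify_points",
    "global_features",
    "iou3d",
    "nms_3d",
    "propose",
    "train_classifier",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class AnchorGrid:
    """Sliding-anchor layout along the grayscale axis.

    ``scales`` are the anchor grayscale widths (k anchors per sliding
    position); ``stride`` is the gray-level spacing of successive centers.
    Centers are placed at stride/2, stride/2 + stride, ... while they do not
    exceed the top of ``gray_range``, giving n positions and n*k anchors.
    """

    scales: tuple[float, ...] = (64.0, 96.0, 128.0)
    stride: float = 8.0
    gray_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if not self.scales or min(self.scales) <= 0:
            raise ConfigError("anchor scales must be positive and non-empty")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1 gray level")

    def centers(self) -> np.ndarray:
        lo, hi = self.gray_range
        n = int(np.floor((hi - lo - self.stride / 2.0) / self.stride)) + 1
        return lo + self.stride / 2.0 + self.stride * np.arange(max(n, 0))

    @property
    def n_anchors(self) -> int:
        return len(self.centers()) * len(self.scales)


@dataclass(frozen=True)
class ScoredBox3D:
    """A 3D box with the class label and probability assigned to its points."""

    box: Box3D
    class_label: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


def generate_anchors(roi, grid: AnchorGrid) -> list[Box3D]:
    """Enumerate the anchor boxes for one interest region.

    Deterministic, center-major / scale-minor ordering; every anchor is
    clipped to the gray range.
    """
    return [
        clip_box(Box3D(l_h=float(c), l_w=float(s), footprint=roi))
        for c in grid.centers()
        for s in grid.scales
    ]


def sample_points(
    points: np.ndarray, n_max: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Reduce or pad a point array to exactly ``n_max`` points.

    Larger sets are subsampled uniformly without replacement (seeded);
    smaller sets are padded by repeating points cyclically.  An empty input
    signals the empty-box condition.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = points.shape[0]
    if n == 0:
        raise EmptyCloudError("cannot sample from an empty point set")
    if n == n_max:
        return points.copy()
    if n > n_max:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        idx = rng.choice(n, size=n_max, replace=False)
        return points[idx]
    reps = np.resize(np.arange(n), n_max)
    return points[reps]


def normalize_points(points: np.ndarray, box: Box3D) -> np.ndarray:
    """Express points in the canonical frame of a 3D box.

    x and y are centered on the footprint's pixel-center and divided by its
    half-extents (corner pixels map to +-1); z is centered on l_h and divided
    by l_w/2 so the box top maps to +1 and the bottom to -1.  All outputs lie
    in [-1, 1] for in-box points.
    """
    points = np.asarray(points, dtype=float)
    fp = box.footprint
    cx = (fp.c0 + fp.c1 - 1) / 2.0
    cy = (fp.r0 + fp.r1 - 1) / 2.0
    hx = max((fp.n_cols - 1) / 2.0, 0.5)
    hy = max((fp.n_rows - 1) / 2.0, 0.5)
    hz = max(box.l_w / 2.0, 0.5)
    out = np.empty_like(points)
    out[:, 0] = (points[:, 0] - cx) / hx
    out[:, 1] = (points[:, 1] - cy) / hy
    out[:, 2] = (points[:, 2] - box.l_h) / hz
    return out


def classify_points(model: PointSetClassifier, points: np.ndarray) -> np.ndarray:
    """Probability vector over candidate classes for one normalized point set."""
    points = np.asarray(points)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"expected (n_max, 3) points, got {points.shape}")
    return model.classify(points)


def global_features(model: PointSetClassifier, points: np.ndarray) -> np.ndarray:
    """Max-pooled global feature f_mp for one normalized point set."""
    points = np.asarray(points)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"expected (n_max, 3) points, got {points.shape}")
    return model.global_features(points)


def _interval_overlap(a: Box3D, b: Box3D) -> float:
    return max(0.0, min(a.z_hi, b.z_hi) - max(a.z_lo, b.z_lo))


def iou3d(a: Box3D, b: Box3D) -> float:
    """3D intersection-over-union of two boxes from their volumes.

    The intersection volume is the footprint-overlap area times the
    gray-interval overlap; IoU = inter / (|A| + |B| - inter).  When the
    footprints coincide this reduces exactly to 1D interval IoU.
    """
    ir = max(0, min(a.footprint.r1, b.footprint.r1) - max(a.footprint.r0, b.footprint.r0))
    ic = max(0, min(a.footprint.c1, b.footprint.c1) - max(a.footprint.c0, b.footprint.c0))
    inter = ir * ic * _interval_overlap(a, b)
    union = a.volume + b.volume - inter
    return inter / union if union > 0 else 0.0


def nms_3d(
    candidates: list[ScoredBox3D],
    iou_threshold: float,
    background_label: str = BACKGROUND,
) -> list[ScoredBox3D]:
    """Non-maximum suppression with 3D IoU, one surviving box per class.

    Within each candidate class, boxes are visited in decreasing score order
    (ties broken by lower input index); a box is suppressed when its 3D IoU
    with an already kept same-class box exceeds the threshold.  Only the
    top-scoring survivor of each class is returned; the background class never
    yields a proposal.  Output is sorted by decreasing score.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError("iou_threshold must be in [0, 1]")
    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(candidates):
        if c.class_label != background_label:
            by_class.setdefault(c.class_label, []).append(i)
    winners: list[ScoredBox3D] = []
    for label, idxs in by_class.items():
        order = sorted(idxs, key=lambda i: (-candidates[i].score, i))
        kept: list[int] = []
        for i in order:
            if all(iou3d(candidates[i].box, candidates[j].box) <= iou_threshold for j in kept):
                kept.append(i)
        if kept:
            winners.append(candidates[kept[0]])
    winners.sort(key=lambda c: -c.score)
    return winners


def propose(
    model: PointSetClassifier,
    cloud: PixelCloud,
    grid: AnchorGrid = AnchorGrid(),
    score_threshold: float = 0.5,
    iou_threshold: float = 0.5,
    n_max: int = 256,
    seed: int = 0,
) -> list[ScoredBox3D]:
    """Generate at most one proposal box per candidate class for one cloud.

    Anchors are enumerated over the cloud's ROI; the points inside each
    non-empty anchor are sampled, normalized and classified in one batch.
    Anchors whose best class is background, or whose score does not exceed
    ``score_threshold``, are dropped; the rest go through :func:`nms_3d`.
    Empty anchors are background by definition (score 1) and never proposed.
    """
    anchors = generate_anchors(cloud.roi, grid)
    rng = np.random.default_rng(seed)
    batch: list[np.ndarray] = []
    kept_anchors: list[Box3D] = []
    from .core import points_in_box  # local to avoid cycle at import time

    for anchor in anchors:
        inside = points_in_box(cloud, anchor)
        if len(inside) == 0:
            continue
        pts = sample_points(inside.points, n_max, rng)
        batch.append(normalize_points(pts, anchor))
        kept_anchors.append(anchor)
    if not batch:
        return []
    probs, _, _ = model.forward(np.stack(batch))
    candidates: list[ScoredBox3D] = []
    for anchor, p in zip(kept_anchors, probs):
        ci = int(np.argmax(p))
        label = model.class_names[ci]
        if label == BACKGROUND or p[ci] <= score_threshold:
            continue
        candidates.append(ScoredBox3D(box=anchor, class_label=label, score=float(p[ci])))
    return nms_3d(candidates, iou_threshold)


# --------------------------------------------------------------------- train


@dataclass(frozen=True)
class TrainConfig:
    """Two-stage training schedule for the point-set classifier.

    Stage 1 runs at a fast learning rate, stage 2 continues at a tenth of it;
    the epoch counts default to a desk-scale schedule.
    """

    lr_stage1: float = 1e-3
    epochs_stage1: int = 20
    lr_stage2: float = 1e-4
    epochs_stage2: int = 20
    batch_size: int = 64


@dataclass
class ClassificationDataset:
    """Fixed-size normalized point sets with integer class labels.

    ``X`` is (N, n_max, 3) float32, ``y`` holds indices into ``class_names``
    (index 0 is conventionally the background class).
    """

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]
    label_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.X.shape[0])


def train_classifier(
    dataset: ClassificationDataset,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    per_point_layer_sizes: tuple[int, ...] = (64, 128, 256),
    head_layer_sizes: tuple[int, ...] = (128,),
    use_input_tnet: bool = False,
) -> tuple[PointSetClassifier, dict]:
    """Train the point-set classifier with Adam on cross-entropy.

    Deterministic for a given seed (weight init and epoch shuffling share one
    generator).  Returns the model and a history dict with the mean training
    loss per epoch.
    """
    present = np.unique(dataset.y)
    if len(present) < 2:
        raise ConfigError("training set must contain at least 2 classes (incl. background)")
    rng = np.random.default_rng(seed)
    model = PointSetClassifier(
        n_classes=len(dataset.class_names),
        class_names=dataset.class_names,
        per_point_layer_sizes=per_point_layer_sizes,
        head_layer_sizes=head_layer_sizes,
        use_input_tnet=use_input_tnet,
    )
    model.init_params(rng)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(val) for k, val in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    X = np.ascontiguousarray(dataset.X, dtype=np.float32)
    y = np.asarray(dataset.y, dtype=np.int64)
    n = len(y)
    losses: list[float] = []
    stages = (
        (config.lr_stage1, config.epochs_stage1),
        (config.lr_stage2, config.epochs_stage2),
    )
    for lr, epochs in stages:
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                probs, _, cache = model.forward(X[idx])
                p_true = np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)
                epoch_loss += float(-np.log(p_true).sum())
                grads = model.backward(cache, y[idx])
                t += 1
                for k, g in grads.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    model.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(
                        np.float32
                    )
            losses.append(epoch_loss / n)
    return model, {"loss": losses}
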