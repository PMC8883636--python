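"""Seeded phantom generator: the data substrate for training and testing.

Real grayscale radiographs have a bright anatomical object whose pixels occupy
a contiguous grayscale band, embedded in a darker background, with noise and
with scattered off-object pixels that share the object's band (the reason the
pipeline needs its 2D interest-region stage).  The generator emulates exactly
this structure:

* background pixels ~ Normal(background_level, noise_sd), rounded and clipped,
* one or more elliptic/rectangular objects whose pixels are drawn uniformly
  from a gray band and perturbed by the same noise,
* distractor pixels with in-band values scattered outside the interest region.

Every sample carries its ground truth (mask, padded ROI, generating band) and
is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Box3D, ConfigError, GrayImage, ROIBox2D, SegMask, image_to_cloud, points_in_box
from .proposals import (
    BACKGROUND,
    AnchorGrid,
    ClassificationDataset,
    generate_anchors,
    normalize_points,
    sample_points,
)
from .refine import RegressionDataset

__all__ = [
    "SynthParams",
    "SynthSample",
    "ObjectTruth",
    "generate_sample",
    "generate_dataset",
    "make_training_sets",
    "band_interval_iou",
]

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class SynthParams:
    """Phantom generation settings.

    The defaults describe a 128x128 image with a dark noisy background
    (mean 40, sd 8 gray levels), a single bright ellipse whose pixels occupy
    the band [140, 200], and 50 in-band distractor pixels scattered outside
    the interest region.  ``extra_bands`` supplies the bands of additional
    objects when ``n_objects`` > 1 (multi-class phantoms).
    """

    image_size: tuple[int, int] = (128, 128)
    background_level: float = 40.0
    noise_sd: float = 8.0
    object_shape: str = "ellipse"
    object_band: tuple[float, float] = (140.0, 200.0)
    object_size_fraction: float = 0.35
    n_distractors: int = 50
    n_objects: int = 1
    extra_bands: tuple[tuple[float, float], ...] = ((80.0, 130.0),)
    roi_padding_fraction: float = 0.10

    def __post_init__(self) -> None:
        low, high = self.object_band
        if not (0 <= low < high <= 255):
            raise ConfigError(f"invalid object band {self.object_band}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 < self.object_size_fraction < 1):
            raise ConfigError("object_size_fraction must be in (0, 1)")
        if self.object_shape not in ("ellipse", "rectangle"):
            raise ConfigError(f"unknown object_shape {self.object_shape!r}")

    def bands(self) -> list[tuple[float, float]]:
        all_bands = [self.object_band, *self.extra_bands]
        if self.n_objects > len(all_bands):
            raise ConfigError("not enough bands configured for n_objects")
        return all_bands[: self.n_objects]


@dataclass(frozen=True)
class ObjectTruth:
    """Ground truth of one generated object."""

    label: str
    band: tuple[float, float]
    mask: SegMask
    roi: ROIBox2D

    @property
    def box3d(self) -> Box3D:
        """The object's ground-truth 3D box on its ROI footprint."""
        low, high = self.band
        return Box3D(l_h=(low + high) / 2.0, l_w=high - low, footprint=self.roi)


@dataclass(frozen=True)
class SynthSample:
    """One phantom with its full ground truth."""

    image: GrayImage
    gt_mask: SegMask
    gt_roi: ROIBox2D
    gt_band: tuple[float, float]
    seed: int
    objects: tuple[ObjectTruth, ...] = ()

    def gt_box3d(self) -> Box3D:
        low, high = self.gt_band
        return Box3D(l_h=(low + high) / 2.0, l_w=high - low, footprint=self.gt_roi)


def _padded_bbox(mask: np.ndarray, pad_fraction: float, H: int, W: int, label: str) -> ROIBox2D:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pad_r = int(round((r1 - r0) * pad_fraction))
    pad_c = int(round((c1 - c0) * pad_fraction))
    return ROIBox2D(
        max(r0 - pad_r, 0), max(c0 - pad_c, 0), min(r1 + pad_r, H), min(c1 + pad_c, W),
        label=label,
    )


def generate_sample(params: SynthParams, seed: int) -> SynthSample:
    """Generate one phantom; bit-identical for a given (params, seed)."""
    rng = np.random.default_rng(seed)
    H, W = params.image_size
    field_ = rng.normal(params.background_level, params.noise_sd, size=(H, W))
    rr, cc = np.mgrid[0:H, 0:W]
    semi_r = params.object_size_fraction * (H - 1) / 2.0
    semi_c = params.object_size_fraction * (W - 1) / 2.0
    if semi_r < 1 or semi_c < 1 or 2 * semi_r > H - 1 or 2 * semi_c > W - 1:
        raise ConfigError("object does not fit in the image at this size fraction")
    bands = params.bands()
    objects: list[ObjectTruth] = []
    union = np.zeros((H, W), dtype=bool)
    for i, band in enumerate(bands):
        label = "object" if params.n_objects == 1 else f"object_{i + 1}"
        mask = None
        for _ in range(100):  # rejection sampling keeps objects disjoint
            cy = rng.uniform(semi_r, H - 1 - semi_r)
            cx = rng.uniform(semi_c, W - 1 - semi_c)
            if params.object_shape == "ellipse":
                cand = ((rr - cy) / semi_r) ** 2 + ((cc - cx) / semi_c) ** 2 <= 1.0
            else:
                cand = (np.abs(rr - cy) <= semi_r) & (np.abs(cc - cx) <= semi_c)
            if not (cand & union).any():
                mask = cand
                break
        if mask is None:
            raise ConfigError("could not place disjoint objects; reduce size or count")
        low, high = band
        n_pix = int(mask.sum())
        values = rng.integers(int(low), int(high) + 1, size=n_pix).astype(float)
        values += rng.normal(0.0, params.noise_sd, size=n_pix)
        field_[mask] = values
        union |= mask
        objects.append(
            ObjectTruth(
                label=label,
                band=band,
                mask=SegMask(mask.astype(np.uint8)),
                roi=_padded_bbox(mask, params.roi_padding_fraction, H, W, label),
            )
        )
    img = np.clip(np.round(field_), 0, 255).astype(np.uint8)
    gt_roi = _padded_bbox(union, params.roi_padding_fraction, H, W, objects[0].label)
    # distractors: in-band values strictly outside the interest region
    outside = np.ones((H, W), dtype=bool)
    outside[gt_roi.r0 : gt_roi.r1, gt_roi.c0 : gt_roi.c1] = False
    flat = np.flatnonzero(outside)
    n_d = min(params.n_distractors, len(flat))
    if n_d > 0:
        spots = rng.choice(flat, size=n_d, replace=False)
        d_bands = [bands[i % len(bands)] for i in range(n_d)]
        d_vals = np.array(
            [rng.integers(int(b[0]), int(b[1]) + 1) for b in d_bands], dtype=np.uint8
        )
        img.ravel()[spots] = d_vals
    return SynthSample(
        image=GrayImage(img),
        gt_mask=SegMask(union.astype(np.uint8)),
        gt_roi=gt_roi,
        gt_band=bands[0],
        seed=int(seed),
        objects=tuple(objects),
    )


def generate_dataset(
    params: SynthParams,
    n: int,
    seed: int,
    band_center_jitter: float = 15.0,
    band_width_jitter: float = 5.0,
    size_jitter: float = 0.05,
) -> list[SynthSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from the master seed.

    The primary object's band center and width, and the object size, are
    jittered uniformly within the given half-ranges — emulating the
    device-to-device intensity variation that makes a single fixed threshold
    unusable on real images.  Set the jitters to 0 for identical bands.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, _SEED_CAP, size=n)
    samples = []
    for s in sample_seeds:
        jrng = np.random.default_rng(int(s) ^ 0x5EED)
        low, high = params.object_band
        center = (low + high) / 2.0 + jrng.uniform(-band_center_jitter, band_center_jitter)
        width = (high - low) + jrng.uniform(-band_width_jitter, band_width_jitter)
        width = max(width, 10.0)
        new_low = float(np.clip(np.round(center - width / 2.0), 1, 253))
        new_high = float(np.clip(np.round(center + width / 2.0), new_low + 1, 254))
        frac = params.object_size_fraction * (1.0 + jrng.uniform(-size_jitter, size_jitter))
        p = replace(params, object_band=(new_low, new_high), object_size_fraction=frac)
        samples.append(generate_sample(p, int(s)))
    return samples


def band_interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """IoU of two closed grayscale intervals."""
    overlap = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - overlap
    return overlap / union if union > 0 else 0.0


def make_training_sets(
    samples: list[SynthSample],
    grid: AnchorGrid = AnchorGrid(),
    pos_iou: float = 0.5,
    neg_iou: float = 0.2,
    n_max: int = 256,
    seed: int = 0,
    max_background_per_sample: int | None = 8,
) -> tuple[ClassificationDataset, RegressionDataset]:
    """Label anchors against ground-truth bands and build both training sets.

    Over each sample's ground-truth ROI, every anchor is compared to every
    object band by gray-interval IoU: the best-matching class is assigned when
    its IoU reaches ``pos_iou``, the anchor is background when all IoUs are at
    most ``neg_iou``, and it is discarded otherwise.  Positives are paired
    with their object's ground-truth 3D box for the regression set.  Empty
    anchors never enter the sets (they are background by definition at
    inference).  Non-empty background anchors may be subsampled per sample to
    keep the classes balanced; ``label_counts`` on the returned classification
    set reports the pre-subsampling balance.
    """
    if not samples:
        raise ConfigError("make_training_sets requires at least one sample")
    rng = np.random.default_rng(seed)
    labels_present = sorted({o.label for s in samples for o in s.objects})
    class_names = (BACKGROUND, *labels_present)
    index_of = {name: i for i, name in enumerate(class_names)}
    X_rows: list[np.ndarray] = []
    y_rows: list[int] = []
    label_counts: dict[str, int] = {name: 0 for name in class_names}
    reg_X: list[np.ndarray] = []
    reg_P: list[Box3D] = []
    reg_G: list[Box3D] = []
    reg_labels: list[str] = []
    for sample in samples:
        cloud = image_to_cloud(sample.image, sample.gt_roi)
        anchors = generate_anchors(sample.gt_roi, grid)
        bg_pool: list[np.ndarray] = []
        for anchor in anchors:
            ious = [band_interval_iou(anchor.interval, o.band) for o in sample.objects]
            best = int(np.argmax(ious))
            if ious[best] >= pos_iou:
                assigned: str | None = sample.objects[best].label
            elif max(ious) <= neg_iou:
                assigned = BACKGROUND
            else:
                assigned = None
            if assigned is None:
                continue
            label_counts[assigned] += 1
            inside = points_in_box(cloud, anchor)
            if len(inside) == 0:
                continue
            pts = normalize_points(sample_points(inside.points, n_max, rng), anchor)
            if assigned == BACKGROUND:
                bg_pool.append(pts)
            else:
                X_rows.append(pts)
                y_rows.append(index_of[assigned])
                obj = sample.objects[best]
                low, high = obj.band
                reg_X.append(pts)
                reg_P.append(anchor)
                reg_G.append(Box3D((low + high) / 2.0, high - low, footprint=anchor.footprint))
                reg_labels.append(assigned)
        if max_background_per_sample is not None and len(bg_pool) > max_background_per_sample:
            keep = rng.choice(len(bg_pool), size=max_background_per_sample, replace=False)
            bg_pool = [bg_pool[i] for i in sorted(keep)]
        X_rows.extend(bg_pool)
        y_rows.extend([index_of[BACKGROUND]] * len(bg_pool))
    n_pos = sum(1 for y in y_rows if y != index_of[BACKGROUND])
    if n_pos == 0:
        raise ConfigError(
            "no positive anchors at the given thresholds; "
            f"label counts before filtering: {label_counts}"
        )
    cls = ClassificationDataset(
        X=np.asarray(X_rows, dtype=np.float32),
        y=np.asarray(y_rows, dtype=np.int64),
        class_names=class_names,
        label_counts=label_counts,
    )
    reg = RegressionDataset(
        X=np.asarray(reg_X, dtype=np.float32),
        proposals=reg_P,
        truths=reg_G,
        labels=reg_labels,
    )
    return cls, reg
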