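"""End-to-end orchestration: configuration, training, segmentation, evaluation.

The full segmentation pass over one image is:

    2D interest regions  ->  per region: pixel-features point cloud
        ->  anchor proposals + point-set classification + 3D-IoU NMS
        ->  linear refinement of each proposal box
        ->  rasterize each refined box, union into a full-size mask

Training builds anchor-labelled point sets from phantoms (or from user
image/mask pairs), trains the point-set classifier and then fits the per-class
ridge box regressors on the trained global features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    Box3D,
    ConfigError,
    GrayImage,
    ROIBox2D,
    SegMask,
    box_to_mask,
    image_to_cloud,
)
from .metrics import EvalRecord, evaluate, write_report
from .nn import PointSetClassifier
from .proposals import (
    AnchorGrid,
    ScoredBox3D,
    TrainConfig,
    propose,
)
from .proposals import train_classifier as _train_classifier
from .refine import BoxRegressor, refine_box, train_regressor
from .roi import DetectorConfig, detect_roi_baseline, load_roi_detections
from .synthetic import (
    ObjectTruth,
    SynthParams,
    SynthSample,
    generate_dataset,
    make_training_sets,
)

__all__ = [
    "PipelineConfig",
    "PipelineModels",
    "SegmentationResult",
    "segment_image",
    "run_training",
    "run_evaluation",
    "whole_image_threshold",
    "truth_from_image_mask",
]

logger = logging.getLogger("cloudseg")

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline in one (YAML-round-trippable) place."""

    detector: str = "baseline"  # "baseline" or path to a JSONL detection file
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    grid: AnchorGrid = field(default_factory=AnchorGrid)
    n_max: int = 256
    score_threshold: float = 0.5
    iou_threshold: float = 0.5
    ridge_lambda: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)
    per_point_layer_sizes: tuple[int, ...] = (64, 128, 256)
    head_layer_sizes: tuple[int, ...] = (128,)
    synth: SynthParams = field(default_factory=SynthParams)
    n_train: int = 200
    band_center_jitter: float = 15.0
    band_width_jitter: float = 5.0
    size_jitter: float = 0.05
    max_background_per_sample: int = 8
    seed: int = 0

    # ------------------------------------------------------------- yaml I/O
    def to_flat_dict(self) -> dict:
        d: dict = {"detector": self.detector}
        d.update(asdict(self.detector_config))
        d["anchor_scales"] = list(self.grid.scales)
        d["anchor_stride"] = self.grid.stride
        d.update(asdict(self.train))
        d.update(
            {
                "per_point_layer_sizes": list(self.per_point_layer_sizes),
                "head_layer_sizes": list(self.head_layer_sizes),
                "n_max": self.n_max,
                "score_threshold": self.score_threshold,
                "iou_threshold": self.iou_threshold,
                "ridge_lambda": self.ridge_lambda,
                "n_train": self.n_train,
                "band_center_jitter": self.band_center_jitter,
                "band_width_jitter": self.band_width_jitter,
                "size_jitter": self.size_jitter,
                "max_background_per_sample": self.max_background_per_sample,
                "seed": self.seed,
            }
        )
        s = asdict(self.synth)
        s["image_size"] = list(self.synth.image_size)
        s["object_band"] = list(self.synth.object_band)
        s["extra_bands"] = [list(b) for b in self.synth.extra_bands]
        d.update(s)
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "PipelineConfig":
        base = cls()
        det = {k: d[k] for k in asdict(base.detector_config) if k in d}
        trn = {k: d[k] for k in asdict(base.train) if k in d}
        syn = {k: d[k] for k in asdict(base.synth) if k in d}
        for key in ("image_size", "object_band"):
            if key in syn:
                syn[key] = tuple(syn[key])
        if "extra_bands" in syn:
            syn["extra_bands"] = tuple(tuple(b) for b in syn["extra_bands"])
        grid_kwargs = {}
        if "anchor_scales" in d:
            grid_kwargs["scales"] = tuple(float(s) for s in d["anchor_scales"])
        if "anchor_stride" in d:
            grid_kwargs["stride"] = float(d["anchor_stride"])
        top = {
            k: d[k]
            for k in (
                "detector",
                "n_max",
                "score_threshold",
                "iou_threshold",
                "ridge_lambda",
                "n_train",
                "band_center_jitter",
                "band_width_jitter",
                "size_jitter",
                "max_background_per_sample",
                "seed",
            )
            if k in d
        }
        if "per_point_layer_sizes" in d:
            top["per_point_layer_sizes"] = tuple(int(v) for v in d["per_point_layer_sizes"])
        if "head_layer_sizes" in d:
            top["head_layer_sizes"] = tuple(int(v) for v in d["head_layer_sizes"])
        return cls(
            detector_config=DetectorConfig(**det),
            grid=AnchorGrid(**grid_kwargs),
            train=TrainConfig(**trn),
            synth=SynthParams(**syn),
            **top,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config file must hold a mapping")
        return cls.from_flat_dict(data)


@dataclass
class PipelineModels:
    """The trained pieces: point-set classifier + per-class box regressors."""

    classifier: PointSetClassifier
    regressors: dict[str, BoxRegressor]

    def save(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cpath = directory / "classifier.npz"
        rpath = directory / "regressors.npz"
        self.classifier.save(cpath)
        labels = sorted(self.regressors)
        meta = {
            "labels": labels,
            "lam": [self.regressors[l].lam for l in labels],
            "feature_dim": self.classifier.feature_dim,
        }
        arrays = {}
        for i, label in enumerate(labels):
            reg = self.regressors[label]
            arrays[f"{i}_w_lh"] = reg.w_lh
            arrays[f"{i}_w_lw"] = reg.w_lw
            arrays[f"{i}_mean"] = reg.feature_mean
            arrays[f"{i}_std"] = reg.feature_std
        np.savez(rpath, meta=np.array(json.dumps(meta)), **arrays)
        return cpath, rpath

    @classmethod
    def load(cls, directory: str | Path) -> "PipelineModels":
        directory = Path(directory)
        classifier = PointSetClassifier.load(directory / "classifier.npz")
        with np.load(directory / "regressors.npz", allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            regressors = {}
            for i, label in enumerate(meta["labels"]):
                regressors[label] = BoxRegressor(
                    class_label=label,
                    w_lh=data[f"{i}_w_lh"],
                    w_lw=data[f"{i}_w_lw"],
                    feature_mean=data[f"{i}_mean"],
                    feature_std=data[f"{i}_std"],
                    lam=float(meta["lam"][i]),
                )
        return cls(classifier=classifier, regressors=regressors)


@dataclass
class SegmentationResult:
    """Final mask plus the per-stage intermediates for audit."""

    mask: SegMask
    rois: list[ROIBox2D]
    proposals: list[tuple[ROIBox2D, list[ScoredBox3D]]]
    refined: list[tuple[ROIBox2D, list[Box3D]]]
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "rois": [list(r.as_tuple()) + [r.score, r.label] for r in self.rois],
            "proposals": [
                {
                    "roi": list(roi.as_tuple()),
                    "boxes": [
                        {
                            "class": p.class_label,
                            "score": p.score,
                            "l_h": p.box.l_h,
                            "l_w": p.box.l_w,
                        }
                        for p in props
                    ],
                }
                for roi, props in self.proposals
            ],
            "refined": [
                {
                    "roi": list(roi.as_tuple()),
                    "boxes": [{"l_h": b.l_h, "l_w": b.l_w} for b in boxes],
                }
                for roi, boxes in self.refined
            ],
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)


def _resolve_rois(
    image: GrayImage,
    config: PipelineConfig,
    image_id: str | None,
    external: dict[str, list[ROIBox2D]] | None,
) -> list[ROIBox2D]:
    if config.detector != "baseline":
        if external is None:
            external = load_roi_detections(config.detector)
        rois = external.get(image_id or "", [])
        if not rois:
            return [ROIBox2D(0, 0, image.height, image.width, score=0.0)]
        return rois
    return detect_roi_baseline(image, config.detector_config)


def segment_image(
    image: GrayImage,
    config: PipelineConfig,
    models: PipelineModels,
    image_id: str | None = None,
    external_rois: dict[str, list[ROIBox2D]] | None = None,
    seed: int | None = None,
) -> SegmentationResult:
    """Segment one grayscale image; returns the mask and all intermediates.

    Multiple interest regions are processed independently and their masks
    unioned.  An image with no surviving ROI or proposal yields an all-zero
    mask (with a note), never a failure.
    """
    seed = config.seed if seed is None else seed
    rois = _resolve_rois(image, config, image_id, external_rois)
    rois = [r.clipped(image.height, image.width) for r in rois]
    notes: list[str] = []
    mask = np.zeros((image.height, image.width), dtype=np.uint8)
    all_props: list[tuple[ROIBox2D, list[ScoredBox3D]]] = []
    all_refined: list[tuple[ROIBox2D, list[Box3D]]] = []
    for k, roi in enumerate(rois):
        cloud = image_to_cloud(image, roi)
        props = propose(
            models.classifier,
            cloud,
            grid=config.grid,
            score_threshold=config.score_threshold,
            iou_threshold=config.iou_threshold,
            n_max=config.n_max,
            seed=(seed + 7919 * k) % _SEED_CAP,
        )
        logger.debug(
            "roi %s: %d points, %d proposals", roi.as_tuple(), len(cloud), len(props)
        )
        refined_boxes: list[Box3D] = []
        for p in props:
            reg = models.regressors.get(p.class_label)
            if reg is None:
                reg = BoxRegressor.identity(p.class_label, models.classifier.feature_dim)
                notes.append(f"no regressor for class {p.class_label!r}; proposal kept")
            refined = refine_box(
                models.classifier,
                reg,
                cloud,
                p,
                n_max=config.n_max,
                seed=(seed + 7919 * k + 17) % _SEED_CAP,
            )
            refined_boxes.append(refined)
            mask = np.maximum(mask, box_to_mask(image, refined).values)
        all_props.append((roi, props))
        all_refined.append((roi, refined_boxes))
        if not props:
            notes.append(f"no proposal in ROI {roi.as_tuple()}")
    if not any(props for _, props in all_props):
        notes.append("no proposal anywhere: image segmented as all-background")
        logger.info("image %s: no proposals", image_id or "<unnamed>")
    return SegmentationResult(
        mask=SegMask(mask), rois=rois, proposals=all_props, refined=all_refined, notes=notes
    )


def whole_image_threshold(image: GrayImage, band: tuple[float, float]) -> SegMask:
    """Plain band thresholding over the full image (no interest region).

    The ablation baseline: everything the ROI stage is meant to improve on.
    """
    arr = image.values.astype(float)
    return SegMask(((arr >= band[0]) & (arr <= band[1])).astype(np.uint8))


def truth_from_image_mask(
    image: GrayImage,
    mask: SegMask,
    label: str = "object",
    percentiles: tuple[float, float] = (1.0, 99.0),
    pad_fraction: float = 0.10,
    image_seed: int = 0,
) -> SynthSample:
    """Build a training sample from a real image + ground-truth mask pair.

    The object's grayscale band is estimated as the given percentile range of
    the object pixels' intensities (robust to annotation noise at the mask
    rim), and the ROI is the padded tight bounding box of the mask.
    """
    m = mask.values.astype(bool)
    if not m.any():
        raise ConfigError("ground-truth mask is empty")
    vals = image.values[m]
    low = float(np.floor(np.percentile(vals, percentiles[0])))
    high = float(np.ceil(np.percentile(vals, percentiles[1])))
    if high <= low:
        high = low + 1.0
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pad_r = int(round((r1 - r0) * pad_fraction))
    pad_c = int(round((c1 - c0) * pad_fraction))
    roi = ROIBox2D(
        max(r0 - pad_r, 0),
        max(c0 - pad_c, 0),
        min(r1 + pad_r, image.height),
        min(c1 + pad_c, image.width),
        label=label,
    )
    obj = ObjectTruth(label=label, band=(low, high), mask=mask, roi=roi)
    return SynthSample(
        image=image,
        gt_mask=mask,
        gt_roi=roi,
        gt_band=(low, high),
        seed=image_seed,
        objects=(obj,),
    )


def run_training(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    samples: list[SynthSample] | None = None,
) -> tuple[PipelineModels, dict]:
    """Train classifier then regressors; optionally write checkpoints + log.

    ``samples`` defaults to a freshly generated synthetic dataset of
    ``config.n_train`` phantoms.  Deterministic for a given config.
    """
    if samples is None:
        samples = generate_dataset(
            config.synth,
            config.n_train,
            config.seed,
            band_center_jitter=config.band_center_jitter,
            band_width_jitter=config.band_width_jitter,
            size_jitter=config.size_jitter,
        )
    cls_set, reg_set = make_training_sets(
        samples,
        grid=config.grid,
        n_max=config.n_max,
        seed=(config.seed + 1) % _SEED_CAP,
        max_background_per_sample=config.max_background_per_sample,
    )
    logger.info(
        "training sets: %d point sets (%s), %d regression pairs",
        len(cls_set),
        cls_set.label_counts,
        len(reg_set),
    )
    classifier, history = _train_classifier(
        cls_set,
        config.train,
        seed=(config.seed + 2) % _SEED_CAP,
        per_point_layer_sizes=config.per_point_layer_sizes,
        head_layer_sizes=config.head_layer_sizes,
    )
    regressors = train_regressor(
        classifier, reg_set, lam=config.ridge_lambda, class_names=cls_set.class_names
    )
    models = PipelineModels(classifier=classifier, regressors=regressors)
    log = {
        "n_samples": len(samples),
        "n_point_sets": len(cls_set),
        "label_counts": cls_set.label_counts,
        "n_regression_pairs": len(reg_set),
        "loss": history["loss"],
        "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        models.save(out_dir)
        (out_dir / "training_log.json").write_text(json.dumps(log, indent=2))
        config.save(out_dir / "config.yaml")
    return models, log


def run_evaluation(
    config: PipelineConfig,
    models: PipelineModels,
    samples: list[SynthSample],
    out_path: str | Path | None = None,
    pooled: bool = False,
) -> tuple[list[EvalRecord], EvalRecord]:
    """Segment every sample and score the masks against ground truth.

    A failure on one image is logged and that image skipped; it does not
    abort the batch.
    """
    predictions: dict[str, SegMask] = {}
    truths: dict[str, SegMask] = {}
    for i, sample in enumerate(samples):
        image_id = f"sample_{i:04d}"
        truths[image_id] = sample.gt_mask
        try:
            result = segment_image(
                sample.image,
                config,
                models,
                image_id=image_id,
                seed=(config.seed + 31 * i) % _SEED_CAP,
            )
        except Exception:  # noqa: BLE001 - image-level isolation
            logger.exception("segmentation failed for %s; skipped", image_id)
            continue
        predictions[image_id] = result.mask
    records, mean, skipped = evaluate(predictions, truths, pooled=pooled)
    for image_id in skipped:
        logger.warning("no prediction/truth counterpart for %s", image_id)
    if out_path is not None:
        write_report(records, mean, out_path)
    return records, mean
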