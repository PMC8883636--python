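"""2D interest-region detection.

The pipeline's first stage crops the image to regions that contain the
segmentation target, so that pixels elsewhere in the image sharing the target's
intensity band cannot pollute the thresholding result.  Production systems use
a fine-tuned neural 2D detector here; this module defines the contract
(image -> scored ROI boxes) together with

* a deterministic intensity-deviation baseline detector, and
* a file-based hook for detections produced by any external detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import GrayImage, ParseError, ROIBox2D

__all__ = ["DetectorConfig", "detect_roi_baseline", "load_roi_detections", "roi_iou2d"]


@dataclass(frozen=True)
class DetectorConfig:
    """Settings for the intensity-deviation baseline detector.

    background_quantile
        Quantile of image intensities taken as the background level.
    deviation_threshold
        Gray levels a pixel must deviate from background to be kept.
    padding_fraction
        Fractional padding added around each component's bounding box.
    min_area
        Minimum connected-component area (pixels) to yield an ROI.
    """

    background_quantile: float = 0.5
    deviation_threshold: float = 25.0
    padding_fraction: float = 0.10
    min_area: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_quantile <= 1.0):
            raise ValueError("background_quantile must be in [0, 1]")
        if not (0.0 <= self.padding_fraction < 1.0):
            raise ValueError("padding_fraction must be in [0, 1)")
        if self.deviation_threshold < 0 or self.min_area < 0:
            raise ValueError("thresholds must be non-negative")


# 8-connectivity: diagonal pixels belong to the same component.
_STRUCTURE = np.ones((3, 3), dtype=bool)


def detect_roi_baseline(
    image: GrayImage, config: DetectorConfig = DetectorConfig(), label: str = "object"
) -> list[ROIBox2D]:
    """Detect interest regions as padded boxes of intensity-deviating blobs.

    Pixels deviating from the background level (a configured intensity
    quantile) by more than ``deviation_threshold`` are grouped into
    8-connected components; each component with at least ``min_area`` pixels
    yields its padded bounding box, clipped to the image.  Boxes are sorted by
    component area (largest first) and scored by component area / box area.

    Never fails: if no component survives, a single whole-image ROI with
    score 0 is returned so the rest of the pipeline still runs.
    """
    arr = image.values.astype(float)
    background = float(np.quantile(arr, config.background_quantile))
    deviating = np.abs(arr - background) > config.deviation_threshold
    labels, n = ndimage.label(deviating, structure=_STRUCTURE)
    rois: list[tuple[int, ROIBox2D]] = []
    if n:
        areas = ndimage.sum_labels(deviating, labels, index=np.arange(1, n + 1))
        slices = ndimage.find_objects(labels)
        for comp_area, sl in zip(areas, slices):
            comp_area = int(comp_area)
            if comp_area < config.min_area or sl is None:
                continue
            r0, r1 = sl[0].start, sl[0].stop
            c0, c1 = sl[1].start, sl[1].stop
            pad_r = int(round((r1 - r0) * config.padding_fraction))
            pad_c = int(round((c1 - c0) * config.padding_fraction))
            box = ROIBox2D(
                r0=max(r0 - pad_r, 0),
                c0=max(c0 - pad_c, 0),
                r1=min(r1 + pad_r, image.height),
                c1=min(c1 + pad_c, image.width),
                label=label,
            )
            score = min(comp_area / box.area, 1.0)
            rois.append((comp_area, ROIBox2D(*box.as_tuple(), score=score, label=label)))
    if not rois:
        return [ROIBox2D(0, 0, image.height, image.width, score=0.0, label=label)]
    rois.sort(key=lambda t: -t[0])
    return [roi for _, roi in rois]


def load_roi_detections(path: str | Path) -> dict[str, list[ROIBox2D]]:
    """Load externally produced 2D detections.

    The interchange format is JSON lines, one record per image::

        {"image": "a.png", "height": 512, "width": 512,
         "boxes": [[r0, c0, r1, c1, score, label], ...]}

    Boxes follow the half-open convention and are validated against the
    declared image size.  An image with an empty box list maps to an empty
    list; callers fall back to a whole-image ROI.
    """
    detections: dict[str, list[ROIBox2D]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
        try:
            image_id = rec["image"]
            height, width = int(rec["height"]), int(rec["width"])
            boxes = rec["boxes"]
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: missing field {exc}") from exc
        parsed: list[ROIBox2D] = []
        for b in boxes:
            try:
                r0, c0, r1, c1 = (int(v) for v in b[:4])
                score = float(b[4]) if len(b) > 4 else 1.0
                lab = str(b[5]) if len(b) > 5 else "object"
                roi = ROIBox2D(r0, c0, r1, c1, score=score, label=lab)
                roi.validate_within(height, width)
            except (ValueError, TypeError, IndexError) as exc:
                raise ParseError(
                    f"{path}:{lineno}: bad box {b!r} for image {image_id!r}: {exc}"
                ) from exc
            parsed.append(roi)
        detections[image_id] = parsed
    return detections


def roi_iou2d(a: ROIBox2D, b: ROIBox2D) -> float:
    """Intersection-over-union of two 2D boxes (0 when disjoint)."""
    ir = max(0, min(a.r1, b.r1) - max(a.r0, b.r0))
    ic = max(0, min(a.c1, b.c1) - max(a.c0, b.c0))
    inter = ir * ic
    union = a.area + b.area - inter
    return inter / union if union else 0.0
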