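"""Segmentation performance assessment: DSC, IoU, FN and FP rates.

For a detected region T and ground-truth region G (binary masks of equal
shape):

    DSC = 2|T n G| / (|T| + |G|)
    IoU = |T n G| / |T u G|
    FN  = |G \\ T| / |G|        (ground-truth pixels missed)
    FP  = |T \\ G| / |G|        (spurious pixels, relative to truth area)

Both FN and FP are normalized by the ground-truth area.  When both masks are
empty, DSC and IoU are defined as 1 (perfect agreement on absence); FN/FP are
undefined for an empty ground truth and signalled as an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import SegMask

__all__ = [
    "EvalRecord",
    "dsc",
    "mask_iou",
    "fn_rate",
    "fp_rate",
    "evaluate",
    "write_report",
]


@dataclass(frozen=True)
class EvalRecord:
    """Per-image metric row (FN/FP are NaN when the truth mask is empty)."""

    image_id: str
    iou: float
    dsc: float
    fn: float
    fp: float


def _counts(T: SegMask, G: SegMask) -> tuple[int, int, int]:
    if T.values.shape != G.values.shape:
        raise ValueError(
            f"mask shapes differ: {T.values.shape} vs {G.values.shape}"
        )
    t = T.values.astype(bool)
    g = G.values.astype(bool)
    return int((t & g).sum()), int(t.sum()), int(g.sum())


def dsc(T: SegMask, G: SegMask) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    inter, nt, ng = _counts(T, G)
    if nt + ng == 0:
        return 1.0
    return 2.0 * inter / (nt + ng)


def mask_iou(T: SegMask, G: SegMask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    inter, nt, ng = _counts(T, G)
    union = nt + ng - inter
    if union == 0:
        return 1.0
    return inter / union


def fn_rate(T: SegMask, G: SegMask) -> float:
    """Fraction of ground-truth pixels missed by the detection."""
    inter, _, ng = _counts(T, G)
    if ng == 0:
        raise ValueError("FN rate undefined for an empty ground-truth mask")
    return (ng - inter) / ng


def fp_rate(T: SegMask, G: SegMask) -> float:
    """Spurious detected pixels as a fraction of the ground-truth area."""
    inter, nt, ng = _counts(T, G)
    if ng == 0:
        raise ValueError("FP rate undefined for an empty ground-truth mask")
    return (nt - inter) / ng


def evaluate(
    predictions: dict[str, SegMask],
    truths: dict[str, SegMask],
    pooled: bool = False,
) -> tuple[list[EvalRecord], EvalRecord, list[str]]:
    """Score a collection of predicted masks against ground truth.

    Returns per-image records, a summary row (id "MEAN") and the list of ids
    skipped for lack of a counterpart mask.  By default the summary is the
    unweighted mean of the per-image metrics; with ``pooled=True`` the four
    metrics are instead computed once over the concatenated pixels of all
    images.
    """
    records: list[EvalRecord] = []
    skipped = sorted(set(predictions) ^ set(truths))
    pool = np.zeros(3, dtype=np.int64)
    for image_id in sorted(set(predictions) & set(truths)):
        T, G = predictions[image_id], truths[image_id]
        inter, nt, ng = _counts(T, G)
        pool += (inter, nt, ng)
        try:
            fn, fp = fn_rate(T, G), fp_rate(T, G)
        except ValueError:
            fn = fp = math.nan
        records.append(
            EvalRecord(image_id, iou=mask_iou(T, G), dsc=dsc(T, G), fn=fn, fp=fp)
        )
    if pooled:
        inter, nt, ng = (int(v) for v in pool)
        union = nt + ng - inter
        mean = EvalRecord(
            "MEAN",
            iou=inter / union if union else 1.0,
            dsc=2 * inter / (nt + ng) if nt + ng else 1.0,
            fn=(ng - inter) / ng if ng else math.nan,
            fp=(nt - inter) / ng if ng else math.nan,
        )
    elif records:
        mean = EvalRecord(
            "MEAN",
            iou=float(np.mean([r.iou for r in records])),
            dsc=float(np.mean([r.dsc for r in records])),
            fn=float(np.nanmean([r.fn for r in records])),
            fp=float(np.nanmean([r.fp for r in records])),
        )
    else:
        mean = EvalRecord("MEAN", math.nan, math.nan, math.nan, math.nan)
    return records, mean, skipped


def write_report(
    records: list[EvalRecord], mean: EvalRecord, path: str | Path
) -> None:
    """Write the evaluation table as CSV: one row per image plus MEAN."""
    lines = ["image_id,iou,dsc,fn,fp"]
    for r in list(records) + [mean]:
        lines.append(f"{r.image_id},{r.iou:.6f},{r.dsc:.6f},{r.fn:.6f},{r.fp:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
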