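# cloudseg

Adaptive thresholding of grayscale images by **3D object detection in a
pixel-features point cloud**.

Objects in grayscale medical images (bone, lung fields, ...) occupy a
contiguous intensity band whose location shifts between devices and images,
which is why a single fixed threshold never generalizes.  `cloudseg` turns
every pixel (row r, col c, value v) of a 2D interest region into the 3D point
(x=c, y=r, z=v) and detects the object as an axis-aligned 3D box in that
cloud: the box shares the region's 2D footprint and is parameterized along
the grayscale axis by a center l_h and width l_w.  The box's top and bottom
are per-image thresholding values; pixels inside its footprint and interval
are the segmentation.

The detector is two-stage:

1. **Proposals** — anchors slide along the gray axis (stride 8, scales
   {64, 96, 128}); the points inside each anchor are classified by a
   point-set network (shared per-point MLP → max-pool global feature f_mp →
   FC head); NMS with volume-based 3D IoU,
   `IoU(A,B) = |A∩B| / (|A| + |B| − |A∩B|)`, keeps one proposal per class.
2. **Refinement** — per class, linear ridge models map f_mp to offsets
   applied as `Ĝ_lh = P_lw·d_lh + P_lh`, `Ĝ_lw = P_lw·exp(d_lw)` with targets
   `t_lh = (G_lh − P_lh)/P_lw`, `t_lw = log(G_lw/P_lw)`, fitted in closed
   form (regularized least squares).

A 2D interest-region stage (pluggable: built-in intensity baseline or any
external detector via a JSON file) crops the image first so in-band pixels
elsewhere cannot pollute the result.  Masks are scored with DSC
(`2|T∩G|/(|T|+|G|)`), IoU, FN and FP rates.  A seeded phantom generator
provides band-structured images with full ground truth, making every stage
trainable and testable offline; see `docs/methods.md` for the model details.

## Worked example

```python
import cloudseg as cs
from cloudseg.pipeline import PipelineConfig, run_training, segment_image
from cloudseg.synthetic import generate_dataset

cfg = PipelineConfig(seed=5)                   # 200 phantoms, default model
models, log = run_training(cfg)
held_out = generate_dataset(cfg.synth, 50, cfg.seed + 10007)

s = held_out[0]
result = segment_image(s.image, cfg, models, seed=1)
roi, (box,) = result.refined[0]
print(f"true band  [{s.gt_band[0]:.0f}, {s.gt_band[1]:.0f}]")
print(f"refined box [{box.z_lo:.1f}, {box.z_hi:.1f}]")
print(f"mask IoU   {cs.mask_iou(result.mask, s.gt_mask):.3f}")
```

prints

```
true band  [131, 187]
refined box [132.3, 183.1]
mask IoU   0.827
```

The refined box's interval lands on the phantom's generating band within a
few gray levels, and thresholding by it recovers the object mask.  Because
the generator perturbs in-band pixel values with N(0, 8) noise, even the
*true* band only reaches ~0.89 IoU on these phantoms; over the 50 held-out
images this run reaches mean IoU 0.887, with both refined band endpoints
within 10 gray levels of truth on 98% of them.

The same flow is available from the shell:

```bash
cloudseg synth --n 20 --out fixtures/        # phantoms + masks + manifest
cloudseg train --out ckpt/                   # classifier + regressors
cloudseg segment --models ckpt/ --out masks/ fixtures/images/*.png
cloudseg evaluate --pred masks/ --truth fixtures/masks/ --out report.csv
cloudseg inspect --models ckpt/ fixtures/images/sample_0000.png
```

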