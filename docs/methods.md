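# Methods

## The model

Grayscale segmentation targets (bone on radiographs being the canonical case)
occupy a contiguous intensity band: object pixels cluster in some interval
[z_lo, z_hi] of the 0–255 gray range, background sits below it, and the band's
location varies from device to device and image to image.  `cloudseg` treats
finding that band as a 3D object-detection problem.

Each pixel (row r, column c, value v) of a 2D interest region becomes the 3D
point (x=c, y=r, z=v) — the *pixel-features point cloud*, a bijection with the
region's pixels.  An axis-aligned 3D box sharing the region's 2D footprint is
parameterized along the grayscale axis by its center `l_h` and width `l_w`;
its closed interval [l_h − l_w/2, l_h + l_w/2] acts as a pair of thresholding
values.  Segmentation is then:

1. **Interest region (2D).**  A detector proposes scored 2D boxes around the
   object so that in-band pixels elsewhere in the image cannot contaminate the
   result.  The built-in baseline estimates the background level as an
   intensity quantile, keeps pixels deviating by more than a threshold, and
   returns padded bounding boxes of large connected components.  Any external
   detector can be substituted through a JSON-lines detection file.
2. **Proposal stage (3D).**  Anchors slide along the grayscale axis (stride 8
   gray levels) at three scales; the points inside each anchor are subsampled
   to a fixed count, normalized to the anchor's frame, and classified by a
   point-set network (shared per-point MLP 3→64→128→256, max-pool to the
   global feature `f_mp`, fully connected head).  Non-maximum suppression with
   volume-based 3D IoU keeps one proposal per candidate class.
3. **Refinement.**  Per class, two linear ridge models map `f_mp` to the
   offsets d_lh (scale-invariant center shift) and d_lw (log width change):
   Ĝ_lh = P_lw·d_lh + P_lh, Ĝ_lw = P_lw·exp(d_lw).  Training targets are
   t_lh = (G_lh − P_lh)/P_lw and t_lw = log(G_lw/P_lw); the penalized
   least-squares problem is solved in closed form (normal equations, features
   standardized with training statistics, intercept appended and unpenalized).
   An SGD fit of the same objective exists purely as a cross-check path.
4. **Back-projection.**  Pixels inside the refined box's footprint whose value
   lies in its closed interval form the binary mask; multiple regions /
   classes are unioned.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| anchor stride | 8 gray levels | spacing of anchor centers on [0, 255] |
| anchor scales | {64, 96, 128} | candidate band widths (gray levels) |
| n_max | 256 | points per box fed to the network |
| score/IoU threshold | 0.5 / 0.5 | proposal acceptance and NMS suppression |
| ridge λ | 1.0 | L2 penalty on standardized features |
| classifier schedule | lr 1e-3 ×20 epochs, then 1e-4 ×20 | two-stage Adam training |
| pos/neg anchor IoU | 0.5 / 0.2 | gray-interval IoU labelling thresholds |

The anchor scales deserve a note: the smallest scale is chosen to be at least
the typical band width.  A proposal strictly *narrower* than the band is
completely filled with points and its point set carries no information about
where the band edges lie outside it, so the linear refinement can only apply
an average correction.  A proposal that *contains* the band sees both edges as
density boundaries inside its normalized frame, which is what makes the
refinement regressor accurate.  With narrow scales included (e.g. 32 when
bands are ~60 wide) the saturated classifier scores let interior anchors win
NMS and held-out band recovery degrades substantially; this was measured, and
is why 64 is the smallest default scale.  For data whose bands are much
narrower or wider, rescale `anchor_scales` accordingly — they are plain
config values.

Classifier scores are softmax probabilities and saturate near 1 on easy
anchors, so the NMS ranking among several good anchors is weakly informative;
the refinement stage, not proposal ranking, is responsible for metric
accuracy.

## The phantom generator

Training and evaluation run on seeded phantoms that emulate the structure the
method exploits: a dark noisy background (mean 40, sd 8), one or more bright
ellipses/rectangles whose pixels are drawn uniformly from a gray band
(default [140, 200]) and perturbed by the same Gaussian noise, and 50
in-band distractor pixels scattered strictly outside the interest region —
the failure mode that motivates the 2D stage, since plain whole-image
thresholding picks all of them up.  Across a dataset the band center jitters
by ±15 gray levels, the width by ±5 and the object size by ±5%, emulating
device-to-device intensity variation; per-image band recovery is therefore a
real inference task, not a constant.

What the phantoms do *not* emulate: anatomical texture (object pixels are
i.i.d. within the band, real tissue has spatial intensity gradients),
overlapping structures, scatter/beam-hardening artifacts, or 16-bit dynamic
range.  Passing the synthetic study shows the detection-and-refinement
machinery recovers generating parameters under the band model; it does not
certify performance on any clinical dataset.

Because band values are perturbed by N(0, 8) noise, roughly 11% of object
pixels fall outside their own generating band; even thresholding with the
*true* band tops out near 0.89 mask IoU on default phantoms.  That ceiling,
not the detector, bounds the achievable score at the default noise level.

## Numerical choices and degenerate inputs

* Grayscale intervals are closed on both ends (a pixel equal to a threshold
  belongs to the object); 2D boxes are half-open, 0-based, row-major.
* `clip_box` floors degenerate intervals at one gray level centered on the
  clipped `l_h`, so a wild regression output can never produce an empty box.
* Empty anchors are background by definition (the classifier never sees
  them); an empty proposal box is returned unrefined with a warning.
* Point sets larger than `n_max` are subsampled uniformly without replacement
  under a seed; smaller ones are padded cyclically (max-pooling makes
  duplicates harmless).
* Point normalization maps footprint corner pixels to ±1 and the box interval
  to [−1, 1]; half-extents are floored at half a pixel / half a gray level to
  avoid division by zero on 1-pixel footprints.
* The ridge system uses an unpenalized intercept; at λ=0 a singular normal
  matrix raises an error advising λ>0.  A class with no training pairs gets a
  zero-weight (identity) regressor.
* NMS ties are broken by lower candidate index; suppression runs within a
  class only, and only the top survivor per class is emitted.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed; reruns are bit-identical.

## Open design points, resolved

* Pixels with value 0 are kept in the cloud (the bijection is unconditional);
  dropping them would silently bias background anchors.
* All detected interest regions are processed and their masks unioned; when
  two classes' gray intervals both claim a pixel, binary output unions them.
* FN and FP rates are both normalized by the ground-truth area.
* Per-image metrics are averaged unweighted; a pooled-pixel mode is a flag.
* Evaluation metrics are computed per image then averaged; training from real
  image/mask pairs estimates the band as the 1st–99th percentile range of
  object-pixel intensities (robust to mask-rim annotation noise).
* The study sizes used throughout (200 training phantoms, 50 held-out, 128²
  images, 256-point sets) are the package's desk-scale defaults; they keep a
  full train-and-evaluate cycle in the minutes range on one CPU while leaving
  every stage statistically meaningful.

## Known limitations

* One box per class per region: two disjoint gray bands of the *same* class
  in one region cannot both be kept.
* The linear refinement extrapolates poorly to band widths far outside the
  training jitter range.
* The baseline 2D detector assumes the object deviates from a roughly
  unimodal background; it is a stand-in for a real 2D detector, not a
  contribution.
* No 16-bit/DICOM windowing, no multi-channel input.
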