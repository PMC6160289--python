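# Methods

This note records the models, parameter choices and numerical conventions
behind `canopycenter`, and what the synthetic benchmark does and does not
establish about real field imagery.

## Pipeline model and assumptions

The pipeline assumes a single young maize plant per frame, viewed from
above, on a soil background whose hue is well below the vegetation window,
with weeds that may match the canopy's colors but are smaller than the
plant. Under those assumptions the four stages are each justified by one
structural property:

* the **HLS window** (35 < H < 99 on the half-degree hue scale, L and S
  strictly inside (0, 255)) relies on soil being brown (hue ≪ 70°) and all
  vegetation being green-to-blue. The strict bounds are kept exactly as
  conventionally printed; they exclude fully black and fully saturated
  pixels, which in practice removes deep shadow.
* the **linear SVM** relies on the canopy central region being blue-shifted
  and more saturated than the surrounding leaves, so ROI and N-ROI pixel
  clouds are linearly separable in raw (H, L, S). Features are deliberately
  unscaled: the penalty C = 0.1 is calibrated on the raw 8-bit scale, and
  standardizing the features would silently change its meaning. A
  kernel-width parameter is accepted in the config for interface
  completeness but ignored by the linear kernel.
* **area filtering** relies on the ROI being the largest surviving
  component ("keep-largest", the default). Frames with several plants
  would need the `min-area` policy instead; this is a user decision the
  method itself cannot make.
* **center detection** relies on the gradient law. The absolute threshold
  T = 30 presupposes exposure control; an optional adaptive mode
  (`min gray in ROI + T`) compensates global lighting shifts and is off by
  default.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| HLS window | (35, 99) × (0, 255) × (0, 255) | half-deg / 8-bit | vegetation hue span 70°–198° |
| SVM penalty C | 0.1 | – | onset of the CV-score plateau; smaller C underfits, larger only adds variance |
| training pixels | 100 (50/50) | pixels | learning curve flattens by this size; interpreted as a *total* (the per-class reading is the config's `sample_size` ÷ 2) |
| CV folds | 4 | – | standard for 100 samples; stratified with a fixed seed |
| connectivity | 8 | – | leaves touch diagonally |
| erosion kernel / passes | 3×3 ones, 1 pass | – | one pass removes the ragged one-pixel boundary; more passes shrink the ROI and cost Qseg |
| gray threshold T | 30 | gray | whorl gray concentrates in 0–30 |
| isohypse levels | multiples of 15 up to 255 | gray | 17-band visualization convention |
| center tolerance | 20 px at 1242×931 | px | recognition band; scaled by image diagonal for other frame sizes |

## Numerical conventions

* Hue is stored as an integer on [0, 180) (2° steps). The float RGB↔HLS
  transforms are exact inverses (≈1e−12); the *integer* round trip can move
  a saturated channel by up to 255/60 per degree of hue quantization plus
  L/S rounding, so its error is bounded by ±6, not by ±2 — the property
  test asserts the honest bound.
* Gray is BT.601 luma, rounded to nearest.
* Erosion treats out-of-image neighbors as background (regions shrink at
  the frame border) — the conservative choice for a region detector.
* Band intervals are half-open [low, high) with the final band closed at
  255; achromatic pixels get hue 0.
* Area-filter ties are broken by the smallest scan-order label; the
  decision boundary itself (f = 0) is assigned to the ROI class; centroid
  coordinates are rounded to the nearest pixel.
* `cross_validate_C` returns the smallest grid value within 1e−6 of the
  maximum mean score (the plateau onset), not the argmax, so the choice is
  stable on a flat plateau.
* Mean ROC across folds is vertical averaging on a 101-point FPR grid;
  per-fold AUC uses the trapezoidal rule on the full threshold sweep.
* Qseg of two empty masks is 1 (perfect agreement on absence); the summary
  SD is population SD by default (`sample_sd=True` switches).

## The synthetic generator

`synthetic_fixtures` renders scenes luma-first: each pixel's RGB is a
target gray level times a hue-dependent unit-luma direction, so the
gradient law gray(r) = floor + slope·r holds exactly before noise and hue
is independent of brightness. Defaults: 256×256 frames, canopy radius
80 px (ROI disc = 0.30 of it), gray floor 8, slope 1.5 gray/px, periphery
hue uniform(45, 75) with 30% white admixture, whorl hue uniform(80, 98)
with 10% admixture (more saturated), weeds hue uniform(40, 95) — chosen to
straddle both canopy regions so some weeds survive the SVM and exercise
the area filter — with 30% of weeds overlapping the canopy boundary.

Two modeling choices deserve explanation:

* **Illumination offset is multiplicative.** The offset parameter (±20
  gray levels at mid-tone) is applied as a gain (128 + offset)/128 rather
  than an additive shift. Physically, a brighter scene scales radiance;
  and an additive +20 would lift the whorl floor to ≥28 and erase the
  sub-30 region *by construction*, which is a statement about the
  arithmetic of the fixture, not about the method.
* **Noise is photon-limited.** Per-channel Gaussian noise has
  sd = noise_sd·√(luma/255) (floor 0.1·noise_sd), with `noise_sd` the
  full-scale sd. A signal-independent sd is sensor-unrealistic and has an
  outsized effect exactly at the dark whorl, where chroma is only a few
  counts and hue becomes meaningless under constant-sd noise.

The study conditions used by the benches draw canopy radius uniform
(40, 120) px, illumination offset uniform(−20, 20), weed count uniform
{0..8} and noise sd uniform(0, 5). *Hard mode* replaces weed blobs with
decoy rosettes of 0.8–1.05× the canopy radius and identical color
statistics; it exists to verify graceful failure, not recovery.

What the generator does **not** emulate: motion blur, specular leaf
highlights, cast shadows with colored penumbrae, overlapping plants,
soil texture/residue, JPEG artifacts, and hue-correlated texture within a
leaf (hue is drawn i.i.d. per pixel). Passing the synthetic benches
therefore demonstrates the pipeline's logic — stage contracts, parameter
recovery, robustness ordering — not field-level accuracy; absolute Qseg
and recognition values on real imagery depend on camera and conditions the
generator does not model.

## Problem sizes

Benches run at 256×256 with 50–200 fixtures per check and a classifier
trained once on three default fixtures (100 pixels total). These sizes were
fixed as the desk-scale study design; the recognition tolerance is scaled
from the 20 px band at the 1242×931 reference frame by image diagonal
(≈4.7 px at 256×256), so the end-to-end recognition criterion is *tighter*
per pixel than at full frame size.

## Known limitations

* Keep-largest area filtering drops all but one plant in multi-plant
  frames.
* The absolute T = 30 threshold fails under strong global lighting shifts
  unless the adaptive mode is enabled.
* The SVM is trained on fixture-derived candidate regions; applying the
  model to imagery with a different camera response requires retraining
  (the CLI `train` command accepts any directory of labeled frames).
* Sub-pixel center refinement and temporal tracking across video frames
  are out of scope; frames are independent.
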