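# canopycenter

Machine-vision recognition of the **maize canopy center** in top-down RGB
images, for precision-weeding equipment and plant-phenotyping pipelines
that must locate young plants against a background of similarly colored
weeds.

Locating a crop plant is easy when it is the only green thing in the frame
and hard when it is not: color indices that separate vegetation from soil
cannot separate the plant from green weeds. This package implements a
multi-level segmentation strategy that exploits two structural properties
of a young maize plant seen from above — the blue-shifted, highly saturated
color of the whorl region relative to the surrounding leaves, and the
*gradient law*: gray level increases monotonically from the canopy center
outward, with the whorl concentrated below gray level 30.

## Method

For an RGB frame `I(x, y)` the pipeline runs four stages:

1. **Global segmentation (HLS mask).** Convert to HLS (hue on the 0–180
   half-degree scale) and keep pixels strictly inside the window

   `Mask_hls(x,y) = 1  iff  35 < H < 99, 0 < L < 255, 0 < S < 255`

   which passes green-through-blue vegetation (hue angles 70°–198°) and
   rejects brown soil. The vegetation region is `ROI∪N-ROI = I · Mask_hls`.

2. **Local segmentation (linear SVM).** A soft-margin linear SVM over raw
   per-pixel `(H, L, S)` features, `f(x) = sign(Σᵢ aᵢ yᵢ (xᵢ·x) + b)`,
   separates the canopy central region (ROI, +1) from surrounding leaves
   (N-ROI, −1). Defaults follow the standard calibration: penalty
   `C = 0.1` (plateau onset of the 4-fold cross-validation score curve)
   and 100 training pixels (50 per class).

3. **Post-processing.** Weed blobs that share the ROI's colors survive the
   SVM but are spatially isolated; connected-component area filtering
   (keep-largest by default) removes them, and one pass of binary erosion
   with the 3×3 all-ones structuring element smooths the ROI boundary.

4. **Center recognition (gray gradient).** The ROI's gray image (BT.601
   luma) is thresholded at `T = 30` (strict); the centroid of the largest
   sub-threshold component is the canopy center. The 17-band isohypse
   quantization (cut points at multiples of 15) and a ring-mean radial
   monotonicity check are provided as gradient-law diagnostics.

Evaluation utilities implement `Qseg`, the intersection-over-union
segmentation-quality factor `|A∩B| / |A∪B|`, reported as mean ± SD percent
over an image set, and the **recognition rate**: the percentage of frames
whose detected center falls within a pixel tolerance of the truth center
(20 px at a 1242×931 reference frame, scaled by image diagonal).

Because no field dataset is distributable, the package ships a seeded
synthetic canopy generator (`synthetic_fixtures`) that reproduces the
structure above — leaf rosette, radial gray gradient with a dark whorl,
hue-split canopy, confusable weed blobs, photon-limited sensor noise — with
full ground truth, so every stage is testable end to end.

## Worked example

```python
import canopycenter as cc

# train once on three default synthetic canopies
train_fixtures, _ = cc.generate_dataset(3, ranges={}, seed=42)
model = cc.train_from_fixtures(train_fixtures)

# analyze one new frame
img, truth = cc.generate_canopy_image(cc.FixtureParams(seed=7))
result = cc.run_pipeline(img, model)

print("vegetation pixels (HLS mask):", result.diagnostics["hls_pixels"])
print("ROI pixels (SVM mask):      ", result.diagnostics["svm_pixels"])
print("ROI pixels (post-processed):", result.diagnostics["post_pixels"])
print("detected center:", (result.center.center.x, result.center.center.y))
print("true center:    ", (truth.center.x, truth.center.y))
print("Qseg vs truth ROI: %.3f" % cc.qseg(result.post_mask, truth.roi))
```

prints

```
vegetation pixels (HLS mask): 14285
ROI pixels (SVM mask):       1827
ROI pixels (post-processed): 1581
detected center: (130, 134)
true center:     (130, 134)
Qseg vs truth ROI: 0.875
```

The HLS window discards ~78% of the 256×256 frame as soil, the SVM keeps
the ~1.8k-pixel canopy central region, post-processing trims the boundary,
and the detected center lands on the true whorl position; the
post-processed mask overlaps the truth ROI with Jaccard quality 0.875.

The same workflow is available from the shell:

```
canopy make-fixtures fixtures/ -n 10 --seed 3
canopy train fixtures/ -o model.txt
canopy run fixtures/ -m model.txt -o out/
```

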