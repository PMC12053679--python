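# gelband

Segmentation-based quantitation of gel-electrophoresis bands.

Gel electrophoresis remains the bench workhorse for separating and
semi-quantifying nucleic acids and proteins, but the conventional analysis
path — extract a lane, collapse it to a 1-D intensity profile, integrate
peaks between hand-tuned baselines — is tedious and fragile for warped,
faint or crowded bands.  `gelband` takes the segmentation view instead:
classify every pixel as *band* or *background*, treat each connected band
as a 2-D object, and quantify it directly.  The package is aimed at wet-lab
scientists and image-analysis developers who want a scriptable,
reproducible gel pipeline with exact synthetic benchmarks.

## What it does

* **Segment** — two classical baselines (three-class Otsu thresholding,
  found by exact maximisation of the between-class variance
  `argmax Σ_k w_k μ_k²` over all threshold pairs, and marker-based
  watershed over a Sobel gradient-magnitude elevation map) plus a trainable
  encoder–decoder network (U-Net topology with a resnet18-pattern encoder,
  implemented from scratch in NumPy with analytic backpropagation).
* **Quantify** — band volume `V = Σ_{(r,c) ∈ band} I(r,c)` with optional
  background correction: global patch mean, local surround mean, or
  rolling-ball (grayscale opening by a ball-shaped structuring element).
* **Organise** — rule-based lane clustering from band centroids (gated by
  half the median band width, merged at a third of it), split-band
  detection (MAD width outliers or vertical proximity under half the median
  band height) and convex-hull repair.
* **Evaluate** — Dice, precision/recall, Hausdorff distance, per-band
  accuracy with the split-band zero rule, and the hold-out regression
  protocol: per lane, hide 5 bands, fit `mass = a·V + b` on the rest,
  predict the hidden masses, average the absolute percentage error over 80
  re-randomised repeats.  Methods are compared with a paired two-sided
  t-test.
* **Simulate** — a seeded synthetic-gel generator with exact instance
  ground truth and per-band true masses, so every stage can be scored
  against a known answer.

## Worked example

```python
import numpy as np
from gelband import (SyntheticGelSpec, generate_gel, label_bands, cluster_lanes,
                     measure_bands, holdout_regression_error, watershed_segment,
                     dice_score)
from gelband.io import SegmentationMask

gel = generate_gel(SyntheticGelSpec(seed=7))          # 6-lane ladder gel
bands = label_bands(SegmentationMask(gel.class_mask)) # ground-truth bands
lanes = cluster_lanes(bands)
print(f"{len(bands)} bands in {len(lanes)} lanes")

volumes = {m.label: m.corrected_volume
           for m in measure_bands(gel.image, bands, method="rollingball")}
truth = gel.band_truth.set_index("label")
def mass_of(b):
    ov = gel.truth_mask[b.pixel_rows, b.pixel_cols]
    return truth.loc[int(np.bincount(ov[ov > 0]).argmax()), "mass"]

lane0 = lanes[0]
v = np.array([volumes[b.label] for b in lane0.bands])
m = np.array([mass_of(b) for b in lane0.bands])
res = holdout_regression_error(v, m, rng=np.random.default_rng(0))
print(f"lane 0 hold-out mass-prediction error: {res.mean_pct_error:.2f}%")

ws = watershed_segment(gel.image)
print(f"watershed Dice vs ground truth: {dice_score(ws, gel.class_mask):.3f}")
```

prints

```
60 bands in 6 lanes
lane 0 hold-out mass-prediction error: 2.35%
watershed Dice vs ground truth: 0.277
```

Ten bands per lane in six lanes are recovered and clustered perfectly; with
rolling-ball-corrected volumes the regression predicts hidden band masses
to about 2% on this gel; the watershed baseline struggles on the same image
(its background-gradient blindness is exactly the weakness the trainable
segmenter addresses — a width-reduced network trained for 20 epochs on 30
such gels reaches a test Dice around 0.94 versus roughly 0.2 for
watershed).

A command-line interface mirrors the library:

```bash
gelband simulate --n 30 --seed 7 --out gels/
gelband segment  --image gels/gel_000.tif --method watershed --out pred.tif
gelband quantify --image gels/gel_000.tif --mask pred.tif --background rollingball --out bands.csv
gelband lanes    --image gels/gel_000.tif --mask pred.tif --repair --out lanes.csv
```

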