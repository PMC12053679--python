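# Methods

This note records the models, conventions and numerical choices behind
`gelband`, in the spirit of a package reference manual: what each stage
assumes, which parameters matter, and what the synthetic benchmarks do and
do not demonstrate.

## Conventions

Coordinates are `(row, col)`, 0-based, origin top-left; rows increase in
the direction of band migration.  Images are kept at their native bit depth
(8- or 16-bit unsigned) and are never rescaled on load; every algorithm
that needs normalised intensities divides by the maximum representable
value (255 or 65535).  Class masks are binary (0 background, 1 band);
instance masks use consecutive positive integer labels.  Band instances are
8-connected components everywhere — a single connectivity convention avoids
disagreements between labelling, metrics and lane rules.

## Synthetic gel generator

The generator emulates ladder-calibration gels: `n_lanes` lanes each carry
the same ladder of bands at fixed migration rows, and each band contributes
`amplitude_per_ng · mass · G(r, c)` where `G` peaks at 1, is Gaussian along
rows (σ_r, default 2.5 px), flat-topped across the lane width (default
28 px) with Gaussian shoulders (σ_c, default 3 px), and can be displaced by
a symmetric sinusoidal row-warp ("band smiling", default amplitude 1.5 px).
On top go a vertical linear background gradient (default offset 20,
top-to-bottom rise 15 intensity units), optional global blur (σ 0.6 px) and
additive Gaussian sensor noise (σ 2), then clipping and integer
quantisation.

The ground-truth mask marks pixels where a band's noiseless term exceeds
2% of its peak.  The band/background boundary on real gels is ultimately a
judgement call, so the generator fixes one and exposes it
(`boundary_frac`); with the Gaussian row profile roughly 1–2% of a band's
integrated signal falls outside its own mask, which sets the floor for any
mask-based volume measurement ("truncation error", measured at −1.15% under
the defaults).

The default ladder has 10 bands whose per-band loaded masses span
25–200 units — about one decade, the spread found in commercial DNA ladder
mass tables.  The default migration rows compress toward the gel bottom as
log-molecular-weight migration does, leaving ~16 px between the last bands.

`generate_quantitation_set` emulates a calibration experiment: per-lane
loading factors uniform in [0.5, 1.5] scale the true masses, and per-gel
jitter varies overall amplitude (×[0.7, 1.3]), noise (×[0.5, 1.5]) and warp
(×[0, 2]), standing in for variable loading, exposure and gel quality.
Degradations (`faint`, `blurry`, `torn`, `contaminant`) reproduce the
qualitative failure modes of difficult real gels.

What the generator does **not** model: camera vignetting and fixed-pattern
noise, PAGE-specific artefacts, saturated smears, well ghosts, and lane-to-
lane cross-talk.  Tests passing on these synthetics therefore demonstrate
algorithmic correctness and calibration behaviour, not performance on
arbitrary real gels.

## Classical segmentation

Both baselines start from the same three-class Otsu analysis of the
normalised histogram (256 bins over the image's value range).  The
implementation maximises the between-class variance over **all** boundary-
bin pairs using cumulative moments, which is exact; ties resolve to the
lexicographically first pair.  Thresholds are reported as the *upper edge*
of the boundary bin, so "intensity strictly above the foreground threshold"
selects exactly the upper histogram class — reporting bin centres (as some
libraries do) lets pixels in the boundary bin's upper half leak across the
threshold.

Thresholding assigns band to every pixel above the foreground threshold.
The watershed variant instead treats the pixels between the two thresholds
as unknown: markers are the definite background (strictly below the lower
threshold) and definite band (strictly above the upper) pixels, the
elevation map is the Sobel gradient magnitude, flooding uses
8-connectivity, and lone background regions enclosed by band pixels are
filled afterwards (binary hole fill, 4-connected background).  Equal-logit
and boundary-equal pixels always fall on the conservative (background or
unknown) side.

## Band quantitation and background correction

A band's volume is the plain sum of raw intensities over its pixel set.
Three corrections are offered; all subtract an estimated background *per
pixel* before summation and none clips negative results (clipping would
bias method comparisons):

* **global** — mean of a user-chosen (or automatically located band-free)
  rectangular patch; exact on uniform backgrounds, systematically wrong
  under gradients.
* **local** — mean of the ring obtained by dilating the band by
  `ring_width` and removing the band and all other bands.  The default
  width is 10 px: the ring must reach beyond the band's own sub-threshold
  shoulders (decay length ≈ 3σ_c ≈ 9 px under the generator defaults) or it
  over-subtracts; a 5 px ring measurably biases volumes by ≈ −1.5%
  beyond the truncation floor, a 10 px ring by ≈ −1%.
* **rolling ball** — grayscale opening with a ball-shaped (non-flat)
  structuring element, radius 50 px by default; the classic shrink-by-
  ratio speed-up (factors 2/4/8 above radii 10/30/100) block-minimises the
  image, opens at reduced radius and bilinearly re-expands, capped at the
  image.  A constant image is reproduced exactly (sub-1e-6 interpolation
  jitter is snapped away); planes are invariant under the opening, so
  linear gradients are estimated without bias.

Mask perturbation (`dilate`/`erode`, 3×3 element) reproduces the
segmentation-boundary sensitivity analysis: volumes are ordered
erode ≤ raw ≤ dilate on non-negative images, and on clean gels the 1-px
perturbation shifts the hold-out regression error by ≲0.1 percentage
points — an order of magnitude below the spread induced by 5% volume noise.

## Lane identification and split-band repair

From all band centroids and the median bounding-box width/height: each band
is linked to its nearest neighbour (Euclidean centroid distance) among
bands whose horizontal centroid distance is strictly less than half the
median width; links are merged with union-find; groups whose mean centroid
columns differ by less than a third of the median width merge further
(iterated to closure).  Lanes number left-to-right, bands top-to-bottom.
Thresholds are strict inequalities; "median average deviation" is read as
the median absolute deviation (MAD), with split candidates flagged either
when two consecutive bands are both low-width MAD outliers (k = 2,
low side only — fragments are narrower, never wider) or when their vertical
centroid distance is under half the median band height.  Repair fills the
convex hull of the union of the two fragments' pixel sets; band pixels are
never removed.

## Trainable segmenter

The network is a U-Net-topology encoder–decoder: a stem convolution, four
down-sampling stages of basic residual blocks (resnet18 channel pattern
64/128/256/512, two blocks per stage, stride-2 first block with 1×1
projection skip), nearest-neighbour upsampling decoder with skip
concatenation and two ConvBNReLU blocks per stage, and a 2-channel 1×1
head (background, band).  `width_multiplier` scales every channel count
(desk-scale experiments use 1/8, ≈ 2.3 × 10⁵ parameters, versus
≈ 1.4 × 10⁷ at full width).  The implementation is pure NumPy with
hand-derived backpropagation for every layer; gradients were verified
against central finite differences in float64 to < 1e-8 relative error.

Training recipe: combined loss `0.5·(1 − soft-Dice) + 0.5·CE` on the
softmax band probability (Dice smoothing ε = 1e-6, aggregated over the
whole batch), Adam (default moments), batch size 2, cosine annealing with
warm restarts from 1e-4 down to 1e-7 with a 100-epoch restart period,
random augmentation (flip p = 0.5; rotation p = 0.5 as a 90° multiple plus
a ±15° residual; blur, additive noise, downscale–upscale and
quantisation-style compression artefacts each p = 0.2, severities capped so
band/background contrast never drops by more than about half), per-epoch
validation Dice on un-augmented, crop-backed predictions, and best-epoch
selection by validation Dice.  Inputs are normalised, then symmetrically
zero-padded to a square whose side is the smallest multiple of 32 covering
the largest dimension (odd pads go bottom/right); at train time each batch
pads to its own maximum (a `global_pad` flag restores dataset-wide
padding).  Encoder weights are randomly initialised (He-normal, seeded);
prediction is per-pixel argmax with ties to background.  Fine-tuning reuses
the same loop for 11 epochs with augmentation restricted to flips and
rotations.

Early training shows a characteristic transient: the class-imbalanced loss
first collapses predictions to all-background (validation Dice dips toward
zero) before band structure emerges; desk-scale experiments must train past
this phase (≳ 10 epochs at the sizes below) before comparisons are
meaningful.

Percentile normalisation (clip at the 0.1/99.9 percentiles, then affine map
to [0, 1]) is available at inference for images whose exposure range
differs from the training distribution.

## Evaluation protocols

Whole-image metrics: Dice 2|P∩T|/(|P|+|T|) (1 when both masks are empty),
pixel precision and recall (precision undefined — `None` — for an empty
prediction), and the symmetric Hausdorff distance between band boundary
pixels (4-neighbourhood boundary, Euclidean metric).  Per-band accuracy
scores each ground-truth band by 100·|T∩P|/|T| against the single predicted
instance overlapping it; overlap by two or more predicted instances — a
split detection — scores 0%, as does no overlap.  A variant with the
predicted-pixel denominator is available and reports are expected to name
the variant in use.

Hold-out regression: per lane, 5 bands are hidden (sampled without
replacement, independently re-randomised across 80 repeats; duplicate
hold-out sets across repeats are allowed), `mass = a·volume + b` is fitted
by ordinary least squares on the rest, and the repeat error is the mean
absolute percentage error of the hidden-mass predictions.  Mass is
regressed on volume (predicting mass from signal); the error is invariant
under affine rescaling of all volumes.  Lanes with fewer than
`n_holdout + 2` usable bands are excluded from the analysis entirely and
counted, to avoid biasing comparisons.  Paired per-lane errors are compared
with a classic paired-samples two-sided t-test; zero-variance differences
return an undefined-statistic flag rather than a number.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at sizes chosen to make every check sharp on one CPU: 50 random 32×32
images for the threshold oracle; 20 gels of 128×128 plus one 32×32 toy for
the watershed contract; 100 random 16×16 mask pairs for metric fidelity;
5 background-free 16-bit gels (30 lanes) plus 100 resampled lanes per noise
level for quantitation recovery; two seeded uniform-background 16-bit gels
for correction fidelity (16-bit so that sensor quantisation, which dominates
the faintest 8-bit bands, does not mask the property under test); 30 gels
of 192×192 with a width-1/8 network trained 20 epochs for the learned-vs-
classical comparison; 100 random grid layouts and 100 injected splits for
the lane tools.  Unit tests use 64×64 gels and a width-1/16 network.

## Known limitations

* The NumPy network trains at CPU desk scale; the full-width, 600-epoch
  regime of GPU practice is out of reach here, so learned-segmentation
  results demonstrate the training machinery and the ordering against
  classical baselines, not attainable real-data accuracy.
* Local background correction still carries a ≈1% negative bias from the
  band's own sub-threshold shoulders; no correction method can beat the
  mask-truncation floor.
* Lane clustering assumes approximately vertical lanes; strongly rotated
  or curved gels need rectification first.
* The rolling-ball shrink approximation departs from the exact opening for
  structures near the block size; radii ≤ 10 use the exact path.
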