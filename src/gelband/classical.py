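"""Classical gel segmentation baselines: multi-Otsu thresholding and
marker-based watershed.

Both follow the same recipe: normalise intensities to [0, 1] by the maximum
representable value of the bit depth, then derive a background and a
foreground (band) threshold by three-class Otsu analysis of the intensity
histogram.  Thresholding assigns the band class to every pixel above the
foreground threshold; the watershed variant instead treats pixels between
the two thresholds as unknown and floods them over a Sobel
gradient-magnitude elevation map from the definite background/band markers,
finally filling enclosed background holes.

The multi-Otsu thresholds are computed by exhaustive maximisation of the
between-class variance over all pairs of histogram bins (vectorised with
cumulative moments), which is exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, segmentation
from sklearn.base import BaseEstimator

from gelband.io import GelImage, SegmentationMask


class DegenerateImageError(ValueError):
    """Raised when an image has too few distinct values to threshold."""


@dataclass(frozen=True)
class OtsuThresholds:
    """Background and foreground thresholds on the normalised [0, 1] scale."""

    t_background: float
    t_foreground: float

    def __post_init__(self) -> None:
        if not 0 <= self.t_background < self.t_foreground <= 1:
            raise ValueError(
                f"thresholds must satisfy 0 <= t_bg < t_fg <= 1, "
                f"got ({self.t_background}, {self.t_foreground})"
            )


def _as_gel_image(image: GelImage | np.ndarray) -> GelImage:
    if isinstance(image, GelImage):
        return image
    arr = np.asarray(image)
    if arr.dtype == np.uint16:
        return GelImage(arr, 16)
    if arr.dtype == np.uint8:
        return GelImage(arr, 8)
    raise TypeError("expected a GelImage or a uint8/uint16 array")


def normalize01(image: GelImage) -> np.ndarray:
    """Divide raw intensities by the maximum bit-type value (255 or 65535)."""
    return image.pixels.astype(np.float64) / image.max_value


def multi_otsu(image01: np.ndarray, n_classes: int = 3, nbins: int = 256) -> OtsuThresholds:
    """Exhaustive multi-Otsu thresholds of a normalised image.

    Builds an ``nbins``-bin histogram over the image's value range and finds
    the ``n_classes - 1`` class boundaries maximising the between-class
    variance by exact search over all boundary-bin pairs.  Each threshold is
    reported as the upper edge of its boundary bin, so "intensity strictly
    above the foreground threshold" selects exactly the pixels of the upper
    histogram class.  With the default three classes the lower threshold
    separates background from intermediate pixels and the upper separates
    intermediate pixels from bands.  Ties resolve to the lexicographically
    first bin pair.

    Currently only ``n_classes = 3`` is supported, matching the two-threshold
    background/foreground analysis.
    """
    if n_classes != 3:
        raise NotImplementedError("only the three-class (two-threshold) variant is supported")
    image01 = np.asarray(image01, dtype=np.float64)
    values = np.unique(image01)
    if values.size < n_classes:
        raise DegenerateImageError(
            f"need >= {n_classes} distinct values, found {values.size}"
        )
    counts, edges = np.histogram(image01, bins=nbins, range=(image01.min(), image01.max()))
    centers = (edges[:-1] + edges[1:]) / 2  # class moments use bin centres

    # cumulative moments with a leading zero so P[b+1]-P[a+1] sums bins a+1..b
    P = np.concatenate([[0.0], np.cumsum(counts)])
    S = np.concatenate([[0.0], np.cumsum(counts * centers)])

    def h(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Sum-of-squares contribution of classes spanning bins (a, b]."""
        w = P[b + 1] - P[a + 1]
        s = S[b + 1] - S[a + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, s**2 / np.where(w > 0, w, 1), 0.0)
        return out

    idx = np.arange(nbins)
    i = idx[:, None]  # last bin of class 1
    j = idx[None, :]  # last bin of class 2
    minus1 = np.full_like(i, -1)
    last = np.full_like(j, nbins - 1)
    objective = h(minus1, i) + h(i, j) + h(j, last)
    objective = np.where(i < j, objective, -np.inf)
    flat = int(np.argmax(objective))  # row-major scan = lexicographic tie-break
    bi, bj = divmod(flat, nbins)
    return OtsuThresholds(float(edges[bi + 1]), float(edges[bj + 1]))


def threshold_segment(
    image: GelImage, thresholds: OtsuThresholds | None = None
) -> SegmentationMask:
    """Multi-Otsu segmentation: band where intensity exceeds the foreground
    threshold, background everywhere else."""
    image = _as_gel_image(image)
    img01 = normalize01(image)
    if thresholds is None:
        thresholds = multi_otsu(img01)
    return SegmentationMask((img01 > thresholds.t_foreground).astype(np.uint8))


def watershed_segment(
    image: GelImage, thresholds: OtsuThresholds | None = None, connectivity: int = 2
) -> SegmentationMask:
    """Marker-based watershed segmentation.

    Pixels strictly below the background threshold are definite background
    markers, pixels strictly above the foreground threshold definite band
    markers; the remaining unknown pixels are flooded over the Sobel
    gradient-magnitude elevation map (8-connectivity by default).  Lone
    background regions enclosed by band pixels are then filled in.
    """
    image = _as_gel_image(image)
    img01 = normalize01(image)
    if thresholds is None:
        thresholds = multi_otsu(img01)
    elevation = filters.sobel(img01)
    markers = np.zeros(img01.shape, dtype=np.int32)
    markers[img01 < thresholds.t_background] = 1  # definite background
    markers[img01 > thresholds.t_foreground] = 2  # definite band
    labels = segmentation.watershed(elevation, markers, connectivity=connectivity)
    band = labels == 2
    band = ndimage.binary_fill_holes(band)
    return SegmentationMask(band.astype(np.uint8))


class MultiOtsuSegmenter(BaseEstimator):
    """Parameter-free band segmenter thresholding at the upper Otsu threshold.

    Follows the scikit-learn estimator protocol; ``fit`` is a no-op kept for
    pipeline compatibility.
    """

    def __init__(self, n_classes: int = 3, nbins: int = 256):
        self.n_classes = n_classes
        self.nbins = nbins

    def fit(self, X=None, y=None):  # noqa: N803 - sklearn signature
        self.is_fitted_ = True
        return self

    def predict(self, image: GelImage | np.ndarray) -> SegmentationMask:
        image = _as_gel_image(image)
        thr = multi_otsu(normalize01(image), self.n_classes, self.nbins)
        return threshold_segment(image, thr)


class WatershedSegmenter(BaseEstimator):
    """Watershed band segmenter with Otsu markers and Sobel elevation."""

    def __init__(self, n_classes: int = 3, nbins: int = 256, connectivity: int = 2):
        self.n_classes = n_classes
        self.nbins = nbins
        self.connectivity = connectivity

    def fit(self, X=None, y=None):  # noqa: N803
        self.is_fitted_ = True
        return self

    def predict(self, image: GelImage | np.ndarray) -> SegmentationMask:
        image = _as_gel_image(image)
        thr = multi_otsu(normalize01(image), self.n_classes, self.nbins)
        return watershed_segment(image, thr, connectivity=self.connectivity)
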