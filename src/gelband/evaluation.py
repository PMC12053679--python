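"""Segmentation quality metrics and hold-out regression quantitation error.

The quantitation-error protocol mirrors ladder-calibration practice: within
one lane, a handful of bands (default 5) are hidden, a straight line
``mass = a * volume + b`` is fitted to the remaining bands, the hidden
masses are predicted from their volumes, and the mean absolute percentage
error of those predictions is recorded.  Repeating with re-randomised
hold-out sets (default 80 repeats) and averaging yields a per-lane error
that is robust to individual band outliers.  Methods are compared across
lanes with a paired two-sided t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import directed_hausdorff

from gelband.io import SegmentationMask
from gelband.quantitation import BandInstance, label_bands, measure_bands


@dataclass
class MetricsReport:
    """Whole-image segmentation metrics plus per-band accuracies (%)."""

    dice: float
    precision: float | None
    recall: float
    hausdorff: float
    per_band_accuracy: list[float] = field(default_factory=list)


@dataclass
class HoldoutRegressionResult:
    """Per-lane mean percentage mass-prediction error over hold-out repeats."""

    lane_id: int
    mean_pct_error: float
    n_repeats: int
    per_repeat_errors: list[float]
    method: str = "none"


def _classes(mask: SegmentationMask | np.ndarray) -> np.ndarray:
    return mask.classes if isinstance(mask, SegmentationMask) else np.asarray(mask)


def dice_score(pred, truth) -> float:
    """Dice overlap 2|P∩T| / (|P|+|T|) of band pixels; 1 if both are empty."""
    p = _classes(pred) > 0
    t = _classes(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def precision_recall(pred, truth) -> tuple[float | None, float]:
    """Pixel precision |P∩T|/|P| and recall |P∩T|/|T| of the band class.

    Precision is ``None`` (undefined) when the prediction is empty; recall
    is 0 when the truth is non-empty and nothing overlaps.
    """
    p = _classes(pred) > 0
    t = _classes(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    inter = int((p & t).sum())
    precision = inter / int(p.sum()) if p.any() else None
    recall = inter / int(t.sum()) if t.any() else 1.0
    return precision, recall


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of band pixels touching background (4-neighbourhood)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
    boundary = mask & ~eroded
    return np.argwhere(boundary)


def hausdorff(pred, truth) -> float:
    """Symmetric Hausdorff distance between band boundary sets (Euclidean px).

    Zero when both masks are empty; raises when exactly one is empty.
    """
    p = _classes(pred) > 0
    t = _classes(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if not p.any() and not t.any():
        return 0.0
    if not p.any() or not t.any():
        raise ValueError("Hausdorff distance needs both masks non-empty")
    bp = _boundary_points(p)
    bt = _boundary_points(t)
    d1 = directed_hausdorff(bp, bt)[0]
    d2 = directed_hausdorff(bt, bp)[0]
    return float(max(d1, d2))


def per_band_accuracy(
    pred: SegmentationMask | np.ndarray,
    truth_instances: list[BandInstance],
    pred_instances: list[BandInstance] | None = None,
    denominator: str = "truth",
) -> list[float]:
    """Per-band segmentation accuracy in percent.

    For each ground-truth band, the predicted instances overlapping it are
    found.  A band whose overlap is split across two or more predicted
    instances scores 0% (a split detection is useless for quantitation), as
    does a band with no overlap at all.  Otherwise the score is
    ``100 * |truth ∩ prediction| / |truth|`` (``denominator='truth'``, the
    default) or ``100 * |truth ∩ prediction| / |prediction|``
    (``denominator='pred'``).
    """
    if denominator not in ("truth", "pred"):
        raise ValueError("denominator must be 'truth' or 'pred'")
    classes = _classes(pred)
    if pred_instances is None:
        pred_instances = label_bands(classes)
    pred_label_map = np.zeros(classes.shape, dtype=np.int32)
    for inst in pred_instances:
        pred_label_map[inst.pixel_rows, inst.pixel_cols] = inst.label
    pred_sizes = {inst.label: inst.n_pixels for inst in pred_instances}

    scores = []
    for band in truth_instances:
        overlapping = pred_label_map[band.pixel_rows, band.pixel_cols]
        labels = np.unique(overlapping[overlapping > 0])
        if labels.size == 0 or labels.size >= 2:
            scores.append(0.0)
            continue
        lbl = int(labels[0])
        inter = int((overlapping == lbl).sum())
        denom = band.n_pixels if denominator == "truth" else pred_sizes[lbl]
        scores.append(100.0 * inter / denom)
    return scores


def holdout_regression_error(
    volumes: np.ndarray,
    masses: np.ndarray,
    n_holdout: int = 5,
    n_repeats: int = 80,
    rng: np.random.Generator | int | None = None,
    lane_id: int = 0,
    method: str = "none",
) -> HoldoutRegressionResult:
    """Hold-out regression error of one lane's band volumes against masses.

    Per repeat: ``n_holdout`` distinct bands are hidden, ``mass = a*volume +
    b`` is fitted by ordinary least squares on the rest, the hidden masses
    are predicted, and the repeat error is the mean absolute percentage
    error over the hidden bands.  The result averages over repeats.

    Requires at least ``n_holdout + 2`` bands.  Repeats whose retained
    volumes have zero variance are skipped with a warning.
    """
    volumes = np.asarray(volumes, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if volumes.shape != masses.shape or volumes.ndim != 1:
        raise ValueError("volumes and masses must be 1-D arrays of equal length")
    n = len(volumes)
    if n < n_holdout + 2:
        raise ValueError(f"need >= {n_holdout + 2} bands, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    errors = []
    for _ in range(n_repeats):
        held = rng.choice(n, size=n_holdout, replace=False)
        keep = np.setdiff1d(np.arange(n), held)
        v_fit, m_fit = volumes[keep], masses[keep]
        if np.ptp(v_fit) == 0:
            warnings.warn("zero variance in retained volumes; repeat skipped")
            continue
        fit = stats.linregress(v_fit, m_fit)
        predicted = fit.slope * volumes[held] + fit.intercept
        errors.append(float(np.mean(100.0 * np.abs(predicted - masses[held]) / masses[held])))
    return HoldoutRegressionResult(
        lane_id=lane_id,
        mean_pct_error=float(np.mean(errors)) if errors else float("nan"),
        n_repeats=len(errors),
        per_repeat_errors=errors,
        method=method,
    )


def paired_comparison(errors_a, errors_b) -> tuple[float | None, float | None, int]:
    """Paired-samples two-sided t-test between two per-lane error vectors.

    Returns ``(t, p, n)``; zero-variance differences yield ``(None, None,
    n)`` rather than a numeric statistic.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and aligned by lane")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    if np.ptp(diffs) == 0 and n > 1:
        if np.all(diffs == 0):
            # zero mean and zero variance: conventionally t=0, p=1
            return 0.0, 1.0, n
        return None, None, n
    res = stats.ttest_rel(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), n


def evaluate_metrics(pred, truth_instances, truth_mask) -> MetricsReport:
    """Bundle whole-image metrics and per-band accuracy into one report."""
    precision, recall = precision_recall(pred, truth_mask)
    return MetricsReport(
        dice=dice_score(pred, truth_mask),
        precision=precision,
        recall=recall,
        hausdorff=hausdorff(pred, truth_mask),
        per_band_accuracy=per_band_accuracy(pred, truth_instances),
    )


def evaluate_method(
    gels,
    segmenter=None,
    background: str = "none",
    n_holdout: int = 5,
    n_repeats: int = 80,
    min_bands: int | None = None,
    rng: np.random.Generator | int | None = None,
    volume_noise_sigma: float = 0.0,
    mask_perturbation: str | None = None,
) -> dict:
    """Per-lane hold-out error analysis over a set of gels.

    For each gel: segment (or use the ground-truth mask when ``segmenter``
    is None), label band instances, assign them to the generator's lanes by
    best truth overlap, measure (optionally background-corrected) volumes,
    and compute the per-lane hold-out regression error.  Lanes with fewer
    than ``n_holdout + 2`` usable bands are excluded from the analysis
    entirely (and counted) to prevent bias.

    ``volume_noise_sigma`` applies multiplicative Gaussian noise to the
    measured volumes (e.g. 0.05 for 5%), emulating measurement error;
    ``mask_perturbation`` ('dilate'/'erode') perturbs the mask by one pixel
    before measurement.

    Returns a dict with per-lane results, the pooled error distribution
    summary and the excluded-lane count.
    """
    from gelband.quantitation import perturb_mask

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if min_bands is None:
        min_bands = n_holdout + 2

    lane_results: list[HoldoutRegressionResult] = []
    excluded = 0
    for gel_idx, gel in enumerate(gels):
        if segmenter is None:
            mask = SegmentationMask(gel.class_mask)
        else:
            mask = segmenter.predict(gel.image)
        if mask_perturbation is not None:
            mask = perturb_mask(mask, mask_perturbation, 1)
        bands = label_bands(mask)
        if not bands:
            excluded += gel.band_truth["lane"].nunique()
            continue
        patch = None
        if background == "global":
            from gelband.quantitation import find_background_patch

            patch = find_background_patch(mask)
        measurements = measure_bands(gel.image, bands, method=background, patch=patch)
        volume_of = {m.label: m.corrected_volume for m in measurements}

        # assign each predicted band to the truth lane it overlaps most
        truth = gel.truth_mask
        lane_of_label = dict(zip(gel.band_truth["label"], gel.band_truth["lane"]))
        per_lane: dict[int, list[float]] = {}
        matched_truth: dict[int, set[int]] = {}
        for band in bands:
            overlap = truth[band.pixel_rows, band.pixel_cols]
            overlap = overlap[overlap > 0]
            if overlap.size == 0:
                continue  # spurious detection outside any true band
            truth_label = int(np.bincount(overlap).argmax())
            lane = int(lane_of_label[truth_label])
            # one prediction per truth band: keep the larger-overlap one
            matched_truth.setdefault(lane, set())
            if truth_label in matched_truth[lane]:
                continue
            matched_truth[lane].add(truth_label)
            mass = float(
                gel.band_truth.loc[gel.band_truth["label"] == truth_label, "mass"].iloc[0]
            )
            v = volume_of[band.label]
            if volume_noise_sigma > 0:
                v *= 1.0 + rng.normal(0.0, volume_noise_sigma)
            per_lane.setdefault(lane, []).append((v, mass))

        for lane, pairs in sorted(per_lane.items()):
            if len(pairs) < min_bands:
                excluded += 1
                continue
            vols = np.array([p[0] for p in pairs])
            ms = np.array([p[1] for p in pairs])
            lane_results.append(
                holdout_regression_error(
                    vols,
                    ms,
                    n_holdout=n_holdout,
                    n_repeats=n_repeats,
                    rng=rng,
                    lane_id=gel_idx * 1000 + lane,
                    method=background,
                )
            )

    errors = np.array([r.mean_pct_error for r in lane_results])
    summary = {
        "n_lanes": len(lane_results),
        "excluded_lanes": excluded,
        "mean": float(np.mean(errors)) if errors.size else float("nan"),
        "median": float(np.median(errors)) if errors.size else float("nan"),
        "q1": float(np.percentile(errors, 25)) if errors.size else float("nan"),
        "q3": float(np.percentile(errors, 75)) if errors.size else float("nan"),
    }
    return {"lanes": lane_results, "summary": summary, "per_lane_errors": errors}
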