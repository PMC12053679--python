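"""Independent reference implementations used by the test suite.

Deliberately naive (double loops, explicit set arithmetic, priority-queue
flooding) so they share no code path with the package implementations they
check.
"""

import heapq

import numpy as np


def brute_force_multi_otsu_bins(image01, nbins=256):
    """Exhaustive double loop over all boundary-bin pairs.

    Returns ``(i, j, t_background, t_foreground)`` where thresholds are
    upper bin edges, matching the package convention.
    """
    counts, edges = np.histogram(image01, bins=nbins, range=(image01.min(), image01.max()))
    centers = (edges[:-1] + edges[1:]) / 2

    def chunk(sl):
        w = counts[sl].sum()
        return (counts[sl] * centers[sl]).sum() ** 2 / w if w else 0.0

    best, best_pair = -np.inf, None
    for i in range(nbins):
        for j in range(i + 1, nbins):
            v = chunk(slice(0, i + 1)) + chunk(slice(i + 1, j + 1)) + chunk(slice(j + 1, nbins))
            if v > best:
                best, best_pair = v, (i, j)
    i, j = best_pair
    return i, j, edges[i + 1], edges[j + 1]


def priority_flood_watershed(elevation, markers, connectivity=2):
    """Reference marker-based watershed via a priority-queue flood."""
    labels = markers.copy()
    nrows, ncols = elevation.shape
    if connectivity == 2:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    heap = []
    counter = 0
    for r in range(nrows):
        for c in range(ncols):
            if labels[r, c] != 0:
                heapq.heappush(heap, (elevation[r, c], counter, r, c))
                counter += 1
    while heap:
        _, _, r, c = heapq.heappop(heap)
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] == 0:
                labels[rr, cc] = labels[r, c]
                heapq.heappush(heap, (elevation[rr, cc], counter, rr, cc))
                counter += 1
    return labels


def naive_pixel_metrics(pred, truth):
    """Dice/precision/recall by explicit coordinate-set arithmetic."""
    p = {tuple(x) for x in np.argwhere(np.asarray(pred) > 0)}
    t = {tuple(x) for x in np.argwhere(np.asarray(truth) > 0)}
    inter = len(p & t)
    dice = 1.0 if not p and not t else 2 * inter / (len(p) + len(t))
    precision = inter / len(p) if p else None
    recall = inter / len(t) if t else 1.0
    return dice, precision, recall


def naive_per_band_accuracy(pred, truth_labelled):
    """Per-truth-band accuracy by explicit set arithmetic.

    ``truth_labelled`` is an instance-labelled truth mask; the prediction is
    labelled here with 8-connected components via a hand-rolled flood fill.
    """
    pred = np.asarray(pred) > 0
    nrows, ncols = pred.shape
    pred_labels = np.zeros((nrows, ncols), int)
    current = 0
    for r in range(nrows):
        for c in range(ncols):
            if pred[r, c] and pred_labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                pred_labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (
                                0 <= r2 < nrows
                                and 0 <= c2 < ncols
                                and pred[r2, c2]
                                and pred_labels[r2, c2] == 0
                            ):
                                pred_labels[r2, c2] = current
                                stack.append((r2, c2))
    scores = []
    for lbl in range(1, truth_labelled.max() + 1):
        truth_px = {tuple(x) for x in np.argwhere(truth_labelled == lbl)}
        overlapping = {pred_labels[r, c] for r, c in truth_px if pred_labels[r, c] > 0}
        if len(overlapping) != 1:
            scores.append(0.0)
            continue
        match = overlapping.pop()
        inter = sum(1 for r, c in truth_px if pred_labels[r, c] == match)
        scores.append(100.0 * inter / len(truth_px))
    return scores
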