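"""Rule-based lane identification and split-band repair.

Bands are grouped into lanes by a nearest-neighbour rule gated on horizontal
centroid distance (half the median band width), followed by merging of
groups whose mean centroid columns are closer than a third of the median
band width.  Split bands — one physical band fragmented into two predicted
instances — are detected within a lane either as low-width outliers
(median-absolute-deviation test) or as vertically near-adjacent pairs
(closer than half the median band height), and are repaired by filling the
convex hull of the two fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import convex_hull_image

from gelband.io import SegmentationMask
from gelband.quantitation import BandInstance


@dataclass
class LaneGroup:
    """Bands assigned to one lane, ordered top to bottom."""

    lane_id: int
    bands: list[BandInstance]
    lane_centroid_col: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a lane must contain at least one band")
        # strict ordering by centroid row; ties broken by smaller column
        self.bands = sorted(self.bands, key=lambda b: (b.centroid[0], b.centroid[1]))


def global_geometry(bands: list[BandInstance]) -> tuple[float, float]:
    """Median bounding-box width and height over all bands."""
    if not bands:
        raise ValueError("need at least one band")
    widths = [b.width for b in bands]
    heights = [b.height for b in bands]
    return float(np.median(widths)), float(np.median(heights))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_lanes(bands: list[BandInstance]) -> list[LaneGroup]:
    """Group bands into lanes.

    1. For each band, the nearest other band (Euclidean centroid distance)
       among those whose horizontal centroid distance is strictly less than
       half the median band width.
    2. Bands are merged with their nearest neighbours (union-find over the
       undirected nearest-neighbour edges).
    3. Groups whose mean centroid columns differ by strictly less than a
       third of the median band width are merged into super-groups, repeated
       to transitive closure; super-groups are the lanes, numbered
       left-to-right.

    Isolated bands form singleton lanes.  The result is a partition and is
    invariant to the input ordering of ``bands``.
    """
    if not bands:
        raise ValueError("need at least one band")
    # canonical processing order makes the partition permutation-invariant
    bands = sorted(bands, key=lambda b: (b.centroid[0], b.centroid[1], b.label))
    n = len(bands)
    median_w, _ = global_geometry(bands)
    cent = np.array([b.centroid for b in bands])  # (n, 2)

    uf = _UnionFind(n)
    for i in range(n):
        best = None
        best_d = np.inf
        for j in range(n):
            if i == j:
                continue
            if abs(cent[i, 1] - cent[j, 1]) < median_w / 2:
                d = float(np.hypot(*(cent[i] - cent[j])))
                if d < best_d:
                    best_d, best = d, j
        if best is not None:
            uf.union(i, best)

    # group centroid columns, then transitive super-group merging
    def group_map() -> dict[int, list[int]]:
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(i)
        return groups

    merged = True
    while merged:
        merged = False
        groups = group_map()
        roots = list(groups)
        cols = {r: float(np.mean([cent[i, 1] for i in groups[r]])) for r in roots}
        for a in range(len(roots)):
            for b in range(a + 1, len(roots)):
                if abs(cols[roots[a]] - cols[roots[b]]) < median_w / 3:
                    uf.union(roots[a], roots[b])
                    merged = True

    groups = group_map()
    lanes = []
    for members in groups.values():
        members_bands = [bands[i] for i in members]
        col = float(np.mean([b.centroid[1] for b in members_bands]))
        lanes.append((col, members_bands))
    lanes.sort(key=lambda t: t[0])
    return [
        LaneGroup(lane_id=i, bands=mb, lane_centroid_col=col)
        for i, (col, mb) in enumerate(lanes)
    ]


def detect_split_bands(
    lane: LaneGroup,
    bands_geometry: tuple[float, float],
    mad_k: float = 2.0,
) -> list[tuple[BandInstance, BandInstance]]:
    """Find vertically adjacent band pairs that look like one split band.

    A pair of consecutive bands in the lane is a candidate if either

    * both widths are low outliers within the lane by the median absolute
      deviation test (``|w - median| > mad_k * MAD`` and ``w < median``), or
    * their vertical centroid distance is less than half the median band
      height (from ``bands_geometry``).
    """
    if len(lane.bands) < 2:
        return []
    _, median_h = bands_geometry
    widths = np.array([b.width for b in lane.bands], dtype=float)
    med_w = float(np.median(widths))
    mad = float(np.median(np.abs(widths - med_w)))

    def low_outlier(w: float) -> bool:
        return mad > 0 and abs(w - med_w) > mad_k * mad and w < med_w

    pairs = []
    for a, b in zip(lane.bands[:-1], lane.bands[1:]):
        by_width = low_outlier(a.width) and low_outlier(b.width)
        by_distance = abs(b.centroid[0] - a.centroid[0]) < median_h / 2
        if by_width or by_distance:
            pairs.append((a, b))
    return pairs


def fill_split_bands(
    mask: SegmentationMask | np.ndarray,
    pairs: list[tuple[BandInstance, BandInstance]],
) -> SegmentationMask:
    """Repair split bands by filling the convex hull of each fragment pair.

    Every pixel inside the convex hull of the union of the two fragments'
    pixel sets becomes band class; existing band pixels are never removed.
    """
    classes = mask.classes if isinstance(mask, SegmentationMask) else np.asarray(mask)
    out = (classes > 0).copy()
    for a, b in pairs:
        canvas = np.zeros_like(out)
        canvas[a.pixel_rows, a.pixel_cols] = True
        canvas[b.pixel_rows, b.pixel_cols] = True
        out |= convex_hull_image(canvas)
    return SegmentationMask(out.astype(np.uint8))


def migration_distances(
    lanes: list[LaneGroup], reference_row: float
) -> list[dict]:
    """Migration distance of each band from the reference (well) row.

    Returns records with lane_id, band_id (top-to-bottom within the lane),
    centroid position and ``distance = centroid_row - reference_row``.
    """
    records = []
    for lane in lanes:
        for band_id, band in enumerate(lane.bands):
            records.append(
                {
                    "lane_id": lane.lane_id,
                    "band_id": band_id,
                    "centroid_row": band.centroid[0],
                    "centroid_col": band.centroid[1],
                    "distance": band.centroid[0] - reference_row,
                }
            )
    return records
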