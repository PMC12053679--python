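"""Seeded synthetic gel images with exact ground truth.

The generator emulates the structure of ladder-calibration gels: several
lanes, each carrying the same ladder of bands with known masses, band signal
proportional to loaded mass, a smooth background gradient, additive sensor
noise and optional blur and band warping ("smiling").  Every image comes with
an instance-labelled ground-truth mask and a per-band table of true masses
and noiseless integrated signals, so segmentation and quantitation accuracy
can be measured exactly.

Band model
----------
A band centred at ``(r0, c0)`` contributes

    amplitude_per_ng * mass * G(row, col)

where ``G`` peaks at 1, is Gaussian along rows (sigma ``band_sigma[0]``),
flat-topped across the lane width with Gaussian shoulders (sigma
``band_sigma[1]``), and optionally displaced along rows by a symmetric
sinusoidal warp across the band ("smiling").  The ground-truth mask marks
pixels where this noiseless term exceeds a fixed fraction (default 2%) of
the band's peak; the band/background boundary is a judgement call on real
gels, so the generator fixes one and exposes it as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from gelband.io import GelImage


class SpecError(ValueError):
    """Raised when a synthetic-gel specification is internally inconsistent."""


#: Default ladder: 10 bands with the roughly one-decade spread of per-band
#: loaded mass (ng) found in commercial DNA ladders, migration rows spaced
#: with the compression typical of log-molecular-weight migration.
DEFAULT_LADDER: tuple[tuple[float, float], ...] = (
    (200.0, 40.0),
    (160.0, 64.0),
    (130.0, 86.0),
    (105.0, 108.0),
    (85.0, 128.0),
    (70.0, 148.0),
    (55.0, 166.0),
    (45.0, 184.0),
    (35.0, 200.0),
    (25.0, 216.0),
)


def scaled_ladder(
    image_rows: int,
    ladder: tuple[tuple[float, float], ...] = DEFAULT_LADDER,
    top: float = 0.16,
    bottom: float = 0.85,
) -> tuple[tuple[float, float], ...]:
    """Rescale a ladder's migration rows into a fraction of the image height,
    preserving relative spacing (masses unchanged)."""
    rows = np.array([r for _, r in ladder])
    lo, hi = rows.min(), rows.max()
    scaled = top * image_rows + (rows - lo) / (hi - lo) * (bottom - top) * image_rows
    return tuple((m, float(r)) for (m, _), r in zip(ladder, scaled))


@dataclass
class SyntheticGelSpec:
    """Parameters of one synthetic gel image.

    Defaults describe a clean-but-realistic 8-bit ladder gel: 6 lanes of a
    10-band two-decade ladder, a mild vertical background gradient, additive
    Gaussian noise and slight blur and smiling.
    """

    image_shape: tuple[int, int] = (256, 360)
    bit_depth: int = 8
    n_lanes: int = 6
    lane_centers: tuple[float, ...] | None = None
    ladder: tuple[tuple[float, float], ...] = DEFAULT_LADDER
    amplitude_per_ng: float = 0.75
    band_sigma: tuple[float, float] = (2.5, 3.0)
    band_width: float = 28.0
    warp_amplitude: float = 1.5
    background: tuple[float, float] = (20.0, 15.0)
    noise_sigma: float = 2.0
    blur_sigma: float = 0.6
    col_jitter: float = 0.0
    boundary_frac: float = 0.02
    allow_saturation: bool = False
    seed: int = 0

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def resolved_lane_centers(self) -> np.ndarray:
        if self.lane_centers is not None:
            return np.asarray(self.lane_centers, dtype=float)
        ncols = self.image_shape[1]
        margin = self.band_width / 2 + 3 * self.band_sigma[1] + 2
        return np.linspace(margin, ncols - margin, self.n_lanes)

    def validate(self) -> None:
        if self.amplitude_per_ng <= 0:
            raise SpecError("amplitude_per_ng must be positive")
        if self.bit_depth not in (8, 16):
            raise SpecError("bit_depth must be 8 or 16")
        if not self.ladder:
            raise SpecError("ladder must contain at least one band")
        nrows, ncols = self.image_shape
        centers = self.resolved_lane_centers()
        if len(centers) != self.n_lanes:
            raise SpecError("lane_centers length must equal n_lanes")
        half = self.band_width / 2 + 3 * self.band_sigma[1]
        if centers.min() - half < 0 or centers.max() + half > ncols:
            raise SpecError("bands extend beyond image columns")
        rows = np.array([r for _, r in self.ladder])
        pad = 3 * self.band_sigma[0] + self.warp_amplitude
        if (rows - pad).min() < 0 or (rows + pad).max() > nrows:
            raise SpecError("bands extend beyond image rows")


@dataclass
class SyntheticGel:
    """A generated gel: image, instance truth mask and per-band truth table.

    ``band_truth`` columns: label, lane, band, mass, row, col, signal —
    where ``signal`` is the noiseless integrated band term over the whole
    image, recorded before clipping.  ``band_image`` and
    ``background_image`` hold the noiseless components.
    """

    image: GelImage
    truth_mask: np.ndarray
    band_truth: pd.DataFrame
    band_image: np.ndarray
    background_image: np.ndarray
    spec: SyntheticGelSpec
    lane_masses: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def class_mask(self) -> np.ndarray:
        """Binary band/background classes derived from the instance mask."""
        return (self.truth_mask > 0).astype(np.uint8)


def _band_term(
    spec: SyntheticGelSpec, r0: float, c0: float, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Peak-1 band profile on the full image grid."""
    sig_r, sig_c = spec.band_sigma
    half_w = spec.band_width / 2
    dc = cols - c0
    # flat top across the lane, Gaussian shoulders beyond the half-width
    excess = np.maximum(np.abs(dc) - half_w, 0.0)
    col_profile = np.exp(-(excess**2) / (2 * sig_c**2))
    # symmetric "smile": band edges displaced upward relative to the centre
    if spec.warp_amplitude != 0:
        phase = np.clip(dc / (half_w + 3 * sig_c), -1.0, 1.0)
        warp = spec.warp_amplitude * 0.5 * (1 - np.cos(np.pi * phase))
    else:
        warp = 0.0
    dr = rows - (r0 + warp)
    row_profile = np.exp(-(dr**2) / (2 * sig_r**2))
    return row_profile * col_profile


def generate_gel(
    spec: SyntheticGelSpec, lane_loads: np.ndarray | None = None
) -> SyntheticGel:
    """Render one synthetic gel.

    The image is ``clip(background + sum of band terms + noise, 0,
    max_value)``; blur, when requested, is applied to the noiseless scene
    before noise is added.  Identical specs (same seed) produce
    bitwise-identical output.  ``lane_loads`` optionally scales each lane's
    true masses (emulating variable loading of the same ladder), scaling the
    rendered signal identically.

    Raises
    ------
    SpecError
        If band masks from different lanes overlap, geometry leaves the
        image, or more than 5% of pixels saturate without
        ``allow_saturation``.
    """
    spec.validate()
    if lane_loads is None:
        lane_loads = np.ones(spec.n_lanes)
    lane_loads = np.asarray(lane_loads, dtype=float)
    if lane_loads.shape != (spec.n_lanes,):
        raise SpecError("lane_loads must have one entry per lane")

    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.image_shape
    rows = np.arange(nrows, dtype=float)[:, None]
    cols = np.arange(ncols, dtype=float)[None, :]

    centers = spec.resolved_lane_centers()
    offset, slope = spec.background
    background = offset + slope * (rows / max(nrows - 1, 1)) * np.ones((1, ncols))

    band_image = np.zeros((nrows, ncols))
    truth = np.zeros((nrows, ncols), dtype=np.int32)
    lane_of_pixel = np.zeros((nrows, ncols), dtype=np.int32)
    records = []
    lane_masses: dict[int, np.ndarray] = {}
    label = 0
    for lane_idx, c_center in enumerate(centers):
        load = float(lane_loads[lane_idx])
        lane_masses[lane_idx] = load * np.array([m for m, _ in spec.ladder])
        for band_idx, (mass, r0) in enumerate(spec.ladder):
            c0 = c_center
            if spec.col_jitter > 0:
                c0 = c_center + rng.uniform(-spec.col_jitter, spec.col_jitter)
            term = _band_term(spec, r0, c0, rows, cols)
            scaled_mass = mass * load
            band = spec.amplitude_per_ng * scaled_mass * term
            sel = term > spec.boundary_frac
            if not sel.any():
                raise SpecError(f"band {band_idx} in lane {lane_idx} has an empty mask")
            clash = sel & (lane_of_pixel != 0) & (lane_of_pixel != lane_idx + 1)
            if clash.any():
                other = int(lane_of_pixel[clash][0]) - 1
                raise SpecError(f"band masks overlap across lanes {other} and {lane_idx}")
            label += 1
            truth[sel] = label
            lane_of_pixel[sel] = lane_idx + 1
            band_image += band
            centroid = ndimage.center_of_mass(sel)
            records.append(
                {
                    "label": label,
                    "lane": lane_idx,
                    "band": band_idx,
                    "mass": scaled_mass,
                    "row": float(centroid[0]),
                    "col": float(centroid[1]),
                    "signal": float(band.sum()),
                }
            )

    scene = background + band_image
    if spec.blur_sigma and spec.blur_sigma > 0:
        scene = ndimage.gaussian_filter(scene, spec.blur_sigma)
    if spec.noise_sigma > 0:
        scene = scene + rng.normal(0.0, spec.noise_sigma, size=scene.shape)
    saturated = np.mean(scene > spec.max_value)
    if saturated >= 0.05 and not spec.allow_saturation:
        raise SpecError(f"{saturated:.1%} of pixels saturate; reduce amplitudes or allow it")
    clipped = np.clip(scene, 0, spec.max_value)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = GelImage(pixels=np.rint(clipped).astype(dtype), bit_depth=spec.bit_depth)

    return SyntheticGel(
        image=image,
        truth_mask=truth,
        band_truth=pd.DataFrame(records),
        band_image=band_image,
        background_image=background,
        spec=spec,
        lane_masses=lane_masses,
    )


def generate_quantitation_set(
    n_gels: int = 30,
    base_spec: SyntheticGelSpec | None = None,
    seed: int = 0,
) -> list[SyntheticGel]:
    """Generate a calibration dataset of ladder gels with known masses.

    Emulates a bench protocol in which variable amounts of ladder are loaded
    into different lanes and gels are imaged under varying conditions:
    per-lane loading factors scale the true masses (uniform 0.5–1.5), and
    per-gel jitter varies overall signal amplitude (uniform 0.7–1.3 on
    ``amplitude_per_ng``), noise level (uniform 0.5–1.5 on ``noise_sigma``)
    and warp (uniform 0–2 on ``warp_amplitude``).

    The ladder must have at least 8 bands so that hold-out regression with 5
    hidden bands remains well-posed.
    """
    base_spec = base_spec if base_spec is not None else SyntheticGelSpec()
    if len(base_spec.ladder) < 8:
        raise SpecError("quantitation ladders need >= 8 bands (5 held out, >= 3 retained)")
    rng = np.random.default_rng(seed)
    gels = []
    for _ in range(n_gels):
        amp = base_spec.amplitude_per_ng * rng.uniform(0.7, 1.3)
        noise = base_spec.noise_sigma * rng.uniform(0.5, 1.5)
        warp = base_spec.warp_amplitude * rng.uniform(0.0, 2.0)
        lane_loads = rng.uniform(0.5, 1.5, size=base_spec.n_lanes)
        gel_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec,
            amplitude_per_ng=amp,
            noise_sigma=noise,
            warp_amplitude=warp,
            seed=gel_seed,
        )
        gels.append(generate_gel(spec, lane_loads=lane_loads))
    return gels


def degrade(
    gel: SyntheticGel,
    kind: str,
    magnitude: float = 0.5,
    seed: int = 0,
) -> SyntheticGel:
    """Apply a controlled degradation, emulating difficult real-world gels.

    Parameters
    ----------
    kind : {'faint', 'blurry', 'torn', 'contaminant'}
        ``faint`` multiplies band amplitudes by ``magnitude`` and re-renders;
        ``blurry`` Gaussian-blurs the image only (sigma = 3 * magnitude px);
        ``torn`` zeroes a random polygonal region and drops fully covered
        bands from the truth; ``contaminant`` adds a bright non-band blob
        that is not added to the truth mask.
    magnitude : float in (0, 1]
    """
    if not 0 < magnitude <= 1:
        raise ValueError("magnitude must be in (0, 1]")
    rng = np.random.default_rng(seed)
    spec = gel.spec
    nrows, ncols = spec.image_shape
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16

    if kind == "faint":
        band_image = gel.band_image * magnitude
        scene = gel.background_image + band_image
        if spec.blur_sigma and spec.blur_sigma > 0:
            scene = ndimage.gaussian_filter(scene, spec.blur_sigma)
        if spec.noise_sigma > 0:
            scene = scene + rng.normal(0.0, spec.noise_sigma, size=scene.shape)
        pixels = np.rint(np.clip(scene, 0, spec.max_value)).astype(dtype)
        truth_table = gel.band_truth.copy()
        truth_table["signal"] = truth_table["signal"] * magnitude
        return SyntheticGel(
            image=GelImage(pixels, spec.bit_depth),
            truth_mask=gel.truth_mask.copy(),
            band_truth=truth_table,
            band_image=band_image,
            background_image=gel.background_image,
            spec=spec,
            lane_masses=dict(gel.lane_masses),
        )
    if kind == "blurry":
        blurred = ndimage.gaussian_filter(gel.image.pixels.astype(float), 3.0 * magnitude)
        return SyntheticGel(
            image=GelImage(np.rint(blurred).astype(dtype), spec.bit_depth),
            truth_mask=gel.truth_mask.copy(),
            band_truth=gel.band_truth.copy(),
            band_image=gel.band_image,
            background_image=gel.background_image,
            spec=spec,
            lane_masses=dict(gel.lane_masses),
        )
    if kind == "torn":
        from skimage.draw import polygon

        # random convex quadrilateral covering roughly `magnitude` of each axis
        half_r = nrows * magnitude / 2
        half_c = ncols * magnitude / 2
        cr = rng.uniform(half_r, nrows - half_r)
        cc = rng.uniform(half_c, ncols - half_c)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
        rr, cc_idx = polygon(cr + half_r * np.sin(angles), cc + half_c * np.cos(angles),
                             shape=(nrows, ncols))
        region = np.zeros((nrows, ncols), dtype=bool)
        region[rr, cc_idx] = True
        pixels = gel.image.pixels.copy()
        pixels[region] = 0
        truth = gel.truth_mask.copy()
        keep_rows = []
        for _, rec in gel.band_truth.iterrows():
            lbl = int(rec["label"])
            covered = region[truth == lbl]
            if covered.size and covered.all():
                truth[truth == lbl] = 0
            else:
                keep_rows.append(rec)
        table = pd.DataFrame(keep_rows).reset_index(drop=True)
        new_truth = np.zeros_like(truth)
        for new_lbl, old_lbl in enumerate(table["label"].astype(int), start=1):
            new_truth[truth == old_lbl] = new_lbl
        table["label"] = np.arange(1, len(table) + 1)
        return SyntheticGel(
            image=GelImage(pixels, spec.bit_depth),
            truth_mask=new_truth,
            band_truth=table,
            band_image=gel.band_image,
            background_image=gel.background_image,
            spec=spec,
            lane_masses=dict(gel.lane_masses),
        )
    if kind == "contaminant":
        rows = np.arange(nrows, dtype=float)[:, None]
        cols = np.arange(ncols, dtype=float)[None, :]
        cr = rng.uniform(0.1 * nrows, 0.9 * nrows)
        cc = rng.uniform(0.1 * ncols, 0.9 * ncols)
        sigma = rng.uniform(6, 14)
        blob = magnitude * spec.max_value * 0.5 * np.exp(
            -((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2)
        )
        pixels = np.clip(gel.image.pixels.astype(float) + blob, 0, spec.max_value)
        return SyntheticGel(
            image=GelImage(np.rint(pixels).astype(dtype), spec.bit_depth),
            truth_mask=gel.truth_mask.copy(),
            band_truth=gel.band_truth.copy(),
            band_image=gel.band_image,
            background_image=gel.background_image,
            spec=spec,
            lane_masses=dict(gel.lane_masses),
        )
    raise ValueError(f"unknown degradation kind {kind!r}")
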