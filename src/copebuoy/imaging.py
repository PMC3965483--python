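"""Micrograph measurement: grid calibration, segmentation, morphometrics.

Automates the manual image-measurement step: the specimen (prosome) is
isolated by global Otsu thresholding and its projected ellipse fitted from
second moments; oil bodies are the bright regions inside the specimen,
traced as contours and classified as droplets (near-circular) or sacs
(elongated).  Pixel geometry is converted to mm through the calibration
obtained from a grid image of known spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .morphometry import MorphometricRecord, ScaleCalibration, apply_scale

logger = logging.getLogger(__name__)

__all__ = ["SegmentationResult", "calibrate_from_grid", "segment", "measure"]

#: regions with eccentricity below this are recorded as droplets
DROPLET_ECCENTRICITY = 0.6
#: minimum oil-region size, px
MIN_OIL_REGION_PX = 20
#: minimum oil-vs-prosome intensity contrast (fraction of dynamic range)
MIN_OIL_CONTRAST = 0.12


@dataclass(frozen=True)
class SegmentationResult:
    """Pixel-space geometry recovered from one micrograph."""

    prosome_axes: tuple[float, float]  # (length, width), px
    prosome_center: tuple[float, float]  # (row, col), px
    prosome_angle: float  # rad, major axis vs image x-axis
    oil_regions: tuple  # tuple of (N, 2) float arrays, (row, col) px
    quality_flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if min(self.prosome_axes) <= 0:
            raise ValueError("prosome axes must be positive")


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    span = img.max() - img.min()
    if span == 0:
        raise ValueError("blank image: no intensity variation")
    return (img - img.min()) / span


def _line_positions(profile: np.ndarray) -> np.ndarray:
    """Positions of dark grid lines along one axis (minima of a profile)."""
    inverted = profile.max() - profile
    prominence = 0.25 * (inverted.max() - inverted.min())
    if prominence == 0:
        return np.array([])
    peaks, _ = find_peaks(inverted, prominence=prominence, distance=3)
    return peaks.astype(float)


def calibrate_from_grid(grid_image: np.ndarray, known_spacing: float) -> ScaleCalibration:
    """Estimate μm/pixel from a grid image with lines *known_spacing* μm apart.

    The grid is detected as intensity minima of the row- and column-mean
    profiles; the scale is the known spacing divided by the median
    inter-line distance, using whichever orientation shows more lines.
    Requires at least 3 detected parallel lines.
    """
    if known_spacing <= 0:
        raise ValueError("known_spacing must be positive")
    img = _as_float(grid_image)
    cols = _line_positions(img.mean(axis=0))
    rows = _line_positions(img.mean(axis=1))
    best = cols if cols.size >= rows.size else rows
    if best.size < 3:
        raise ValueError(
            f"fewer than 3 grid lines detected ({best.size}); cannot calibrate"
        )
    gaps = np.diff(best)
    spacing_px = float(np.median(gaps))
    rel_unc = float(np.median(np.abs(gaps - spacing_px)) / spacing_px)
    return ScaleCalibration(
        microns_per_pixel=known_spacing / spacing_px,
        grid_spacing=known_spacing,
        relative_uncertainty=rel_unc,
    )


def _region_contour(mask: np.ndarray) -> np.ndarray:
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    return max(contours, key=len)


def segment(image: np.ndarray) -> SegmentationResult:
    """Deterministic specimen + oil-body segmentation of one micrograph."""
    img = _as_float(image)
    thresh = threshold_otsu(img)
    fg = img > thresh
    labels = skmeasure.label(fg)
    if labels.max() == 0:
        raise ValueError("no foreground found")
    props = skmeasure.regionprops(labels, intensity_image=img)
    props.sort(key=lambda r: r.area, reverse=True)
    specimen = props[0]
    flags: list[str] = []
    if len(props) > 1 and props[1].area > 0.1 * specimen.area:
        flags.append("multiple_bodies")
    minr, minc, maxr, maxc = specimen.bbox
    if minr == 0 or minc == 0 or maxr == labels.shape[0] or maxc == labels.shape[1]:
        flags.append("touching_border")

    mask = labels == specimen.label
    length = float(specimen.axis_major_length)
    width = float(specimen.axis_minor_length)
    center = tuple(map(float, specimen.centroid))
    angle = float(specimen.orientation)

    # oil bodies: bright regions inside the specimen
    inside = img[mask]
    oil_regions: list[np.ndarray] = []
    t2 = threshold_otsu(inside) if inside.size > 1 and np.ptp(inside) > 0 else None
    if t2 is not None:
        oil_mask = mask & (img > t2)
        body_mean = float(inside[inside <= t2].mean()) if np.any(inside <= t2) else 0.0
        oil_vals = img[oil_mask]
        contrast = float(oil_vals.mean() - body_mean) if oil_vals.size else 0.0
        if contrast < MIN_OIL_CONTRAST:
            if 0 < contrast:
                flags.append("low_contrast")
            oil_mask[:] = False
        oil_labels = skmeasure.label(oil_mask)
        for region in skmeasure.regionprops(oil_labels):
            if region.area < MIN_OIL_REGION_PX:
                continue
            sub = oil_labels == region.label
            oil_regions.append(_region_contour(sub))
    return SegmentationResult(
        prosome_axes=(length, width),
        prosome_center=center,
        prosome_angle=angle,
        oil_regions=tuple(oil_regions),
        quality_flags=tuple(flags),
    )


def measure(
    image: np.ndarray,
    cal: ScaleCalibration,
    metadata: dict,
) -> MorphometricRecord:
    """Measure one micrograph into a morphometric record in mm units.

    ``metadata`` must supply species_label, stage_label, site, date_label
    and depth_layer_m, which pass through verbatim.  Oil regions with
    eccentricity below 0.6 are recorded as droplet diameters
    (area-equivalent); elongated regions as a digitised contour (the
    largest one, if several).
    """
    seg = segment(image)
    length_mm = apply_scale(max(seg.prosome_axes), cal)
    width_mm = apply_scale(min(seg.prosome_axes), cal)

    droplets: list[float] = []
    contour_regions: list[tuple[float, np.ndarray]] = []
    for contour in seg.oil_regions:
        poly = [(float(c), float(r)) for r, c in contour]  # (x, y) px
        from .morphometry import polygon_area as _poly_area

        area_px = _poly_area(poly)
        # eccentricity from the polygon's second moments
        from .morphometry import contour_equivalent_axes

        eq_l, eq_w = contour_equivalent_axes(poly)
        ecc = float(np.sqrt(max(1.0 - (eq_w / eq_l) ** 2, 0.0)))
        if ecc < DROPLET_ECCENTRICITY:
            d_px = 2.0 * np.sqrt(area_px / np.pi)
            droplets.append(apply_scale(d_px, cal))
        else:
            contour_regions.append((area_px, np.asarray(poly)))

    geometry: dict = {}
    if contour_regions:
        if droplets:
            logger.warning("mixed droplet/sac regions; keeping the largest sac contour")
        _, poly = max(contour_regions, key=lambda t: t[0])
        geometry["sac_contour"] = tuple(
            (x * cal.microns_per_pixel / 1000.0, y * cal.microns_per_pixel / 1000.0)
            for x, y in poly
        )
    elif droplets:
        geometry["droplet_diameters"] = tuple(droplets)

    return MorphometricRecord(
        species_label=str(metadata["species_label"]),
        stage_label=str(metadata["stage_label"]),
        site=str(metadata["site"]),
        date_label=str(metadata["date_label"]),
        depth_layer_m=float(metadata["depth_layer_m"]),
        prosome_length=length_mm,
        prosome_width=min(width_mm, length_mm * 0.999),
        **geometry,
    )
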