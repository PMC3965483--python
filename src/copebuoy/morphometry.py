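"""Morphometric lipid quantification for copepod micrograph measurements.

Converts the geometry measured on a micrograph — prosome length and width,
oil-droplet diameters, oil-sac axes or a digitised sac contour — into
projected areas (mm²), volumes (mm³), % lipid area and the lipid volume
fraction ``f_lipid`` that feeds the body-density model.

Conventions
-----------
* Lengths are mm, areas mm², volumes mm³ everywhere; microns appear only at
  the pixel-calibration boundary (:func:`apply_scale`).
* The prosome's projected outline is treated as an ellipse on (length,
  width); its volume as a prolate spheroid about the long axis with the
  dorso-ventral axis equal to the width.
* Multiple oil droplets are independent spheres, summed by area and volume.
* A digitised sac contour is converted to a volume through the ellipse with
  the same area and the same second-moment aspect ratio
  (:func:`contour_equivalent_axes`), then the prolate-spheroid formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LinearRing

__all__ = [
    "MorphometricRecord",
    "LipidQuant",
    "ScaleCalibration",
    "ellipse_area",
    "droplet_lipid_area",
    "polygon_area",
    "spheroid_volume",
    "contour_equivalent_axes",
    "quantify",
    "apply_scale",
]

#: f_lipid at or above this exceeds the non-tissue volume budget
#: (tissue fraction is fixed at 0.2 in the body-composition model).
LIPID_FRACTION_BUDGET = 0.8


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-physical scale from a calibration grid image."""

    microns_per_pixel: float
    grid_spacing: float  # the grid's known spacing, um
    relative_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0 or self.grid_spacing <= 0:
            raise ValueError("calibration scales must be positive")


@dataclass(frozen=True)
class MorphometricRecord:
    """One individual's identity, sampling context and measured geometry.

    Exactly one lipid geometry may be present: ``droplet_diameters``,
    the sac ellipse pair ``(sac_length, sac_width)``, or ``sac_contour``.
    An individual with none (or an empty droplet list) is lipid-empty.
    """

    species_label: str
    stage_label: str
    site: str
    date_label: str
    depth_layer_m: float
    prosome_length: float  # mm
    prosome_width: float  # mm
    droplet_diameters: tuple[float, ...] | None = None
    sac_length: float | None = None
    sac_width: float | None = None
    sac_contour: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.prosome_length >= self.prosome_width > 0:
            raise ValueError(
                "require prosome_length >= prosome_width > 0, got "
                f"L={self.prosome_length}, W={self.prosome_width}"
            )
        if (self.sac_length is None) != (self.sac_width is None):
            raise ValueError("sac_length and sac_width must be given together")
        present = [
            self.droplet_diameters is not None,
            self.sac_length is not None,
            self.sac_contour is not None,
        ]
        if sum(present) > 1:
            raise ValueError("at most one lipid geometry may be present")
        if self.droplet_diameters is not None:
            object.__setattr__(
                self, "droplet_diameters", tuple(float(d) for d in self.droplet_diameters)
            )
            if any(d <= 0 for d in self.droplet_diameters):
                raise ValueError("droplet diameters must be positive")
        if self.sac_length is not None:
            if not self.sac_length >= self.sac_width > 0:  # type: ignore[operator]
                raise ValueError("require sac_length >= sac_width > 0")
        if self.sac_contour is not None:
            object.__setattr__(
                self,
                "sac_contour",
                tuple((float(x), float(y)) for x, y in self.sac_contour),
            )
            _validate_contour(self.sac_contour)

    @property
    def geometry_kind(self) -> str:
        if self.droplet_diameters is not None:
            return "droplets"
        if self.sac_length is not None:
            return "sac_ellipse"
        if self.sac_contour is not None:
            return "sac_contour"
        return "none"


@dataclass(frozen=True)
class LipidQuant:
    """Derived areas, volumes and lipid fractions for one individual."""

    prosome_area: float  # mm^2
    lipid_area: float  # mm^2
    percent_lipid_area: float  # %
    prosome_volume: float  # mm^3
    lipid_volume: float  # mm^3
    lipid_volume_fraction: float  # dimensionless, the model's f_lipid
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 <= self.lipid_area <= self.prosome_area:
            raise ValueError(
                f"lipid_area {self.lipid_area} outside [0, prosome_area="
                f"{self.prosome_area}]"
            )
        if not 0.0 <= self.lipid_volume_fraction < 1.0:
            raise ValueError(
                f"lipid_volume_fraction {self.lipid_volume_fraction} outside [0, 1)"
            )


def ellipse_area(length: float, width: float) -> float:
    """Projected area of an ellipse with full axes *length* and *width*, mm²."""
    if not length >= width > 0:
        raise ValueError(f"require length >= width > 0, got ({length}, {width})")
    return math.pi / 4.0 * length * width


def droplet_lipid_area(diameters: Sequence[float]) -> float:
    """Summed projected area of circular oil droplets; empty list → 0."""
    if any(d <= 0 for d in diameters):
        raise ValueError("droplet diameters must be positive")
    return math.pi / 4.0 * sum(d * d for d in diameters)


def _validate_contour(contour: Sequence[tuple[float, float]]) -> None:
    if len(contour) < 3:
        raise ValueError("contour needs at least 3 vertices")
    ring = LinearRing(contour)
    if not ring.is_valid or not ring.is_simple:
        raise ValueError("contour is self-intersecting or degenerate")


def polygon_area(contour: Sequence[tuple[float, float]]) -> float:
    """Absolute shoelace area of a simple polygon, orientation independent."""
    _validate_contour(contour)
    pts = np.asarray(contour, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    return abs(0.5 * float(cross.sum()))


def spheroid_volume(length: float, width: float) -> float:
    """Prolate spheroid about the long axis (third axis = width), mm³.

    V = (pi/6) * length * width²; for length == width this is the sphere
    formula pi d³/6.
    """
    if not length >= width > 0:
        raise ValueError(f"require length >= width > 0, got ({length}, {width})")
    return math.pi / 6.0 * length * width * width


def _polygon_moments(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed area and central second-moment (covariance) matrix of a polygon."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise ValueError("degenerate zero-area contour")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    # second moments about the origin
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0  # integral of y^2
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0  # integral of x^2
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central moments, normalised to a covariance over the polygon interior
    cov = (
        np.array(
            [
                [iyy - a * cx * cx, ixy - a * cx * cy],
                [ixy - a * cx * cy, ixx - a * cy * cy],
            ]
        )
        / a
    )
    return abs(a), cov


def contour_equivalent_axes(contour: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Axes (length, width) of the ellipse matching a contour's area and shape.

    The returned ellipse has exactly the polygon's shoelace area and the
    aspect ratio of its second-moment (covariance) ellipse, so
    ``ellipse_area(length, width) == polygon_area(contour)`` to machine
    precision.  This is the geometry used to assign a spheroid volume to
    manually digitised oil-sac contours.
    """
    _validate_contour(contour)
    pts = np.asarray(contour, dtype=float)
    area, cov = _polygon_moments(pts)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        raise ValueError("degenerate contour: zero second moment")
    aspect = math.sqrt(eigvals[1] / eigvals[0])  # major/minor, >= 1
    width = math.sqrt(4.0 * area / (math.pi * aspect))
    length = aspect * width
    return length, width


def quantify(record: MorphometricRecord) -> LipidQuant:
    """Full area/volume quantification of one measured individual.

    Dispatches on the record's lipid geometry: droplets are summed as
    circles (area) and spheres (volume); a sac measured as an ellipse uses
    the ellipse/prolate-spheroid formulas; a digitised contour uses the
    shoelace area and the equivalent-ellipse spheroid volume.
    """
    p_area = ellipse_area(record.prosome_length, record.prosome_width)
    p_vol = spheroid_volume(record.prosome_length, record.prosome_width)
    kind = record.geometry_kind
    if kind == "droplets":
        l_area = droplet_lipid_area(record.droplet_diameters)  # type: ignore[arg-type]
        l_vol = sum(math.pi / 6.0 * d**3 for d in record.droplet_diameters)  # type: ignore[union-attr]
    elif kind == "sac_ellipse":
        l_area = ellipse_area(record.sac_length, record.sac_width)  # type: ignore[arg-type]
        l_vol = spheroid_volume(record.sac_length, record.sac_width)  # type: ignore[arg-type]
    elif kind == "sac_contour":
        l_area = polygon_area(record.sac_contour)  # type: ignore[arg-type]
        eq_l, eq_w = contour_equivalent_axes(record.sac_contour)  # type: ignore[arg-type]
        l_vol = spheroid_volume(eq_l, eq_w)
    else:
        l_area = 0.0
        l_vol = 0.0

    if l_area > p_area:
        raise ValueError(
            f"lipid area {l_area:.4g} mm^2 exceeds prosome area {p_area:.4g} mm^2"
        )
    f_lipid = l_vol / p_vol
    flags: tuple[str, ...] = ()
    if f_lipid >= LIPID_FRACTION_BUDGET:
        flags = ("lipid_fraction_exceeds_budget",)
        warnings.warn(
            f"lipid volume fraction {f_lipid:.3f} >= {LIPID_FRACTION_BUDGET}: "
            "exceeds the non-tissue volume budget of the density model",
            stacklevel=2,
        )
    return LipidQuant(
        prosome_area=p_area,
        lipid_area=l_area,
        percent_lipid_area=100.0 * l_area / p_area,
        prosome_volume=p_vol,
        lipid_volume=l_vol,
        lipid_volume_fraction=f_lipid,
        flags=flags,
    )


def apply_scale(pixels, cal: ScaleCalibration, *, kind: str = "length"):
    """Convert pixel measurements to mm using a grid calibration.

    Parameters
    ----------
    pixels
        A scalar, an array, or a polygon (sequence of (x, y)) in pixel units.
    cal
        The :class:`ScaleCalibration` from the grid image.
    kind
        ``"length"`` (factor μm/px ÷ 1000) or ``"area"`` (squared factor).
        Polygons are always treated as coordinate (length) quantities.
    """
    if cal is None:
        raise ValueError("missing calibration")
    factor = cal.microns_per_pixel / 1000.0  # mm per pixel
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:  # polygon
        return [(x * factor, y * factor) for x, y in arr]
    if kind == "length":
        scaled = arr * factor
    elif kind == "area":
        scaled = arr * factor * factor
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(scaled) if np.isscalar(pixels) or arr.ndim == 0 else scaled
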