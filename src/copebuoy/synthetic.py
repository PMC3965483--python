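"""Synthetic morphometric populations, CTD profiles and micrographs.

Every downstream stage of the pipeline (quantification, density modelling,
statistics, image measurement) is testable without field data: this module
generates populations with the published per-group sample sizes and
prosome-length distributions, hydrographic profiles for three site
archetypes, and raster micrographs whose ground-truth areas are known
analytically.

All generators are pure functions of (specification, seed).

Lipid-content levels and CTD temperature/salinity values are *illustrative
configuration defaults* — editable study inputs, not measured values — and
are never used as test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .morphometry import MorphometricRecord, ellipse_area
from .buoyancy import CTDProfile

__all__ = [
    "GroupSpec",
    "CTDArchetype",
    "SyntheticImage",
    "generate_population",
    "generate_ctd",
    "generate_micrograph",
    "generate_grid_image",
    "default_archetypes",
]

SITES = ("red_sea", "med_sea", "arctic")
GEOMETRIES = ("droplets", "sac_ellipse", "sac_contour")

#: ceiling for simulated % lipid area (truncation bound of the generator)
MAX_LIPID_PCT = 95.0


@dataclass(frozen=True)
class GroupSpec:
    """One species/stage/site/date/depth group of a simulated study."""

    species_label: str
    stage_label: str
    site: str
    date_label: str
    depth_layer_m: float
    n: int
    prosome_length_mean: float  # mm
    prosome_length_sd: float  # mm
    width_to_length_ratio: float
    lipid_pct_mean: float  # % of prosome area, illustrative config
    lipid_pct_sd: float
    lipid_geometry: str = "droplets"
    lipid_distribution: str = "truncnorm"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.prosome_length_sd < 0:
            raise ValueError("prosome_length_sd must be >= 0")
        if not 0.0 <= self.lipid_pct_mean < 100.0:
            raise ValueError("lipid_pct_mean must lie in [0, 100)")
        if self.lipid_pct_sd < 0:
            raise ValueError("lipid_pct_sd must be >= 0")
        if not 0.0 < self.width_to_length_ratio < 1.0:
            raise ValueError("width_to_length_ratio must lie in (0, 1)")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.lipid_geometry not in GEOMETRIES:
            raise ValueError(f"unknown lipid_geometry {self.lipid_geometry!r}")
        if self.lipid_distribution not in ("truncnorm", "lognormal"):
            raise ValueError("lipid_distribution must be 'truncnorm' or 'lognormal'")


@dataclass(frozen=True)
class CTDArchetype:
    """Site-level hydrographic shape: depth grid with T and S values."""

    site: str
    depth_grid: tuple[float, ...]
    temperature: tuple[float, ...]
    salinity: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_grid, dtype=float)
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.salinity, dtype=float)
        if d.size == 0:
            raise ValueError("empty depth grid")
        if not (d.size == t.size == s.size):
            raise ValueError("grid/temperature/salinity must have equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(t < -2.0) or np.any(t > 35.0):
            raise ValueError("temperature outside [-2, 35] degC")
        if np.any(s < 0.0) or np.any(s > 45.0):
            raise ValueError("salinity outside [0, 45]")


@dataclass(frozen=True)
class SyntheticImage:
    """Rendered micrograph with analytic ground truth."""

    raster: np.ndarray  # 2D uint16 grayscale
    scale: float  # um per pixel
    truth_prosome_area: float  # mm^2
    truth_lipid_area: float  # mm^2
    truth_contours: tuple = field(default=())
    record: MorphometricRecord | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not self.truth_lipid_area < self.truth_prosome_area:
            raise ValueError("truth_lipid_area must be below truth_prosome_area")


def default_archetypes() -> dict[str, CTDArchetype]:
    """Illustrative hydrographic archetypes for the three study sites.

    Shapes emulate the field settings — warm, near-isothermal subtropical
    columns (Red Sea, Mediterranean) and a strongly stratified cold Arctic
    fjord with a warm fresh surface lens — but the numbers are editable
    configuration, not measurements.
    """
    grid = tuple(float(z) for z in range(0, 85, 5))
    red_t = tuple(25.0 - 0.01 * z for z in grid)
    red_s = tuple(40.5 + 0.002 * z for z in grid)
    med_t = tuple(27.5 - 0.05 * z for z in grid)
    med_s = tuple(39.2 + 0.003 * z for z in grid)
    arc_t = tuple(5.5 - 5.0 * min(z, 30.0) / 30.0 for z in grid)
    arc_s = tuple(32.0 + 2.6 * min(z, 30.0) / 30.0 for z in grid)
    return {
        "red_sea": CTDArchetype("red_sea", grid, red_t, red_s),
        "med_sea": CTDArchetype("med_sea", grid, med_t, med_s),
        "arctic": CTDArchetype("arctic", grid, arc_t, arc_s),
    }


def _truncated_normal(rng, mean, sd, lower, upper, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lipid_percents(rng, spec: GroupSpec) -> np.ndarray:
    if spec.lipid_distribution == "lognormal":
        if spec.lipid_pct_mean <= 0:
            return np.zeros(spec.n)
        # moment-matched lognormal, truncated by resampling at the ceiling
        var = spec.lipid_pct_sd**2
        sigma2 = math.log(1.0 + var / spec.lipid_pct_mean**2)
        mu = math.log(spec.lipid_pct_mean) - sigma2 / 2.0
        out = rng.lognormal(mu, math.sqrt(sigma2), size=spec.n)
        for _ in range(100):
            bad = out >= MAX_LIPID_PCT
            if not bad.any():
                break
            out[bad] = rng.lognormal(mu, math.sqrt(sigma2), size=int(bad.sum()))
        return np.minimum(out, MAX_LIPID_PCT - 1e-9)
    return _truncated_normal(
        rng, spec.lipid_pct_mean, spec.lipid_pct_sd, 0.0, MAX_LIPID_PCT, spec.n
    )


def _ellipse_polygon(length, width, n_vertices=48, jitter=None, rng=None):
    """Polygonal contour of an ellipse, optional radial jitter, area-true."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = np.ones(n_vertices)
    if jitter and rng is not None:
        r += rng.uniform(-jitter, jitter, size=n_vertices)
    x = 0.5 * length * r * np.cos(theta)
    y = 0.5 * width * r * np.sin(theta)
    # rescale so the polygon area equals the requested ellipse area exactly
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    poly_area = abs(0.5 * float(cross.sum()))
    target = ellipse_area(max(length, width), min(length, width))
    f = math.sqrt(target / poly_area)
    return tuple(zip((x * f).tolist(), (y * f).tolist()))


def _make_geometry(rng, spec: GroupSpec, pl: float, pw: float, pct: float):
    """Build the lipid geometry realising a target % lipid area."""
    if pct <= 0:
        if spec.lipid_geometry == "droplets":
            return {"droplet_diameters": ()}
        return {}
    target_area = pct / 100.0 * ellipse_area(pl, pw)
    if spec.lipid_geometry == "droplets":
        k = int(rng.integers(1, 4))
        shares = rng.dirichlet(np.full(k, 5.0)) * target_area
        diam = np.sqrt(4.0 * shares / math.pi)
        return {"droplet_diameters": tuple(float(d) for d in diam)}
    aspect = float(rng.uniform(2.5, 3.5))
    sac_w = math.sqrt(4.0 * target_area / (math.pi * aspect))
    sac_l = aspect * sac_w
    if sac_l > 0.9 * pl:  # keep the sac inside the prosome
        sac_l = 0.9 * pl
        sac_w = 4.0 * target_area / (math.pi * sac_l)
    if spec.lipid_geometry == "sac_ellipse":
        return {"sac_length": sac_l, "sac_width": sac_w}
    contour = _ellipse_polygon(sac_l, sac_w, jitter=0.02, rng=rng)
    return {"sac_contour": contour}


def generate_population(spec: GroupSpec, seed: int) -> list[MorphometricRecord]:
    """Draw one group of individuals from the spec's distributions.

    Prosome lengths come from a normal distribution truncated at ±4 SD and
    at zero; widths are length × ratio with 2% multiplicative noise; the
    implied % lipid area is drawn from a truncated normal on [0, 95] (or a
    moment-matched lognormal when requested) and realised exactly by the
    constructed droplet/sac geometry.
    """
    rng = np.random.default_rng(seed)
    lower = max(0.0, spec.prosome_length_mean - 4.0 * spec.prosome_length_sd)
    upper = spec.prosome_length_mean + 4.0 * spec.prosome_length_sd
    lengths = _truncated_normal(
        rng, spec.prosome_length_mean, spec.prosome_length_sd, lower, upper, spec.n
    )
    ratio_noise = 1.0 + rng.normal(0.0, 0.02, size=spec.n)
    widths = lengths * spec.width_to_length_ratio * ratio_noise
    widths = np.minimum(widths, lengths * 0.999)
    percents = _lipid_percents(rng, spec)
    records = []
    for pl, pw, pct in zip(lengths, widths, percents):
        geometry = _make_geometry(rng, spec, float(pl), float(pw), float(pct))
        records.append(
            MorphometricRecord(
                species_label=spec.species_label,
                stage_label=spec.stage_label,
                site=spec.site,
                date_label=spec.date_label,
                depth_layer_m=spec.depth_layer_m,
                prosome_length=float(pl),
                prosome_width=float(pw),
                **geometry,
            )
        )
    return records


def generate_ctd(archetype: CTDArchetype, noise_sd: float, seed: int) -> CTDProfile:
    """Perturb an archetype with independent Gaussian noise on T and S."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(archetype.temperature) + rng.normal(0, noise_sd, len(archetype.temperature))
    s = np.asarray(archetype.salinity) + rng.normal(0, noise_sd, len(archetype.salinity))
    return CTDProfile(
        depth=archetype.depth_grid,
        temperature=tuple(map(float, t)),
        salinity=tuple(map(float, np.clip(s, 0.0, 45.0))),
    )


# ---------------------------------------------------------------------------
# raster rendering

_BACKGROUND = 0.15
_PROSOME = 0.55
_OIL = 0.90


def _fill_ellipse(img, cy, cx, ry, rx, value):
    from skimage.draw import ellipse as draw_ellipse

    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=img.shape)
    img[rr, cc] = value


def generate_micrograph(
    record: MorphometricRecord,
    scale: float,
    noise_level: float,
    seed: int,
    margin: float = 0.25,
) -> SyntheticImage:
    """Render one individual as a grayscale micrograph with known truth.

    The prosome is a filled axis-aligned ellipse at mid intensity on a dark
    background; oil bodies are brighter regions inside it (disks for
    droplets, an ellipse for sacs, the digitised polygon for contour sacs).
    Additive Gaussian noise of standard deviation ``noise_level`` (on the
    0–1 intensity scale) is applied before 16-bit quantisation.  Truth
    areas are the analytic areas of the rendered shapes.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    px_per_mm = 1000.0 / scale
    h = int(round(record.prosome_width * px_per_mm * (1 + 2 * margin)))
    w = int(round(record.prosome_length * px_per_mm * (1 + 2 * margin)))
    if max(h, w) > 4096:
        raise ValueError("rendered raster exceeds 4096 px; use a coarser scale")
    img = np.full((h, w), _BACKGROUND, dtype=float)
    cy, cx = h / 2.0, w / 2.0
    ry = record.prosome_width / 2.0 * px_per_mm
    rx = record.prosome_length / 2.0 * px_per_mm
    if ry * 2 >= h or rx * 2 >= w:
        raise ValueError("prosome exceeds raster bounds")
    _fill_ellipse(img, cy, cx, ry, rx, _PROSOME)

    truth_prosome = ellipse_area(record.prosome_length, record.prosome_width)
    truth_lipid = 0.0
    contours = []
    rng = np.random.default_rng(seed)
    kind = record.geometry_kind
    if kind == "droplets" and record.droplet_diameters:
        from skimage.draw import disk

        diams = record.droplet_diameters
        total_span = sum(diams) * px_per_mm
        gap = max((2 * rx * 0.8 - total_span) / (len(diams) + 1), 2.0)
        x = cx - (total_span + gap * (len(diams) - 1)) / 2.0
        for d in diams:
            r = d / 2.0 * px_per_mm
            x += r
            rr, cc = disk((cy, x), r, shape=img.shape)
            img[rr, cc] = _OIL
            truth_lipid += math.pi / 4.0 * d * d
            contours.append(("disk", (cy, x), r))
            x += r + gap
    elif kind == "sac_ellipse":
        sr_y = record.sac_width / 2.0 * px_per_mm  # type: ignore[operator]
        sr_x = record.sac_length / 2.0 * px_per_mm  # type: ignore[operator]
        _fill_ellipse(img, cy, cx, sr_y, sr_x, _OIL)
        truth_lipid = ellipse_area(record.sac_length, record.sac_width)  # type: ignore[arg-type]
        contours.append(("ellipse", (cy, cx), (sr_y, sr_x)))
    elif kind == "sac_contour":
        from skimage.draw import polygon as draw_polygon

        from .morphometry import polygon_area

        pts = np.asarray(record.sac_contour, dtype=float)
        rr = cy + pts[:, 1] * px_per_mm
        cc = cx + pts[:, 0] * px_per_mm
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
            raise ValueError("sac contour exceeds raster bounds")
        fr, fc = draw_polygon(rr, cc, shape=img.shape)
        img[fr, fc] = _OIL
        truth_lipid = polygon_area(record.sac_contour)  # type: ignore[arg-type]
        contours.append(("polygon", tuple(zip(rr.tolist(), cc.tolist()))))

    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    raster = np.round(img * 65535.0).astype(np.uint16)
    return SyntheticImage(
        raster=raster,
        scale=scale,
        truth_prosome_area=truth_prosome,
        truth_lipid_area=truth_lipid,
        truth_contours=tuple(contours),
        record=record,
    )


def generate_grid_image(
    spacing_px: float, shape: tuple[int, int] = (400, 400), line_value: float = 0.1,
    background: float = 0.9, line_width: int = 2,
) -> np.ndarray:
    """Calibration-grid raster: dark horizontal+vertical lines on light field."""
    if spacing_px <= line_width:
        raise ValueError("spacing must exceed line width")
    img = np.full(shape, background, dtype=float)
    # lines at integer multiples of the spacing so inter-line pixel
    # distances are uniform (no half-pixel rounding alternation)
    for x in np.arange(spacing_px, shape[1] - 1, spacing_px):
        lo = int(round(x))
        img[:, lo : lo + line_width] = line_value
    for y in np.arange(spacing_px, shape[0] - 1, spacing_px):
        lo = int(round(y))
        img[lo : lo + line_width, :] = line_value
    return np.round(img * 65535.0).astype(np.uint16)
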