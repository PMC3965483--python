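"""Geometry and quantification: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copebuoy import (
    MorphometricRecord,
    ScaleCalibration,
    apply_scale,
    contour_equivalent_axes,
    droplet_lipid_area,
    ellipse_area,
    polygon_area,
    quantify,
    spheroid_volume,
)


def _regular_polygon(n, rx=1.0, ry=1.0, rotate=0.0):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False) + rotate
    return list(zip(rx * np.cos(th), ry * np.sin(th)))


class TestClosedForms:
    @pytest.mark.parametrize(
        "fn, args, expected",
        [
            (ellipse_area, (1.0, 1.0), math.pi / 4),
            (ellipse_area, (2.0, 1.0), math.pi / 2),
            (droplet_lipid_area, ([1.0],), math.pi / 4),
            (droplet_lipid_area, ([1.0, 1.0],), math.pi / 2),
            (droplet_lipid_area, ([],), 0.0),
            (spheroid_volume, (1.0, 1.0), math.pi / 6),
            (spheroid_volume, (2.0, 1.0), math.pi / 3),
            (polygon_area, ([(0, 0), (1, 0), (1, 1), (0, 1)],), 1.0),
            (polygon_area, ([(0, 1), (1, 1), (1, 0), (0, 0)],), 1.0),  # reversed
        ],
    )
    def test_exact_values(self, fn, args, expected):
        assert fn(*args) == pytest.approx(expected, abs=1e-9)

    def test_sphere_consistency(self):
        d = 0.37
        assert spheroid_volume(d, d) == pytest.approx(math.pi * d**3 / 6, rel=1e-12)

    @pytest.mark.parametrize("fn", [ellipse_area, spheroid_volume])
    def test_invalid_axes_raise(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, -0.5)
        with pytest.raises(ValueError):
            fn(0.5, 1.0)  # width > length

    def test_negative_diameter_raises(self):
        with pytest.raises(ValueError):
            droplet_lipid_area([0.5, -0.1])


class TestPolygonOracles:
    def test_self_intersecting_contour_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError):
            polygon_area(bowtie)
        with pytest.raises(ValueError):
            polygon_area([(0, 0), (1, 1)])

    def test_convex_polygon_matches_monte_carlo(self, rng):
        """Shoelace area vs point-in-polygon MC estimate (1e6 points)."""
        from shapely.geometry import Point, Polygon

        radii = rng.uniform(0.6, 1.4, size=12)
        th = np.sort(rng.uniform(0, 2 * math.pi, size=12))
        poly = [(r * math.cos(t), r * math.sin(t)) for r, t in zip(radii, th)]
        area = polygon_area(poly)
        shp = Polygon(poly)
        n = 10**6
        pts = rng.uniform(-1.5, 1.5, size=(n, 2))
        inside = shp.contains(Point(0, 0))  # warm shapely up; trivial
        from shapely import contains_xy

        hits = contains_xy(shp, pts[:, 0], pts[:, 1]).sum()
        mc_area = hits / n * 9.0
        assert area == pytest.approx(mc_area, rel=5e-3)

    def test_ellipse_area_matches_rasterization(self):
        """Ellipse closed form vs pixel-count oracle at >= 100 px."""
        from skimage.draw import ellipse as draw_ellipse

        L, W = 2.0, 1.0
        px_per_unit = 200.0
        rr, cc = draw_ellipse(300, 300, W / 2 * px_per_unit, L / 2 * px_per_unit,
                              shape=(600, 600))
        pixel_area = len(rr) / px_per_unit**2
        assert ellipse_area(L, W) == pytest.approx(pixel_area, rel=1e-2)


class TestEquivalentAxes:
    def test_dense_ellipse_contour_recovers_axes(self):
        contour = _regular_polygon(720, rx=1.0, ry=0.5)
        length, width = contour_equivalent_axes(contour)
        assert length == pytest.approx(2.0, rel=1e-2)
        assert width == pytest.approx(1.0, rel=1e-2)

    def test_circle_contour_is_isotropic(self):
        contour = _regular_polygon(256, rx=1.0, ry=1.0)
        length, width = contour_equivalent_axes(contour)
        assert length == pytest.approx(width, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_area_preserved_for_random_convex_polygons(self, seed):
        rng = np.random.default_rng(seed)
        radii = rng.uniform(0.3, 1.2, size=10)
        th = np.sort(rng.uniform(0, 2 * math.pi, size=10))
        poly = [(r * math.cos(t), r * math.sin(t)) for r, t in zip(radii, th)]
        length, width = contour_equivalent_axes(poly)
        assert ellipse_area(length, width) == pytest.approx(
            polygon_area(poly), rel=1e-9
        )

    def test_degenerate_contour_raises(self):
        collinear = [(0, 0), (1, 0), (2, 0)]
        with pytest.raises(ValueError):
            contour_equivalent_axes(collinear)


class TestQuantify:
    def test_hand_computed_droplet_example(self, droplet_record):
        q = quantify(droplet_record)
        # 100 * (pi*0.01) / ((pi/4)*0.5) = 8.0 %
        assert q.percent_lipid_area == pytest.approx(8.0, rel=1e-12)
        assert q.lipid_volume == pytest.approx(math.pi / 6 * 0.2**3, rel=1e-12)

    def test_lipid_empty_record(self):
        rec = MorphometricRecord("sp", "C5", "red_sea", "d", 5, 1.0, 0.5)
        q = quantify(rec)
        assert q.percent_lipid_area == 0.0
        assert q.lipid_volume_fraction == 0.0

    def test_scaling_all_lengths_by_two(self, droplet_record):
        q1 = quantify(droplet_record)
        scaled = MorphometricRecord(
            "sp", "C5", "red_sea", "d", 5, 2.0, 1.0,
            droplet_diameters=(0.4,),
        )
        q2 = quantify(scaled)
        assert q2.percent_lipid_area == pytest.approx(q1.percent_lipid_area, rel=1e-12)
        assert q2.lipid_volume == pytest.approx(8 * q1.lipid_volume, rel=1e-12)
        assert q2.prosome_volume == pytest.approx(8 * q1.prosome_volume, rel=1e-12)

    def test_contour_and_parametric_sac_agree(self):
        """Ellipse-consistent contours give the same volume as sac axes."""
        sac_l, sac_w = 0.6, 0.2
        contour = [(0.5 * sac_l * math.cos(t), 0.5 * sac_w * math.sin(t))
                   for t in np.linspace(0, 2 * math.pi, 360, endpoint=False)]
        via_axes = quantify(MorphometricRecord(
            "sp", "C5", "red_sea", "d", 5, 1.2, 0.5,
            sac_length=sac_l, sac_width=sac_w))
        via_contour = quantify(MorphometricRecord(
            "sp", "C5", "red_sea", "d", 5, 1.2, 0.5, sac_contour=contour))
        assert via_contour.lipid_volume == pytest.approx(via_axes.lipid_volume, rel=1e-2)
        assert via_contour.lipid_area == pytest.approx(via_axes.lipid_area, rel=1e-3)

    def test_lipid_exceeding_prosome_raises(self):
        rec = MorphometricRecord("sp", "C5", "red_sea", "d", 5, 1.0, 0.5,
                                 droplet_diameters=(0.9,))
        with pytest.raises(ValueError, match="exceeds prosome"):
            quantify(rec)

    def test_overfull_lipid_fraction_flagged(self):
        rec = MorphometricRecord("sp", "C5", "red_sea", "d", 5, 1.0, 0.9,
                                 sac_length=0.97, sac_width=0.85)
        with pytest.warns(UserWarning, match="non-tissue volume budget"):
            q = quantify(rec)
        assert "lipid_fraction_exceeds_budget" in q.flags

    def test_record_geometry_exclusivity(self):
        with pytest.raises(ValueError):
            MorphometricRecord("sp", "C5", "red_sea", "d", 5, 1.0, 0.5,
                               droplet_diameters=(0.1,), sac_length=0.3,
                               sac_width=0.1)


class TestApplyScale:
    CAL = ScaleCalibration(microns_per_pixel=1.0, grid_spacing=10.0)

    def test_linear_and_area(self):
        assert apply_scale(1000.0, self.CAL) == pytest.approx(1.0)
        assert apply_scale(1e6, self.CAL, kind="area") == pytest.approx(1.0)

    def test_round_trip_identity(self):
        cal = ScaleCalibration(microns_per_pixel=0.73, grid_spacing=10.0)
        mm = 1.234
        px = mm / (cal.microns_per_pixel / 1000.0)
        assert apply_scale(px, cal) == pytest.approx(mm, rel=1e-12)

    def test_missing_calibration(self):
        with pytest.raises(ValueError):
            apply_scale(10.0, None)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    length=st.floats(0.3, 5.0),
    ratio=st.floats(0.1, 0.95),
    d_frac=st.floats(0.05, 0.4),
    scale=st.floats(0.1, 10.0),
)
def test_percent_lipid_area_scale_invariant(length, ratio, d_frac, scale):
    """% lipid area is invariant under uniform linear scaling."""
    width = length * ratio
    d = width * d_frac
    base = quantify(MorphometricRecord("sp", "C5", "red_sea", "d", 5,
                                       length, width, droplet_diameters=(d,)))
    scaled = quantify(MorphometricRecord("sp", "C5", "red_sea", "d", 5,
                                         length * scale, width * scale,
                                         droplet_diameters=(d * scale,)))
    assert scaled.percent_lipid_area == pytest.approx(
        base.percent_lipid_area, rel=1e-9)
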