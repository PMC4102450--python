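import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from mitoflip.geometry import (GeometryError, LobeParams, build_ea_geometry,
                               build_la_geometry, export_obj, prolate_area,
                               region_of, signed_distance, surface_area)


def test_sphere_limit_total_area():
    """Two equal spheres joined by a vanishing neck have area ~ 8 pi r^2."""
    m = LobeParams(semi_axis_long=1.0, semi_axis_short=1.0)
    d = LobeParams(semi_axis_long=1.0, semi_axis_short=1.0, orientation="daughter")
    g = build_ea_geometry(m, d, perinuclear_thickness_lobe=0.001,
                          neck_opening_radius=0.01)
    assert surface_area(g, "ONM") == pytest.approx(8 * np.pi, rel=5e-3)
    assert surface_area(g, "ONM", "mother_lobe") == pytest.approx(4 * np.pi, rel=5e-3)


def test_prolate_lobe_area_matches_closed_form():
    m = LobeParams(semi_axis_long=1.2, semi_axis_short=0.9)
    d = LobeParams(semi_axis_long=1.0, semi_axis_short=0.8, orientation="daughter")
    g = build_ea_geometry(m, d, neck_opening_radius=0.03)
    assert surface_area(g, "ONM", "mother_lobe") == pytest.approx(
        prolate_area(1.2, 0.9), rel=5e-3)


def test_inm_offset_by_perinuclear_thickness(ea_asym):
    """INM radius sits one lobe thickness (22 nm) inside the ONM."""
    xq = np.array(-1.2)  # mother lobe, away from neck and apex
    gap = float(ea_asym.onm.rho(xq) - ea_asym.inm.rho(xq))
    # radial gap >= normal-offset thickness; equal where the surface is flat
    assert 0.022 <= gap < 0.05


def test_la_bridge_area_and_inm_radius(la_standard):
    assert surface_area(la_standard, "ONM", "bridge") == pytest.approx(
        np.pi * 0.2 * 2.85, rel=1e-2)
    assert float(la_standard.inm.rho(np.array(0.0))) == pytest.approx(0.1 - 0.013, abs=1e-4)


def test_sphere_recovered_from_teardrop_limit():
    """piriform_deviation -> 0 and a vanishing bridge recover sphere areas."""
    m = LobeParams(piriform_scale=2.0, piriform_deviation=0.0)
    d = LobeParams(piriform_scale=2.0, piriform_deviation=0.0, orientation="daughter")
    g = build_la_geometry(m, d, bridge_length=0.05, bridge_diameter=0.1)
    assert surface_area(g, "ONM") == pytest.approx(2 * 4 * np.pi * 1.0 ** 2, rel=5e-3)


def test_signed_distance_basic(ea_spheres):
    centre = np.array([-1.0, 0.0, 0.0])  # near the mother-lobe centre
    sd = signed_distance(ea_spheres, "ONM", centre)
    assert sd == pytest.approx(-1.0, rel=0.05)
    pts = ea_spheres.onm.sample_surface(50, np.random.default_rng(0))
    assert np.max(np.abs(signed_distance(ea_spheres, "ONM", pts))) < 1e-6


def test_signed_distance_sign_matches_ray_casting(la_standard):
    """Sign agrees with point-in-polygon on the meridian cross-section."""
    prof = la_standard.onm
    poly = Polygon(np.column_stack(
        [np.concatenate([prof.x, prof.x[::-1]]),
         np.concatenate([prof.r, -prof.r[::-1]])]))
    rng = np.random.default_rng(1)
    pts = rng.uniform([-3, -2, -2], [3, 2, 2], size=(300, 3))
    sd = signed_distance(la_standard, "ONM", pts)
    for p, s in zip(pts, sd):
        inside = poly.contains(Point(p[0], np.hypot(p[1], p[2])))
        if abs(s) > 1e-3:  # skip points numerically on the surface
            assert (s < 0) == inside


def test_region_labels(la_standard, ea_spheres):
    on_bridge = np.array([0.0, 0.1, 0.0])
    assert region_of(la_standard, "ONM", on_bridge) == "bridge"
    neck_pt = np.array([0.0, float(ea_spheres.onm.rho(np.array(0.0))), 0.0])
    assert region_of(ea_spheres, "ONM", neck_pt) == "neck"
    with pytest.raises(GeometryError):
        region_of(la_standard, "ONM", np.array([0.0, 5.0, 0.0]))


def test_region_area_fractions_match_sampling(la_standard):
    """Uniform surface sampling reproduces analytic region area fractions."""
    prof = la_standard.onm
    pts = prof.sample_surface(10_000, np.random.default_rng(3))
    labels = la_standard.region_of_x(pts[:, 0])
    total = surface_area(la_standard, "ONM")
    for region in ("mother_lobe", "bridge", "daughter_lobe"):
        frac = np.mean(labels == region)
        expected = surface_area(la_standard, "ONM", region) / total
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / 10_000) + 0.005)


def test_inm_strictly_inside_onm(la_standard, ea_asym):
    for g in (la_standard, ea_asym):
        pts = g.inm.sample_surface(500, np.random.default_rng(4))
        assert np.max(g.onm.signed_distance(pts)) < 0


def test_parameter_validation():
    with pytest.raises(GeometryError):
        LobeParams(semi_axis_long=-1.0, semi_axis_short=0.5).ea_axes()
    with pytest.raises(GeometryError):
        LobeParams(semi_axis_long=0.5, semi_axis_short=0.9).ea_axes()
    m = LobeParams(piriform_scale=1.0)
    d = LobeParams(piriform_scale=1.0, orientation="daughter")
    with pytest.raises(GeometryError):  # bridge wider than the lobes
        build_la_geometry(m, d, bridge_length=1.0, bridge_diameter=1.5)
    small = LobeParams(semi_axis_long=0.8, semi_axis_short=0.7)
    big = LobeParams(semi_axis_long=1.2, semi_axis_short=1.0, orientation="daughter")
    with pytest.warns(UserWarning, match="daughter"):
        build_ea_geometry(small, big)


def test_obj_export(tmp_path, ea_spheres):
    path = tmp_path / "onm.obj"
    export_obj(ea_spheres, "ONM", str(path))
    text = path.read_text()
    assert text.startswith("v ") and "\nf " in text
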