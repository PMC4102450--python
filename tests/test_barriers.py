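import numpy as np
import pytest

from mitoflip.barriers import (BarrierConfigError, LipidDomainConfig, ProteinRing,
                               domain_membership, place_protein_ring, preset_domain,
                               ring_capacity, ring_layout)


@pytest.mark.parametrize("length,expected", [(2.85, 5), (1.2, 3), (4.5, 7)])
def test_ring_layout_counts(length, expected):
    """Measured bridge lengths yield the reported 3/5/7-ring layouts."""
    centres = ring_layout(length, 0.3)
    assert centres.size == expected


def test_ring_layout_geometry_rules():
    centres = ring_layout(2.85, 0.3)
    assert np.allclose(centres, -centres[::-1])          # symmetric about midpoint
    assert centres[0] == pytest.approx(-2.85 / 2 + 0.15)  # flush with the junction
    gaps = np.diff(centres) - 0.3
    assert np.all(gaps >= 0.15 - 1e-9) and np.all(gaps <= 0.6 + 1e-9)


def test_ring_layout_infeasible_reports_windows():
    with pytest.raises(BarrierConfigError, match="feasible bridge-length"):
        ring_layout(0.95, 0.3)
    with pytest.raises(BarrierConfigError):
        ring_layout(0.2, 0.3)  # bridge shorter than one ring


def test_ring_capacity_packing_arithmetic():
    ring = ProteinRing(n=0, protein_diameter=11.0, overlap_fraction=0.15)
    circ = 2 * np.pi * 150.0  # nm
    assert ring_capacity(circ, ring) == int(np.floor(circ / (11.0 * 0.85)))
    double = ProteinRing(n=0, arrangement="double")
    assert ring_capacity(circ, double) == 2 * ring_capacity(circ, ring)


def test_place_protein_ring(ea_spheres):
    assert place_protein_ring(ea_spheres, ProteinRing(n=0)).shape == (0, 3)
    ring = ProteinRing(n=30, position=0.0)
    c1 = place_protein_ring(ea_spheres, ring, seed=5)
    c2 = place_protein_ring(ea_spheres, ring, seed=5)
    assert np.array_equal(c1, c2)  # deterministic given seed
    assert np.max(np.abs(ea_spheres.onm.signed_distance(c1))) < 1e-3
    spacing = np.linalg.norm(np.diff(np.vstack([c1, c1[:1]]), axis=0), axis=1)
    assert np.all(spacing * 1e3 >= 11.0 * 0.85 - 1e-6)
    with pytest.raises(BarrierConfigError, match="capacity"):
        place_protein_ring(ea_spheres, ProteinRing(n=10_000), seed=1)


def test_double_ring_two_circles(ea_spheres):
    ring = ProteinRing(n=40, arrangement="double", position=0.0)
    centres = place_protein_ring(ea_spheres, ring, seed=2)
    xs = np.unique(np.round(centres[:, 0], 6))
    assert xs.size == 2
    assert (xs[1] - xs[0]) * 1e3 == pytest.approx(8.0, abs=1e-6)  # 8 nm apart


def test_domain_membership(la_standard):
    homog = LipidDomainConfig(layout="homogeneous_bridge", P_in=15.0)
    assert domain_membership(homog, la_standard, np.array([0.0, 0.1, 0.0]))
    assert not domain_membership(homog, la_standard, np.array([-2.5, 0.5, 0.0]))
    multi = LipidDomainConfig(layout="multi_ring", width=0.3, P_in=10.0)
    pts = la_standard.onm.sample_surface(8000, np.random.default_rng(0))
    lo, hi = la_standard.junction_planes
    on_bridge = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
    frac = np.mean(domain_membership(multi, la_standard, pts[on_bridge]))
    assert frac == pytest.approx(5 * 0.3 / 2.85, abs=0.03)  # 5 rings of 300 nm


def test_domain_config_validation():
    with pytest.raises(BarrierConfigError):
        LipidDomainConfig(P_in=150.0)
    with pytest.raises(BarrierConfigError):
        LipidDomainConfig(P_in=50.0, P_out=20.0)  # domain may exclude, not attract
    with pytest.raises(BarrierConfigError):
        ProteinRing(n=-1)


def test_presets_reflect_fitted_entry_probabilities():
    assert preset_domain("ea_single_ring_nsg1").P_in == 3.5
    assert preset_domain("ea_single_ring_src1").P_in == 7.0
    assert preset_domain("la_homogeneous_nsg1").P_in == 15.0
    npc = preset_domain("la_single_ring_npc_both")
    assert npc.P_in == 1.5 and npc.width == pytest.approx(0.1)
    assert preset_domain("la_multi_ring_src1").P_in == 30.0
    override = preset_domain("la_homogeneous_nsg1", P_in=20.0)
    assert override.P_in == 20.0
    with pytest.raises(BarrierConfigError, match="unknown preset"):
        preset_domain("nope")
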