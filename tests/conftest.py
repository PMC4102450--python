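import numpy as np
import pytest

from mitoflip.geometry import LobeParams, Profile, build_ea_geometry, build_la_geometry


@pytest.fixture(scope="session")
def ea_spheres():
    """Symmetric EA nucleus: two equal unit-sphere lobes."""
    m = LobeParams(semi_axis_long=1.0, semi_axis_short=1.0)
    d = LobeParams(semi_axis_long=1.0, semi_axis_short=1.0, orientation="daughter")
    return build_ea_geometry(m, d)


@pytest.fixture(scope="session")
def ea_asym():
    """Asymmetric EA nucleus (mother prolate, smaller daughter)."""
    m = LobeParams(semi_axis_long=1.2, semi_axis_short=0.9)
    d = LobeParams(semi_axis_long=0.95, semi_axis_short=0.8, orientation="daughter")
    return build_ea_geometry(m, d)


@pytest.fixture(scope="session")
def la_standard():
    """LA nucleus at the measured mean bridge length."""
    m = LobeParams(piriform_scale=2.2, piriform_deviation=0.5)
    d = LobeParams(piriform_scale=2.0, piriform_deviation=0.5, orientation="daughter")
    return build_la_geometry(m, d, bridge_length=2.85, bridge_diameter=0.2)


@pytest.fixture(scope="session")
def la_small():
    """Reduced-scale LA nucleus for kinetics tests."""
    m = LobeParams(piriform_scale=1.2, piriform_deviation=0.4)
    d = LobeParams(piriform_scale=1.2, piriform_deviation=0.4, orientation="daughter")
    return build_la_geometry(m, d, bridge_length=2.0, bridge_diameter=0.3)


@pytest.fixture(scope="session")
def cylinder_profile():
    """Open cylinder: intrinsically flat surface for Brownian oracles."""
    xs = np.linspace(-4.0, 4.0, 200)
    return Profile(xs, np.full_like(xs, 1.0), {}, n_vertices=8000, fillet=0.0)
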