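import numpy as np
import pytest

from mitoflip import units
from mitoflip.hydrodynamics import (HydroModelError, InclusionSpec, MembraneSpec,
                                    domain_diffusion, domain_thickness,
                                    invert_surface_viscosity, membrane_report,
                                    petrov_schwille_D, reduced_radius,
                                    saffman_delbruck_D, viscous_drag)


def _membrane_at_eps(r_nm: float, eps: float) -> MembraneSpec:
    mu_s = r_nm * 1e-9 * 2 * units.CYTOPLASM_VISCOSITY / eps
    return MembraneSpec(mu_s=mu_s)


def test_sd_logarithmic_size_dependence():
    """Doubling the inclusion radius lowers D by exactly kT ln2 / (4 pi mu_s)."""
    mem = _membrane_at_eps(2.0, 1e-3)
    d1 = saffman_delbruck_D(InclusionSpec(r=2.0), mem)
    d2 = saffman_delbruck_D(InclusionSpec(r=4.0), mem)
    expected_drop = units.m2_s_to_um2_s(
        units.K_B * mem.T / (4 * np.pi * mem.mu_s) * np.log(2))
    assert d1 - d2 == pytest.approx(expected_drop, rel=1e-12)


def test_ps_reduces_to_sd_at_small_reduced_radius():
    for r in (1.0, 2.0, 5.0):
        mem = _membrane_at_eps(r, 1e-3)
        incl = InclusionSpec(r=r)
        assert petrov_schwille_D(incl, mem) == pytest.approx(
            saffman_delbruck_D(incl, mem), rel=1e-2)


def test_ps_monotone_decreasing_in_radius():
    mem = MembraneSpec(mu_s=1e-9)
    ds = [petrov_schwille_D(InclusionSpec(r=r), mem)
          for r in np.linspace(1.0, 100.0, 40)]
    assert np.all(np.diff(ds) < 0)


def test_reduced_radius_scaling_and_window_warning():
    mem = MembraneSpec(mu_s=1e-9)
    e1 = reduced_radius(InclusionSpec(r=2.0), mem, warn=False)
    e2 = reduced_radius(InclusionSpec(r=4.0), mem, warn=False)
    assert e2 == pytest.approx(2 * e1)
    tiny = _membrane_at_eps(2.0, 1e-5)
    with pytest.warns(UserWarning, match="outside the validated window"):
        reduced_radius(InclusionSpec(r=2.0), tiny)


def test_viscosity_inversion_round_trip():
    mem = MembraneSpec(mu_s=1e-9)
    for d_eff in (0.05, 0.3, 1.0):
        incl = InclusionSpec(r=3.0, D_eff=d_eff)
        mu = invert_surface_viscosity(d_eff, incl, mem)
        assert petrov_schwille_D(incl, mem.with_surface_viscosity(mu)) == pytest.approx(
            d_eff, rel=1e-6)
    mu_slow = invert_surface_viscosity(0.05, InclusionSpec(r=3.0), mem)
    mu_fast = invert_surface_viscosity(1.0, InclusionSpec(r=3.0), mem)
    assert mu_slow > mu_fast  # slower diffusion implies higher viscosity


def test_einstein_smoluchowski_relations():
    zeta = viscous_drag(0.3, T=303.15)
    assert zeta * units.um2_s_to_m2_s(0.3) == pytest.approx(
        units.K_B * 303.15, rel=1e-12)
    assert viscous_drag(0.6) == pytest.approx(viscous_drag(0.3) / 2)
    # a three-fold raft drag drops 0.3 um^2/s to 0.1 um^2/s
    assert domain_diffusion(0.3, 3.0) == pytest.approx(0.1)
    assert domain_diffusion(0.3, 1.0) == pytest.approx(0.3)
    folds = np.array([1.0, 2.0, 5.0])
    assert np.allclose([domain_diffusion(1.0, f) for f in folds], 1.0 / folds)


def test_domain_thickness_bilayer():
    # ~7 A per leaflet thickens a 4 nm bilayer to ~5.4 nm
    assert domain_thickness(4.0, 0.7) == pytest.approx(5.4)
    assert domain_thickness(4.0, 0.0) == pytest.approx(4.0)


def test_membrane_spec_consistency_check():
    MembraneSpec(h=4.0, mu_m=0.25, mu_s=0.25 * 4e-9)  # consistent
    with pytest.raises(HydroModelError):
        MembraneSpec(h=4.0, mu_m=0.25, mu_s=1e-8)
    with pytest.raises(HydroModelError):
        MembraneSpec()  # neither viscosity given
    with pytest.raises(HydroModelError):
        InclusionSpec(r=-1.0)


def test_membrane_report_round_trips():
    mem = MembraneSpec(mu_s=1e-9)
    df = membrane_report(
        [("A", InclusionSpec(r=2.0, D_eff=0.3)),
         ("B", InclusionSpec(r=40.0, D_eff=0.05))], mem)
    assert list(df["species"]) == ["A", "B"]
    assert np.allclose(df["D_in_um2_s"], df["D_out_um2_s"] / 3.0)
    # inverted surface viscosity reproduces the measured D through the PS model
    for _, row in df.iterrows():
        m_fit = mem.with_surface_viscosity(row["mu_s_Pa_s_m"])
        incl = InclusionSpec(r=row["radius_nm"])
        assert petrov_schwille_D(incl, m_fit) == pytest.approx(
            row["D_out_um2_s"], rel=1e-6)
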