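import numpy as np
import pytest

from mitoflip.barriers import LipidDomainConfig, PermeablePlane, ProteinRing
from mitoflip.engine import (BoxEnclosure, EngineConfigError, FlipProtocol,
                             InteriorEnclosure, ShellEnclosure, Species,
                             apply_domain_rule, bleach_step, choose_time_step,
                             collide_obstacles, run_flip, surface_step, volume_step)
from mitoflip.flip_analysis import degree_of_compartmentalization


def test_choose_time_step_reference_values():
    """dt = dx^2/(2 d D): 40 us corresponds to ~7 nm for a membrane species."""
    nsg1 = Species(name="Nsg1", enclosure="ONM", D_eff=0.3)
    tetr = Species(name="TetR", enclosure="nucleoplasm", D_eff=1.9)
    dt, steps = choose_time_step([nsg1], target_resolution=6.93)
    assert dt == pytest.approx(40e-6, rel=2e-3)
    dt40 = 40e-6
    # implied step lengths at 40 us
    _, steps = choose_time_step([nsg1, tetr], target_resolution=1.0, governing="TetR")
    dx_nsg1 = np.sqrt(2 * 2 * 0.3 * dt40) * 1e3
    dx_tetr = np.sqrt(2 * 3 * 1.9 * dt40) * 1e3
    assert dx_nsg1 == pytest.approx(6.93, abs=0.01)
    assert dx_tetr == pytest.approx(21.4, abs=0.1)
    # halving the target resolution quarters the time step
    dt_half, _ = choose_time_step([nsg1], target_resolution=6.93 / 2)
    assert dt_half == pytest.approx(dt / 4)
    with pytest.raises(EngineConfigError):
        choose_time_step([])


def test_surface_step_zero_diffusion_is_identity(cylinder_profile):
    rng = np.random.default_rng(0)
    pos = cylinder_profile.sample_surface(50, rng)
    new, _ = surface_step(pos, cylinder_profile, 0.0, 1e-3, rng)
    assert np.allclose(new, pos, atol=1e-9)


def test_surface_msd_on_flat_cylinder(cylinder_profile):
    """Lateral MSD on an intrinsically flat surface follows 4 D t."""
    rng = np.random.default_rng(1)
    n, steps, D, dt = 3000, 200, 1.0, 1e-3
    pos = np.column_stack([np.zeros(n), np.ones(n), np.zeros(n)])
    phi0 = np.zeros(n)
    hint = None
    for _ in range(steps):
        pos, hint = surface_step(pos, cylinder_profile, D, dt, rng, hint)
    phi = np.arctan2(pos[:, 2], pos[:, 1])
    msd = np.mean(pos[:, 0] ** 2 + np.unwrap(np.column_stack([phi0, phi]), axis=1)[:, 1] ** 2)
    expect = 4 * D * dt * steps
    se = np.std(pos[:, 0] ** 2 + phi ** 2) / np.sqrt(n)
    assert abs(msd - expect) < 3 * se + 0.02 * expect


def test_box_msd_and_reflection():
    rng = np.random.default_rng(2)
    box = BoxEnclosure(np.array([[-50.0, 50.0]] * 3))
    pos = np.zeros((3000, 3))
    D, dt, steps = 1.9, 1e-3, 200
    for _ in range(steps):
        pos = volume_step(pos, D, dt, box, rng)
    assert np.all(box.contains(pos))
    msd = np.mean(np.sum(pos ** 2, axis=1))
    d2 = np.sum(pos ** 2, axis=1)
    se = np.std(d2) / np.sqrt(pos.shape[0])
    assert abs(msd - 6 * D * dt * steps) < 3 * se


def test_perinuclear_shell_containment(ea_asym):
    """A perinuclear diffuser never violates the ONM/INM bounds."""
    shell = ShellEnclosure(ea_asym.onm, ea_asym.inm)
    rng = np.random.default_rng(3)
    pos = shell.sample(40, rng)
    for _ in range(2500):
        pos = volume_step(pos, 0.05, 1e-4, shell, rng)
        assert np.all(shell.contains(pos))


def test_interior_enclosure_sampling_and_reflection(ea_spheres):
    interior = InteriorEnclosure(ea_spheres.inm)
    rng = np.random.default_rng(4)
    pos = interior.sample(500, rng)
    assert np.all(interior.contains(pos))
    for _ in range(200):
        pos = volume_step(pos, 1.9, 1e-3, interior, rng)
    assert np.all(interior.contains(pos))


def test_apply_domain_rule_limits():
    rng = np.random.default_rng(5)
    iv = np.array([[0.0, 1.0]])
    x_old = np.full(2000, -0.005)
    x_new = np.full(2000, 0.005)  # all proposals enter the domain
    acc, member, rej = apply_domain_rule(x_old, x_new, iv, 1.0, 1.0, rng)
    assert np.all(member) and not np.any(rej)
    acc, member, rej = apply_domain_rule(x_old, x_new, iv, 0.0, 1.0, rng)
    assert not np.any(member) and np.all(rej)
    assert np.all(acc[rej] == x_old[rej])  # rejected moves stay put
    acc, member, rej = apply_domain_rule(x_old, x_new, iv, 0.25, 1.0, rng)
    assert np.mean(member) == pytest.approx(0.25, abs=0.04)


def test_collide_obstacles_cases():
    centres = np.array([[0.0, 0.0, 0.0]])
    old = np.array([[0.05, 0.0, 0.0]])
    free = np.array([[0.08, 0.0, 0.0]])
    assert np.allclose(collide_obstacles(old, free, np.empty((0, 3)), 0.01), free)
    grazing = np.array([[0.05, 0.05, 0.0]])  # stays clear of the sphere
    assert np.allclose(collide_obstacles(old, grazing, centres, 0.02), grazing)
    # a move ending inside the obstacle is rejected
    inside = np.array([[0.005, 0.0, 0.0]])
    assert np.allclose(collide_obstacles(old, inside, centres, 0.02), old)
    # tunnelling straight through is rejected too
    through = np.array([[-0.05, 0.0, 0.0]])
    assert np.allclose(collide_obstacles(old, through, centres, 0.02), old)


def test_bleach_step_exponential_law():
    """A particle held inside the spot bleaches at rate k (exact per-step prob)."""
    rng = np.random.default_rng(6)
    k, dt = 150.0, 4e-5
    p = 1 - np.exp(-k * dt)
    assert p == pytest.approx(5.982e-3, abs=2e-6)
    n = 20000
    unb = np.ones(n, dtype=bool)
    in_spot = np.ones(n, dtype=bool)
    steps = 400
    for _ in range(steps):
        unb = bleach_step(unb, in_spot, k, dt, rng)
    expect = np.exp(-k * dt * steps)
    assert np.mean(unb) == pytest.approx(expect, abs=3 * np.sqrt(expect / n) + 1e-3)
    untouched = bleach_step(np.ones(10, dtype=bool), np.ones(10, dtype=bool), 0.0, dt, rng)
    assert np.all(untouched)


def test_run_flip_deterministic_and_conserving(ea_spheres):
    sp = Species(name="Nsg1", enclosure="ONM", D_eff=0.3, copy_number=150)
    proto = FlipProtocol(t_total=3.0, sampling_dt=0.25)
    t1 = run_flip(ea_spheres, sp, [], proto, 1e-3, seed=9)
    t2 = run_flip(ea_spheres, sp, [], proto, 1e-3, seed=9)
    assert np.array_equal(t1.mother_fraction, t2.mother_fraction)
    assert np.array_equal(t1.daughter_fraction, t2.daughter_fraction)
    assert t1.mother_fraction[0] == 1.0 and t1.daughter_fraction[0] == 1.0
    # without bleaching both lobes stay flat at 1 (particle number conserved)
    flat = run_flip(ea_spheres, sp, [], FlipProtocol(t_total=2.0, sampling_dt=0.5,
                                                     k_bleach=0.0), 1e-3, seed=9)
    assert np.allclose(flat.mother_fraction, 1.0, atol=0.12)
    assert np.allclose(flat.daughter_fraction, 1.0, atol=0.12)


def test_volume_species_runs(ea_spheres):
    sp = Species(name="TetR", enclosure="nucleoplasm", D_eff=1.9, copy_number=400)
    proto = FlipProtocol(t_total=4.0, sampling_dt=0.5)
    tr = run_flip(ea_spheres, sp, [], proto, 1e-3, seed=2)
    assert tr.mother_fraction[-1] < 0.7  # spot sits in the mother lobe


def test_fully_open_plane_matches_no_barrier(ea_spheres):
    """A permeable plane at P=100% leaves the decay statistics unchanged."""
    sp = Species(name="Nsg1", enclosure="ONM", D_eff=0.3, copy_number=250)
    proto = FlipProtocol(t_total=15.0, sampling_dt=0.5)
    base, open_plane = [], []
    for seed in range(4):
        t0 = run_flip(ea_spheres, sp, [], proto, 1e-3, seed=seed)
        t1 = run_flip(ea_spheres, sp, [PermeablePlane(position=0.0, P=100.0)],
                      proto, 1e-3, seed=seed + 50)
        base.append(t0.daughter_fraction[-1])
        open_plane.append(t1.daughter_fraction[-1])
    spread = np.std(base + open_plane, ddof=1)
    assert abs(np.mean(base) - np.mean(open_plane)) < 3 * spread


def test_cp_decreases_with_plane_permeability(ea_spheres):
    """Lower plane permeability means stronger compartmentalization."""
    sp = Species(name="Nsg1", enclosure="ONM", D_eff=0.3, copy_number=250)
    proto = FlipProtocol(t_total=150.0, sampling_dt=1.0)
    cps = {}
    for P in (1.0, 100.0):
        vals = []
        for seed in (0, 1):
            tr = run_flip(ea_spheres, sp, [PermeablePlane(position=0.0, P=P)],
                          proto, 1e-3, seed=seed)
            vals.append(degree_of_compartmentalization(tr).cp)
        cps[P] = np.mean(vals)
    # at 1% the plane is rate limiting; at 100% geometry alone sets the CP
    assert cps[1.0] > 2 * cps[100.0]


def test_species_validation():
    with pytest.raises(EngineConfigError):
        Species(name="x", enclosure="ONM", D_eff=-1.0)
    with pytest.raises(EngineConfigError):
        Species(name="x", enclosure="ONM", D_eff=0.3, D_in_domain=0.5)
    with pytest.raises(EngineConfigError):
        FlipProtocol(loss_fraction=1.5)
    with pytest.raises(EngineConfigError):
        FlipProtocol(placement="bridge_fraction")  # missing fraction
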