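import numpy as np
import pandas as pd
import pytest

from mitoflip.engine import FlipTrace
from mitoflip.flip_analysis import (AnalysisError, CPResult, crossing_region,
                                    degree_of_compartmentalization, deviation,
                                    grid_fit, partition_coefficient, time_to_loss,
                                    transmission_coefficient)


def _trace(times, mother, daughter):
    return FlipTrace(times=np.asarray(times, float), mother_fraction=np.asarray(mother, float),
                     daughter_fraction=np.asarray(daughter, float))


def test_time_to_loss_exponential_closed_form():
    lam = 0.1
    t = np.linspace(0, 60, 601)
    y = np.exp(-lam * t)
    t30 = time_to_loss(t, y, 0.30, smooth_window=1)
    assert t30 == pytest.approx(np.log(1 / 0.7) / lam, rel=1e-3)


def test_time_to_loss_flags_and_interpolates():
    t = np.linspace(0, 10, 11)
    assert time_to_loss(t, np.ones(11)) == np.inf
    ramp = 1.0 - 0.05 * t          # crosses 0.7 at exactly t = 6
    assert time_to_loss(t, ramp, smooth_window=1) == pytest.approx(6.0, abs=0.1)


def test_degree_of_compartmentalization_ratios():
    t = np.linspace(0, 100, 1001)
    same = _trace(t, np.exp(-0.05 * t), np.exp(-0.05 * t))
    cp = degree_of_compartmentalization(same, smooth_window=1)
    assert cp.cp == pytest.approx(1.0, rel=1e-6)
    assert cp.cp * cp.cp_inv == pytest.approx(1.0)
    twice = _trace(t, np.exp(-0.1 * t), np.exp(-0.05 * t))
    assert degree_of_compartmentalization(twice, smooth_window=1).cp == pytest.approx(2.0, rel=1e-3)
    flat = _trace(t, np.exp(-0.1 * t), np.ones_like(t))
    with pytest.raises(AnalysisError):
        degree_of_compartmentalization(flat)


def test_deviation_properties_and_bruteforce_oracle():
    t = np.linspace(0, 10, 21)
    a = _trace(t, np.exp(-0.1 * t), np.exp(-0.05 * t))
    assert deviation(a, a) == 0.0
    offset = _trace(t, a.mother_fraction + 0.05, a.daughter_fraction + 0.05)
    assert deviation(offset, a) == pytest.approx(5.0, rel=1e-9)
    assert deviation(a, offset) == pytest.approx(deviation(offset, a))
    rng = np.random.default_rng(0)
    b = _trace(t, rng.random(21), rng.random(21))
    # brute-force double loop over lobes and time points
    acc = 0.0
    for sim, ref in ((b.mother_fraction, a.mother_fraction),
                     (b.daughter_fraction, a.daughter_fraction)):
        acc += sum(abs(s - r) for s, r in zip(sim, ref)) / len(t)
    assert deviation(b, a) == pytest.approx(100 * acc / 2, rel=1e-12)
    assert deviation(b, a, scale="fraction") == pytest.approx(acc / 2, rel=1e-12)


def test_deviation_refuses_extrapolation():
    t = np.linspace(0, 10, 11)
    short = _trace(t[:5], np.ones(5), np.ones(5))
    full = _trace(t, np.ones(11), np.ones(11))
    with pytest.raises(AnalysisError):
        deviation(short, full)


def test_grid_fit_ties_break_to_smaller_value():
    t = np.linspace(0, 5, 6)
    ref = _trace(t, np.ones(6), np.ones(6))

    def factory(value, cell, seed):
        off = 0.1 * abs(value - 15.0)   # symmetric around 15: 10 and 20 tie
        return _trace(t, np.ones(6) + off, np.ones(6) + off)

    res = grid_fit(factory, [10.0, 20.0], [ref], replicates=1, seed=0)
    assert res.best_value == 10.0
    res2 = grid_fit(factory, [5.0, 15.0, 25.0], [ref], replicates=1, seed=0)
    assert res2.best_value == 15.0
    assert res2.mean_deviation[res2.best_index] == res2.mean_deviation.min()


def test_partition_and_transmission_arithmetic():
    assert partition_coefficient(10.0, 90.0, 1.0, 9.0) == pytest.approx(1.0)
    assert transmission_coefficient(1.0, 1.0, 1.0) == pytest.approx(1.0)
    assert transmission_coefficient(0.5, 0.2, 2.0) == pytest.approx(
        transmission_coefficient(0.5, 0.2, 1.0) / 2)
    # tenfold-ish barrier thickening from the EA neck to the LA bridge
    ratio = transmission_coefficient(1.0, 1.0, 0.3) / transmission_coefficient(1.0, 1.0, 2.85)
    assert ratio == pytest.approx(9.5)
    with pytest.raises(AnalysisError):
        transmission_coefficient(-1.0, 1.0, 1.0)


def test_crossing_region_shapes():
    pos = np.linspace(0, 1, 11)
    sharp = np.where(pos < 0.5, 3.0, -3.0)      # step: narrow barrier signature
    sharp_df = pd.DataFrame({"position": pos, "cp": np.exp(sharp),
                             "cp_inv": np.exp(-sharp)})
    grad = 3.0 - 6.0 * pos                      # linear: distributed barrier
    grad_df = pd.DataFrame({"position": pos, "cp": np.exp(grad),
                            "cp_inv": np.exp(-grad)})
    w_sharp, n_sharp = crossing_region(sharp_df)
    w_grad, n_grad = crossing_region(grad_df)
    assert n_sharp == 1 and n_grad == 1
    assert w_grad > 2 * w_sharp


def test_cp_result_invariant():
    cp = CPResult(t30_mother=10.0, t30_daughter=25.0)
    assert cp.cp == pytest.approx(2.5)
    assert cp.cp * cp.cp_inv == pytest.approx(1.0)
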