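"""Statistics on virtual FLIP traces.

The degree of compartmentalization (°CP) is the ratio of the times the
daughter and mother lobes take to lose 30% of their initial fluorescence
under continuous bleaching of the mother side; °CP > 1 means slower
daughter-side loss, i.e. a stronger barrier between the lobes.  This module
also provides the bleach-position °CP / °CP⁻¹ scans along the LA bridge, the
mean absolute deviation between simulated and reference decay profiles, grid
fitting of barrier parameters by deviation minimisation, and the equilibrium
partition and transmission (permeability) coefficients of a lipid-domain
barrier, k = K_p · D_in / δ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .barriers import LipidDomainConfig
from .engine import (FlipProtocol, FlipTrace, Species, apply_domain_rule,
                     run_flip, surface_step)
from .geometry import NuclearGeometry

__all__ = [
    "CPResult", "FitResult", "BarrierPermeability",
    "time_to_loss", "degree_of_compartmentalization", "cp_scan",
    "deviation", "grid_fit", "partition_coefficient",
    "equilibrium_partition", "transmission_coefficient", "crossing_region",
]


class AnalysisError(ValueError):
    pass


@dataclass
class CPResult:
    """Times to 30% loss per lobe and their ratio (°CP)."""

    t30_mother: float
    t30_daughter: float

    @property
    def cp(self) -> float:
        return self.t30_daughter / self.t30_mother

    @property
    def cp_inv(self) -> float:
        return self.t30_mother / self.t30_daughter


@dataclass
class FitResult:
    """Grid-fit outcome: deviation surface and the best-fitting parameter."""

    parameter: str
    grid: np.ndarray
    mean_deviation: np.ndarray          # % per grid point
    per_cell_deviation: np.ndarray      # (n_grid, n_cells) %
    best_value: float
    best_index: int


@dataclass
class BarrierPermeability:
    """Partition coefficient, in-domain diffusivity, thickness -> permeability."""

    K_p: float
    D_in: float     # um^2/s
    delta: float    # um

    @property
    def k_perm(self) -> float:
        return self.K_p * self.D_in / self.delta


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(series, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series, dtype=float), kernel, mode="same")
    return num / den


def time_to_loss(times: np.ndarray, series: np.ndarray, loss_fraction: float = 0.30,
                 smooth_window: int = 5) -> float:
    """First time the (smoothed) trace crosses 1 - loss_fraction.

    Linearly interpolated between samples; returns ``inf`` if the level is
    never crossed (stochastic traces are moving-average smoothed first, since
    raw traces are not monotone).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    y = _smooth(series, smooth_window)
    # traces are normalised to start at 1; anchor the first sample so the
    # one-sided smoothing window cannot fake an instantaneous crossing
    y[0] = series[0]
    level = 1.0 - loss_fraction
    below = y <= level
    if not np.any(below):
        return np.inf
    i = int(np.argmax(below))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = y[i - 1], y[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


def degree_of_compartmentalization(trace: FlipTrace, loss_fraction: float = 0.30,
                                   smooth_window: int = 5) -> CPResult:
    """°CP = t30(daughter) / t30(mother); both lobes must cross the level."""
    tm = time_to_loss(trace.times, trace.mother_fraction, loss_fraction, smooth_window)
    td = time_to_loss(trace.times, trace.daughter_fraction, loss_fraction, smooth_window)
    if not np.isfinite(tm) or not np.isfinite(td):
        raise AnalysisError("a lobe never lost the required fraction; "
                            "extend t_total or check the protocol")
    return CPResult(t30_mother=tm, t30_daughter=td)


def cp_scan(geometry: NuclearGeometry, species: Species, barrier_set,
            protocol: FlipProtocol, dt: float, seed: int,
            positions: Sequence[float] = tuple(np.linspace(0.0, 1.0, 11)),
            replicates: int = 1, loss_fraction: float = 0.30) -> pd.DataFrame:
    """°CP and °CP⁻¹ versus bleach-spot position along the LA bridge.

    Eleven evenly spaced positions by default: 0% at the mother-bridge
    junction, 100% at the bridge-daughter junction.  With several replicates
    the ratio of the replicate-mean loss times is reported per position.
    """
    if geometry.stage != "LA":
        raise AnalysisError("bridge scans require an LA geometry")
    rows = []
    for k, f in enumerate(positions):
        tms, tds = [], []
        for rep in range(replicates):
            proto = FlipProtocol(
                spot_radius=protocol.spot_radius, spot_length=protocol.spot_length,
                placement="bridge_fraction", bridge_fraction=float(f),
                k_bleach=protocol.k_bleach, t_total=protocol.t_total,
                sampling_dt=protocol.sampling_dt, loss_fraction=protocol.loss_fraction)
            trace = run_flip(geometry, species, barrier_set, proto, dt,
                             seed=seed + 1000 * k + rep)
            cp = degree_of_compartmentalization(trace, loss_fraction)
            tms.append(cp.t30_mother)
            tds.append(cp.t30_daughter)
        tm, td = float(np.mean(tms)), float(np.mean(tds))
        rows.append({"position": float(f), "t30_mother": tm, "t30_daughter": td,
                     "cp": td / tm, "cp_inv": tm / td})
    return pd.DataFrame(rows)


def deviation(sim_trace: FlipTrace, reference_trace: FlipTrace,
              scale: str = "percent") -> float:
    """Mean absolute sim-reference difference over time and both lobes.

    The simulated trace is linearly resampled onto the reference time grid
    (extrapolation is refused); the result is in percentage points of
    normalised fluorescence (``scale='fraction'`` returns the raw fraction).
    """
    t_ref = np.asarray(reference_trace.times, dtype=float)
    t_sim = np.asarray(sim_trace.times, dtype=float)
    if t_ref[0] < t_sim[0] - 1e-12 or t_ref[-1] > t_sim[-1] + 1e-12:
        raise AnalysisError("simulated trace does not cover the reference time span")
    devs = []
    for sim, ref in ((sim_trace.mother_fraction, reference_trace.mother_fraction),
                     (sim_trace.daughter_fraction, reference_trace.daughter_fraction)):
        interp = np.interp(t_ref, t_sim, np.asarray(sim, dtype=float))
        devs.append(np.mean(np.abs(interp - np.asarray(ref, dtype=float))))
    d = float(np.mean(devs))
    return 100.0 * d if scale == "percent" else d


def grid_fit(run_factory: Callable[..., FlipTrace], grid: Sequence[float],
             references: Sequence[FlipTrace], replicates: int = 3, seed: int = 0,
             parameter: str = "parameter") -> FitResult:
    """Fit a barrier parameter by scanning a grid and minimising deviation.

    ``run_factory(value, cell_index, seed)`` must return a simulated trace
    for one reference cell.  For each grid value the deviation is averaged
    over reference cells and replicates; the best value is the argmin, ties
    broken toward the smaller parameter value.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise AnalysisError("empty parameter grid")
    n_cells = len(references)
    per_cell = np.zeros((grid.size, n_cells))
    for gi, value in enumerate(grid):
        for ci, ref in enumerate(references):
            devs = [deviation(run_factory(value, ci, seed + 100_000 * gi + 1000 * ci + r), ref)
                    for r in range(replicates)]
            per_cell[gi, ci] = np.mean(devs)
    mean_dev = per_cell.mean(axis=1)
    best = int(np.argmin(mean_dev))  # argmin returns the first (smallest) index on ties
    return FitResult(parameter=parameter, grid=grid, mean_deviation=mean_dev,
                     per_cell_deviation=per_cell, best_value=float(grid[best]),
                     best_index=best)


# ---------------------------------------------------------------------------
# partition / transmission coefficients
# ---------------------------------------------------------------------------

def partition_coefficient(n_in: float, n_out: float, area_in: float, area_out: float) -> float:
    """K_p = (N_in / A_in) / (N_out / A_out) from equilibrium mean counts."""
    if min(area_in, area_out) <= 0 or n_out <= 0:
        raise AnalysisError("need positive areas and out-of-domain occupancy")
    return (n_in / area_in) / (n_out / area_out)


def equilibrium_partition(geometry: NuclearGeometry, species: Species,
                          domain: LipidDomainConfig, dt: float, seed: int,
                          t_equil: float = 5.0, t_sample: float = 20.0,
                          sample_every: int = 20) -> float:
    """Measure K_p by time-averaging domain occupancy before any bleaching.

    Runs the surface engine without the bleach reaction: particles
    equilibrate for ``t_equil`` seconds, then in/out counts are averaged over
    ``t_sample`` seconds and converted to surface concentrations with the
    domain band areas.
    """
    if hasattr(geometry, "profile"):
        surface = species.enclosure if species.enclosure in ("ONM", "INM") else "ONM"
        prof = geometry.profile(surface)
    else:  # a bare Profile (e.g. a flat cylinder oracle surface)
        prof = geometry
    intervals = domain.intervals(geometry)
    area_in = sum(prof.area_between(a, b) for a, b in intervals)
    area_out = prof.total_area() - area_in
    d_in = domain.D_in.get(species.name, species.D_in_domain)
    if d_in is None:
        d_in = species.D_eff
    d_ratio = d_in / species.D_eff
    p_in, p_out = domain.P_in / 100.0, domain.P_out / 100.0

    rng = np.random.default_rng(seed)
    n = species.copy_number
    pos = prof.sample_surface(n, rng)
    _, _, hint = prof.project_2d(pos[:, 0], np.hypot(pos[:, 1], pos[:, 2]), hint=None)

    n_steps_eq = int(round(t_equil / dt))
    n_steps_sm = int(round(t_sample / dt))

    if intervals.shape[0] == 1:
        # fast path: the kernel's lobe counters (x < lo, x > hi) count the
        # out-of-domain population when (lo, hi) are the domain edges
        from ._kernels import flip_surface_kernel

        a, b = intervals[0]
        unbleached = np.ones(n, dtype=bool)
        hint64 = hint.astype(np.int64)  # evolves in place across both calls
        flip_surface_kernel(
            prof.x, prof.r, prof.vertex_spacing, pos, hint64,
            unbleached, float(species.D_eff), float(d_in), float(dt),
            int(n_steps_eq), max(n_steps_eq, 1),
            np.ascontiguousarray(intervals, dtype=np.float64), p_in, p_out,
            False, 0.0, 1.0, np.empty((0, 3)), 0.0,
            0.0, 0.0, 0.0, 0.0, 0.0, float(a), float(b), rng,
            np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64))
        n_chunks = max(1, n_steps_sm // sample_every)
        out_counts = np.zeros(n_chunks, dtype=np.int64)
        out2 = np.zeros(n_chunks, dtype=np.int64)
        flip_surface_kernel(
            prof.x, prof.r, prof.vertex_spacing, pos, hint64,
            unbleached, float(species.D_eff), float(d_in), float(dt),
            int(n_chunks * sample_every), int(sample_every),
            np.ascontiguousarray(intervals, dtype=np.float64), p_in, p_out,
            False, 0.0, 1.0, np.empty((0, 3)), 0.0,
            0.0, 0.0, 0.0, 0.0, 0.0, float(a), float(b), rng,
            out_counts, out2)
        n_out_mean = float(np.mean(out_counts + out2))
        n_in_mean = n - n_out_mean
        return partition_coefficient(n_in_mean, n_out_mean, area_in, area_out)

    def member(x):
        m = np.zeros(x.shape, dtype=bool)
        for a, b in intervals:
            m |= (x >= a) & (x <= b)
        return m

    in_domain = member(pos[:, 0])
    sums = np.zeros(2)
    n_samples = 0
    for step in range(n_steps_eq + n_steps_sm):
        d_arr = np.where(in_domain, d_in, species.D_eff)
        new_pos, new_hint = surface_step(pos, prof, d_arr, dt, rng, hint)
        disp_sq = np.sum((new_pos - pos) ** 2, axis=1)
        _, memb, rej = apply_domain_rule(pos[:, 0], new_pos[:, 0], intervals,
                                         p_in, p_out, rng, d_ratio,
                                         disp_sq=disp_sq,
                                         sigma_sq_out=2.0 * species.D_eff * dt)
        if np.any(rej):
            new_pos[rej] = pos[rej]
            new_hint[rej] = hint[rej]
        pos, hint = new_pos, new_hint
        in_domain = member(pos[:, 0])
        if step >= n_steps_eq and (step - n_steps_eq) % sample_every == 0:
            n_in = int(np.sum(in_domain))
            sums += (n_in, n - n_in)
            n_samples += 1
    n_in_mean, n_out_mean = sums / max(n_samples, 1)
    return partition_coefficient(n_in_mean, n_out_mean, area_in, area_out)


def transmission_coefficient(K_p: float, D_in: float, delta: float) -> float:
    """Barrier permeability k = K_p · D_in / δ (um/s)."""
    if min(K_p, D_in, delta) <= 0:
        raise AnalysisError("K_p, D_in and delta must all be positive")
    return K_p * D_in / delta


def crossing_region(scan: pd.DataFrame, frac: float = 0.25) -> tuple[float, int]:
    """Width (in bridge fractions) of the °CP/°CP⁻¹ crossing region of a scan.

    The region is where |°CP - °CP⁻¹| falls below ``frac`` times its maximum
    over the scan (evaluated on a dense linear interpolation); the count of
    sign changes of °CP - °CP⁻¹ is returned alongside.  A narrow central
    barrier yields a single sharp crossing; a distributed barrier an extended
    overlap region.
    """
    pos = scan["position"].to_numpy()
    # log(cp) = -log(cp_inv): antisymmetric and scale-free, so the crossing
    # region is where the two curves approach each other on the ratio scale
    logr = np.log(scan["cp"].to_numpy())
    fine = np.linspace(pos.min(), pos.max(), 1001)
    dfine = np.interp(fine, pos, logr)
    thr = frac * np.max(np.abs(dfine))
    inside = np.abs(dfine) <= thr
    width = float(np.sum(inside) / inside.size * (pos.max() - pos.min()))
    signs = np.sign(logr)
    signs = signs[signs != 0]
    n_cross = int(np.sum(np.diff(signs) != 0))
    return width, n_cross
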