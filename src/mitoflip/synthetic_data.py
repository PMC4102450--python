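"""Synthetic study populations and reference FLIP data.

The real study measured heterogeneous populations of dividing nuclei (21
early-anaphase and 34 late-anaphase cells) and fitted barrier parameters
against FLIP decay profiles from a prior publication that is not distributed
here.  This module generates everything those stages need:

* heterogeneous nuclear geometries — LA bridge lengths are drawn from the
  measured 2.85 +/- 0.83 um distribution (truncated to the window where a
  {3, 5, 7}-ring layout is feasible), perinuclear thicknesses from the
  TEM-measured 22 +/- 6 nm (lobes) and 13 +/- 4 nm (bridge) distributions;
  lobe dimensions use plausible defaults since the source figures print no
  numbers, and every distribution is configurable;
* "experimental-like" reference FLIP profiles — each cell is simulated with
  known ground-truth barrier parameters and i.i.d. Gaussian observation
  noise is added to the normalised fluorescence, so parameter-recovery tests
  can fit blinded references against sealed truth.

Everything is deterministic given ``PopulationSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .barriers import ring_layout
from .engine import FlipProtocol, FlipTrace, Species, run_flip
from .geometry import (LobeParams, NuclearGeometry, build_ea_geometry,
                       build_la_geometry)

__all__ = ["PopulationSpec", "ReferenceFlipData", "sample_population",
           "make_reference_flip"]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Draw from N(mean, sd) truncated to [lo, hi] by resampling."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


@dataclass
class PopulationSpec:
    """Distributions defining a heterogeneous population of nuclei.

    All lengths in um.  ``bridge_length`` follows the measured LA
    distribution; its truncation window keeps every sampled bridge compatible
    with a {3, 5, 7} ring layout of ``ring_width`` rings.  Lobe-dimension
    defaults are package choices (the source prints no numbers) and are fully
    configurable.
    """

    stage: Literal["EA", "LA"] = "LA"
    n_cells: int | None = None            # defaults: 21 EA / 34 LA
    seed: int = 0
    # LA lobes (teardrops)
    lobe_scale_mean: float = 2.0
    lobe_scale_sd: float = 0.25
    daughter_scale_ratio: float = 0.9
    piriform_deviation_mean: float = 0.5
    piriform_deviation_sd: float = 0.15
    # EA lobes (prolate ellipsoids)
    ea_mother_long: tuple[float, float] = (1.5, 0.2)     # mean, sd
    ea_mother_short: tuple[float, float] = (1.05, 0.12)
    ea_daughter_long: tuple[float, float] = (1.25, 0.18)
    ea_daughter_short: tuple[float, float] = (0.9, 0.1)
    # bridge (LA)
    bridge_length_mean: float = 2.85
    bridge_length_sd: float = 0.83
    bridge_diameter: float = 0.2
    ring_width: float = 0.3
    # perinuclear space thicknesses
    thickness_lobe: tuple[float, float] = (0.022, 0.006)
    thickness_bridge: tuple[float, float] = (0.013, 0.004)

    def __post_init__(self):
        if self.n_cells is None:
            self.n_cells = 21 if self.stage == "EA" else 34
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def bridge_window(self) -> tuple[float, float]:
        """Bridge lengths admitting a {3,5,7} ring layout with the gap rule."""
        w = self.ring_width
        lo = 3 * w + 2 * (w / 2.0)      # 3 rings at the minimum gap
        hi = 7 * w + 6 * (2.0 * w)      # 7 rings at the maximum gap
        return lo, hi


@dataclass
class ReferenceFlipData:
    """Blinded reference traces plus sealed ground truth."""

    references: list[FlipTrace]
    truth: dict = field(default_factory=dict)
    noise_sd: float = 0.03
    seed: int = 0

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def sample_population(spec: PopulationSpec) -> list[NuclearGeometry]:
    """Sample ``spec.n_cells`` nuclear geometries, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    t_lobe = _truncated_normal(rng, *spec.thickness_lobe, 1e-3, 0.08, n)
    geoms: list[NuclearGeometry] = []
    if spec.stage == "EA":
        t = t_lobe
        am = _truncated_normal(rng, *spec.ea_mother_long, 0.5, 4.0, n)
        bm = _truncated_normal(rng, *spec.ea_mother_short, 0.4, 3.0, n)
        ad = _truncated_normal(rng, *spec.ea_daughter_long, 0.4, 4.0, n)
        bd = _truncated_normal(rng, *spec.ea_daughter_short, 0.3, 3.0, n)
        for i in range(n):
            bmi = min(bm[i], am[i])     # prolate: long >= short
            bdi = min(bd[i], ad[i])
            geoms.append(build_ea_geometry(
                LobeParams(semi_axis_long=am[i], semi_axis_short=bmi),
                LobeParams(semi_axis_long=ad[i], semi_axis_short=bdi,
                           orientation="daughter"),
                perinuclear_thickness_lobe=t[i]))
        return geoms
    lo, hi = spec.bridge_window()
    lengths = _truncated_normal(rng, spec.bridge_length_mean, spec.bridge_length_sd,
                                lo, hi, n)
    t_bridge = _truncated_normal(rng, *spec.thickness_bridge, 1e-3,
                                 spec.bridge_diameter / 2.0 * 0.9, n)
    scales = _truncated_normal(rng, spec.lobe_scale_mean, spec.lobe_scale_sd, 0.8, 4.0, n)
    devs = _truncated_normal(rng, spec.piriform_deviation_mean,
                             spec.piriform_deviation_sd, 0.0, 1.0, n)
    for i in range(n):
        mother = LobeParams(piriform_scale=scales[i], piriform_deviation=devs[i])
        daughter = LobeParams(piriform_scale=spec.daughter_scale_ratio * scales[i],
                              piriform_deviation=devs[i], orientation="daughter")
        geoms.append(build_la_geometry(
            mother, daughter, bridge_length=lengths[i],
            bridge_diameter=spec.bridge_diameter,
            perinuclear_thickness_lobe=t_lobe[i],
            perinuclear_thickness_bridge=t_bridge[i]))
        # every sampled LA bridge must admit a ring layout by construction
        ring_layout(lengths[i], spec.ring_width)
    return geoms


def make_reference_flip(population: Sequence[NuclearGeometry], species: Species,
                        true_barriers: Sequence, protocol: FlipProtocol, dt: float,
                        noise_sd: float = 0.03, seed: int = 0) -> ReferenceFlipData:
    """Simulate each cell with the true barrier parameters and add noise.

    The returned references carry no barrier information in their metadata;
    the ground truth is sealed separately so fits can be run blind.
    """
    rng = np.random.default_rng(seed + 555)
    refs = []
    for i, geom in enumerate(population):
        trace = run_flip(geom, species, true_barriers, protocol, dt, seed=seed + i)
        noisy_m = trace.mother_fraction + rng.normal(0.0, noise_sd,
                                                     trace.mother_fraction.shape)
        noisy_d = trace.daughter_fraction + rng.normal(0.0, noise_sd,
                                                       trace.daughter_fraction.shape)
        refs.append(FlipTrace(times=trace.times, mother_fraction=noisy_m,
                              daughter_fraction=noisy_d, seed=None,
                              metadata={"cell": i}))
    truth = {
        "barriers": [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in vars(b).items()} | {"kind": type(b).__name__}
            for b in true_barriers],
        "species": species.name,
        "noise_sd": noise_sd,
    }
    return ReferenceFlipData(references=refs, truth=truth, noise_sd=noise_sd, seed=seed)
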