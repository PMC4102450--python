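"""Diffusion-barrier models: permeable planes, lipid domains, protein rings.

Three composable barrier ingredients restrict lateral exchange between the
mother and daughter nuclear lobes:

* ``PermeablePlane`` -- a virtual plane crossed with a fixed per-encounter
  probability; a phenomenological stand-in used to quantify overall barrier
  permeability.
* ``LipidDomainConfig`` -- a specialised (sphingolipid-like) membrane domain,
  thicker and more viscous than the surrounding bilayer.  A particle whose
  proposed step would enter the domain is admitted with probability ``P_in``
  (per boundary encounter) and leaves with probability ``P_out`` (100% by
  default, reflecting preferential solubility in ordinary lipid); inside the
  domain it diffuses at the slower ``D_in``.  Layouts: a single ring of given
  width, multiple parallel rings spanning the bridge, or a homogeneous domain
  covering the bridge junction-to-junction.
* ``ProteinRing`` -- an immobile ring of hard-sphere proteins (11 nm default
  diameter, ~15% allowed overlap between neighbours, mimicking polymerised
  filaments) placed on a surface circle; optionally a septin-style double
  ring (two 4 nm circles 8 nm apart).

Probabilities are percentages (0-100), axial positions and widths in the
units of the geometry (um), protein sizes in nm where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import NuclearGeometry

__all__ = [
    "PermeablePlane", "LipidDomainConfig", "ProteinRing",
    "ring_layout", "place_protein_ring", "domain_membership",
    "ring_capacity", "DOMAIN_PRESETS", "preset_domain",
]


class BarrierConfigError(ValueError):
    """Raised for infeasible or inconsistent barrier configurations."""


@dataclass
class PermeablePlane:
    """Virtual barrier plane at an axial position, crossed with probability P (%)."""

    position: float = 0.0
    P: float = 100.0

    def __post_init__(self):
        if not 0.0 <= self.P <= 100.0:
            raise BarrierConfigError("crossing probability P must be in [0, 100] %")


@dataclass
class LipidDomainConfig:
    """A specialised lipid domain on one or both nuclear membranes.

    ``layout`` is one of ``single_ring`` (requires ``width``; ``centre``
    defaults to the neck / bridge midpoint), ``multi_ring`` (300 nm rings laid
    out along the bridge by :func:`ring_layout`) or ``homogeneous_bridge``
    (junction plane to junction plane).
    """

    layout: Literal["single_ring", "multi_ring", "homogeneous_bridge"] = "single_ring"
    width: float = 0.3            # ring width, um (single_ring / multi_ring)
    centre: float = 0.0           # ring centre, um (single_ring)
    surfaces: Literal["ONM", "INM", "both"] = "both"
    P_in: float = 100.0           # % per boundary encounter
    P_out: float = 100.0          # % per boundary encounter
    D_in: dict = field(default_factory=dict)  # species name -> um^2/s

    def __post_init__(self):
        if not (0.0 < self.P_in <= 100.0) or not (0.0 < self.P_out <= 100.0):
            # P_in = 0 would trap nothing and partition K = 0; the engine
            # accepts it only through an explicit plane, not a domain
            if self.P_in != 0.0:
                raise BarrierConfigError("P_in and P_out must be in (0, 100] %")
        if self.P_in > self.P_out:
            raise BarrierConfigError("require P_in <= P_out (domain excludes, not attracts)")
        if self.layout in ("single_ring", "multi_ring") and self.width <= 0:
            raise BarrierConfigError("ring width must be positive")

    def applies_to(self, surface: str) -> bool:
        return self.surfaces == "both" or self.surfaces.upper() == surface.upper()

    def intervals(self, geometry: NuclearGeometry) -> np.ndarray:
        """Axial (x1, x2) intervals covered by the domain, shape (k, 2)."""
        if self.layout == "single_ring":
            return np.array([[self.centre - self.width / 2.0,
                              self.centre + self.width / 2.0]])
        lo, hi = geometry.junction_planes
        if self.layout == "homogeneous_bridge":
            return np.array([[lo, hi]])
        if geometry.stage != "LA" or geometry.bridge_length is None:
            raise BarrierConfigError("multi_ring layout requires an LA geometry")
        centres = ring_layout(geometry.bridge_length, self.width)
        half = self.width / 2.0
        return np.array([[c - half, c + half] for c in centres])


@dataclass
class ProteinRing:
    """An immobile ring of hard-sphere proteins on a surface circle."""

    n: int = 0
    protein_diameter: float = 11.0      # nm
    overlap_fraction: float = 0.15      # allowed neighbour overlap, fraction of diameter
    arrangement: Literal["single", "double"] = "single"
    ring_width: float = 4.0             # nm, per ring in the double arrangement
    separation: float = 8.0             # nm between the two rings (double)
    surface: str = "ONM"
    position: float = 0.0               # axial centre, um

    def __post_init__(self):
        if self.n < 0:
            raise BarrierConfigError("protein count must be >= 0")
        if self.protein_diameter <= 0:
            raise BarrierConfigError("protein diameter must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise BarrierConfigError("overlap fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# ring layout along the LA bridge
# ---------------------------------------------------------------------------

def ring_layout(bridge_length: float, ring_width: float) -> np.ndarray:
    """Centres of parallel ring domains distributed along the bridge.

    One ring sits at the bridge centre, two flush with the lobe junctions and
    the rest evenly interleaved; the count is the largest of {3, 5, 7} whose
    inter-ring gap g = (L - k w) / (k - 1) satisfies w/2 <= g <= 2 w.  Centres
    are returned in increasing axial order, symmetric about the midpoint.
    """
    if bridge_length <= ring_width:
        raise BarrierConfigError("bridge must be longer than one ring width")
    feasible = {}
    for k in (7, 5, 3):
        gap = (bridge_length - k * ring_width) / (k - 1)
        if ring_width / 2.0 - 1e-12 <= gap <= 2.0 * ring_width + 1e-12:
            feasible[k] = gap
    if not feasible:
        lims = {k: (k * ring_width + (k - 1) * ring_width / 2.0,
                    k * ring_width + (k - 1) * 2.0 * ring_width) for k in (3, 5, 7)}
        raise BarrierConfigError(
            f"no ring count in {{3,5,7}} satisfies the gap rule for bridge length "
            f"{bridge_length:g} um with {ring_width:g} um rings; feasible bridge-length "
            f"windows: " + ", ".join(f"{k} rings: [{a:g}, {b:g}] um" for k, (a, b) in lims.items()))
    k = max(feasible)
    half = bridge_length / 2.0
    first = -half + ring_width / 2.0
    last = half - ring_width / 2.0
    return np.linspace(first, last, k)


def ring_capacity(circumference_nm: float, ring: ProteinRing) -> int:
    """Maximum protein count on the ring circle(s) given the overlap allowance."""
    spacing = ring.protein_diameter * (1.0 - ring.overlap_fraction)
    cap = int(np.floor(circumference_nm / spacing))
    if ring.arrangement == "double":
        cap *= 2
    return cap


def place_protein_ring(geometry: NuclearGeometry, ring: ProteinRing,
                       seed: int | None = None) -> np.ndarray:
    """Obstacle sphere centres (N, 3) for a protein ring on the surface.

    Proteins are spaced evenly around the surface circle at the ring's axial
    position; a seeded random phase decorrelates the ring orientation between
    cells.  The double arrangement places two circles ``separation`` nm apart
    (half the proteins on each).
    """
    prof = geometry.profile(ring.surface)
    if ring.n == 0:
        return np.empty((0, 3))
    sep_um = ring.separation * 1e-3

    if ring.arrangement == "double":
        x_positions = [ring.position - sep_um / 2.0, ring.position + sep_um / 2.0]
        counts = [ring.n // 2, ring.n - ring.n // 2]
    else:
        x_positions = [ring.position]
        counts = [ring.n]

    total_cap = 0
    for x0 in x_positions:
        radius_um = float(prof.rho(np.asarray(x0)))
        if radius_um <= 0:
            raise BarrierConfigError(f"no surface circle at axial position {x0:g} um")
        total_cap += int(np.floor(2.0 * np.pi * radius_um * 1e3
                                  / (ring.protein_diameter * (1.0 - ring.overlap_fraction))))
    if ring.n > total_cap:
        raise BarrierConfigError(
            f"{ring.n} proteins exceed the ring packing capacity ({total_cap})")

    rng = np.random.default_rng(seed)
    pts = []
    for x0, cnt in zip(x_positions, counts):
        if cnt == 0:
            continue
        radius_um = float(prof.rho(np.asarray(x0)))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        phi = phase + np.linspace(0.0, 2.0 * np.pi, cnt, endpoint=False)
        pts.append(np.column_stack([
            np.full(cnt, x0), radius_um * np.cos(phi), radius_um * np.sin(phi)]))
    return np.vstack(pts)


def domain_membership(config: LipidDomainConfig, geometry: NuclearGeometry,
                      points: np.ndarray) -> np.ndarray:
    """Boolean domain membership for surface points (pure function of x)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = pts[:, 0]
    ivals = config.intervals(geometry)
    member = np.zeros(x.shape, dtype=bool)
    for x1, x2 in ivals:
        member |= (x >= x1) & (x <= x2)
    if np.asarray(points).ndim == 1:
        return bool(member[0])
    return member


# ---------------------------------------------------------------------------
# named presets (Table-style fitted exclusion probabilities)
# ---------------------------------------------------------------------------

# Fitted per-encounter domain entry probabilities (%), by marker and scenario.
DOMAIN_PRESETS: dict[str, dict] = {
    # EA: one 300 nm ring at the neck
    "ea_single_ring_nsg1":  dict(layout="single_ring", width=0.3, surfaces="ONM", P_in=3.5),
    "ea_single_ring_src1":  dict(layout="single_ring", width=0.3, surfaces="INM", P_in=7.0),
    "ea_single_ring_npc_onm":  dict(layout="single_ring", width=0.3, surfaces="ONM", P_in=1.6),
    "ea_single_ring_npc_both": dict(layout="single_ring", width=0.3, surfaces="both", P_in=1.5),
    # LA: one ring at the bridge centre (300 nm; 100 nm for the NPC)
    "la_single_ring_nsg1":  dict(layout="single_ring", width=0.3, surfaces="ONM", P_in=3.5),
    "la_single_ring_src1":  dict(layout="single_ring", width=0.3, surfaces="INM", P_in=7.0),
    "la_single_ring_npc_onm":  dict(layout="single_ring", width=0.1, surfaces="ONM", P_in=1.6),
    "la_single_ring_npc_both": dict(layout="single_ring", width=0.1, surfaces="both", P_in=1.5),
    # LA: multiple 300 nm rings along the bridge
    "la_multi_ring_nsg1":  dict(layout="multi_ring", width=0.3, surfaces="ONM", P_in=10.0),
    "la_multi_ring_src1":  dict(layout="multi_ring", width=0.3, surfaces="INM", P_in=30.0),
    "la_multi_ring_npc_onm":  dict(layout="multi_ring", width=0.3, surfaces="ONM", P_in=20.0),
    "la_multi_ring_npc_both": dict(layout="multi_ring", width=0.3, surfaces="both", P_in=20.0),
    # LA: homogeneous domain spanning the bridge
    "la_homogeneous_nsg1":  dict(layout="homogeneous_bridge", surfaces="ONM", P_in=15.0),
    "la_homogeneous_src1":  dict(layout="homogeneous_bridge", surfaces="INM", P_in=35.0),
    "la_homogeneous_npc_onm":  dict(layout="homogeneous_bridge", surfaces="ONM", P_in=30.0),
    "la_homogeneous_npc_both": dict(layout="homogeneous_bridge", surfaces="both", P_in=30.0),
}


def preset_domain(name: str, **overrides) -> LipidDomainConfig:
    """Build a LipidDomainConfig from a named preset, with optional overrides."""
    if name not in DOMAIN_PRESETS:
        raise BarrierConfigError(
            f"unknown preset {name!r}; available: {sorted(DOMAIN_PRESETS)}")
    kwargs = dict(DOMAIN_PRESETS[name])
    kwargs.update(overrides)
    return LipidDomainConfig(**kwargs)
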