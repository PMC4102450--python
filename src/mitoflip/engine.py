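"""Seeded Brownian-dynamics engine for virtual FLIP experiments.

Particles diffuse either laterally on a membrane surface (ONM, INM, or the
nuclear-envelope mid-surface for perinuclear diffusers such as the NPC) or in
a volume (nucleoplasm, perinuclear shell).  Surface motion is an isotropic
Gaussian step in the local tangent plane followed by projection back onto the
surface; volume motion is a 3D Gaussian step with specular reflection at the
enclosing surfaces.

Barrier rules are applied to each proposed displacement:

* lipid-domain crossing — a step whose endpoint changes domain membership is
  accepted with the per-encounter probability P_in (entering) or P_out
  (exiting); rejected steps are reflected at the domain boundary.  Entry
  acceptance carries a sqrt(D_in/D_out) interface factor so that a pure
  viscosity drop inside the domain creates no spurious partitioning and the
  equilibrium surface-concentration ratio equals P_in/P_out independently of
  the time step.
* protein-ring obstacles — hard spheres; displacements that would overlap or
  tunnel through an obstacle are rejected (reflected off the contact point or
  bounced back).
* permeable plane — crossings of the virtual plane are accepted with a fixed
  probability, otherwise reflected.

Photobleaching is an irreversible conversion applied to unbleached particles
inside the cigar-shaped bleach spot with the exact per-step probability
1 - exp(-k_bleach * dt), so coarse time steps remain unbiased.  The per-lobe
unbleached fractions, normalised to t = 0, form a :class:`FlipTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .barriers import LipidDomainConfig, PermeablePlane, ProteinRing, place_protein_ring
from .geometry import NuclearGeometry, Profile

__all__ = [
    "Species", "FlipProtocol", "FlipTrace", "BleachSpot",
    "choose_time_step", "surface_step", "volume_step",
    "apply_domain_rule", "collide_obstacles", "bleach_step", "run_flip",
    "BoxEnclosure", "InteriorEnclosure", "ShellEnclosure",
]


class EngineConfigError(ValueError):
    """Raised when a run configuration is inconsistent."""


# ---------------------------------------------------------------------------
# configuration records
# ---------------------------------------------------------------------------

@dataclass
class Species:
    """A diffusing fluorescent reporter."""

    name: str
    enclosure: Literal["nucleoplasm", "ONM", "INM", "NE", "perinuclear"]
    D_eff: float                      # um^2/s outside any domain
    copy_number: int = 1000
    D_in_domain: float | None = None  # um^2/s inside a lipid domain
    particle_radius: float = 2.0      # nm
    excluded_volume: bool = False
    fluorescence_weight: float = 1.0  # e.g. 32 Nup49 copies per NPC

    def __post_init__(self):
        if self.D_eff <= 0 or self.copy_number < 1:
            raise EngineConfigError("species needs D_eff > 0 and copy_number >= 1")
        if self.D_in_domain is not None and self.D_in_domain > self.D_eff:
            raise EngineConfigError("D_in_domain must not exceed D_eff")

    @property
    def dof(self) -> int:
        return 3 if self.enclosure in ("nucleoplasm", "perinuclear") else 2

    @property
    def is_surface(self) -> bool:
        return self.enclosure in ("ONM", "INM", "NE")


@dataclass
class FlipProtocol:
    """Bleach-spot shape/placement and acquisition settings."""

    spot_radius: float = 0.25          # um, capsule radius
    spot_length: float = 1.0           # um, capsule cylindrical length
    placement: Literal["mother_edge", "bridge_fraction"] = "mother_edge"
    bridge_fraction: float | None = None   # 0..1 along the bridge (LA scans)
    k_bleach: float = 150.0            # 1/s
    t_total: float = 60.0              # s
    sampling_dt: float = 0.5           # s
    loss_fraction: float = 0.30

    def __post_init__(self):
        if not 0.0 < self.loss_fraction < 1.0:
            raise EngineConfigError("loss_fraction must be in (0, 1)")
        if self.k_bleach < 0:
            raise EngineConfigError("k_bleach must be >= 0")
        if self.placement == "bridge_fraction":
            if self.bridge_fraction is None or not 0.0 <= self.bridge_fraction <= 1.0:
                raise EngineConfigError("bridge_fraction must be in [0, 1]")


@dataclass
class BleachSpot:
    """Cigar (capsule) bleach volume: a segment with a radius."""

    centre: np.ndarray
    axis: np.ndarray
    half_length: float
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.centre
        t = d @ self.axis
        t = np.clip(t, -self.half_length, self.half_length)
        foot = self.centre + t[:, None] * self.axis
        return np.sum((points - foot) ** 2, axis=1) <= self.radius ** 2


def make_bleach_spot(geometry: NuclearGeometry, protocol: FlipProtocol) -> BleachSpot:
    """Place the capsule per the protocol: lateral edge of the mother lobe,
    centred on the nuclear envelope, or at a relative position on the bridge."""
    prof = geometry.onm
    if protocol.placement == "mother_edge":
        lo, _ = geometry.junction_planes
        mask = prof.x < lo if geometry.stage == "LA" else prof.x < 0.0
        if not np.any(mask):
            raise EngineConfigError("no mother-lobe vertices to place the spot on")
        i = np.argmax(np.where(mask, prof.r, -1.0))
        centre = np.array([prof.x[i], prof.r[i], 0.0])
    else:
        lo, hi = geometry.junction_planes
        x0 = lo + protocol.bridge_fraction * (hi - lo)
        centre = np.array([x0, float(prof.rho(np.asarray(x0))), 0.0])
    # capsule axis along the optical (z) axis
    return BleachSpot(centre=centre, axis=np.array([0.0, 0.0, 1.0]),
                      half_length=protocol.spot_length / 2.0, radius=protocol.spot_radius)


@dataclass
class FlipTrace:
    """Per-lobe unbleached fraction versus time for one simulated FLIP run."""

    times: np.ndarray
    mother_fraction: np.ndarray
    daughter_fraction: np.ndarray
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "mother": self.mother_fraction,
                             "daughter": self.daughter_fraction})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "FlipTrace":
        df = pd.read_csv(path)
        return cls(times=df["time"].to_numpy(), mother_fraction=df["mother"].to_numpy(),
                   daughter_fraction=df["daughter"].to_numpy(), metadata=meta)


# ---------------------------------------------------------------------------
# time step
# ---------------------------------------------------------------------------

def choose_time_step(species_set: Sequence[Species], target_resolution: float = 7.0,
                     governing: str | None = None) -> tuple[float, dict[str, float]]:
    """Time step dt = dx^2 / (2 d D) for a target spatial resolution.

    ``target_resolution`` is in nm.  The governing species defaults to the one
    yielding the smallest dt (largest 2 d D); pass ``governing`` to pin it,
    since the appropriate choice (fastest volumetric versus membrane species)
    depends on which enclosure's resolution matters for the barrier at hand.
    Returns (dt in s, per-species implied step length in nm at that dt).
    """
    if not species_set:
        raise EngineConfigError("empty species set")
    dx_um = target_resolution * 1e-3
    by_name = {s.name: s for s in species_set}
    if governing is not None:
        gov = by_name[governing]
    else:
        gov = max(species_set, key=lambda s: 2 * s.dof * s.D_eff)
    dt = dx_um ** 2 / (2.0 * gov.dof * gov.D_eff)
    steps = {s.name: float(np.sqrt(2.0 * s.dof * s.D_eff * dt) * 1e3) for s in species_set}
    return dt, steps


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------

def surface_step(positions: np.ndarray, profile: Profile, D, dt: float,
                 rng: np.random.Generator, hint: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One tangent-plane Gaussian step projected back to the surface.

    ``D`` may be a scalar or a per-particle array (um^2/s).  Returns the new
    positions and the polyline hint indices for the next projection.
    """
    positions = np.atleast_2d(positions)
    n = positions.shape[0]
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    r = np.hypot(y, z)
    if hint is None:
        _, _, hint = profile.project_2d(x, r, hint=None)
    tx, tr = profile.tangent_2d(hint)
    safe = r > 1e-12
    cy = np.where(safe, y / np.where(safe, r, 1.0), 1.0)
    cz = np.where(safe, z / np.where(safe, r, 1.0), 0.0)
    # meridian and azimuthal unit tangents
    emx, emy, emz = tx, tr * cy, tr * cz
    eay, eaz = -cz, cy
    sigma = np.sqrt(2.0 * np.asarray(D, dtype=float) * dt)
    xi1 = rng.standard_normal(n) * sigma
    xi2 = rng.standard_normal(n) * sigma
    nx = x + xi1 * emx
    ny = y + xi1 * emy + xi2 * eay
    nz = z + xi1 * emz + xi2 * eaz
    nr = np.hypot(ny, nz)
    # the local search window must cover the largest displacement drawn
    max_step = float(np.max(np.hypot(xi1, xi2))) if n else 0.0
    window = int(np.ceil(max_step / profile.vertex_spacing)) + 4
    px, pr, idx = profile.project_2d(nx, nr, hint=hint, window=window)
    scale = np.where(nr > 1e-12, pr / np.where(nr > 1e-12, nr, 1.0), 0.0)
    out = np.column_stack([px, ny * scale, nz * scale])
    # degenerate on-axis proposals keep a deterministic azimuth
    on_axis = nr <= 1e-12
    if np.any(on_axis):
        out[on_axis, 1] = pr[on_axis]
        out[on_axis, 2] = 0.0
    return out, idx


class BoxEnclosure:
    """Axis-aligned box with specular reflection (used for free-diffusion checks)."""

    def __init__(self, bounds: np.ndarray):
        self.bounds = np.asarray(bounds, dtype=float)  # (3, 2)

    def reflect(self, points: np.ndarray) -> np.ndarray:
        p = points.copy()
        for k in range(3):
            lo, hi = self.bounds[k]
            span = hi - lo
            q = np.mod(p[:, k] - lo, 2 * span)
            p[:, k] = lo + np.where(q > span, 2 * span - q, q)
        return p

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all((points >= self.bounds[:, 0]) & (points <= self.bounds[:, 1]), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.bounds[:, 0], self.bounds[:, 1], size=(n, 3))


class InteriorEnclosure:
    """Interior volume of a closed surface of revolution."""

    def __init__(self, profile: Profile):
        self.profile = profile

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.profile.contains(points)

    def reflect(self, points: np.ndarray) -> np.ndarray:
        p = points.copy()
        x_lo, x_hi = self.profile.x_range
        for _ in range(3):
            p[:, 0] = np.clip(p[:, 0], 2 * x_lo - p[:, 0], None)
            p[:, 0] = np.where(p[:, 0] > x_hi, 2 * x_hi - p[:, 0], p[:, 0])
            p[:, 0] = np.where(p[:, 0] < x_lo, 2 * x_lo - p[:, 0], p[:, 0])
            rho = self.profile.rho(p[:, 0])
            r = np.hypot(p[:, 1], p[:, 2])
            out = r > rho
            if not np.any(out):
                break
            scale = np.where(out & (r > 1e-12), (2 * rho - r) / np.where(r > 1e-12, r, 1.0), 1.0)
            scale = np.clip(scale, 0.0, 1.0)
            p[:, 1] *= scale
            p[:, 2] *= scale
        # safety clamp for rare multi-reflection failures
        rho = self.profile.rho(p[:, 0])
        r = np.hypot(p[:, 1], p[:, 2])
        bad = r > rho
        if np.any(bad):
            shrink = np.where(bad, 0.99 * rho / np.maximum(r, 1e-12), 1.0)
            p[:, 1] *= shrink
            p[:, 2] *= shrink
        return p

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x_lo, x_hi = self.profile.x_range
        r_max = self.profile.r.max()
        pts = np.empty((0, 3))
        while pts.shape[0] < n:
            m = 4 * (n - pts.shape[0]) + 16
            cand = np.column_stack([
                rng.uniform(x_lo, x_hi, m),
                rng.uniform(-r_max, r_max, m),
                rng.uniform(-r_max, r_max, m)])
            cand = cand[self.contains(cand)]
            pts = np.vstack([pts, cand])
        return pts[:n]


class ShellEnclosure:
    """Perinuclear shell between an outer and an inner surface of revolution."""

    def __init__(self, outer: Profile, inner: Profile):
        self.outer = outer
        self.inner = inner

    def contains(self, points: np.ndarray) -> np.ndarray:
        x = points[:, 0]
        r = np.hypot(points[:, 1], points[:, 2])
        x_lo, x_hi = self.outer.x_range
        inside_outer = (x > x_lo) & (x < x_hi) & (r < self.outer.rho(x))
        in_lo, in_hi = self.inner.x_range
        in_inner = (x > in_lo) & (x < in_hi) & (r < self.inner.rho(x))
        return inside_outer & ~in_inner

    def reflect(self, points: np.ndarray) -> np.ndarray:
        p = points.copy()
        x_lo, x_hi = self.outer.x_range
        for _ in range(4):
            p[:, 0] = np.where(p[:, 0] > x_hi, 2 * x_hi - p[:, 0], p[:, 0])
            p[:, 0] = np.where(p[:, 0] < x_lo, 2 * x_lo - p[:, 0], p[:, 0])
            r = np.hypot(p[:, 1], p[:, 2])
            r_out = self.outer.rho(p[:, 0])
            r_in = self.inner.rho(p[:, 0])
            new_r = r.copy()
            over = r > r_out
            new_r[over] = (2 * r_out - r)[over]
            under = (r < r_in) & (r_in > 0)
            new_r[under] = (2 * r_in - r)[under]
            if not (np.any(over) or np.any(under)):
                break
            scale = np.where(r > 1e-12, new_r / np.maximum(r, 1e-12), 1.0)
            p[:, 1] *= scale
            p[:, 2] *= scale
        # clamp leftovers to the shell midline
        r = np.hypot(p[:, 1], p[:, 2])
        r_out = self.outer.rho(p[:, 0])
        r_in = self.inner.rho(p[:, 0])
        bad = (r > r_out) | ((r < r_in) & (r_in > 0))
        if np.any(bad):
            mid = 0.5 * (r_out + r_in)
            scale = np.where(bad, mid / np.maximum(r, 1e-12), 1.0)
            p[:, 1] *= scale
            p[:, 2] *= scale
        return p

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x_lo, x_hi = self.outer.x_range
        r_max = self.outer.r.max()
        pts = np.empty((0, 3))
        while pts.shape[0] < n:
            m = 16 * (n - pts.shape[0]) + 16
            cand = np.column_stack([
                rng.uniform(x_lo, x_hi, m),
                rng.uniform(-r_max, r_max, m),
                rng.uniform(-r_max, r_max, m)])
            cand = cand[self.contains(cand)]
            pts = np.vstack([pts, cand])
        return pts[:n]


def volume_step(positions: np.ndarray, D: float, dt: float, enclosure,
                rng: np.random.Generator) -> np.ndarray:
    """One 3D Gaussian step with specular reflection at the enclosure walls."""
    positions = np.atleast_2d(positions)
    sigma = np.sqrt(2.0 * D * dt)
    prop = positions + rng.standard_normal(positions.shape) * sigma
    return enclosure.reflect(prop)


# ---------------------------------------------------------------------------
# barrier rules
# ---------------------------------------------------------------------------

def _membership_x(x: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    member = np.zeros(x.shape, dtype=bool)
    for x1, x2 in intervals:
        member |= (x >= x1) & (x <= x2)
    return member


def apply_domain_rule(old_pos: np.ndarray, proposed_pos: np.ndarray,
                      intervals: np.ndarray, p_in: float, p_out: float,
                      rng: np.random.Generator, d_ratio: float = 1.0,
                      disp_sq: np.ndarray | None = None,
                      sigma_sq_out: float | None = None, dof: int = 2
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept/reject proposed displacements crossing a lipid-domain boundary.

    ``p_in``/``p_out`` are fractions in [0, 1].  When the in-domain diffusion
    differs (``d_ratio`` = D_in/D_out < 1), a Metropolis-Hastings factor for
    the step-size change multiplies the crossing acceptance so the
    equilibrium surface-concentration ratio is exactly P_in/P_out regardless
    of the slowdown or the time step; ``disp_sq`` (squared proposed
    displacement per particle) and ``sigma_sq_out`` (= 2 D_out dt) supply the
    proposal densities.  Rejected moves keep the old position.

    Returns (accepted x positions, final membership mask, rejected mask).
    """
    x_old = np.atleast_1d(old_pos[..., 0] if old_pos.ndim > 1 else old_pos)
    x_new = np.atleast_1d(proposed_pos[..., 0] if proposed_pos.ndim > 1 else proposed_pos)
    m_old = _membership_x(x_old, intervals)
    m_new = _membership_x(x_new, intervals)
    crossing = m_old != m_new
    acc = np.where(m_new, p_in, p_out) * np.ones_like(x_new)
    if d_ratio != 1.0 and disp_sq is not None and sigma_sq_out is not None:
        s2 = np.where(m_old, d_ratio * sigma_sq_out, sigma_sq_out)
        s2_new = np.where(m_new, d_ratio * sigma_sq_out, sigma_sq_out)
        with np.errstate(over="ignore"):
            hastings = (s2 / s2_new) ** (dof / 2.0) * np.exp(
                disp_sq / (2.0 * s2) - disp_sq / (2.0 * s2_new))
        acc = acc * np.minimum(1.0, hastings)
    u = rng.random(x_new.shape)
    reject = crossing & (u >= acc)
    x_acc = np.where(reject, x_old, x_new)
    return x_acc, _membership_x(x_acc, intervals), reject


def collide_obstacles(old_pos: np.ndarray, proposed_pos: np.ndarray,
                      centres: np.ndarray, contact_radius: float) -> np.ndarray:
    """Resolve hard-sphere obstacle collisions for proposed displacements.

    A displacement whose segment (including its endpoint) passes within the
    contact radius of an obstacle centre is rejected: the particle keeps its
    old position.  Returns corrected positions.
    """
    if centres.size == 0:
        return proposed_pos
    old_pos = np.atleast_2d(old_pos)
    new = np.atleast_2d(proposed_pos).copy()
    r2 = contact_radius ** 2
    seg = new - old_pos
    w = centres[None, :, :] - old_pos[:, None, :]
    seg_len2 = np.maximum(np.sum(seg ** 2, axis=1), 1e-300)
    t = np.clip(np.einsum("nmk,nk->nm", w, seg) / seg_len2[:, None], 0.0, 1.0)
    closest = old_pos[:, None, :] + t[:, :, None] * seg[:, None, :]
    d2_seg = np.sum((closest - centres[None, :, :]) ** 2, axis=2)
    hit = np.any(d2_seg < r2, axis=1)
    new[hit] = old_pos[hit]
    return new


def bleach_step(unbleached: np.ndarray, in_spot: np.ndarray, k_bleach: float,
                dt: float, rng: np.random.Generator) -> np.ndarray:
    """Irreversibly convert unbleached particles inside the spot.

    Conversion uses the exact per-step probability 1 - exp(-k dt); particles
    outside the spot and already-bleached particles are unaffected.
    """
    if k_bleach <= 0:
        return unbleached
    p = 1.0 - np.exp(-k_bleach * dt)
    hit = unbleached & in_spot & (rng.random(unbleached.shape) < p)
    out = unbleached.copy()
    out[hit] = False
    return out


# ---------------------------------------------------------------------------
# full virtual FLIP run
# ---------------------------------------------------------------------------

def _lobe_masks(geometry: NuclearGeometry, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = geometry.junction_planes
    return x < lo, x > hi


def run_flip(geometry: NuclearGeometry, species: Species,
             barrier_set: Sequence | None, protocol: FlipProtocol,
             dt: float, seed: int) -> FlipTrace:
    """Simulate one FLIP experiment and return the per-lobe decay trace.

    ``barrier_set`` may contain :class:`LipidDomainConfig`,
    :class:`ProteinRing` and :class:`PermeablePlane` objects in any mix.
    The run is deterministic given the full configuration and ``seed``; the
    total particle count (bleached + unbleached) is conserved exactly.
    """
    barrier_set = list(barrier_set or [])
    rng = np.random.default_rng(seed)

    domains = [b for b in barrier_set if isinstance(b, LipidDomainConfig)]
    rings = [b for b in barrier_set if isinstance(b, ProteinRing)]
    planes = [b for b in barrier_set if isinstance(b, PermeablePlane)]
    if len(domains) > 1:
        raise EngineConfigError("at most one lipid-domain configuration per run")

    # enclosure / surface selection
    if species.enclosure in ("ONM", "INM"):
        prof = geometry.profile(species.enclosure)
        enclosure = None
    elif species.enclosure == "NE":
        # perinuclear diffuser (NPC): lateral motion on the envelope mid-surface
        prof = geometry.profile("NE")
        enclosure = None
    elif species.enclosure == "nucleoplasm":
        prof = None
        enclosure = InteriorEnclosure(geometry.inm)
    elif species.enclosure == "perinuclear":
        prof = None
        enclosure = ShellEnclosure(geometry.onm, geometry.inm)
    else:
        raise EngineConfigError(f"unknown enclosure {species.enclosure!r}")

    # domain applicability: surface species see domains on their own membrane;
    # an NE-spanning diffuser is affected by a domain on either membrane
    domain = None
    if domains:
        d = domains[0]
        if species.enclosure == "NE" or (species.is_surface and d.applies_to(species.enclosure)):
            domain = d
    if domain is not None:
        intervals = domain.intervals(geometry)
        p_in = domain.P_in / 100.0
        p_out = domain.P_out / 100.0
        d_in = domain.D_in.get(species.name, species.D_in_domain)
        if d_in is None:
            d_in = species.D_eff
        d_ratio = d_in / species.D_eff
    else:
        intervals = None
        d_in = species.D_eff
        d_ratio = 1.0

    obstacle_centres = np.empty((0, 3))
    contact_radius = 0.0
    if rings and species.is_surface or rings and species.enclosure == "NE":
        all_c = [place_protein_ring(geometry, rg, seed=seed + 7919) for rg in rings]
        obstacle_centres = np.vstack([c for c in all_c if c.size]) if all_c else obstacle_centres
        if obstacle_centres.size:
            rg = rings[0]
            contact_radius = (species.particle_radius
                              + rg.protein_diameter / 2.0 * (1.0 - rg.overlap_fraction)) * 1e-3

    spot = make_bleach_spot(geometry, protocol)

    n = species.copy_number
    if prof is not None:
        pos = prof.sample_surface(n, rng)
        if obstacle_centres.size:
            # avoid starting particles frozen inside an obstacle
            for _ in range(20):
                d2 = np.min(np.sum((pos[:, None, :] - obstacle_centres[None, :, :]) ** 2,
                                   axis=2), axis=1)
                stuck = d2 < contact_radius ** 2
                if not np.any(stuck):
                    break
                pos[stuck] = prof.sample_surface(int(np.sum(stuck)), rng)
        _, _, hint = prof.project_2d(pos[:, 0], np.hypot(pos[:, 1], pos[:, 2]), hint=None)
    else:
        pos = enclosure.sample(n, rng)
        hint = None

    unbleached = np.ones(n, dtype=bool)
    if intervals is not None:
        in_domain = _membership_x(pos[:, 0], intervals)
    else:
        in_domain = np.zeros(n, dtype=bool)

    n_steps = int(round(protocol.t_total / dt))
    sample_every = max(1, int(round(protocol.sampling_dt / dt)))
    m_mask, d_mask = _lobe_masks(geometry, pos[:, 0])
    n_m0 = max(int(np.sum(m_mask)), 1)
    n_d0 = max(int(np.sum(d_mask)), 1)

    times = [0.0]
    mother = [1.0]
    daughter = [1.0]
    p_bleach = 1.0 - np.exp(-protocol.k_bleach * dt) if protocol.k_bleach > 0 else 0.0

    # fast path: compiled kernel for membrane species under the standard rules
    use_kernel = (prof is not None and not species.excluded_volume
                  and len(planes) <= 1 and abs(spot.centre[2]) < 1e-12)
    if use_kernel:
        from ._kernels import flip_surface_kernel

        lo, hi = geometry.junction_planes
        n_samples = n_steps // sample_every
        mother_counts = np.zeros(n_samples, dtype=np.int64)
        daughter_counts = np.zeros(n_samples, dtype=np.int64)
        iv = intervals if intervals is not None else np.empty((0, 2))
        p_in_eff = p_in if intervals is not None else 1.0
        p_out_eff = p_out if intervals is not None else 1.0
        plane = planes[0] if planes else None
        flip_surface_kernel(
            prof.x, prof.r, prof.vertex_spacing,
            pos, hint.astype(np.int64), unbleached,
            float(species.D_eff), float(d_in), float(dt), int(n_steps), int(sample_every),
            np.ascontiguousarray(iv, dtype=np.float64), float(p_in_eff), float(p_out_eff),
            plane is not None, float(plane.position) if plane else 0.0,
            float(plane.P / 100.0) if plane else 1.0,
            np.ascontiguousarray(obstacle_centres, dtype=np.float64), float(contact_radius),
            float(spot.centre[0]), float(spot.centre[1]), float(spot.half_length),
            float(spot.radius), float(p_bleach),
            float(lo), float(hi), rng,
            mother_counts, daughter_counts)
        t_samp = np.arange(1, n_samples + 1) * sample_every * dt
        return FlipTrace(
            times=np.concatenate(([0.0], t_samp)),
            mother_fraction=np.concatenate(([1.0], mother_counts / n_m0)),
            daughter_fraction=np.concatenate(([1.0], daughter_counts / n_d0)),
            seed=seed,
            metadata={
                "stage": geometry.stage, "species": species.name, "dt": dt,
                "k_bleach": protocol.k_bleach, "placement": protocol.placement,
                "bridge_fraction": protocol.bridge_fraction,
                "n_particles": n, "barriers": [type(b).__name__ for b in barrier_set],
            })

    for step in range(1, n_steps + 1):
        x_old = pos[:, 0].copy()
        if prof is not None:
            d_arr = np.where(in_domain, d_in, species.D_eff) if intervals is not None \
                else species.D_eff
            new_pos, new_hint = surface_step(pos, prof, d_arr, dt, rng, hint)
        else:
            new_pos = volume_step(pos, species.D_eff, dt, enclosure, rng)
            new_hint = None

        if intervals is not None:
            disp_sq = np.sum((new_pos - pos) ** 2, axis=1)
            _, memb, rej = apply_domain_rule(
                x_old, new_pos[:, 0], intervals, p_in, p_out, rng, d_ratio,
                disp_sq=disp_sq, sigma_sq_out=2.0 * species.D_eff * dt,
                dof=2 if species.is_surface else 3)
            if np.any(rej):
                new_pos[rej] = pos[rej]
                if new_hint is not None:
                    new_hint[rej] = hint[rej]
                memb[rej] = in_domain[rej]
            in_domain = memb

        for plane in planes:
            crossed = (x_old - plane.position) * (new_pos[:, 0] - plane.position) < 0
            if np.any(crossed):
                blocked = crossed & (rng.random(n) >= plane.P / 100.0)
                if np.any(blocked):
                    xr = 2 * plane.position - new_pos[blocked, 0]
                    if prof is not None:
                        r_guess = np.hypot(new_pos[blocked, 1], new_pos[blocked, 2])
                        px, pr, idx = prof.project_2d(xr, r_guess, hint=hint[blocked])
                        scale = np.where(r_guess > 1e-12, pr / np.maximum(r_guess, 1e-12), 0.0)
                        new_pos[blocked, 0] = px
                        new_pos[blocked, 1] *= scale
                        new_pos[blocked, 2] *= scale
                        new_hint[blocked] = idx
                    else:
                        new_pos[blocked, 0] = xr
                        new_pos[blocked] = (enclosure.reflect(new_pos[blocked])
                                            if enclosure is not None else new_pos[blocked])

        if obstacle_centres.size:
            near = np.abs(new_pos[:, 0] - obstacle_centres[:, 0].mean()) < 0.2
            if np.any(near):
                new_pos[near] = collide_obstacles(pos[near], new_pos[near],
                                                  obstacle_centres, contact_radius)

        if species.excluded_volume:
            # particle-particle exclusion: movers landing within 2 r of any
            # other particle's current position are bounced back
            rr = 2.0 * species.particle_radius * 1e-3
            d2 = np.sum((new_pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
            np.fill_diagonal(d2, np.inf)
            clash = np.min(d2, axis=1) < rr * rr
            new_pos[clash] = pos[clash]

        if prof is not None and (intervals is not None or obstacle_centres.size
                                 or species.excluded_volume or planes):
            # re-derive hints where positions were corrected outside surface_step
            rr = np.hypot(new_pos[:, 1], new_pos[:, 2])
            px, pr, new_hint = prof.project_2d(new_pos[:, 0], rr, hint=new_hint)
            scale = np.where(rr > 1e-12, pr / np.maximum(rr, 1e-12), 0.0)
            new_pos = np.column_stack([px, new_pos[:, 1] * scale, new_pos[:, 2] * scale])

        pos = new_pos
        hint = new_hint
        if intervals is not None:
            in_domain = _membership_x(pos[:, 0], intervals)

        if p_bleach > 0.0:
            in_spot = spot.contains(pos)
            hit = unbleached & in_spot & (rng.random(n) < p_bleach)
            unbleached[hit] = False

        if step % sample_every == 0:
            m_mask, d_mask = _lobe_masks(geometry, pos[:, 0])
            times.append(step * dt)
            mother.append(np.sum(unbleached & m_mask) / n_m0)
            daughter.append(np.sum(unbleached & d_mask) / n_d0)

    return FlipTrace(
        times=np.asarray(times), mother_fraction=np.asarray(mother),
        daughter_fraction=np.asarray(daughter), seed=seed,
        metadata={
            "stage": geometry.stage, "species": species.name, "dt": dt,
            "k_bleach": protocol.k_bleach, "placement": protocol.placement,
            "bridge_fraction": protocol.bridge_fraction,
            "n_particles": n, "barriers": [type(b).__name__ for b in barrier_set],
        })
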