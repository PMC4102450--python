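"""Parametric 3D models of the dividing S. cerevisiae nucleus.

The nuclear envelope in early anaphase (EA) is modelled as two prolate
ellipsoids joined tip-to-tip at the bud neck; in late anaphase (LA) as two
teardrop lobes joined by a cylindrical bridge.  Both the outer and inner
nuclear membranes (ONM, INM) are surfaces of revolution about the division
axis (x), with the mother lobe at x < 0 and the neck / bridge centre at x = 0.
The INM is obtained by subtracting the perinuclear-space thickness from the
ONM dimensions.

Teardrop lobes use a one-parameter family interpolating between a sphere and
the pear-shaped ("piriform") quartic b^2 y^2 = x^3 (a - x):

    rho(s)^2 = C * s^(1 + 2 dev) * (L - s),   s in [0, L]

where ``s`` is the axial distance from the pointed tip, ``L`` the lobe length
and ``dev`` the deviation-from-sphere parameter: dev = 0 is exactly a sphere
of diameter L, dev = 1 the piriform quartic.  ``C`` is fixed so the maximal
radius equals the requested lobe half-width.

Each built surface is represented by a dense polyline of its meridian profile
(r as a single-valued function of x), which supports fast containment tests,
projection (used by the Brownian engine), area quadrature and uniform surface
sampling.  All lengths are micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "LobeParams",
    "Profile",
    "NuclearGeometry",
    "build_ea_geometry",
    "build_la_geometry",
    "signed_distance",
    "region_of",
    "surface_area",
    "REGIONS",
]

REGIONS = ("mother_lobe", "neck", "bridge", "daughter_lobe")

# default perinuclear-space thicknesses (um): 22 nm at lobes, 13 nm at bridge
DEFAULT_THICKNESS_LOBE = 0.022
DEFAULT_THICKNESS_BRIDGE = 0.013
# default EA neck opening radius (um): half of the 300 nm domain width
DEFAULT_NECK_OPENING_RADIUS = 0.150

_SURFACE_TOL = 1e-6  # um, tolerance for "point on surface" preconditions


class GeometryError(ValueError):
    """Raised for inconsistent geometric parameters."""


@dataclass
class LobeParams:
    """Dimensions of one nuclear lobe.

    EA lobes are prolate ellipsoids described by ``semi_axis_long`` (along the
    division axis) and ``semi_axis_short``.  LA lobes are teardrops described
    by ``piriform_scale`` (axial length), ``piriform_deviation`` (0 = sphere)
    and optionally ``semi_axis_short`` as the maximal lobe radius (defaults to
    half the scale, matching the sphere limit).
    """

    semi_axis_long: float | None = None
    semi_axis_short: float | None = None
    piriform_scale: float | None = None
    piriform_deviation: float = 0.0
    orientation: Literal["mother", "daughter"] = "mother"

    def ea_axes(self) -> tuple[float, float]:
        a, b = self.semi_axis_long, self.semi_axis_short
        if a is None or b is None or a <= 0 or b <= 0:
            raise GeometryError("EA lobe requires positive semi_axis_long/short")
        if a < b:
            raise GeometryError("prolate lobe requires semi_axis_long >= semi_axis_short")
        return float(a), float(b)

    def la_dims(self) -> tuple[float, float, float]:
        ell = self.piriform_scale
        if ell is None or ell <= 0:
            raise GeometryError("LA lobe requires positive piriform_scale")
        radius = self.semi_axis_short if self.semi_axis_short is not None else ell / 2.0
        if radius <= 0:
            raise GeometryError("LA lobe radius must be positive")
        dev = float(self.piriform_deviation)
        if dev < 0:
            raise GeometryError("piriform_deviation must be >= 0")
        return float(ell), float(radius), dev

    def ea_volume(self) -> float:
        a, b = self.ea_axes()
        return 4.0 / 3.0 * np.pi * a * b * b


# ---------------------------------------------------------------------------
# teardrop (sphere <-> piriform blend) profile helpers
# ---------------------------------------------------------------------------

def _power_lobe_coeff(ell: float, radius: float, dev: float) -> tuple[float, float]:
    """Return (C, p) with rho^2 = C s^p (ell - s) and max radius = radius."""
    p = 1.0 + 2.0 * dev
    s_star = p * ell / (p + 1.0)
    c = radius ** 2 / (s_star ** p * (ell - s_star))
    return c, p


def _power_lobe_rho(s: np.ndarray, ell: float, c: float, p: float) -> np.ndarray:
    s = np.clip(s, 0.0, ell)
    return np.sqrt(np.clip(c * s ** p * (ell - s), 0.0, None))


# ---------------------------------------------------------------------------
# meridian profile (polyline-backed surface of revolution)
# ---------------------------------------------------------------------------

class Profile:
    """Meridian profile r(x) of a closed surface of revolution.

    ``x`` runs from the far (mother) apex to the far (daughter) apex; the
    radius is a single-valued, piecewise-smooth function of x that vanishes at
    both ends.  Backed by a dense polyline resampled to uniform arc length.
    """

    def __init__(self, x: np.ndarray, r: np.ndarray, region_bounds: dict[str, tuple[float, float]],
                 n_vertices: int = 8000, fillet: float = 0.050):
        x = np.asarray(x, dtype=float)
        r = np.asarray(r, dtype=float)
        if np.any(np.diff(x) < 0):
            raise GeometryError("profile x must be non-decreasing")
        # resample to (approximately) uniform arc length
        seg = np.hypot(np.diff(x), np.diff(r))
        arc = np.concatenate(([0.0], np.cumsum(seg)))
        total = arc[-1]
        u = np.linspace(0.0, total, n_vertices)
        self.x = np.interp(u, arc, x)
        self.r = np.maximum(np.interp(u, arc, r), 0.0)
        # round slope discontinuities (neck / junction creases) over ~`fillet`
        # um of arc so closest-point projection is well conditioned there; the
        # perturbation to smooth regions is sub-nanometre
        if fillet > 0.0 and n_vertices > 10:
            spacing = total / max(n_vertices - 1, 1)
            k = int(round(fillet / max(spacing, 1e-12)))
            if k >= 2:
                kern = np.ones(2 * k + 1) / (2 * k + 1)
                rp = np.pad(self.r, k, mode="edge")
                smoothed = np.convolve(rp, kern, mode="valid")
                # keep the closed apexes exact: blend back over the outer 2k
                blend = np.ones(n_vertices)
                ramp = np.linspace(0.0, 1.0, 2 * k)
                blend[:2 * k] = ramp
                blend[-2 * k:] = ramp[::-1]
                self.r = blend * smoothed + (1.0 - blend) * self.r
        # enforce strict monotonicity for interp queries
        self.x = np.maximum.accumulate(self.x)
        eps = 1e-12 * max(total, 1.0)
        dup = np.diff(self.x) <= 0
        if np.any(dup):
            self.x = self.x + np.arange(self.x.size) * eps
        self.region_bounds = dict(region_bounds)
        self._seg_dx = np.diff(self.x)
        self._seg_dr = np.diff(self.r)
        self._seg_len = np.hypot(self._seg_dx, self._seg_dr)
        # lateral (frustum) area per segment and cumulative area
        self._seg_area = np.pi * (self.r[:-1] + self.r[1:]) * self._seg_len
        self._cum_area = np.concatenate(([0.0], np.cumsum(self._seg_area)))
        self.vertex_spacing = float(total / max(n_vertices - 1, 1))

    # -- basic queries -----------------------------------------------------

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def rho(self, x: np.ndarray) -> np.ndarray:
        """Surface radius at axial position x (0 outside the axial range)."""
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.x, self.r, left=0.0, right=0.0)
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point strictly inside the enclosed volume."""
        points = np.atleast_2d(points)
        x = points[:, 0]
        rad = np.hypot(points[:, 1], points[:, 2])
        inside = (x > self.x[0]) & (x < self.x[-1]) & (rad < self.rho(x))
        return inside

    def total_area(self) -> float:
        return float(self._cum_area[-1])

    def area_between(self, x1: float, x2: float) -> float:
        """Lateral surface area of the band x1 <= x <= x2."""
        if x2 < x1:
            x1, x2 = x2, x1
        a1 = np.interp(x1, self.x, self._cum_x_area())
        a2 = np.interp(x2, self.x, self._cum_x_area())
        return float(a2 - a1)

    def _cum_x_area(self) -> np.ndarray:
        return self._cum_area

    # -- projection --------------------------------------------------------

    def project_2d(self, x0: np.ndarray, r0: np.ndarray,
                   hint: np.ndarray | None = None, window: int = 24
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project (x0, r0) in the meridian half-plane onto the profile.

        Returns (x, r, index) of the closest polyline point; ``hint`` (previous
        vertex indices) restricts the search to a local window for speed, as
        engine steps are small compared with the profile extent.
        """
        x0 = np.asarray(x0, dtype=float)
        r0 = np.asarray(r0, dtype=float)
        n = self.x.size
        if hint is None:
            idx0 = np.searchsorted(self.x, x0).clip(0, n - 1)
            window = n  # global search on first call
        else:
            idx0 = np.asarray(hint).clip(0, n - 1)
        if window >= n:
            # full search: vectorised distance to every vertex (analysis use)
            d2 = (self.x[None, :] - x0[:, None]) ** 2 + (self.r[None, :] - r0[:, None]) ** 2
            best = np.argmin(d2, axis=1)
        else:
            offs = np.arange(-window, window + 1)
            cand = (idx0[:, None] + offs[None, :]).clip(0, n - 1)
            d2 = (self.x[cand] - x0[:, None]) ** 2 + (self.r[cand] - r0[:, None]) ** 2
            best = cand[np.arange(x0.size), np.argmin(d2, axis=1)]
        # refine: orthogonal projection onto the better adjacent segment
        return self._refine_segment(best, x0, r0)

    def _refine_segment(self, idx: np.ndarray, x0: np.ndarray, r0: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nseg = self._seg_dx.size
        xs = np.empty_like(x0)
        rs = np.empty_like(r0)
        seg_best = np.zeros(x0.shape, dtype=np.int64)
        best_d2 = np.full(x0.shape, np.inf)
        for s in (np.clip(idx - 1, 0, nseg - 1), np.clip(idx, 0, nseg - 1)):
            dx, dr, ln = self._seg_dx[s], self._seg_dr[s], self._seg_len[s]
            ln2 = np.maximum(ln * ln, 1e-300)
            t = ((x0 - self.x[s]) * dx + (r0 - self.r[s]) * dr) / ln2
            t = np.clip(t, 0.0, 1.0)
            px = self.x[s] + t * dx
            pr = self.r[s] + t * dr
            d2 = (px - x0) ** 2 + (pr - r0) ** 2
            upd = d2 < best_d2
            xs = np.where(upd, px, xs)
            rs = np.where(upd, pr, rs)
            seg_best = np.where(upd, s, seg_best)
            best_d2 = np.where(upd, d2, best_d2)
        return xs, np.maximum(rs, 0.0), seg_best

    def tangent_2d(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit meridian tangent (dx, dr) at the given vertex indices."""
        s = np.clip(idx, 0, self._seg_dx.size - 1)
        ln = np.maximum(self._seg_len[s], 1e-300)
        return self._seg_dx[s] / ln, self._seg_dr[s] / ln

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed Euclidean distance: negative inside, positive outside."""
        points = np.atleast_2d(points)
        x0 = points[:, 0]
        rad = np.hypot(points[:, 1], points[:, 2])
        px, pr, _ = self.project_2d(x0, rad, hint=None)
        dist = np.hypot(px - x0, pr - rad)
        sign = np.where(self.contains(points), -1.0, 1.0)
        return sign * dist

    # -- sampling ----------------------------------------------------------

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points uniformly distributed over the surface area."""
        u = rng.uniform(0.0, self._cum_area[-1], size=n)
        seg = np.searchsorted(self._cum_area, u, side="right") - 1
        seg = np.clip(seg, 0, self._seg_area.size - 1)
        frac = (u - self._cum_area[seg]) / np.maximum(self._seg_area[seg], 1e-300)
        x = self.x[seg] + frac * self._seg_dx[seg]
        r = np.maximum(self.r[seg] + frac * self._seg_dr[seg], 0.0)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


# ---------------------------------------------------------------------------
# geometry container
# ---------------------------------------------------------------------------

@dataclass
class NuclearGeometry:
    """One nucleus at one anaphase stage, with ONM and INM profiles."""

    stage: Literal["EA", "LA"]
    mother: LobeParams
    daughter: LobeParams
    onm: Profile
    inm: Profile
    bridge_length: float | None = None
    bridge_diameter: float | None = None
    perinuclear_thickness_lobe: float = DEFAULT_THICKNESS_LOBE
    perinuclear_thickness_bridge: float = DEFAULT_THICKNESS_BRIDGE
    neck_opening_radius: float | None = None
    metadata: dict = field(default_factory=dict)

    def profile(self, surface: str) -> Profile:
        surface = surface.upper()
        if surface == "ONM":
            return self.onm
        if surface == "INM":
            return self.inm
        if surface in ("NE", "MID"):
            return self._mid_profile()
        raise GeometryError(f"unknown surface {surface!r}")

    def _mid_profile(self) -> Profile:
        """Mid-surface between ONM and INM (used for perinuclear diffusers)."""
        if not hasattr(self, "_mid_cache"):
            x = self.onm.x
            r_on = self.onm.r
            r_in = self.inm.rho(x)
            mid = 0.5 * (r_on + np.where(r_in > 0, r_in, r_on))
            self._mid_cache = Profile(x, mid, self.onm.region_bounds,
                                      n_vertices=self.onm.x.size)
        return self._mid_cache

    @property
    def junction_planes(self) -> tuple[float, float]:
        """Axial positions of the mother-side and daughter-side junctions."""
        if self.stage == "LA":
            half = self.bridge_length / 2.0
            return -half, half
        return 0.0, 0.0

    def region_of_x(self, x: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Primary region label for axial coordinates (vectorised)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.junction_planes
        labels = np.empty(x.shape, dtype=object)
        if self.stage == "EA":
            labels[:] = "daughter_lobe"
            labels[x < -atol] = "mother_lobe"
            labels[np.abs(x) <= atol] = "neck"
        else:
            labels[:] = "bridge"
            labels[x < lo] = "mother_lobe"
            labels[x > hi] = "daughter_lobe"
        return labels


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _ellipsoid_lobe_polyline(a: float, b: float, neck_radius: float,
                             side: str, n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Meridian polyline of a prolate lobe truncated at the neck circle.

    The lobe is positioned so its surface meets the plane x = 0 at radius
    ``neck_radius`` (mother: from the left, daughter: mirrored).
    """
    if neck_radius >= b:
        raise GeometryError("neck opening radius must be smaller than the lobe half-width")
    x_off = a * np.sqrt(1.0 - (neck_radius / b) ** 2)
    # mother: centre at -x_off; t from pi (far apex) down to t_j at x = 0
    t_j = np.arccos(np.clip(x_off / a, -1.0, 1.0))
    t = np.linspace(np.pi, t_j, n)
    x = -x_off + a * np.cos(t)
    r = b * np.sin(t)
    if side == "daughter":
        x = -x[::-1]
        r = r[::-1]
    return x, r


def _teardrop_lobe_polyline(ell: float, radius: float, dev: float,
                            junction_radius: float, junction_x: float,
                            side: str, n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Meridian polyline of a teardrop lobe truncated at the bridge junction.

    The pointed tip faces the bridge; the lobe is truncated where its radius
    first reaches ``junction_radius`` and that circle is placed at
    ``junction_x``.
    """
    c, p = _power_lobe_coeff(ell, radius, dev)
    if junction_radius >= radius:
        raise GeometryError("bridge radius must be smaller than the lobe half-width")
    # first s (rising branch, s < s*) with rho(s) == junction_radius
    from scipy.optimize import brentq
    s_star = p * ell / (p + 1.0)
    if junction_radius <= 0:
        s_j = 0.0
    else:
        s_j = brentq(lambda s: _power_lobe_rho(np.array([s]), ell, c, p)[0] - junction_radius,
                     1e-12 * ell, s_star)
    s = np.linspace(s_j, ell, n)
    r = _power_lobe_rho(s, ell, c, p)
    r[0] = junction_radius
    r[-1] = 0.0
    if side == "mother":
        x = junction_x - (s - s_j)
        return x[::-1], r[::-1]
    x = junction_x + (s - s_j)
    return x, r


def _stitch(*parts: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    xs, rs = [], []
    for i, (x, r) in enumerate(parts):
        if i > 0:
            x, r = x[1:], r[1:]  # drop duplicated junction vertex
        xs.append(x)
        rs.append(r)
    return np.concatenate(xs), np.concatenate(rs)


def build_ea_geometry(mother: LobeParams, daughter: LobeParams,
                      perinuclear_thickness_lobe: float = DEFAULT_THICKNESS_LOBE,
                      neck_opening_radius: float = DEFAULT_NECK_OPENING_RADIUS,
                      n_vertices: int = 8000, fillet: float = 0.050) -> NuclearGeometry:
    """Two prolate ellipsoid lobes joined tip-to-tip at the bud neck (x = 0).

    The neck is a finite circular aperture of radius ``neck_opening_radius``
    so that membrane particles can cross between lobes; the perinuclear-space
    thickness is subtracted from the ONM dimensions to obtain the INM.
    """
    am, bm = mother.ea_axes()
    ad, bd = daughter.ea_axes()
    t = perinuclear_thickness_lobe
    if t < 0 or neck_opening_radius <= 0:
        raise GeometryError("thickness must be >= 0 and neck opening > 0")
    if daughter.ea_volume() > mother.ea_volume():
        warnings.warn("daughter lobe larger than mother lobe (budding usually implies "
                      "daughter <= mother)", stacklevel=2)

    def make(axes_shrink: float, neck_r: float) -> Profile:
        xm, rm = _ellipsoid_lobe_polyline(am - axes_shrink, bm - axes_shrink, neck_r, "mother")
        xd, rd = _ellipsoid_lobe_polyline(ad - axes_shrink, bd - axes_shrink, neck_r, "daughter")
        x, r = _stitch((xm, rm), (xd, rd))
        bounds = {"mother_lobe": (float(x[0]), 0.0), "daughter_lobe": (0.0, float(x[-1]))}
        return Profile(x, r, bounds, n_vertices=n_vertices, fillet=fillet)

    neck_inm = neck_opening_radius - t
    if neck_inm <= 0:
        raise GeometryError("neck opening must exceed the perinuclear thickness")
    onm = make(0.0, neck_opening_radius)
    inm = make(t, neck_inm)
    return NuclearGeometry(
        stage="EA", mother=mother, daughter=daughter, onm=onm, inm=inm,
        perinuclear_thickness_lobe=t, perinuclear_thickness_bridge=t,
        neck_opening_radius=neck_opening_radius,
        metadata={"neck_opening_radius": neck_opening_radius},
    )


def build_la_geometry(mother: LobeParams, daughter: LobeParams,
                      bridge_length: float, bridge_diameter: float = 0.2,
                      perinuclear_thickness_lobe: float = DEFAULT_THICKNESS_LOBE,
                      perinuclear_thickness_bridge: float = DEFAULT_THICKNESS_BRIDGE,
                      n_vertices: int = 8000, fillet: float = 0.050) -> NuclearGeometry:
    """Dumbbell nucleus: teardrop lobes joined by a cylindrical bridge.

    The bridge spans ``|x| <= bridge_length / 2`` with constant diameter; the
    lobe-bridge junctions are hard intersections at the bridge end planes.
    """
    if bridge_length <= 0:
        raise GeometryError("bridge_length must be positive")
    if bridge_diameter <= 0:
        raise GeometryError("bridge_diameter must be positive")
    ell_m, rad_m, dev_m = mother.la_dims()
    ell_d, rad_d, dev_d = daughter.la_dims()
    if bridge_diameter / 2.0 >= min(rad_m, rad_d):
        raise GeometryError("bridge wider than a lobe")
    t_l, t_b = perinuclear_thickness_lobe, perinuclear_thickness_bridge
    half = bridge_length / 2.0
    r_bridge = bridge_diameter / 2.0
    if r_bridge - t_b <= 0:
        raise GeometryError("bridge radius must exceed the perinuclear thickness at the bridge")

    def make(shrink_l: float, shrink_b: float) -> Profile:
        rb = r_bridge - shrink_b
        xm, rm = _teardrop_lobe_polyline(ell_m - 2 * shrink_l, rad_m - shrink_l,
                                         dev_m, rb, -half, "mother")
        xb = np.array([-half, half])
        rbb = np.array([rb, rb])
        xd, rd = _teardrop_lobe_polyline(ell_d - 2 * shrink_l, rad_d - shrink_l,
                                         dev_d, rb, half, "daughter")
        x, r = _stitch((xm, rm), (xb, rbb), (xd, rd))
        bounds = {"mother_lobe": (float(x[0]), -half), "bridge": (-half, half),
                  "daughter_lobe": (half, float(x[-1]))}
        return Profile(x, r, bounds, n_vertices=n_vertices, fillet=fillet)

    onm = make(0.0, 0.0)
    inm = make(t_l, t_b)
    return NuclearGeometry(
        stage="LA", mother=mother, daughter=daughter, onm=onm, inm=inm,
        bridge_length=bridge_length, bridge_diameter=bridge_diameter,
        perinuclear_thickness_lobe=t_l, perinuclear_thickness_bridge=t_b,
        metadata={},
    )


# ---------------------------------------------------------------------------
# module-level queries (spec operations)
# ---------------------------------------------------------------------------

def signed_distance(geometry: NuclearGeometry, surface: str, points: np.ndarray) -> np.ndarray:
    """Signed distance to the named surface: negative inside, zero on it."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = geometry.profile(surface).signed_distance(pts)
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def region_of(geometry: NuclearGeometry, surface: str, points: np.ndarray,
              tol: float = 1e-3) -> np.ndarray:
    """Primary region label of surface points (must lie on the surface)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sd = geometry.profile(surface).signed_distance(pts)
    if np.any(np.abs(sd) > tol):
        raise GeometryError("point is not on the requested surface")
    labels = geometry.region_of_x(pts[:, 0])
    if np.asarray(points).ndim == 1:
        return labels[0]
    return labels


def surface_area(geometry: NuclearGeometry, surface: str, region: str | None = None) -> float:
    """Surface area (um^2) of the whole surface or one labelled region."""
    prof = geometry.profile(surface)
    if region is None:
        return prof.total_area()
    if region not in prof.region_bounds:
        if region == "neck":  # EA neck plane has zero lateral area
            return 0.0
        raise GeometryError(f"unknown region {region!r}")
    x1, x2 = prof.region_bounds[region]
    return prof.area_between(x1, x2)


def export_obj(geometry: NuclearGeometry, surface: str, path: str,
               n_phi: int = 64, stride: int = 8) -> None:
    """Write a triangulated revolve of the surface profile as an OBJ file."""
    prof = geometry.profile(surface)
    x = prof.x[::stride]
    r = prof.r[::stride]
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    verts = []
    for xi, ri in zip(x, r):
        for p in phi:
            verts.append((xi, ri * np.cos(p), ri * np.sin(p)))
    lines = [f"v {vx:.6f} {vy:.6f} {vz:.6f}" for vx, vy, vz in verts]
    nrow = len(x)
    for i in range(nrow - 1):
        for j in range(n_phi):
            a = i * n_phi + j + 1
            b = i * n_phi + (j + 1) % n_phi + 1
            c = (i + 1) * n_phi + j + 1
            d = (i + 1) * n_phi + (j + 1) % n_phi + 1
            lines.append(f"f {a} {b} {d}")
            lines.append(f"f {a} {d} {c}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def prolate_area(a: float, b: float) -> float:
    """Closed-form surface area of a full prolate ellipsoid (a >= b)."""
    if np.isclose(a, b):
        return 4.0 * np.pi * a * a
    e = np.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * np.pi * b * b * (1.0 + (a / (b * e)) * np.arcsin(e))
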