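"""Membrane hydrodynamics: Saffman-Delbrueck and Petrov-Schwille mobilities.

Lateral diffusion of a cylindrical inclusion of radius ``r`` in a membrane of
thickness ``h`` and bulk viscosity ``mu_m`` (surface viscosity
``mu_s = mu_m * h``), flanked by fluids of bulk viscosities ``mu_f_top`` and
``mu_f_bot``, follows the Saffman-Delbrueck (SD) law

    D = k_B T / (4 pi mu_s) * [ln(2 / eps) - gamma]

valid for small reduced radius ``eps = r (mu_f_top + mu_f_bot) / mu_s``.  The
Petrov-Schwille (PS) rational approximation extends this to arbitrary eps
(1e-3 <= eps <= 1e5) and reduces to SD as eps -> 0:

    D = k_B T / (4 pi mu_s) *
        [ln(2/eps) - gamma + 4 eps/pi - (eps^2/2) ln(2/eps)] /
        [1 - (eps^3/pi) ln(2/eps) + c1 eps^{b1} / (1 + c2 eps^{b2})]

with the published fit constants c1 = 0.73761, b1 = 2.74819, c2 = 0.52119,
b2 = 0.61465.  The assignment of the four constants to positions in the
rational approximation follows the original publication and is verified by
the SD limit (a mis-assignment breaks the eps -> 0 agreement).

The Einstein-Smoluchowski relation D = k_B T / zeta links diffusion to the
viscous drag; within a thicker, more viscous lipid domain a given fold
increase in drag lowers D by the same factor.

Radii and thicknesses are nanometres, diffusion coefficients um^2/s,
viscosities SI, temperature kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .units import (CYTOPLASM_VISCOSITY, EULER_GAMMA, K_B, M_PER_NM, T_FLIP,
                    m2_s_to_um2_s, um2_s_to_m2_s)

__all__ = [
    "MembraneSpec", "InclusionSpec", "PS_CONSTANTS",
    "saffman_delbruck_D", "reduced_radius", "petrov_schwille_D",
    "invert_surface_viscosity", "domain_diffusion", "viscous_drag",
    "domain_thickness", "membrane_report",
]

# Petrov-Schwille fit constants (c1, b1, c2, b2)
PS_CONSTANTS = (0.73761, 2.74819, 0.52119, 0.61465)

EPS_VALID = (1e-3, 1e5)


class HydroModelError(ValueError):
    """Raised when a hydrodynamic model is evaluated outside its validity."""


@dataclass
class MembraneSpec:
    """Membrane and flanking-fluid properties.

    Either ``mu_s`` (surface viscosity, Pa s m) or ``mu_m`` (bulk membrane
    viscosity, Pa s) together with the thickness may be given; when both are
    supplied they must satisfy mu_s ~= mu_m * h.
    """

    h: float = 4.0                      # membrane thickness, nm
    h_domain: float | None = None       # thickness inside the lipid domain, nm
    mu_s: float | None = None           # surface viscosity, Pa s m
    mu_m: float | None = None           # bulk membrane viscosity, Pa s
    mu_f_top: float = CYTOPLASM_VISCOSITY   # flanking fluid, Pa s
    mu_f_bot: float = CYTOPLASM_VISCOSITY   # flanking fluid, Pa s
    T: float = T_FLIP                   # temperature, K

    def __post_init__(self):
        if self.h <= 0 or self.T <= 0 or self.mu_f_top <= 0 or self.mu_f_bot <= 0:
            raise HydroModelError("membrane parameters must be positive")
        if self.mu_s is None and self.mu_m is None:
            raise HydroModelError("one of mu_s or mu_m is required")
        if self.mu_s is None:
            self.mu_s = self.mu_m * self.h * M_PER_NM
        elif self.mu_m is not None:
            implied = self.mu_m * self.h * M_PER_NM
            if not np.isclose(implied, self.mu_s, rtol=1e-3, atol=0.0):
                raise HydroModelError(
                    f"inconsistent viscosities: mu_m*h = {implied:.4g} != mu_s = {self.mu_s:.4g}")
        if self.mu_s <= 0:
            raise HydroModelError("surface viscosity must be positive")

    def with_surface_viscosity(self, mu_s: float) -> "MembraneSpec":
        return MembraneSpec(h=self.h, h_domain=self.h_domain, mu_s=mu_s,
                            mu_f_top=self.mu_f_top, mu_f_bot=self.mu_f_bot, T=self.T)


@dataclass
class InclusionSpec:
    """A membrane protein treated as a cylindrical inclusion."""

    r: float                        # inclusion radius, nm
    D_eff: float | None = None      # measured effective diffusion, um^2/s
    name: str = ""

    def __post_init__(self):
        if self.r <= 0:
            raise HydroModelError("inclusion radius must be positive")
        if self.D_eff is not None and self.D_eff <= 0:
            raise HydroModelError("D_eff must be positive when given")


def reduced_radius(incl: InclusionSpec, mem: MembraneSpec, warn: bool = True) -> float:
    """Dimensionless reduced radius eps = r (mu_f_top + mu_f_bot) / mu_s."""
    eps = incl.r * M_PER_NM * (mem.mu_f_top + mem.mu_f_bot) / mem.mu_s
    if warn and not (EPS_VALID[0] <= eps <= EPS_VALID[1]):
        warnings.warn(f"reduced radius eps = {eps:.3g} outside the validated window "
                      f"[{EPS_VALID[0]:g}, {EPS_VALID[1]:g}]", stacklevel=2)
    return eps


def saffman_delbruck_D(incl: InclusionSpec, mem: MembraneSpec) -> float:
    """SD diffusion coefficient (um^2/s); requires a small reduced radius."""
    eps = reduced_radius(incl, mem, warn=False)
    if eps > 0.1:
        warnings.warn(f"SD model applied at eps = {eps:.3g} > 0.1; "
                      "prefer petrov_schwille_D", stacklevel=2)
    log_arg = 2.0 / eps
    if log_arg <= 1.0:
        raise HydroModelError("SD logarithm argument <= 1: inclusion too large "
                              "for the Saffman-Delbrueck regime")
    d = K_B * mem.T / (4.0 * np.pi * mem.mu_s) * (np.log(log_arg) - EULER_GAMMA)
    return m2_s_to_um2_s(d)


def petrov_schwille_D(incl: InclusionSpec, mem: MembraneSpec) -> float:
    """PS diffusion coefficient (um^2/s), valid for arbitrary reduced radius."""
    eps = reduced_radius(incl, mem)
    c1, b1, c2, b2 = PS_CONSTANTS
    ln = np.log(2.0 / eps)
    num = ln - EULER_GAMMA + 4.0 * eps / np.pi - 0.5 * eps * eps * ln
    den = 1.0 - (eps ** 3 / np.pi) * ln + c1 * eps ** b1 / (1.0 + c2 * eps ** b2)
    d = K_B * mem.T / (4.0 * np.pi * mem.mu_s) * num / den
    if not np.isfinite(d):
        raise HydroModelError(f"non-finite PS mobility at eps = {eps:.3g}")
    return m2_s_to_um2_s(d)


def invert_surface_viscosity(D_eff: float, incl: InclusionSpec, mem: MembraneSpec,
                             bracket: tuple[float, float] = (1e-14, 1e-2)) -> float:
    """Surface viscosity mu_s (Pa s m) at which the PS model yields D_eff.

    Solved by bracketed root finding on log10(mu_s); D is strictly decreasing
    in mu_s, so the root is unique within the bracket.
    """
    if D_eff <= 0:
        raise HydroModelError("D_eff must be positive")

    def f(log_mu):
        m = mem.with_surface_viscosity(10.0 ** log_mu)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return petrov_schwille_D(incl, m) - D_eff

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise HydroModelError("no bracket for surface-viscosity inversion; "
                              "widen the bracket or check D_eff")
    log_mu = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    return 10.0 ** log_mu


def domain_diffusion(D_out: float, drag_fold: float) -> float:
    """Diffusion inside a lipid domain whose viscous drag is drag_fold higher.

    Einstein-Smoluchowski (D = k_B T / zeta): an n-fold drag increase drops D
    to D/n; e.g. the three-fold raft drag turns 0.3 into 0.1 um^2/s.
    """
    if drag_fold < 1:
        raise HydroModelError("drag_fold must be >= 1")
    return D_out / drag_fold


def viscous_drag(D: float, T: float = T_FLIP) -> float:
    """Viscous drag zeta = k_B T / D (kg/s) from a diffusion coefficient."""
    if D <= 0:
        raise HydroModelError("D must be positive")
    return K_B * T / um2_s_to_m2_s(D)


def domain_thickness(h: float, leaflet_increase: float) -> float:
    """Bilayer thickness inside a domain: h + one increase per leaflet (nm).

    A ~7 A height increase per leaflet thickens a 4 nm membrane to ~5.4 nm.
    """
    if h <= 0 or leaflet_increase < 0:
        raise HydroModelError("inputs must be positive")
    return h + 2.0 * leaflet_increase


def membrane_report(species: list[tuple[str, InclusionSpec]], mem: MembraneSpec,
                    drag_fold: float = 3.0, leaflet_increase: float = 0.7):
    """Per-species table of inverted viscosities, drags and domain diffusion.

    For each (label, inclusion) with a measured effective D, invert the PS
    model for the surface viscosity, then report the viscous drag and the
    expected diffusion coefficient inside a lipid domain with ``drag_fold``
    higher drag and a membrane thickened by ``leaflet_increase`` nm per
    leaflet.  Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for label, incl in species:
        if incl.D_eff is None:
            raise HydroModelError(f"species {label!r} lacks a measured D_eff")
        mu_s = invert_surface_viscosity(incl.D_eff, incl, mem)
        m_fit = mem.with_surface_viscosity(mu_s)
        rows.append({
            "species": label,
            "radius_nm": incl.r,
            "thickness_nm": mem.h,
            "thickness_domain_nm": domain_thickness(mem.h, leaflet_increase),
            "mu_s_Pa_s_m": mu_s,
            "reduced_radius": reduced_radius(incl, m_fit, warn=False),
            "D_out_um2_s": incl.D_eff,
            "zeta_out_kg_s": viscous_drag(incl.D_eff, mem.T),
            "D_in_um2_s": domain_diffusion(incl.D_eff, drag_fold),
            "zeta_in_kg_s": viscous_drag(domain_diffusion(incl.D_eff, drag_fold), mem.T),
        })
    return pd.DataFrame(rows)
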