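"""Physical constants and unit conventions.

Lengths are micrometres, time seconds and temperature kelvin at every API
boundary; viscosities are SI (Pa s for bulk, Pa s m for surface).  Conversions
between the micrometre world of the simulator and the SI world of the
hydrodynamic formulas are centralised here.
"""

# Boltzmann constant, J/K
K_B = 1.380649e-23

# Euler-Mascheroni constant (enters the Saffman-Delbrueck logarithm)
EULER_GAMMA = 0.577215

# Bulk viscosity of water at 303.15 K (30 C), Pa s
WATER_VISCOSITY_303K = 7.978e-4

# Temperature at which the reference FLIP experiments were performed, K
T_FLIP = 303.15

# Cytoplasm (and, by assumption, nucleoplasm and periplasm) bulk viscosity:
# 1.5x water at 30 C, Pa s
CYTOPLASM_VISCOSITY = 1.5 * WATER_VISCOSITY_303K

# metres per micrometre / nanometre
M_PER_UM = 1e-6
M_PER_NM = 1e-9
UM2_PER_M2 = 1e12


def um2_s_to_m2_s(d_um2_s: float) -> float:
    """Convert a diffusion coefficient from um^2/s to m^2/s."""
    return d_um2_s / UM2_PER_M2


def m2_s_to_um2_s(d_m2_s: float) -> float:
    """Convert a diffusion coefficient from m^2/s to um^2/s."""
    return d_m2_s * UM2_PER_M2
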