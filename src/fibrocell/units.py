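"""Unit system and physical-scale conversions.

The simulator works in a single internal unit system chosen so that the
mechanical parameter values of collagen-like fiber gels come out as numbers
of order one:

===========  ==========  =================================
quantity     unit        SI equivalent
===========  ==========  =================================
length       micrometre  1e-6 m
force        nanonewton  1e-9 N
energy       fJ          1 nN * 1 um = 1e-15 J
time         second      1 s
stiffness    nN/um       1e-3 N/m
===========  ==========  =================================

Cellular-Potts energies are dimensionless and live on their own scale (the
motility temperature T); they never mix with mechanical energies.

One lattice site spans 0.25 um and one Monte Carlo step of the coupled model
corresponds to 2.88 s of wall-clock time, so that 1e4 steps amount to roughly
eight hours of cell culture.
"""

from __future__ import annotations

import math

#: Physical edge length of one lattice site [um].
LATTICE_SPACING_UM: float = 0.25

#: Physical duration of one coupled Monte Carlo step [s].
STEP_DURATION_S: float = 2.88

# Conversion factors between SI and internal units.
N_PER_M_TO_NN_PER_UM: float = 1e3      # 1 N/m  = 1e3 nN/um
J_TO_FJ: float = 1e15                  # 1 J    = 1e15 fJ
N_TO_NN: float = 1e9                   # 1 N    = 1e9 nN
PER_N_TO_PER_NN: float = 1e-9          # 1 N^-1 = 1e-9 nN^-1


def sites_to_um(distance_sites: float) -> float:
    """Convert a distance in lattice sites to micrometres."""
    return distance_sites * LATTICE_SPACING_UM


def steps_to_seconds(steps: float) -> float:
    """Convert a number of Monte Carlo steps to seconds."""
    return steps * STEP_DURATION_S


def modulus_to_spring_constant(young_modulus_pa: float,
                               diameter_m: float,
                               segment_length_m: float) -> float:
    """Spring constant of a fiber segment modeled as a cylindrical rod.

    K = Y * A / L with cross-sectional area A = pi * (d/2)**2.

    Parameters
    ----------
    young_modulus_pa
        Tensile (Young's) modulus of the fiber material [Pa].
    diameter_m
        Rod diameter [m].
    segment_length_m
        Length of one discretized segment, i.e. the spring rest length [m].

    Returns
    -------
    float
        Spring constant in N/m.  For collagen (Y = 1e6 Pa, d = 0.125 um,
        L = 0.4 um) this evaluates to ~3.1e-2 N/m.
    """
    if young_modulus_pa <= 0 or diameter_m <= 0 or segment_length_m <= 0:
        raise ValueError("all rod parameters must be positive")
    area = math.pi * (diameter_m / 2.0) ** 2
    return young_modulus_pa * area / segment_length_m
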