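"""Unit conventions shared by every engine.

Energies are stored in wavenumbers (cm^-1), times in femtoseconds during
propagation, and transfer times are reported in picoseconds.  Conversions
between wavenumbers and angular frequencies use

    omega[fs^-1] = 2 pi c[cm fs^-1] * E[cm^-1]

so that a 1 cm^-1 splitting corresponds to an angular frequency of about
1.883652e-4 fs^-1.
"""

import math

#: Speed of light in cm / fs.
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5

#: Boltzmann constant in cm^-1 / K.
BOLTZMANN_CM1_K = 0.695034800

#: Angular frequency (fs^-1) per wavenumber (cm^-1).
CM1_TO_ANGFS = 2.0 * math.pi * SPEED_OF_LIGHT_CM_FS

FS_PER_PS = 1000.0
PS_PER_NS = 1000.0


def cm1_to_angular_fs(energy_cm1):
    """Convert an energy in cm^-1 to an angular frequency in rad/fs."""
    return energy_cm1 * CM1_TO_ANGFS


def angular_fs_to_cm1(omega_fs):
    """Convert an angular frequency in rad/fs to an energy in cm^-1."""
    return omega_fs / CM1_TO_ANGFS


def thermal_energy_cm1(temperature_k):
    """k_B T in cm^-1 for a temperature in kelvin."""
    return BOLTZMANN_CM1_K * temperature_k
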