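"""Physical constants used throughout the package.

Values are CODATA-style and immutable.  Internal unit conventions:
lengths in nm, scattering vector q in 1/nm, form-factor amplitudes in
Angstrom (the native unit of the five-Gaussian coefficient tables),
energies in eV where they face the user (Monte Carlo, beam energy).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI unless noted)."""

    electron_rest_mass: float = 9.1093837015e-31  # m0, kg
    planck: float = 6.62607015e-34                # h, J s
    light_speed: float = 299792458.0              # c, m/s
    thomson_length: float = 2.8179403262e-3       # r0, nm (2.82 pm)
    boltzmann: float = 8.617333262e-5             # kB, eV/K
    elementary_charge: float = 1.602176634e-19    # e, C
    vacuum_permittivity: float = 8.8541878128e-12 # eps0, F/m
    bohr_radius_nm: float = 0.0529177210903       # a0, nm

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"constant {name} must be strictly positive")


CONSTANTS = PhysicalConstants()

#: rest energy of the electron, eV
ELECTRON_REST_ENERGY_EV = (
    CONSTANTS.electron_rest_mass * CONSTANTS.light_speed**2
    / CONSTANTS.elementary_charge
)
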