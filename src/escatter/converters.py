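"""Scattering-vector conversions and the electron-density converter.

Conversions between the scattering-vector conventions

    q = (4 pi / lambda) sin(theta),   k = theta / lambda,   s = q / (2 pi)

and the zero-potential converter that maps a bulk electron density
(e-/nm^3, the X-ray contrast quantity) to the corresponding bulk zero
potential phi0 (reported in e-/nm), the electron-scattering analog used
for solvent contrast.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import ELECTRON_REST_ENERGY_EV, CONSTANTS
from .species import lookup_species

__all__ = [
    "BeamParameters",
    "Composition",
    "electron_wavelength",
    "k_from_q",
    "q_from_k",
    "s_from_q",
    "q_from_s",
    "parse_formula",
    "zero_potential",
]

#: documented default acceleration voltage (kV)
DEFAULT_VOLTAGE_KV = 200.0


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength (nm) of beam electrons.

    lambda = h c / sqrt(E_kin (E_kin + 2 m0 c^2)) with E_kin = e V.
    200 kV gives 2.508 pm.
    """
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    e_kin = voltage_kv * 1e3  # eV
    hc_ev_nm = (CONSTANTS.planck * CONSTANTS.light_speed
                / CONSTANTS.elementary_charge) * 1e9
    return hc_ev_nm / np.sqrt(e_kin * (e_kin + 2 * ELECTRON_REST_ENERGY_EV))


@dataclass(frozen=True)
class BeamParameters:
    """Beam wavelength (nm), optionally derived from a voltage (kV)."""

    wavelength: float | None = None
    voltage_kv: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength is None and self.voltage_kv is None:
            raise ValueError("provide wavelength or voltage_kv")
        if self.wavelength is None:
            object.__setattr__(self, "wavelength",
                               electron_wavelength(self.voltage_kv))
        elif self.voltage_kv is not None:
            expected = electron_wavelength(self.voltage_kv)
            if abs(self.wavelength - expected) > 1e-6 * expected:
                raise ValueError(
                    f"wavelength {self.wavelength} nm inconsistent with "
                    f"{self.voltage_kv} kV (expected {expected:.6g} nm)")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")


def k_from_q(q, beam: BeamParameters):
    """k = arcsin(q lambda / 4 pi) / lambda (both in 1/nm)."""
    q = np.asarray(q, dtype=float)
    lam = beam.wavelength
    x = q * lam / (4.0 * np.pi)
    if np.any(np.abs(x) > 1.0):
        raise ValueError(
            "q lambda / 4 pi out of [-1, 1]: scattering angle undefined")
    out = np.arcsin(x) / lam
    return out if out.ndim else float(out)


def q_from_k(k, beam: BeamParameters):
    """q = (4 pi / lambda) sin(k lambda) (both in 1/nm)."""
    k = np.asarray(k, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("k must be finite")
    lam = beam.wavelength
    out = 4.0 * np.pi / lam * np.sin(k * lam)
    return out if out.ndim else float(out)


def s_from_q(q):
    """s = q / 2 pi."""
    out = np.asarray(q, dtype=float) / (2.0 * np.pi)
    return out if out.ndim else float(out)


def q_from_s(s):
    """q = 2 pi s."""
    out = 2.0 * np.pi * np.asarray(s, dtype=float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Composition:
    """Chemical composition as (species symbol, count) pairs."""

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("composition must be non-empty")
        for sym, n in self.items:
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"count for {sym!r} must be a positive integer")
            lookup_species(sym)  # raises for unknown symbols


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse a simple chemical formula like 'H2O' or 'C6H12O6'."""
    formula = formula.strip()
    pos = 0
    items: list[tuple[str, int]] = []
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos or not m.group(1):
            break
        items.append((m.group(1), int(m.group(2) or 1)))
        pos = m.end()
    if pos != len(formula) or not items:
        raise ValueError(f"cannot parse chemical formula {formula!r}")
    return Composition(tuple(items))


def zero_potential(rho_bulk: float, composition: Composition | str) -> float:
    """Convert a bulk electron density to the bulk zero potential.

    The proportion coefficient is the ratio of composition-weighted X-ray
    to electron coefficient sums,

        p = [sum_i n_i f_i^x(0)] / [sum_i n_i f_i^e(0)],

    and phi0 = rho_bulk / p, reported in e-/nm as printed by the
    convention this package follows (water at 333 e-/nm^3 gives
    101.27 e-/nm).
    """
    if rho_bulk < 0:
        raise ValueError("rho_bulk must be >= 0")
    if isinstance(composition, str):
        composition = parse_formula(composition)
    sum_x = 0.0
    sum_e = 0.0
    for sym, n in composition.items:
        rec = lookup_species(sym)
        fx0 = (rec.xray_coeffs.f0 if rec.xray_coeffs is not None
               else sum(lookup_species(c).xray_coeffs.f0
                        for c in rec.constituents))
        sum_x += n * fx0
        sum_e += n * rec.electron_coeffs.f0
    if sum_e == 0.0:
        raise ValueError("degenerate composition: electron coefficient sum is 0")
    p = sum_x / sum_e
    return rho_bulk / p
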