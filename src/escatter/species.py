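"""Species tables and form-factor primitives.

The package evaluates electron scattering through five-Gaussian
parameterizations of the atomic (and atomic-group) form factors,

    f(q) = sum_j a_j exp(-b_j (q / 40 pi)^2),

with q in 1/nm and the widths b_j in Angstrom^2 exactly as published
(q[1/nm] / (40 pi) equals sin(theta)/lambda in 1/Angstrom).  Amplitudes
a_j are in Angstrom for the electron tables and in electrons for the
X-ray tables.  The electron parameterization is accurate up to
q ~ 250 1/nm.

Three coefficient tables ship with the package as plain-text files
(``data/*.tsv``): a published electron table for neutral atoms plus the
common protein atomic groups (CH, CH2, CH3, NH, NH2, NH3, OH, SH), an
X-ray table with f(0) = Z, and a supplementary electron table whose rows
were derived from the X-ray table through the Mott-Bethe relation (its
header says so; see the file).

The Debye formula implemented here is the exact orientation-averaged
intensity of an atomic model and serves as the oracle for every vacuum
scattering path in the package.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .constants import CONSTANTS, ELECTRON_REST_ENERGY_EV

_DATA_DIR = Path(__file__).parent / "data"

#: highest q (1/nm) at which the electron tables are considered accurate
Q_VALID_MAX = 250.0

__all__ = [
    "FiveGaussianCoefficients",
    "SpeciesRecord",
    "GroupGeometry",
    "UnknownSpeciesError",
    "lookup_species",
    "tabulated_symbols",
    "electron_form_factor",
    "xray_form_factor",
    "mott_bethe_form_factor",
    "debye_intensity",
    "fit_five_gaussian",
]


class UnknownSpeciesError(KeyError):
    """Raised when a symbol is not present in the embedded tables."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"species not tabulated: {self.symbol!r}"


@dataclass(frozen=True)
class FiveGaussianCoefficients:
    """Five (a_j, b_j) pairs; a in table-native units, b in Angstrom^2."""

    a: tuple[float, float, float, float, float]
    b: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 5:
            raise ValueError("exactly five (a, b) pairs required")

    def __call__(self, q):
        """Evaluate the five-Gaussian form factor at q (1/nm)."""
        q = np.asarray(q, dtype=float)
        s2 = (q / (40.0 * np.pi)) ** 2
        out = np.zeros_like(s2)
        for aj, bj in zip(self.a, self.b):
            out += aj * np.exp(-bj * s2)
        return out if out.ndim else float(out)

    @property
    def f0(self) -> float:
        """f(0) = sum of amplitudes."""
        return float(sum(self.a))


@dataclass(frozen=True)
class SpeciesRecord:
    """Immutable per-species record from the embedded tables."""

    symbol: str
    atomic_number: int
    electron_coeffs: FiveGaussianCoefficients
    xray_coeffs: FiveGaussianCoefficients | None
    radius: float          # nm
    mass: float            # amu
    constituents: tuple[str, ...] = ()   # empty for plain elements
    derived: bool = False  # True if the electron row is Mott-Bethe-derived

    @property
    def excluded_volume(self) -> float:
        """V = (4/3) pi r^3 in nm^3."""
        return 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def is_group(self) -> bool:
        return bool(self.constituents)


def _read_ff_table(name: str) -> pd.DataFrame:
    return pd.read_csv(_DATA_DIR / name, sep="\t", comment="#")


def _load_tables() -> dict[str, SpeciesRecord]:
    props = _read_ff_table("species_props.tsv").set_index("symbol")
    xray = _read_ff_table("xray_ff.tsv").set_index("symbol")

    def coeffs(row) -> FiveGaussianCoefficients:
        return FiveGaussianCoefficients(
            tuple(float(row[f"a{i}"]) for i in range(1, 6)),
            tuple(float(row[f"b{i}"]) for i in range(1, 6)),
        )

    records: dict[str, SpeciesRecord] = {}
    for name, derived in (("electron_ff.tsv", False),
                          ("electron_ff_derived.tsv", True)):
        for _, row in _read_ff_table(name).iterrows():
            sym = str(row["symbol"])
            p = props.loc[sym]
            cons = () if p["constituents"] == "-" else tuple(
                p["constituents"].split(","))
            xc = coeffs(xray.loc[sym]) if sym in xray.index else None
            records[sym] = SpeciesRecord(
                symbol=sym,
                atomic_number=int(row["Z"]),
                electron_coeffs=coeffs(row),
                xray_coeffs=xc,
                radius=float(p["radius_nm"]),
                mass=float(p["mass"]),
                constituents=cons,
                derived=derived,
            )
    return records


_RECORDS: dict[str, SpeciesRecord] = _load_tables()
# case-insensitive lookup maps; elements take precedence over groups
_ELEMENTS = {s.upper(): s for s, r in _RECORDS.items() if not r.is_group}
_GROUPS = {s.upper(): s for s, r in _RECORDS.items() if r.is_group}


def tabulated_symbols() -> list[str]:
    """All species symbols available for lookup."""
    return sorted(_RECORDS)


def lookup_species(symbol: str) -> SpeciesRecord:
    """Return the immutable record for an element or atomic-group symbol.

    Matching is case-insensitive after stripping whitespace; element
    symbols take precedence over group symbols on collision.
    """
    key = str(symbol).strip().upper()
    canonical = _ELEMENTS.get(key) or _GROUPS.get(key)
    if canonical is None:
        raise UnknownSpeciesError(str(symbol).strip())
    return _RECORDS[canonical]


def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    if np.any(q > Q_VALID_MAX):
        warnings.warn(
            f"form factor evaluated beyond its validity range "
            f"(q > {Q_VALID_MAX:g} 1/nm)", stacklevel=3)
    return q


def electron_form_factor(symbol: str, q):
    """Electron form factor (Angstrom) of a species at q (1/nm)."""
    rec = lookup_species(symbol)
    return rec.electron_coeffs(_check_q(q))


def xray_form_factor(symbol: str, q):
    """X-ray form factor (electrons) at q (1/nm).

    Groups carry no X-ray row of their own; their form factor is the sum
    over constituent atoms.
    """
    rec = lookup_species(symbol)
    q = _check_q(q)
    if rec.xray_coeffs is not None:
        return rec.xray_coeffs(q)
    out = np.zeros_like(np.asarray(q, dtype=float))
    for sym in rec.constituents:
        out = out + lookup_species(sym).xray_coeffs(q)
    return out if out.ndim else float(out)


def mott_bethe_form_factor(atomic_number, fx, q, voltage_kv: float | None = None):
    """Electron form factor (Angstrom) from the X-ray one via Mott-Bethe.

    f_e(q) = gamma * (2 / a0) (Z - f_x) / q^2 with q in 1/Angstrom; the
    result shares units with :func:`electron_form_factor`.  By default the
    electron mass is the rest mass (gamma = 1); passing an acceleration
    voltage (kV) applies the relativistic mass.  This is a cross-check
    utility -- the main pipeline evaluates the tabulated parameterization
    directly, which is more accurate.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Mott-Bethe is singular at q = 0; q must be > 0")
    gamma = 1.0
    if voltage_kv is not None:
        gamma = 1.0 + voltage_kv * 1e3 / ELECTRON_REST_ENERGY_EV
    a0_angstrom = CONSTANTS.bohr_radius_nm * 10.0
    q_angstrom = q / 10.0
    out = gamma * (2.0 / a0_angstrom) * (np.asarray(atomic_number, float) - fx) \
        / q_angstrom**2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GroupGeometry:
    """Explicit atomic geometry (symbols + positions in nm)."""

    symbols: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.symbols) == 0:
            raise ValueError("at least one atom required")
        if pos.shape != (len(self.symbols), 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)


def _atoms_of(atoms) -> tuple[list[str], np.ndarray]:
    """Accept a GroupGeometry or any object with .symbols/.positions."""
    return list(atoms.symbols), np.asarray(atoms.positions, dtype=float)


def debye_intensity(atoms, q):
    """Exact orientation-averaged intensity via the Debye formula.

    I(q) = sum_i f_i^2 + sum_{j>i} 2 f_i f_j sinc(q r_ij), with
    sinc(0) = 1.  Works for any atomic model; this is the oracle against
    which all vacuum orientation averages are tested.
    """
    symbols, pos = _atoms_of(atoms)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    n = len(symbols)
    # per-atom form factors, grouped by species for speed
    f = np.empty((n, q.size))
    for sym in set(symbols):
        rec = lookup_species(sym)
        idx = [i for i, s in enumerate(symbols) if s == sym]
        f[idx] = rec.electron_coeffs(q)[None, :]
    intensity = np.sum(f**2, axis=0)
    if n > 1:
        rij = pdist(pos)
        iu, ju = np.triu_indices(n, k=1)
        # np.sinc(x) = sin(pi x)/(pi x)
        sinc = np.sinc(np.outer(rij, q) / np.pi)
        intensity = intensity + 2.0 * np.sum(f[iu] * f[ju] * sinc, axis=0)
    return intensity if np.ndim(q) else float(intensity[0])


class FitConvergenceError(RuntimeError):
    """Five-Gaussian fit failed to converge; carries diagnostics."""


def fit_five_gaussian(geometry, q_max: float = Q_VALID_MAX,
                      n_points: int = 500, seed: int = 0,
                      n_starts: int = 8):
    """Fit a five-Gaussian form factor to sqrt(Debye intensity).

    The fit runs on a uniform q grid [0, q_max] with ``n_points`` samples
    (>= 50).  Amplitudes are solved linearly for trial widths (separable
    least squares); widths are optimized by seeded multi-start
    Nelder-Mead.  Returns ``(FiveGaussianCoefficients, rmse)`` where rmse
    is the root-mean-square residual over the fit grid.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if q_max > Q_VALID_MAX:
        warnings.warn("fitting beyond the validity range of the atomic tables")
    qg = np.linspace(0.0, q_max, n_points)
    y = np.sqrt(debye_intensity(geometry, qg))
    s2 = (qg / (40.0 * np.pi)) ** 2

    def solve_a(bvec):
        design = np.exp(-np.outer(s2, bvec))
        avec, *_ = np.linalg.lstsq(design, y, rcond=None)
        return avec, design @ avec

    def cost(logb):
        _, fitted = solve_a(np.exp(logb))
        return float(np.sqrt(np.mean((fitted - y) ** 2)))

    rng = np.random.default_rng(seed)
    base = np.log([0.3, 1.5, 6.0, 18.0, 50.0])
    best = None
    for trial in range(n_starts):
        x0 = base if trial == 0 else base + rng.normal(0.0, 0.4, 5)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-13})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError(
            f"five-Gaussian fit did not converge after {n_starts} starts "
            f"(best rmse: {None if best is None else best.fun})")
    b = np.exp(best.x)
    a, _ = solve_a(b)
    order = np.argsort(b)
    coeffs = FiveGaussianCoefficients(tuple(a[order]), tuple(b[order]))
    return coeffs, float(best.fun)
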