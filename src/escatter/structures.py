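"""Structure I/O, synthetic fixtures, centering, and ligand swapping.

Real-space models are :class:`AtomicStructure` objects: an ordered list of
sites (position in nm, species symbol).  PDB files (coordinates in
Angstrom) are the interchange format for atomic models; docking lists
(``.dol`` text files) carry per-copy translations and Tait-Bryan rotations
for assembly symmetries.

The PDB element column normally carries an element symbol; this package
additionally accepts atomic-group symbols (CH, NH2, ...) carried in the
atom-name column with element ``X``, which is also how it writes them.

dol file contract (one placement per row, whitespace-separated)::

    index  x_nm  y_nm  z_nm  alpha_deg  beta_deg  gamma_deg

where (alpha, beta, gamma) are intrinsic Tait-Bryan rotations about
x, then y, then z (see :mod:`escatter.hierarchy`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .species import lookup_species

__all__ = [
    "AtomicStructure",
    "DockingList",
    "LigandSwapSpec",
    "read_pdb",
    "write_pdb",
    "read_dol",
    "write_dol",
    "center_structure",
    "make_graphene",
    "make_helix",
    "make_toy",
    "swap_ligand",
]

#: default graphene carbon-carbon bond length, nm
GRAPHENE_BOND_NM = 0.142


@dataclass(frozen=True)
class AtomicStructure:
    """Ordered atomic sites: species symbols and positions in nm."""

    symbols: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    name: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        if pos.shape != (len(self.symbols), 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "symbols", tuple(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def translated(self, shift) -> "AtomicStructure":
        return replace(self, positions=self.positions + np.asarray(shift, float))

    def rotated(self, matrix) -> "AtomicStructure":
        return replace(self, positions=self.positions @ np.asarray(matrix, float).T)

    @property
    def masses(self) -> np.ndarray:
        return np.array([lookup_species(s).mass for s in self.symbols])

    @property
    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.positions).sum(axis=0) / m.sum()

    @property
    def diameter(self) -> float:
        """Largest extent D_max (nm); 0 for a single atom."""
        if len(self) < 2:
            return 0.0
        from scipy.spatial.distance import pdist
        return float(pdist(self.positions).max())


@dataclass(frozen=True)
class DockingList:
    """Ordered placements: translations (nm) and Tait-Bryan angles (deg)."""

    translations: np.ndarray = field(repr=False)
    angles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations, dtype=float))
        a = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if t.size == 0:
            t = t.reshape(0, 3)
        if a.size == 0:
            a = a.reshape(0, 3)
        if t.shape[1] != 3 or a.shape[1] != 3 or t.shape[0] != a.shape[0]:
            raise ValueError("translations and angles must both be (n, 3)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("placements must be finite")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "angles", a)

    def __len__(self) -> int:
        return self.translations.shape[0]


# ---------------------------------------------------------------- PDB I/O

def _species_from_atom(atom: gemmi.Atom, serial: int) -> str:
    el = atom.element.name
    if el not in ("X", "", "D"):
        try:
            return lookup_species(el).symbol
        except KeyError:
            pass
    name = atom.name.strip()
    try:
        return lookup_species(name).symbol
    except KeyError:
        raise ValueError(
            f"atom serial {serial}: cannot resolve species from element "
            f"{el!r} / name {atom.name!r}") from None


def read_pdb(path) -> AtomicStructure:
    """Read ATOM/HETATM records; coordinates are converted Angstrom -> nm.

    Species come from the element column; atoms whose element is ``X`` (or
    missing) fall back to the atom name, which is how atomic-group symbols
    are carried.  Only the first altloc of each site is kept.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()
    symbols: list[str] = []
    coords: list[list[float]] = []
    serial = 0
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    serial += 1
                    symbols.append(_species_from_atom(atom, serial))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not symbols:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return AtomicStructure(tuple(symbols), np.asarray(coords) * 0.1,
                           name=path.stem)


def write_pdb(structure: AtomicStructure, path) -> None:
    """Write an AtomicStructure as HETATM records (nm -> Angstrom)."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    residue = gemmi.Residue()
    residue.name = "MOL"
    residue.seqid = gemmi.SeqId(1, " ")
    residue.het_flag = "H"
    for i, (sym, pos) in enumerate(zip(structure.symbols, structure.positions)):
        atom = gemmi.Atom()
        rec = lookup_species(sym)
        if rec.is_group:
            atom.name = sym
            atom.element = gemmi.Element("X")
        else:
            atom.name = f"{sym}{(i % 999) + 1}"
            atom.element = gemmi.Element(sym)
        atom.pos = gemmi.Position(*(pos * 10.0))
        residue.add_atom(atom)
    chain.add_residue(residue)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------- dol I/O

_DOL_HEADER = (
    "# docking list: index x_nm y_nm z_nm alpha_deg beta_deg gamma_deg\n"
    "# rotations are intrinsic Tait-Bryan about x, then y, then z\n")


def read_dol(path) -> DockingList:
    """Read a docking-list text file (see module docstring for columns)."""
    translations: list[list[float]] = []
    angles: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: row {lineno}: expected 7 fields, got {len(fields)}")
            try:
                values = [float(x) for x in fields]
            except ValueError:
                raise ValueError(
                    f"{path}: row {lineno}: non-numeric field") from None
            translations.append(values[1:4])
            angles.append(values[4:7])
    return DockingList(np.asarray(translations), np.asarray(angles))


def write_dol(docking: DockingList, path) -> None:
    with open(path, "w") as fh:
        fh.write(_DOL_HEADER)
        for i, (t, a) in enumerate(zip(docking.translations, docking.angles)):
            fh.write(f"{i:d} {t[0]:.12g} {t[1]:.12g} {t[2]:.12g} "
                     f"{a[0]:.12g} {a[1]:.12g} {a[2]:.12g}\n")


# ---------------------------------------------------------- transformations

def center_structure(structure: AtomicStructure) -> AtomicStructure:
    """Shift the structure so its center of mass sits at the origin.

    Masses are standard atomic masses; group species weigh the sum of
    their constituents.
    """
    if len(structure) == 0:
        raise ValueError("cannot center an empty structure")
    return structure.translated(-structure.center_of_mass)


# ---------------------------------------------------------------- fixtures

def make_graphene(n1: int, n2: int,
                  layers: tuple[tuple[float, float], ...] = ((0.0, 0.0),),
                  bond: float = GRAPHENE_BOND_NM) -> AtomicStructure:
    """Hexagonal graphene lattice of n1 x n2 unit cells in the xz-plane.

    The beam axis is y; each unit cell holds two carbons.  ``layers`` is a
    sequence of (spacing_nm, twist_deg) pairs, one per monolayer: spacing
    is the gap to the previous layer (ignored for the first) and twist is
    the in-plane rotation about the beam axis.  The lattice is centered on
    the origin in the plane so twists share a common axis.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    a = bond * np.sqrt(3.0)
    a1 = np.array([a, 0.0, 0.0])
    a2 = np.array([a / 2.0, 0.0, a * np.sqrt(3.0) / 2.0])
    basis = [np.zeros(3), (a1 + a2) / 3.0]
    cells = (np.arange(n1)[:, None, None] * a1
             + np.arange(n2)[None, :, None] * a2).reshape(-1, 3)
    mono = np.concatenate([cells + b for b in basis], axis=0)
    mono -= mono.mean(axis=0)  # center in-plane

    coords = []
    y = 0.0
    for i, (spacing, twist) in enumerate(layers):
        if i > 0:
            y += spacing
        t = np.deg2rad(twist)
        rot_y = np.array([[np.cos(t), 0.0, np.sin(t)],
                          [0.0, 1.0, 0.0],
                          [-np.sin(t), 0.0, np.cos(t)]])
        layer = mono @ rot_y.T
        layer[:, 1] += y
        coords.append(layer)
    pos = np.concatenate(coords, axis=0)
    pos[:, 1] -= pos[:, 1].mean()  # center the stack along the beam axis
    return AtomicStructure(("C",) * len(pos), pos, name="graphene")


def make_helix(pitch: float, radius: float, n_start: int = 1,
               handedness: str = "right", n_protofilaments: int = 1,
               subunits_per_protofilament: int = 1) -> DockingList:
    """Docking list for a continuous n-start helical lattice (axis = z).

    Convention: subunit k of protofilament p sits at azimuth
    ``sign * 2 pi p / P`` (sign +1 for right-, -1 for left-handed) at
    height ``k * pitch + p * n_start * pitch / P``.  Each protofilament is
    a vertical stack with axial period equal to the pitch; laterally
    adjacent protofilaments are staggered by ``n_start * pitch / P``, so
    the lattice climbs ``n_start * pitch`` per turn and the subunits lie
    on ``n_start`` interleaved helical strands.  Each placement's rotation
    aligns the subunit with its azimuth (rotation about z).  The lattice
    is centered axially.
    """
    if pitch <= 0 or radius <= 0:
        raise ValueError("pitch and radius must be positive")
    if min(n_start, n_protofilaments, subunits_per_protofilament) < 1:
        raise ValueError("all counts must be >= 1")
    if handedness not in ("right", "left"):
        raise ValueError("handedness must be 'right' or 'left'")
    sign = 1.0 if handedness == "right" else -1.0
    P = n_protofilaments
    stagger = n_start * pitch / P
    translations = []
    angles = []
    for p in range(P):
        phi = sign * 2.0 * np.pi * p / P
        for k in range(subunits_per_protofilament):
            z = k * pitch + p * stagger
            translations.append([radius * np.cos(phi),
                                 radius * np.sin(phi), z])
            angles.append([0.0, 0.0, np.rad2deg(phi)])
    translations = np.asarray(translations)
    translations[:, 2] -= translations[:, 2].mean()
    return DockingList(translations, np.asarray(angles))


def make_toy(n_atoms: int = 10, seed: int = 0,
             species: tuple[str, ...] = ("C", "N", "O"),
             extent: float = 1.0) -> AtomicStructure:
    """Deterministic pseudo-random molecular cluster for tests and demos.

    Atoms are drawn from a seeded generator inside a ball of the given
    extent (nm) with a minimum separation of 0.1 nm; species cycle through
    the given symbols.  Identical parameters always give identical atoms.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    while len(pos) < n_atoms:
        cand = rng.uniform(-extent, extent, 3)
        if np.linalg.norm(cand) > extent:
            continue
        if pos and np.min(np.linalg.norm(np.array(pos) - cand, axis=1)) < 0.1:
            continue
        pos.append(cand)
    symbols = tuple(species[i % len(species)] for i in range(n_atoms))
    return AtomicStructure(symbols, np.array(pos), name=f"toy{n_atoms}")


# ------------------------------------------------------------ ligand swap

@dataclass(frozen=True)
class LigandSwapSpec:
    """Bound-atom indices for ligand replacement.

    The "far" atom of each ligand is the atom most distant from its bound
    atom, ties broken by lowest atom index.
    """

    bound_index_a: int
    bound_index_b: int


def _far_atom(structure: AtomicStructure, bound: int) -> int:
    d = np.linalg.norm(structure.positions - structure.positions[bound], axis=1)
    return int(np.argmax(d))  # first occurrence wins ties


def _rodrigues(vectors: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    return (vectors * cos_t
            + np.cross(np.broadcast_to(axis, vectors.shape), vectors) * sin_t
            + np.outer(vectors @ axis, axis) * (1.0 - cos_t))


def swap_ligand(ligand_a: AtomicStructure, ligand_b: AtomicStructure,
                spec: LigandSwapSpec) -> AtomicStructure:
    """Pose ligand B in place of ligand A (rigid motion only).

    B is shifted so its bound atom is at the origin, rotated (Rodrigues)
    so its bound-to-farthest direction aligns with A's bound-to-farthest
    direction, then translated so its bound atom lands on A's bound-atom
    position.  Intra-ligand distances are preserved exactly.
    """
    for st, idx, tag in ((ligand_a, spec.bound_index_a, "A"),
                         (ligand_b, spec.bound_index_b, "B")):
        if not 0 <= idx < len(st):
            raise IndexError(f"bound atom index {idx} out of range for ligand {tag}")
    bound_a = ligand_a.positions[spec.bound_index_a]
    bound_b = ligand_b.positions[spec.bound_index_b]
    start = ligand_b.positions[_far_atom(ligand_b, spec.bound_index_b)] - bound_b
    end = ligand_a.positions[_far_atom(ligand_a, spec.bound_index_a)] - bound_a
    if np.linalg.norm(start) == 0.0 or np.linalg.norm(end) == 0.0:
        raise ValueError("degenerate ligand: bound and far atoms coincide")

    shifted = ligand_b.positions - bound_b
    u = start / np.linalg.norm(start)
    v = end / np.linalg.norm(end)
    cross = np.cross(u, v)
    sin_t = np.linalg.norm(cross)
    cos_t = float(np.clip(u @ v, -1.0, 1.0))
    if sin_t < 1e-12:
        if cos_t > 0.0:            # already aligned
            rotated = shifted
        else:                      # antiparallel: any axis perpendicular to u
            axis = None
            for canonical in np.eye(3):
                if np.linalg.norm(np.cross(u, canonical)) > 1e-8:
                    axis = np.cross(u, canonical)
                    break
            rotated = _rodrigues(shifted, axis, np.pi)
    else:
        rotated = _rodrigues(shifted, cross / sin_t, np.arccos(cos_t))
    return replace(ligand_b, positions=rotated + bound_a)
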