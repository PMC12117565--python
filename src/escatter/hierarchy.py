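"""Assembly-symmetry trees and the hierarchical amplitude sum.

A supramolecular model is a tree whose leaves are atomic structures,
geometric models, or precomputed reciprocal grids, and whose nodes dock
copies of their child through lists of (rotation, translation)
placements.  The amplitude of a node is

    F(q) = sum_m [ F_child(A_m^-1 q) * sum_k exp(i q . R_{m,k}) ]

summed over the unique orientations A_m, each sharing one translation
phase sum over its K_m translations.

Rotation convention: Tait-Bryan angles (alpha, beta, gamma) in degrees
are intrinsic rotations about x, then y, then z.  Files written by this
package carry the convention in a header comment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .scattering import (GeometricModel, ReciprocalGrid, amplitude_vacuum,
                         build_grid, geometric_amplitude, suggest_parameters)
from .structures import AtomicStructure, DockingList

__all__ = ["tait_bryan", "AssemblyNode", "assembly_amplitude", "flatten"]

#: atom count above which hybrid evaluation pre-grids an atomic leaf
HYBRID_ATOM_THRESHOLD = 400


def tait_bryan(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic x -> y -> z Tait-Bryan angles (deg)."""
    return Rotation.from_euler("XYZ", [alpha, beta, gamma],
                               degrees=True).as_matrix()


def _check_rotations(mats: np.ndarray) -> np.ndarray:
    mats = np.asarray(mats, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    eye = np.eye(3)
    for m in mats:
        if not np.allclose(m.T @ m, eye, atol=1e-10):
            raise ValueError("orientation matrices must be orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-10):
            raise ValueError("orientation matrices must be proper (det = +1)")
    return mats


@dataclass(frozen=True)
class AssemblyNode:
    """Tree node: a child model plus rigid placements of it.

    ``policy`` selects how the child is evaluated at rotated arguments:
    'direct' (re-evaluate at every q), 'grid' (pre-grid the child), or
    'hybrid' (grid atomic leaves above HYBRID_ATOM_THRESHOLD atoms,
    everything else direct).  Grids require ``grid_qmax``; the shell count
    defaults to the suggest_parameters heuristic.
    """

    child: object
    rotations: np.ndarray = field(repr=False)     # (M, 3, 3)
    translations: np.ndarray = field(repr=False)  # (M, 3)
    policy: str = "direct"
    grid_qmax: float | None = None
    grid_shells: int | None = None

    def __post_init__(self) -> None:
        rot = _check_rotations(self.rotations)
        tr = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if len(rot) != len(tr) or tr.shape[1] != 3:
            raise ValueError("rotations and translations must align, (M,3,3)/(M,3)")
        if len(rot) == 0:
            raise ValueError("placements must be non-empty")
        if self.policy not in ("direct", "grid", "hybrid"):
            raise ValueError(f"unknown evaluation policy {self.policy!r}")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "translations", tr)

    @classmethod
    def from_docking_list(cls, child, docking: DockingList, **kw) -> "AssemblyNode":
        rot = np.stack([tait_bryan(*a) for a in docking.angles]) \
            if len(docking) else np.empty((0, 3, 3))
        return cls(child, rot, docking.translations, **kw)

    @classmethod
    def single(cls, child, rotation=None, translation=(0.0, 0.0, 0.0), **kw):
        rot = np.eye(3) if rotation is None else rotation
        return cls(child, rot[None], np.asarray(translation, float)[None], **kw)


def _unique_orientations(rotations: np.ndarray):
    """Group placement indices by orientation (1e-9 on matrix entries)."""
    keys = np.round(rotations / 1e-9).astype(np.int64).reshape(len(rotations), -1)
    groups: dict[bytes, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key.tobytes(), []).append(i)
    return [(rotations[idx[0]], idx) for idx in groups.values()]


def _child_source(node: AssemblyNode):
    """Resolve the child into a callable amplitude source per policy."""
    child = node.child
    if isinstance(child, ReciprocalGrid):
        return child
    if isinstance(child, AssemblyNode):
        base = lambda qvec: assembly_amplitude(child, qvec)  # noqa: E731
    elif isinstance(child, AtomicStructure):
        base = lambda qvec: amplitude_vacuum(child, qvec)  # noqa: E731
    elif isinstance(child, GeometricModel):
        base = lambda qvec: geometric_amplitude(child, qvec)  # noqa: E731
    elif callable(child):
        base = child
    else:
        raise TypeError(f"cannot evaluate assembly child of type {type(child)}")

    use_grid = node.policy == "grid" or (
        node.policy == "hybrid"
        and isinstance(child, AtomicStructure)
        and len(child) > HYBRID_ATOM_THRESHOLD)
    if not use_grid:
        return base
    if node.grid_qmax is None:
        raise ValueError("grid/hybrid policy needs grid_qmax on the node")
    shells = node.grid_shells
    if shells is None:
        if isinstance(child, AtomicStructure):
            shells = suggest_parameters(child, node.grid_qmax).n_shells
        else:
            shells = 64
    return build_grid(base, node.grid_qmax, shells)


def assembly_amplitude(node: AssemblyNode, qvec):
    """Hierarchical amplitude of an assembly tree at one or many q."""
    q = np.asarray(qvec, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    source = _child_source(node)
    out = np.zeros(len(q), dtype=complex)
    for rot, idx in _unique_orientations(node.rotations):
        child_vals = source(q @ rot)  # rows q_i^T A  ==  (A^-1 q_i)^T
        phases = np.exp(1j * q @ node.translations[idx].T).sum(axis=1)
        out += child_vals * phases
    return out[0] if single else out


def flatten(node: AssemblyNode) -> AtomicStructure:
    """Expand an all-atomic tree into one explicit structure.

    Applies each placement's rigid motion (rotate, then translate) to the
    child's atoms, recursively.  This is the test oracle for
    assembly_amplitude: the flattened structure fed to amplitude_vacuum
    must agree with the hierarchical sum.
    """
    child = node.child
    if isinstance(child, AssemblyNode):
        child = flatten(child)
    if not isinstance(child, AtomicStructure):
        raise TypeError("cannot flatten: leaves must be atomic structures")
    symbols: list[str] = []
    coords: list[np.ndarray] = []
    for rot, tr in zip(node.rotations, node.translations):
        symbols.extend(child.symbols)
        coords.append(child.positions @ rot.T + tr)
    return AtomicStructure(tuple(symbols), np.concatenate(coords, axis=0))
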