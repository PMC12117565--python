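"""Complex scattering amplitudes and the reciprocal-space grid.

Amplitude conventions
---------------------
Every amplitude source in this package is a callable mapping an array of
scattering vectors ``qvec`` of shape (n, 3) (components in 1/nm) to a
complex array of shape (n,).  The vacuum amplitude of an atomic model is

    F(q) = sum_j f_j(|q|) exp(i q . r_j)

with f_j the tabulated electron form factor (Angstrom) and r_j in nm.

Solvent handling follows two interchangeable routes: Gaussian dummy atoms
(one per atomic site, amplitude phi0 * V_j * exp(-V_m^(2/3) q^2 / 4 pi))
or a voxelized excluded volume; a solvation layer of different contrast is
always represented by voxels.  phi0 is the bulk zero potential as produced
by :func:`escatter.converters.zero_potential`; its product with a volume
in nm^3 shares units with the form factors.

The reciprocal grid samples a source on spherical shells uniform in |q|
with a shared equiangular (theta, phi) layout and evaluates elsewhere by
trilinear interpolation in (|q|, theta, phi); a dense Cartesian layout is
available as a debugging fallback.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .species import lookup_species
from .structures import AtomicStructure

__all__ = [
    "SolventModel",
    "VoxelGrid",
    "GeometricModel",
    "ReciprocalGrid",
    "GridSettings",
    "amplitude_vacuum",
    "atomic_source",
    "c1_factor",
    "dummy_atom_excluded_amplitude",
    "voxelize",
    "voxel_amplitude",
    "solvated_amplitude",
    "solvated_source",
    "geometric_amplitude",
    "geometric_source",
    "build_grid",
    "grid_interpolate",
    "suggest_parameters",
]

_CHUNK = 262144  # q-vectors per evaluation chunk (memory control)


def _as_qvec(qvec) -> tuple[np.ndarray, bool]:
    q = np.asarray(qvec, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[-1] != 3:
        raise ValueError("qvec must have 3 components")
    return q, single


# ------------------------------------------------------------ vacuum

def amplitude_vacuum(structure: AtomicStructure, qvec):
    """Vacuum amplitude of an atomic model at one or many q-vectors."""
    q, single = _as_qvec(qvec)
    out = np.zeros(len(q), dtype=complex)
    qnorm = np.linalg.norm(q, axis=1)
    symbols = structure.symbols
    pos = structure.positions
    for sym in set(symbols):
        rec = lookup_species(sym)
        f = rec.electron_coeffs(qnorm)
        idx = [i for i, s in enumerate(symbols) if s == sym]
        sub = pos[idx]
        for lo in range(0, len(q), max(1, _CHUNK // max(len(sub), 1))):
            hi = lo + max(1, _CHUNK // max(len(sub), 1))
            phases = np.exp(1j * q[lo:hi] @ sub.T)
            out[lo:hi] += f[lo:hi] * phases.sum(axis=1)
    return out[0] if single else out


def atomic_source(structure: AtomicStructure):
    """Amplitude source closure for a vacuum atomic model."""
    return lambda qvec: amplitude_vacuum(structure, qvec)


# ------------------------------------------------------------ solvent

@dataclass(frozen=True)
class SolventModel:
    """Excluded-solvent / solvation-layer description.

    phi0 and phi0_layer are zero potentials in the converter's units;
    c1 uniformly adjusts the excluded volume (default 1, warn outside
    (0.95, 1.05)); voxel_size is the voxel edge v in nm; layer_thickness
    in nm; solvent_only drops the molecular term (the 'a' switch).
    """

    method: str = "none"            # none | dummy_atom | voxel
    phi0: float = 0.0
    phi0_layer: float | None = None  # None: same as bulk (no layer contrast)
    c1: float = 1.0
    voxel_size: float = 0.2
    layer_thickness: float = 0.0
    solvent_only: bool = False

    @property
    def layer_contrast(self) -> float:
        """phi0_layer - phi0; zero when no layer is configured."""
        return 0.0 if self.phi0_layer is None else self.phi0_layer - self.phi0

    def __post_init__(self) -> None:
        if self.method not in ("none", "dummy_atom", "voxel"):
            raise ValueError(f"unknown solvent method {self.method!r}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.95 < self.c1 < 1.05:
            warnings.warn("c1 outside the (0.95, 1.05) band; the excluded-"
                          "volume adjustment is meant to vary by <5%")


def c1_factor(q, c1: float, mean_volume: float):
    """Excluded-volume adjustment C1(q) = c1^3 exp[-V_m^(2/3) q^2 (c1^2-1)/(4 pi)]."""
    if mean_volume <= 0:
        raise ValueError("mean atomic volume must be positive")
    q = np.asarray(q, dtype=float)
    out = c1**3 * np.exp(-mean_volume ** (2.0 / 3.0) * q**2
                         * (c1**2 - 1.0) / (4.0 * np.pi))
    return out if out.ndim else float(out)


def _volumes(structure: AtomicStructure) -> np.ndarray:
    return np.array([lookup_species(s).excluded_volume for s in structure.symbols])


def dummy_atom_excluded_amplitude(structure: AtomicStructure,
                                  solvent: SolventModel, qvec):
    """Phase-summed Gaussian dummy-atom excluded-solvent term.

    Returns C1(q) * sum_j phi0 V_j exp(-V_m^(2/3) q^2 / 4 pi) e^{i q.r_j},
    i.e. the full excluded-solvent subtrahend of the in-solution
    amplitude.  V_m is the mean excluded volume over the atoms present
    (explicit hydrogens or group symbols only; no implicit hydrogens).
    """
    q, single = _as_qvec(qvec)
    qnorm = np.linalg.norm(q, axis=1)
    volumes = _volumes(structure)
    vm = volumes.mean()
    gauss = np.exp(-vm ** (2.0 / 3.0) * qnorm**2 / (4.0 * np.pi))
    phases = np.exp(1j * q @ structure.positions.T)
    out = (c1_factor(qnorm, solvent.c1, vm) * solvent.phi0 * gauss
           * (phases @ volumes))
    return out[0] if single else out


# ------------------------------------------------------------ voxels

@dataclass(frozen=True)
class VoxelGrid:
    """Regular-lattice voxel classification of a structure's volume."""

    voxel_size: tuple[float, float, float]
    excluded_centers: np.ndarray = field(repr=False)
    layer_centers: np.ndarray = field(repr=False)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def excluded_volume(self) -> float:
        return self.voxel_volume * len(self.excluded_centers)


def voxelize(structure: AtomicStructure, solvent: SolventModel) -> VoxelGrid:
    """Classify space around the structure into excluded / layer voxels.

    A voxel is excluded iff its center lies within the tabulated species
    radius of any atom; solvation-layer voxels are non-excluded voxels
    whose center lies within ``layer_thickness`` of an excluded-voxel
    center (lattice distance transform).  Convergent as voxel_size -> 0.
    """
    v = solvent.voxel_size
    empty = np.zeros((0, 3))
    if len(structure) == 0:
        return VoxelGrid((v, v, v), empty, empty)
    radii = np.array([lookup_species(s).radius for s in structure.symbols])
    pos = structure.positions
    margin = radii.max() + solvent.layer_thickness + v
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    ns = np.ceil((hi - lo) / v).astype(int) + 1
    axes = [lo[d] + v * (np.arange(ns[d]) + 0.5) for d in range(3)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    centers = mesh.reshape(-1, 3)

    excluded = np.zeros(len(centers), dtype=bool)
    for r in np.unique(radii):
        tree = cKDTree(pos[radii == r])
        d, _ = tree.query(centers, distance_upper_bound=r + 1e-12)
        excluded |= np.isfinite(d)

    if solvent.layer_thickness > 0 and excluded.any():
        from scipy.ndimage import distance_transform_edt
        mask = excluded.reshape(ns)
        dist = distance_transform_edt(~mask, sampling=(v, v, v))
        layer = (~mask) & (dist <= solvent.layer_thickness + 1e-12)
        layer_centers = centers[layer.reshape(-1)]
    else:
        layer_centers = empty
    return VoxelGrid((v, v, v), centers[excluded], layer_centers)


def voxel_amplitude(grid: VoxelGrid, which: str, qvec):
    """Amplitude of the excluded or solvation-layer voxel set.

    F(q) = f_voxel(q) sum_j e^{i q . r_j} with the separable single-voxel
    factor f_voxel = prod_i sin(q_i d_i / 2) / (q_i / 2), which tends to
    the voxel volume as q -> 0.
    """
    if which not in ("excluded", "layer"):
        raise ValueError("which must be 'excluded' or 'layer'")
    centers = (grid.excluded_centers if which == "excluded"
               else grid.layer_centers)
    q, single = _as_qvec(qvec)
    dims = np.asarray(grid.voxel_size)
    # d * sinc(q d / (2 pi)) == sin(q d / 2) / (q / 2), finite at q = 0
    f_voxel = np.prod(dims * np.sinc(q * dims / (2.0 * np.pi)), axis=1)
    if len(centers) == 0:
        out = np.zeros(len(q), dtype=complex)
    else:
        out = f_voxel * np.exp(1j * q @ centers.T).sum(axis=1)
    return out[0] if single else out


# ------------------------------------------------------------ solvated

def solvated_amplitude(structure: AtomicStructure, solvent: SolventModel,
                       qvec, voxel_grid: VoxelGrid | None = None):
    """Amplitude of the solvated molecule.

    a * F_mol - phi0 * (excluded term) + (phi0_layer - phi0) * F_layer,
    with the excluded term by the configured method and a = 0 when
    solvent_only.  A voxel grid is built on demand when the method or a
    non-trivial layer needs one (pass ``voxel_grid`` to reuse).
    """
    q, single = _as_qvec(qvec)
    a = 0.0 if solvent.solvent_only else 1.0
    out = np.zeros(len(q), dtype=complex)
    if a != 0.0:
        out += amplitude_vacuum(structure, q)

    layer_contrast = solvent.layer_contrast
    needs_voxels = (solvent.method == "voxel"
                    or (layer_contrast != 0.0))
    if solvent.method == "none" and layer_contrast == 0.0:
        return out[0] if single else out

    if needs_voxels and voxel_grid is None:
        if layer_contrast != 0.0 and solvent.layer_thickness <= 0.0:
            raise ValueError(
                "solvation-layer contrast requested but layer_thickness is 0 "
                "and no voxel grid was supplied")
        voxel_grid = voxelize(structure, solvent)

    if solvent.method == "dummy_atom":
        out -= dummy_atom_excluded_amplitude(structure, solvent, q)
    elif solvent.method == "voxel":
        out -= solvent.phi0 * voxel_amplitude(voxel_grid, "excluded", q)

    if layer_contrast != 0.0:
        out += layer_contrast * voxel_amplitude(voxel_grid, "layer", q)
    return out[0] if single else out


def solvated_source(structure: AtomicStructure, solvent: SolventModel):
    """Amplitude source closure with the voxel grid built once."""
    grid = None
    layer_contrast = solvent.layer_contrast
    if solvent.method == "voxel" or layer_contrast != 0.0:
        if layer_contrast != 0.0 and solvent.layer_thickness <= 0.0:
            raise ValueError(
                "solvation-layer contrast requested but layer_thickness is 0")
        grid = voxelize(structure, solvent)
    return lambda qvec: solvated_amplitude(structure, solvent, qvec,
                                           voxel_grid=grid)


# ------------------------------------------------------------ geometric

@dataclass(frozen=True)
class GeometricModel:
    """Uniform sphere or core-shell sphere with zero-potential contrast.

    ``radii`` strictly increasing (nm); ``contrasts`` one per region, in
    the same units as phi0 (region contrast relative to the surroundings
    is handled by superposition).
    """

    radii: tuple[float, ...]
    contrasts: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if len(r) == 0 or len(r) != len(self.contrasts):
            raise ValueError("radii and contrasts must match and be non-empty")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")

    @classmethod
    def sphere(cls, radius: float, contrast: float) -> "GeometricModel":
        return cls((radius,), (contrast,))

    @classmethod
    def core_shell(cls, core_radius: float, shell_radius: float,
                   core_contrast: float, shell_contrast: float) -> "GeometricModel":
        return cls((core_radius, shell_radius), (core_contrast, shell_contrast))


def _sphere_amp(qnorm: np.ndarray, radius: float) -> np.ndarray:
    """4 pi (sin qR - qR cos qR) / q^3, -> (4/3) pi R^3 as q -> 0."""
    x = qnorm * radius
    out = np.empty_like(x)
    small = x < 1e-4
    out[small] = (4.0 / 3.0) * np.pi * radius**3 * (1.0 - x[small] ** 2 / 10.0)
    xs = x[~small]
    out[~small] = 4.0 * np.pi * (np.sin(xs) - xs * np.cos(xs)) / (qnorm[~small] ** 3)
    return out


def geometric_amplitude(model: GeometricModel, qvec):
    """Closed-form amplitude of a (core-shell) sphere; real-valued."""
    q, single = _as_qvec(qvec)
    qnorm = np.linalg.norm(q, axis=1)
    contrasts = list(model.contrasts) + [0.0]
    out = np.zeros(len(q), dtype=complex)
    for i, radius in enumerate(model.radii):
        step = contrasts[i] - contrasts[i + 1]
        if step != 0.0:
            out += step * _sphere_amp(qnorm, radius)
    return out[0] if single else out


def geometric_source(model: GeometricModel):
    return lambda qvec: geometric_amplitude(model, qvec)


# ------------------------------------------------------------ grids

class GridRangeError(ValueError):
    """Interpolation requested beyond the grid's qmax."""


@dataclass(frozen=True)
class ReciprocalGrid:
    """Sampled complex amplitude over the ball |q| <= qmax.

    Spherical layout: shells uniform in |q| (spacing qmax / n_shells) with
    a shared equiangular angular grid (theta x phi, phi periodic), sized
    with the shell count; evaluation is trilinear in (|q|, theta, phi).
    Cartesian layout: dense regular grid over the bounding cube (debug
    fallback).
    """

    qmax: float
    n_shells: int
    layout: str
    values: np.ndarray = field(repr=False)       # spherical: (n_shells+1, T, M)
    theta: np.ndarray = field(repr=False)        # (T,)   polar angles
    phi: np.ndarray = field(repr=False)          # (M,)   azimuths
    axis: np.ndarray = field(repr=False)         # cartesian axis samples

    def __call__(self, qvec):
        return grid_interpolate(self, qvec)


def _spherical_nodes(qmax: float, n_shells: int, angular_oversampling: float):
    # phase variation per angular step at the rim matches the radial one
    # when n_theta ~ pi/2 * n_shells; oversampling scales both directions
    n_theta = max(9, int(np.ceil(angular_oversampling * n_shells)) + 1)
    n_phi = max(16, 2 * (n_theta - 1))
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    r = np.linspace(0.0, qmax, n_shells + 1)
    return r, theta, phi


def build_grid(source, qmax: float, n_shells: int,
               layout: str = "spherical",
               angular_oversampling: float = 1.6) -> ReciprocalGrid:
    """Sample an amplitude source on a reciprocal grid.

    ``source`` is any callable mapping (n, 3) q-vectors to complex
    amplitudes (atomic, solvated, geometric, or a nested assembly).
    """
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    if qmax <= 0:
        raise ValueError("qmax must be positive")
    if layout == "spherical":
        r, theta, phi = _spherical_nodes(qmax, n_shells, angular_oversampling)
        st, ct = np.sin(theta), np.cos(theta)
        # nodes: (r, theta, phi) -> cartesian, z along the polar axis
        rr, tt, pp = np.meshgrid(r, np.arange(theta.size),
                                 np.arange(phi.size), indexing="ij")
        x = rr * st[tt] * np.cos(phi[pp])
        y = rr * st[tt] * np.sin(phi[pp])
        z = rr * ct[tt]
        nodes = np.stack([x, y, z], axis=-1).reshape(-1, 3)
        vals = source(nodes).reshape(r.size, theta.size, phi.size)
        return ReciprocalGrid(qmax=qmax, n_shells=n_shells, layout="spherical",
                              values=vals, theta=theta, phi=phi,
                              axis=np.empty(0))
    if layout == "cartesian":
        n_axis = 2 * n_shells + 1
        axis = np.linspace(-qmax, qmax, n_axis)
        mesh = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
        vals = source(mesh.reshape(-1, 3)).reshape(n_axis, n_axis, n_axis)
        return ReciprocalGrid(qmax=qmax, n_shells=n_shells, layout="cartesian",
                              values=vals, theta=np.empty(0), phi=np.empty(0),
                              axis=axis)
    raise ValueError(f"unknown grid layout {layout!r}")


def grid_interpolate(grid: ReciprocalGrid, qvec):
    """Evaluate a grid at arbitrary q-vectors inside |q| <= qmax."""
    q, single = _as_qvec(qvec)
    qnorm = np.linalg.norm(q, axis=1)
    if np.any(qnorm > grid.qmax * (1.0 + 1e-9)):
        raise GridRangeError(
            f"|q| = {qnorm.max():.6g} exceeds grid qmax = {grid.qmax:.6g}")

    if grid.layout == "cartesian":
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator(
            (grid.axis,) * 3, grid.values, method="linear")
        out = interp(np.clip(q, grid.axis[0], grid.axis[-1]))
        return out[0] if single else out

    dr = grid.qmax / grid.n_shells
    theta, phi = grid.theta, grid.phi
    dth = theta[1] - theta[0]
    dph = phi[1] - phi[0]

    with np.errstate(invalid="ignore"):
        th = np.arccos(np.clip(np.divide(q[:, 2], qnorm,
                                         out=np.zeros_like(qnorm),
                                         where=qnorm > 0), -1.0, 1.0))
    ph = np.mod(np.arctan2(q[:, 1], q[:, 0]), 2.0 * np.pi)

    def axis_weights(x, step, nmax):
        i = np.floor(x / step + 1e-9).astype(int)
        i = np.clip(i, 0, nmax - 1)
        w = x / step - i
        return i, np.clip(w, 0.0, 1.0)

    ir, wr = axis_weights(qnorm, dr, grid.n_shells)
    it, wt = axis_weights(th, dth, theta.size - 1)
    ip = np.floor(ph / dph + 1e-9).astype(int) % phi.size
    wp = np.clip(ph / dph - np.floor(ph / dph + 1e-9), 0.0, 1.0)
    ip1 = (ip + 1) % phi.size

    v = grid.values
    out = np.zeros(len(q), dtype=complex)
    for dr_i, wgt_r in ((0, 1.0 - wr), (1, wr)):
        for dt_i, wgt_t in ((0, 1.0 - wt), (1, wt)):
            for ip_i, wgt_p in ((ip, 1.0 - wp), (ip1, wp)):
                out += (wgt_r * wgt_t * wgt_p
                        * v[ir + dr_i, it + dt_i, ip_i])
    return out[0] if single else out


@dataclass(frozen=True)
class GridSettings:
    """Suggested computational parameters for a structure."""

    n_shells: int
    n_orientation_samples: int


#: declared grid-pipeline tolerance: max |interpolated - direct| over random
#: q-vectors, relative to the RMS amplitude, at suggested settings
GRID_RELATIVE_TOLERANCE = 0.10


def suggest_parameters(structure: AtomicStructure, qmax: float,
                       margin: int = 8) -> GridSettings:
    """Nyquist-style heuristic for grid density.

    The amplitude of a structure of diameter D oscillates on a reciprocal
    scale ~ 2 pi / D; shells are placed at three times that density
    (n_shells = 3 ceil(qmax D / pi) + margin) so that the trilinear
    interpolation meets GRID_RELATIVE_TOLERANCE.  Deterministic.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    d_max = structure.diameter
    n_shells = 3 * int(np.ceil(qmax * d_max / np.pi)) + margin
    n_orient = max(1000, n_shells**2)
    return GridSettings(n_shells=n_shells, n_orientation_samples=n_orient)
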