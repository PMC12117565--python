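"""Lennard-Jones Metropolis Monte Carlo and ensemble-averaged intensities.

Atoms interact through the pair potential

    V(r) = 4 eps [ (sigma_ev / r)^12 - (sigma_ev / r)^6 ]

with eps in eV and the excluded-volume length sigma_ev in nm; the
minimum sits at r = 2^(1/6) sigma_ev with depth -eps.  Sampling is
single-atom Metropolis at temperature T with acceptance
min(1, exp(-dE / kB T)); after an equilibration phase (during which the
step size adapts toward ~40% acceptance, then freezes) configurations
are retained at a fixed interval until the requested count.  Everything
is reproducible from the seed.

The ensemble intensity mirrors the nanoparticle protocol: per retained
configuration the atomic amplitude is computed (optionally plus a static
amplitude, e.g. rigid ligands) and the resulting intensities are
averaged with equal weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import CONSTANTS
from .intensity import Curve1D, Pattern2D, crystal_pattern, orientation_average
from .scattering import amplitude_vacuum
from .structures import AtomicStructure

__all__ = ["LJConfig", "Ensemble", "lj_energy", "run_mc",
           "ensemble_intensity", "kbt_to_ev"]


def kbt_to_ev(n_kbt: float, temperature: float) -> float:
    """Convert an energy in units of kB*T at the given temperature to eV."""
    return n_kbt * CONSTANTS.boltzmann * temperature


@dataclass(frozen=True)
class LJConfig:
    """Simulation parameters for the LJ Metropolis sampler."""

    epsilon: float              # well depth, eV
    sigma_ev: float             # excluded-volume length, nm
    temperature: float = 298.0  # K
    steps: int = 10000          # production moves (after equilibration)
    max_step: float = 0.02      # initial max displacement, nm
    equilibration: int = 2000   # equilibration moves
    sampling_interval: int = 50 # moves between retained configurations
    n_retain: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epsilon, self.sigma_ev, self.temperature) <= 0:
            raise ValueError("epsilon, sigma_ev, temperature must be positive")
        if self.n_retain * self.sampling_interval > self.steps:
            raise ValueError("steps too few to retain n_retain configurations "
                             "at the requested sampling interval")


@dataclass(frozen=True)
class Ensemble:
    """Retained configurations with energies and acceptance statistics."""

    configurations: tuple[AtomicStructure, ...]
    energies: np.ndarray = field(repr=False)
    acceptance_rate: float = 0.0
    final_step: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("ensemble must be non-empty")
        n = len(self.configurations[0])
        if any(len(c) != n for c in self.configurations):
            raise ValueError("all configurations must share the atom count")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")


def lj_energy(positions, epsilon: float, sigma_ev: float) -> float:
    """Total Lennard-Jones energy (eV) over unique pairs."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 2:
        return 0.0
    r = pdist(positions)
    if np.any(r <= 0.0):
        raise ValueError("coincident atoms: LJ energy diverges")
    x6 = (sigma_ev / r) ** 6
    return float(4.0 * epsilon * np.sum(x6 * x6 - x6))


def _atom_energy(positions: np.ndarray, i: int, pos_i: np.ndarray,
                 epsilon: float, sigma_ev: float) -> float:
    d = np.linalg.norm(positions - pos_i, axis=1)
    d = np.delete(d, i)
    if np.any(d <= 0.0):
        return np.inf
    x6 = (sigma_ev / d) ** 6
    return float(4.0 * epsilon * np.sum(x6 * x6 - x6))


def run_mc(start: AtomicStructure, cfg: LJConfig) -> Ensemble:
    """Metropolis sampling of the LJ system from a starting structure.

    Single-atom uniform-cube displacements; during equilibration the step
    size adapts toward ~40% acceptance (factor 1.1 up/down every 50
    moves), then freezes.  Raises a diagnostic error if a long window
    passes with zero accepted moves.
    """
    if len(start) < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(cfg.seed)
    pos = start.positions.copy()
    n = len(pos)
    beta = 1.0 / (CONSTANTS.boltzmann * cfg.temperature)
    energy = lj_energy(pos, cfg.epsilon, cfg.sigma_ev)
    step = cfg.max_step

    retained: list[AtomicStructure] = []
    energies: list[float] = []
    accepted = attempted = 0
    window_accepted = 0
    since_last_accept = 0

    total = cfg.equilibration + cfg.steps
    for move in range(total):
        i = int(rng.integers(n))
        trial = pos[i] + rng.uniform(-step, step, 3)
        old = _atom_energy(pos, i, pos[i], cfg.epsilon, cfg.sigma_ev)
        new = _atom_energy(pos, i, trial, cfg.epsilon, cfg.sigma_ev)
        delta = new - old
        if delta <= 0.0 or rng.random() < np.exp(-beta * delta):
            pos[i] = trial
            energy += delta
            accepted += 1
            window_accepted += 1
            since_last_accept = 0
        else:
            since_last_accept += 1
        attempted += 1
        if since_last_accept >= 5000:
            raise RuntimeError(
                "no accepted moves in 5000 attempts; try a smaller max_step "
                f"(current {step:.3g} nm) or a higher temperature")

        in_equilibration = move < cfg.equilibration
        if in_equilibration and (move + 1) % 50 == 0:
            rate = window_accepted / 50.0
            step *= 1.1 if rate > 0.4 else 1.0 / 1.1
            window_accepted = 0

        if not in_equilibration:
            prod_move = move - cfg.equilibration + 1
            if (prod_move % cfg.sampling_interval == 0
                    and len(retained) < cfg.n_retain):
                retained.append(replace(start, positions=pos.copy()))
                # recompute occasionally to stop drift of the running sum
                energy = lj_energy(pos, cfg.epsilon, cfg.sigma_ev)
                energies.append(energy)

    if len(retained) < cfg.n_retain:
        raise RuntimeError(
            f"retained only {len(retained)} of {cfg.n_retain} configurations")
    return Ensemble(tuple(retained), np.asarray(energies),
                    acceptance_rate=accepted / attempted,
                    final_step=step, seed=cfg.seed)


def mean_bond_length(ens: Ensemble) -> float:
    """Mean nearest-neighbor distance over the ensemble (nm)."""
    vals = []
    for conf in ens.configurations:
        d = squareform(pdist(conf.positions))
        np.fill_diagonal(d, np.inf)
        vals.append(d.min(axis=1).mean())
    return float(np.mean(vals))


def ensemble_intensity(ens: Ensemble, static_source=None,
                       estimand: str = "1D", q_values=None,
                       n_points: int = 129, qmax: float = 70.0,
                       orientation=(0.0, 0.0),
                       n_samples: int = 2000, seed: int = 0):
    """Unweighted mean intensity over the retained configurations.

    Per configuration the amplitude is F_config + F_static (the static
    source, e.g. ligands held rigid, may be None) and the intensity is
    computed per the estimand: '1D' solution orientation average on
    ``q_values`` or '2D' single-orientation detector pattern.
    """
    if estimand not in ("1D", "2D"):
        raise ValueError("estimand must be '1D' or '2D'")
    if estimand == "1D" and q_values is None:
        raise ValueError("1D estimand needs q_values")

    def config_source(conf):
        def src(qvec):
            amp = amplitude_vacuum(conf, qvec)
            if static_source is not None:
                amp = amp + static_source(qvec)
            return amp
        return src

    total = None
    for conf in ens.configurations:
        src = config_source(conf)
        if estimand == "1D":
            curve = orientation_average(src, q_values, n_samples=n_samples,
                                        seed=seed)
            part = curve.intensity
        else:
            part = crystal_pattern(src, orientation, n_points, qmax).intensity
        total = part.copy() if total is None else total + part
    mean = total / len(ens.configurations)
    if estimand == "1D":
        return Curve1D(np.atleast_1d(np.asarray(q_values, float)), mean)
    return Pattern2D(qmax, mean)
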