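"""Observable intensities from complex amplitudes.

All operations consume an amplitude *source* (a callable mapping (n, 3)
q-vectors in 1/nm to complex amplitudes: atomic, solvated, geometric,
grid, or assembly) and produce either a 1D curve I(q) or a 2D detector
pattern I(q_perp, q_z).

Detector geometry: the beam runs along y; the detector axes are x
(horizontal, "q_perp") and z (vertical, "q_z"), each sampled on a
uniform [-qmax, qmax] grid with the same number of points, pixel
coordinates taken at pixel centers.  By default the Ewald sphere is
treated as flat (q_y = 0), appropriate for high-energy electrons;
passing a wavelength activates the curved mapping
q_y = sqrt(k^2 - q_x^2 - q_z^2) - k with k = 2 pi / lambda.

Stochastic operations draw orientations from a seeded generator and are
bit-reproducible from (seed, n_samples).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial.transform import Rotation

__all__ = [
    "Curve1D",
    "Pattern2D",
    "AngularDistribution",
    "ResolutionModel",
    "orientation_average",
    "crystal_pattern",
    "fiber_pattern",
    "distribution_intensity",
    "apply_resolution",
    "polydisperse_intensity",
    "azimuthal_integrate",
]


@dataclass(frozen=True)
class Curve1D:
    """1D intensity curve: q (1/nm, ascending), I(q), optional error."""

    q: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)
    error: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if q.shape != i.shape or q.ndim != 1:
            raise ValueError("q and intensity must be matching 1D arrays")
        if np.any(np.diff(q) < 0):
            raise ValueError("q must be ascending")
        if np.any(i[np.isfinite(i)] < -1e-12):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if self.error is not None:
            e = np.asarray(self.error, dtype=float)
            if e.shape != q.shape:
                raise ValueError("error must match q")
            object.__setattr__(self, "error", e)

    def write(self, path, header: str = "") -> None:
        cols = [self.q, self.intensity]
        names = "q_nm^-1 intensity"
        if self.error is not None:
            cols.append(self.error)
            names += " error"
        np.savetxt(path, np.column_stack(cols),
                   header=(header + "\n" if header else "") + names)

    @classmethod
    def read(cls, path) -> "Curve1D":
        data = np.loadtxt(path, ndmin=2)
        err = data[:, 2] if data.shape[1] > 2 else None
        return cls(data[:, 0], data[:, 1], err)


@dataclass(frozen=True)
class Pattern2D:
    """Square detector pattern over (q_perp, q_z) in [-qmax, qmax]^2."""

    qmax: float
    intensity: np.ndarray = field(repr=False)  # (n, n); [i, j] = (q_perp_i, q_z_j)

    def __post_init__(self) -> None:
        m = np.asarray(self.intensity, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("intensity must be a square matrix")
        object.__setattr__(self, "intensity", m)

    @property
    def n_points(self) -> int:
        return self.intensity.shape[0]

    @property
    def axis(self) -> np.ndarray:
        """Pixel-center coordinates shared by both detector axes."""
        return np.linspace(-self.qmax, self.qmax, self.n_points)

    def write(self, path, header: str = "") -> None:
        np.savetxt(path, self.intensity,
                   header=(header + "\n" if header else "")
                   + f"qmax={self.qmax:.9g} n={self.n_points}")


@dataclass(frozen=True)
class AngularDistribution:
    """Orientation distribution for Monte-Carlo intensity estimates.

    kinds: 'uniform_sphere', 'fixed' (mean used as the orientation),
    'gaussian_1d' (polar angle only), 'gaussian_2d' (polar + azimuth),
    'uniform_1d', 'uniform_2d'.  Angles in degrees; mean = (polar,
    azimuth), sigma/range per angle.
    """

    kind: str = "uniform_sphere"
    mean: tuple[float, float] = (0.0, 0.0)
    sigma: tuple[float, float] = (0.0, 0.0)
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = ("uniform_sphere", "fixed", "gaussian_1d", "gaussian_2d",
                 "uniform_1d", "uniform_2d")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be >= 0")

    def rotations(self) -> np.ndarray:
        """Sample rotation matrices (n, 3, 3) from the distribution."""
        rng = np.random.default_rng(self.seed)
        n = self.n_samples
        if self.kind == "uniform_sphere":
            return Rotation.random(n, random_state=rng).as_matrix()
        polar = np.full(n, self.mean[0])
        azim = np.full(n, self.mean[1])
        if self.kind in ("gaussian_1d", "gaussian_2d"):
            polar = rng.normal(self.mean[0], self.sigma[0], n)
            if self.kind == "gaussian_2d":
                azim = rng.normal(self.mean[1], self.sigma[1], n)
        elif self.kind in ("uniform_1d", "uniform_2d"):
            polar = rng.uniform(self.mean[0] - self.sigma[0],
                                self.mean[0] + self.sigma[0], n)
            if self.kind == "uniform_2d":
                azim = rng.uniform(self.mean[1] - self.sigma[1],
                                   self.mean[1] + self.sigma[1], n)
        return Rotation.from_euler(
            "yx", np.column_stack([azim, polar]), degrees=True).as_matrix()


@dataclass(frozen=True)
class ResolutionModel:
    """Gaussian instrument resolution with standard deviation sigma (1/nm)."""

    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# --------------------------------------------------------------- averaging

def _sphere_directions_mc(n: int, rng) -> np.ndarray:
    """Randomized spherical Fibonacci lattice: n near-uniform directions
    rotated by a random rotation.  The stratification makes the actual
    quadrature error much smaller than the i.i.d. standard error the
    estimator reports, which is therefore conservative."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * np.mod(i / golden, 1.0)
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs @ Rotation.random(random_state=rng).as_matrix().T


def _sphere_quadrature(order: int):
    """Gauss-Legendre x uniform-azimuth product rule on the sphere."""
    x, w = np.polynomial.legendre.leggauss(order)
    n_phi = 2 * order
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    st = np.sqrt(1.0 - x**2)
    dirs = np.stack([np.outer(st, np.cos(phi)),
                     np.outer(st, np.sin(phi)),
                     np.repeat(x[:, None], n_phi, axis=1)],
                    axis=-1).reshape(-1, 3)
    weights = np.repeat(w / (2.0 * n_phi), n_phi)
    return dirs, weights


def orientation_average(source, q_values, method: str = "monte_carlo",
                        n_samples: int = 2000, seed: int = 0) -> Curve1D:
    """Solution orientation average I(q) = <|F(q u)|^2> over directions u.

    Monte Carlo reports the standard error of the mean per q; the
    quadrature method uses a Gauss-Legendre x azimuth product rule with
    ``order = ceil(sqrt(n_samples / 2))`` nodes in the polar direction.
    """
    q_values = np.atleast_1d(np.asarray(q_values, dtype=float))
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        dirs = _sphere_directions_mc(n_samples, rng)
        weights = np.full(len(dirs), 1.0 / len(dirs))
    elif method == "sphere_quadrature":
        order = int(np.ceil(np.sqrt(n_samples / 2.0)))
        dirs, weights = _sphere_quadrature(order)
    else:
        raise ValueError("method must be 'monte_carlo' or 'sphere_quadrature'")

    intensity = np.empty(q_values.size)
    stderr = np.empty(q_values.size)
    for i, q in enumerate(q_values):
        amp2 = np.abs(source(dirs * q)) ** 2
        mean = float(weights @ amp2)
        intensity[i] = mean
        if method == "monte_carlo":
            var = float(weights @ (amp2 - mean) ** 2)
            stderr[i] = np.sqrt(var / len(amp2))
        else:
            stderr[i] = 0.0
    return Curve1D(q_values, intensity, stderr)


# --------------------------------------------------------------- 2D maps

def _detector_qvecs(n_points: int, qmax: float,
                    wavelength: float | None) -> np.ndarray:
    axis = np.linspace(-qmax, qmax, n_points)
    qx, qz = np.meshgrid(axis, axis, indexing="ij")
    if wavelength is None:
        qy = np.zeros_like(qx)
    else:
        k = 2.0 * np.pi / wavelength
        rad2 = np.clip(k**2 - qx**2 - qz**2, 0.0, None)
        qy = np.sqrt(rad2) - k
    return np.stack([qx, qy, qz], axis=-1).reshape(-1, 3)


def crystal_pattern(source, orientation: tuple[float, float] = (0.0, 0.0),
                    n_points: int = 129, qmax: float = 70.0,
                    ewald: str = "flat",
                    wavelength: float | None = None) -> Pattern2D:
    """2D pattern of a single fixed orientation (azimuth, polar; degrees).

    The structure is rotated by the azimuth about the beam axis (y) after
    tilting by the polar angle about x; ewald='curved' requires a
    wavelength and puts each pixel on the Ewald sphere.
    """
    if ewald not in ("flat", "curved"):
        raise ValueError("ewald must be 'flat' or 'curved'")
    if ewald == "curved" and wavelength is None:
        raise ValueError("curved Ewald mapping needs a wavelength")
    qvecs = _detector_qvecs(n_points, qmax,
                            wavelength if ewald == "curved" else None)
    azimuth, polar = orientation
    rot = Rotation.from_euler("yx", [azimuth, polar], degrees=True).as_matrix()
    vals = np.abs(source(qvecs @ rot)) ** 2
    return Pattern2D(qmax, vals.reshape(n_points, n_points))


def fiber_pattern(source, n_points: int = 129, qmax: float = 70.0,
                  polar: float = 90.0, n_azimuth: int = 360) -> Pattern2D:
    """Fiber-diffraction pattern: azimuthal average about the fiber axis.

    The fiber axis is z tilted by (90 - polar) degrees about x (polar is
    the angle between axis and beam; the default 90 puts the axis in the
    detector plane).  The average uses deterministic uniform quadrature
    over ``n_azimuth`` sample rotations about the fiber axis.
    """
    axis = np.linspace(-qmax, qmax, n_points)
    qx, qz = np.meshgrid(axis, axis, indexing="ij")
    tilt = Rotation.from_euler("x", 90.0 - polar, degrees=True).as_matrix()
    out = np.zeros(qx.size)
    phis = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    base = np.stack([qx, np.zeros_like(qx), qz], axis=-1).reshape(-1, 3)
    for phi in phis:
        spin = Rotation.from_euler("z", phi).as_matrix()
        qrot = base @ (tilt @ spin)
        out += np.abs(source(qrot)) ** 2
    return Pattern2D(qmax, (out / n_azimuth).reshape(n_points, n_points))


def distribution_intensity(source, dist: AngularDistribution,
                           output: str = "1D", q_values=None,
                           n_points: int = 65, qmax: float = 70.0):
    """Monte-Carlo intensity averaged over an angular distribution.

    output='1D' averages |F|^2 at each |q| over orientations applied to a
    reference direction set; output='2D' averages detector patterns over
    sampled orientations.  Reproducible from the distribution's seed.
    """
    rots = dist.rotations()
    if output == "2D":
        qvecs = _detector_qvecs(n_points, qmax, None)
        out = np.zeros(len(qvecs))
        for rot in rots:
            out += np.abs(source(qvecs @ rot)) ** 2
        return Pattern2D(qmax, (out / len(rots)).reshape(n_points, n_points))
    if output != "1D":
        raise ValueError("output must be '1D' or '2D'")
    if q_values is None:
        raise ValueError("1D output needs q_values")
    q_values = np.atleast_1d(np.asarray(q_values, dtype=float))
    ref = np.array([0.0, 1.0, 0.0])  # beam direction as reference
    dirs = rots @ ref
    intensity = np.empty(q_values.size)
    stderr = np.empty(q_values.size)
    for i, q in enumerate(q_values):
        amp2 = np.abs(source(dirs * q)) ** 2
        intensity[i] = amp2.mean()
        stderr[i] = amp2.std(ddof=1) / np.sqrt(len(amp2)) if len(amp2) > 1 else 0.0
    return Curve1D(q_values, intensity, stderr)


# --------------------------------------------------------------- smoothing

def apply_resolution(data, res: ResolutionModel):
    """Convolve with a Gaussian instrument resolution function.

    1D curves are convolved along q, 2D patterns along both detector
    axes; the kernel is truncated at +-4 sigma and renormalized.
    sigma = 0 returns the input unchanged.
    """
    if res.sigma == 0.0:
        return data
    if isinstance(data, Curve1D):
        dq = np.diff(data.q)
        if dq.size == 0 or not np.allclose(dq, dq[0], rtol=1e-6):
            raise ValueError("resolution smearing needs a uniform q grid")
        if res.sigma > data.q[-1] - data.q[0]:
            warnings.warn("resolution sigma exceeds the data range")
        smooth = gaussian_filter1d(data.intensity, res.sigma / dq[0],
                                   mode="nearest", truncate=4.0)
        return Curve1D(data.q, smooth, data.error)
    if isinstance(data, Pattern2D):
        dq = 2.0 * data.qmax / (data.n_points - 1)
        if res.sigma > 2.0 * data.qmax:
            warnings.warn("resolution sigma exceeds the data range")
        smooth = gaussian_filter(data.intensity, res.sigma / dq,
                                 mode="nearest", truncate=4.0)
        return Pattern2D(data.qmax, smooth)
    raise TypeError("data must be Curve1D or Pattern2D")


def polydisperse_intensity(model_factory, mean: float, sigma_param: float,
                           n: int = 15, span_sigmas: float = 3.0,
                           **intensity_kw) -> Curve1D:
    """Gaussian-weighted intensity average over a model parameter.

    ``model_factory(value)`` must return an intensity Curve1D for the
    parameter value (e.g. a sphere radius).  The parameter is sampled at
    ``n`` equally spaced values spanning mean +- span_sigmas * sigma
    with normalized Gaussian weights; nonphysical samples (where the
    factory raises ValueError) are dropped with a warning and the weights
    renormalized.  sigma_param = 0 returns the monodisperse result.
    """
    if sigma_param < 0:
        raise ValueError("sigma_param must be >= 0")
    if sigma_param == 0.0:
        return model_factory(mean, **intensity_kw)
    values = np.linspace(mean - span_sigmas * sigma_param,
                         mean + span_sigmas * sigma_param, n)
    weights = np.exp(-0.5 * ((values - mean) / sigma_param) ** 2)
    weights /= weights.sum()
    total = None
    kept = 0.0
    for value, weight in zip(values, weights):
        try:
            curve = model_factory(value, **intensity_kw)
        except ValueError as exc:
            warnings.warn(f"dropping nonphysical parameter {value:g}: {exc}")
            continue
        contrib = weight * curve.intensity
        total = contrib if total is None else total + contrib
        kept += weight
        q = curve.q
    if total is None:
        raise ValueError("no physical parameter samples")
    return Curve1D(q, total / kept)


# --------------------------------------------------------------- binning

def azimuthal_integrate(pattern: Pattern2D, n_bins: int) -> Curve1D:
    """Azimuthally integrate a 2D pattern into I(q).

    Each pixel contributes at q = sqrt(q_perp^2 + q_z^2); shells are
    half-open intervals [(i-1) dq, i dq) with dq = qmax / n_bins, and the
    shell intensity is the mean over its pixels.  Empty shells are
    reported as NaN (flagged, not zero-filled).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    axis = pattern.axis
    qp, qz = np.meshgrid(axis, axis, indexing="ij")
    qpix = np.sqrt(qp**2 + qz**2).ravel()
    dq = pattern.qmax / n_bins
    shell = np.floor(qpix / dq).astype(int)
    keep = shell < n_bins
    counts = np.bincount(shell[keep], minlength=n_bins)
    sums = np.bincount(shell[keep], weights=pattern.intensity.ravel()[keep],
                       minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * dq
    return Curve1D(centers, mean)
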