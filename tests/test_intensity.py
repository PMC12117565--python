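"""Intensity estimands: averages, 2D patterns, smearing, binning."""
import numpy as np
import pytest

import escatter as es
from escatter.intensity import (AngularDistribution, Curve1D, Pattern2D,
                                ResolutionModel)


def isotropic_gaussian_source(qvec):
    """Synthetic isotropic amplitude F = exp(-q^2 / 2) (I = exp(-q^2))."""
    q = np.atleast_2d(np.asarray(qvec, float))
    return np.exp(-0.5 * np.linalg.norm(q, axis=1) ** 2).astype(complex)


class TestOrientationAverage:
    def test_single_atom_exact_and_zero_variance(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        q = np.linspace(0.0, 50.0, 6)
        curve = es.orientation_average(es.atomic_source(st), q,
                                       n_samples=100, seed=0)
        assert curve.intensity == pytest.approx(
            es.electron_form_factor("C", q) ** 2)
        assert curve.error == pytest.approx(np.zeros(6), abs=1e-12)

    def test_matches_debye_for_atomic_model(self, toy20):
        q = np.linspace(0.5, 40.0, 12)
        oracle = es.debye_intensity(toy20, q)
        curve = es.orientation_average(es.atomic_source(toy20), q,
                                       n_samples=2000, seed=7)
        assert np.all(np.abs(curve.intensity - oracle) <=
                      3 * np.maximum(curve.error, 1e-12))

    def test_seed_reproducibility(self, toy20):
        q = [5.0, 20.0]
        a = es.orientation_average(es.atomic_source(toy20), q, seed=42)
        b = es.orientation_average(es.atomic_source(toy20), q, seed=42)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.error, b.error)

    def test_quadrature_agrees_with_oracle(self, toy20):
        q = np.linspace(0.5, 30.0, 8)
        curve = es.orientation_average(es.atomic_source(toy20), q,
                                       method="sphere_quadrature",
                                       n_samples=2000)
        oracle = es.debye_intensity(toy20, q)
        assert curve.intensity == pytest.approx(oracle, rel=1e-3)

    def test_too_few_samples_refused(self, toy20):
        with pytest.raises(ValueError):
            es.orientation_average(es.atomic_source(toy20), [1.0], n_samples=5)


class TestCrystalPattern:
    def test_central_pixel_is_f0_squared(self, toy20):
        pat = es.crystal_pattern(es.atomic_source(toy20), n_points=65,
                                 qmax=30.0)
        f0 = sum(es.electron_form_factor(s, 0.0) for s in toy20.symbols)
        center = pat.intensity[32, 32]
        assert center == pytest.approx(f0**2, rel=1e-10)

    def test_flat_ewald_pattern_is_centrosymmetric(self, toy20):
        pat = es.crystal_pattern(es.atomic_source(toy20), n_points=33,
                                 qmax=25.0)
        assert pat.intensity == pytest.approx(pat.intensity[::-1, ::-1],
                                              rel=1e-9)

    def test_graphene_first_order_ring_position(self):
        # six first-order reflections at |q| = 4 pi / (sqrt(3) a); the
        # finite lattice's shape function times the decaying form factor
        # biases the apparent maximum slightly inward, hence 2 pixels
        mono = es.make_graphene(10, 10)
        pat = es.crystal_pattern(es.atomic_source(mono), n_points=201,
                                 qmax=35.0)
        expected = 4 * np.pi / (np.sqrt(3) * np.sqrt(3) * 0.142)
        axis = pat.axis
        qp, qz = np.meshgrid(axis, axis, indexing="ij")
        qabs = np.hypot(qp, qz)
        ring = (qabs > 20.0) & (qabs < 35.0)
        masked = np.where(ring, pat.intensity, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        dq = axis[1] - axis[0]
        assert np.hypot(axis[i], axis[j]) == pytest.approx(expected, abs=2 * dq)

    def test_curved_ewald_needs_wavelength(self, toy20):
        with pytest.raises(ValueError):
            es.crystal_pattern(es.atomic_source(toy20), ewald="curved")


class TestFiberPattern:
    def test_cylindrically_symmetric_source_unchanged(self):
        pat_f = es.fiber_pattern(isotropic_gaussian_source, n_points=33,
                                 qmax=3.0, n_azimuth=16)
        pat_c = es.crystal_pattern(isotropic_gaussian_source, n_points=33,
                                   qmax=3.0)
        assert pat_f.intensity == pytest.approx(pat_c.intensity, rel=1e-9)

    def test_mirror_symmetry_along_qz(self, toy20):
        pat = es.fiber_pattern(es.atomic_source(toy20), n_points=33,
                               qmax=20.0, n_azimuth=24)
        assert pat.intensity == pytest.approx(pat.intensity[:, ::-1], rel=1e-9)

    def test_helix_layer_lines_at_pitch_harmonics(self):
        # helical lattice with pitch 12.214 -> layer lines at n 2 pi / pitch
        pitch = 12.214
        dol = es.make_helix(pitch, 11.9, 3, "left", 14, 16)
        node = es.AssemblyNode.from_docking_list(
            es.AtomicStructure(("C",), [[0, 0, 0]]), dol)
        flat = es.flatten(node)
        pat = es.fiber_pattern(es.atomic_source(flat), n_points=129,
                               qmax=1.3, n_azimuth=60)
        axis = pat.axis
        dq = axis[1] - axis[0]
        profile = pat.intensity.max(axis=0)
        for n in (1, 2):
            expected = n * 2 * np.pi / pitch
            window = (axis > expected - 0.15) & (axis < expected + 0.15)
            peak_q = axis[window][np.argmax(profile[window])]
            assert abs(peak_q - expected) <= dq


class TestDistributionIntensity:
    def test_sigma_zero_matches_fixed_orientation(self, toy20):
        src = es.atomic_source(toy20)
        fixed = AngularDistribution(kind="fixed", mean=(30.0, 50.0),
                                    n_samples=16, seed=1)
        gauss = AngularDistribution(kind="gaussian_2d", mean=(30.0, 50.0),
                                    sigma=(0.0, 0.0), n_samples=16, seed=2)
        q = [5.0, 15.0, 25.0]
        a = es.distribution_intensity(src, fixed, q_values=q)
        b = es.distribution_intensity(src, gauss, q_values=q)
        assert a.intensity == pytest.approx(b.intensity, rel=1e-9)

    def test_uniform_sphere_matches_orientation_average(self, toy20):
        src = es.atomic_source(toy20)
        dist = AngularDistribution(kind="uniform_sphere", n_samples=4000,
                                   seed=3)
        q = np.linspace(1.0, 30.0, 6)
        a = es.distribution_intensity(src, dist, q_values=q)
        oracle = es.debye_intensity(toy20, q)
        assert np.all(np.abs(a.intensity - oracle) <=
                      4 * np.maximum(a.error, 1e-12))

    def test_seed_determinism(self, toy20):
        src = es.atomic_source(toy20)
        dist = AngularDistribution(kind="gaussian_1d", mean=(10.0, 0.0),
                                   sigma=(5.0, 0.0), n_samples=64, seed=9)
        a = es.distribution_intensity(src, dist, q_values=[10.0])
        b = es.distribution_intensity(src, dist, q_values=[10.0])
        assert np.array_equal(a.intensity, b.intensity)

    def test_2d_output_shape(self, toy20):
        dist = AngularDistribution(kind="uniform_sphere", n_samples=8, seed=0)
        pat = es.distribution_intensity(es.atomic_source(toy20), dist,
                                        output="2D", n_points=17, qmax=10.0)
        assert pat.intensity.shape == (17, 17)


class TestApplyResolution:
    def test_sigma_zero_is_identity(self):
        curve = Curve1D(np.linspace(0, 10, 11), np.arange(11.0))
        assert es.apply_resolution(curve, ResolutionModel(0.0)) is curve

    def test_impulse_spreads_and_preserves_sum(self):
        q = np.linspace(0.0, 10.0, 101)
        impulse = np.zeros(101)
        impulse[50] = 1.0
        curve = Curve1D(q, impulse)
        out = es.apply_resolution(curve, ResolutionModel(0.3))
        assert out.intensity.sum() == pytest.approx(1.0, rel=1e-6)
        assert out.intensity[50] < 1.0
        assert out.intensity.max() == out.intensity[50]

    def test_gaussian_semigroup(self):
        q = np.linspace(0.0, 10.0, 201)
        rng = np.random.default_rng(0)
        base = Curve1D(q, rng.uniform(0.5, 2.0, 201))
        twice = es.apply_resolution(
            es.apply_resolution(base, ResolutionModel(0.2)),
            ResolutionModel(0.2))
        once = es.apply_resolution(base, ResolutionModel(0.2 * np.sqrt(2)))
        inner = slice(30, -30)
        assert twice.intensity[inner] == pytest.approx(once.intensity[inner],
                                                       rel=1e-3)

    def test_2d_smoothing_preserves_total(self):
        pat = Pattern2D(5.0, np.pad(np.ones((1, 1)), 20)[None][0])
        out = es.apply_resolution(pat, ResolutionModel(0.4))
        assert out.intensity.sum() == pytest.approx(1.0, rel=1e-6)


class TestPolydispersity:
    @staticmethod
    def _sphere_curve(radius, q=None):
        q = np.linspace(0.0, 10.0, 200) if q is None else q
        gm = es.GeometricModel.sphere(radius, 1.0)
        qv = np.column_stack([q, np.zeros_like(q), np.zeros_like(q)])
        return Curve1D(q, np.abs(es.geometric_amplitude(gm, qv)) ** 2)

    def test_sigma_zero_is_monodisperse(self):
        mono = self._sphere_curve(2.0)
        poly = es.polydisperse_intensity(self._sphere_curve, 2.0, 0.0)
        assert poly.intensity == pytest.approx(mono.intensity)

    def test_smearing_fills_first_minimum(self):
        radius = 2.0
        q_min = 4.4934 / radius  # first amplitude zero of the sphere
        q = np.array([q_min])
        mono = self._sphere_curve(radius, q=q)
        poly = es.polydisperse_intensity(self._sphere_curve, radius, 0.1, q=q)
        assert poly.intensity[0] > mono.intensity[0]

    def test_nonphysical_samples_dropped(self):
        def factory(radius):
            if radius <= 0:
                raise ValueError("negative radius")
            return self._sphere_curve(radius)
        with pytest.warns(UserWarning, match="nonphysical"):
            out = es.polydisperse_intensity(factory, 0.5, 0.3)
        assert np.all(np.isfinite(out.intensity))


class TestAzimuthalIntegration:
    def test_constant_pattern_gives_constant_curve(self):
        pat = Pattern2D(10.0, np.full((41, 41), 3.3))
        curve = es.azimuthal_integrate(pat, 10)
        filled = np.isfinite(curve.intensity)
        assert np.all(curve.intensity[filled] == pytest.approx(3.3))

    def test_shell_mean_arithmetic(self):
        intensity = np.zeros((41, 41))
        intensity[20, 30] = 7.0  # single bright pixel
        pat = Pattern2D(10.0, intensity)
        curve = es.azimuthal_integrate(pat, 10)
        axis = pat.axis
        qpix = np.hypot(axis[20], axis[30])
        shell = int(qpix / (10.0 / 10))
        qp, qz = np.meshgrid(axis, axis, indexing="ij")
        in_shell = (np.floor(np.hypot(qp, qz) / 1.0).astype(int) == shell)
        assert curve.intensity[shell] == pytest.approx(7.0 / in_shell.sum())

    def test_recovers_analytic_isotropic_profile(self):
        pat = es.crystal_pattern(isotropic_gaussian_source, n_points=201,
                                 qmax=3.0)
        curve = es.azimuthal_integrate(pat, 30)
        keep = np.isfinite(curve.intensity) & (curve.q < 2.5)
        assert curve.intensity[keep] == pytest.approx(
            np.exp(-curve.q[keep] ** 2), rel=0.08)

    def test_empty_shells_flagged_nan(self):
        pat = Pattern2D(10.0, np.ones((5, 5)))  # coarse pattern, many bins
        curve = es.azimuthal_integrate(pat, 50)
        assert np.isnan(curve.intensity).any()
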