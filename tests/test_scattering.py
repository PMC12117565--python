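"""Amplitudes: vacuum, solvent models, geometric bodies, reciprocal grids."""
import numpy as np
import pytest

import escatter as es
from escatter.scattering import (GRID_RELATIVE_TOLERANCE, GridRangeError,
                                 SolventModel, dummy_atom_excluded_amplitude,
                                 suggest_parameters, voxel_amplitude, voxelize)

from conftest import random_qvecs


class TestVacuumAmplitude:
    def test_single_atom_is_real_form_factor(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        q = np.array([0.0, 0.0, 17.0])
        amp = es.amplitude_vacuum(st, q)
        assert amp.imag == 0.0
        assert amp.real == pytest.approx(es.electron_form_factor("C", 17.0))

    def test_translation_is_pure_phase(self, toy20, rng):
        shift = np.array([0.3, -0.7, 1.1])
        q = random_qvecs(rng, 50, 40.0)
        a = es.amplitude_vacuum(toy20, q)
        b = es.amplitude_vacuum(toy20.translated(shift), q)
        assert np.abs(b) == pytest.approx(np.abs(a), rel=1e-10)
        assert b == pytest.approx(a * np.exp(1j * q @ shift), rel=1e-10)

    def test_friedel_symmetry(self, toy20, rng):
        q = random_qvecs(rng, 64, 50.0)
        assert es.amplitude_vacuum(toy20, -q) == pytest.approx(
            np.conj(es.amplitude_vacuum(toy20, q)), rel=1e-10)

    def test_orientation_average_matches_debye(self, graphene3x3):
        # <|F|^2> over the sphere at q = 30 equals the Debye intensity
        curve = es.orientation_average(es.atomic_source(graphene3x3), [30.0],
                                       n_samples=4000, seed=11)
        oracle = es.debye_intensity(graphene3x3, [30.0])[0]
        assert abs(curve.intensity[0] - oracle) <= 3 * curve.error[0]


class TestC1Factor:
    def test_unity_when_c1_is_one(self):
        q = np.linspace(0, 100, 11)
        assert es.c1_factor(q, 1.0, 0.01) == pytest.approx(np.ones(11))

    def test_cube_at_zero(self):
        assert es.c1_factor(0.0, 1.04, 0.02) == pytest.approx(1.04**3)

    def test_direct_formula(self):
        c1, vm, q = 1.04, 0.01, 10.0
        expected = c1**3 * np.exp(-vm ** (2 / 3) * q**2 * (c1**2 - 1) / (4 * np.pi))
        assert es.c1_factor(q, c1, vm) == pytest.approx(expected)


class TestDummyAtomSolvent:
    def test_zero_phi0_reduces_to_vacuum(self, toy20, rng):
        sm = SolventModel(method="dummy_atom", phi0=0.0)
        q = random_qvecs(rng, 20, 30.0)
        assert es.solvated_amplitude(toy20, sm, q) == pytest.approx(
            es.amplitude_vacuum(toy20, q))

    def test_single_atom_at_q_zero(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        rec = es.lookup_species("C")
        sm = SolventModel(method="dummy_atom", phi0=10.0)
        amp = es.solvated_amplitude(st, sm, [0.0, 0.0, 0.0])
        assert amp.real == pytest.approx(
            es.electron_form_factor("C", 0.0) - 10.0 * rec.excluded_volume)

    def test_contrast_match_cancels_at_q_zero(self, toy20):
        f0 = sum(es.electron_form_factor(s, 0.0) for s in toy20.symbols)
        v = sum(es.lookup_species(s).excluded_volume for s in toy20.symbols)
        sm = SolventModel(method="dummy_atom", phi0=f0 / v, c1=1.0)
        assert abs(es.solvated_amplitude(toy20, sm, [0.0, 0.0, 0.0])) < 1e-10

    def test_excluded_term_friedel(self, toy20, rng):
        sm = SolventModel(method="dummy_atom", phi0=5.0)
        q = random_qvecs(rng, 32, 40.0)
        term = dummy_atom_excluded_amplitude(toy20, sm, q)
        anti = dummy_atom_excluded_amplitude(toy20, sm, -q)
        assert anti == pytest.approx(np.conj(term), rel=1e-10)


class TestVoxels:
    def test_single_atom_volume_converges(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        exact = es.lookup_species("C").excluded_volume
        errs = []
        for v in (0.05, 0.025):
            grid = voxelize(st, SolventModel(method="voxel", voxel_size=v))
            errs.append(abs(grid.excluded_volume - exact) / exact)
        assert errs[0] < 0.15
        assert errs[1] < errs[0]

    def test_zero_thickness_layer_empty(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        grid = voxelize(st, SolventModel(method="voxel", voxel_size=0.05))
        assert len(grid.layer_centers) == 0

    def test_disjoint_spheres_additive(self):
        sm = SolventModel(method="voxel", voxel_size=0.05)
        one = voxelize(es.AtomicStructure(("C",), [[0, 0, 0]]), sm)
        two = voxelize(es.AtomicStructure(("C", "C"),
                                          [[0, 0, 0], [5.0, 0, 0]]), sm)
        assert len(two.excluded_centers) == 2 * len(one.excluded_centers)

    def test_layer_and_excluded_disjoint(self):
        st = es.make_toy(4, seed=9)
        grid = voxelize(st, SolventModel(method="voxel", voxel_size=0.1,
                                         layer_thickness=0.2))
        excl = {tuple(np.round(c, 9)) for c in grid.excluded_centers}
        layer = {tuple(np.round(c, 9)) for c in grid.layer_centers}
        assert excl and layer and not (excl & layer)

    def test_amplitude_at_q_zero_is_total_volume(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        grid = voxelize(st, SolventModel(method="voxel", voxel_size=0.05))
        amp = voxel_amplitude(grid, "excluded", [0.0, 0.0, 0.0])
        assert amp.real == pytest.approx(grid.excluded_volume)

    def test_single_voxel_separable_zero(self):
        from escatter.scattering import VoxelGrid
        grid = VoxelGrid((0.2, 0.2, 0.2), np.zeros((1, 3)), np.zeros((0, 3)))
        assert abs(voxel_amplitude(grid, "excluded",
                                   [2 * np.pi / 0.2, 0.0, 0.0])) < 1e-15

    def test_dummy_vs_voxel_excluded_match_at_q_zero(self, toy20):
        # both excluded-solvent routes tend to phi0 * excluded volume
        sm = SolventModel(method="voxel", phi0=1.0, voxel_size=0.04)
        grid = voxelize(toy20, sm)
        vox = voxel_amplitude(grid, "excluded", [0.0, 0.0, 0.0]).real
        smd = SolventModel(method="dummy_atom", phi0=1.0)
        dummy = dummy_atom_excluded_amplitude(toy20, smd, [0.0, 0.0, 0.0]).real
        # voxel union <= sum of per-atom volumes (overlaps), discretization
        assert vox == pytest.approx(dummy, rel=0.1)


class TestSolvatedAmplitude:
    def test_none_equals_vacuum(self, toy20, rng):
        q = random_qvecs(rng, 10, 20.0)
        sm = SolventModel(method="none")
        assert es.solvated_amplitude(toy20, sm, q) == pytest.approx(
            es.amplitude_vacuum(toy20, q))

    def test_equal_layer_potential_drops_layer_term(self, toy20, rng):
        q = random_qvecs(rng, 10, 20.0)
        base = SolventModel(method="dummy_atom", phi0=3.0)
        with_layer = SolventModel(method="dummy_atom", phi0=3.0,
                                  phi0_layer=3.0, layer_thickness=0.2)
        assert es.solvated_amplitude(toy20, with_layer, q) == pytest.approx(
            es.solvated_amplitude(toy20, base, q))

    def test_layer_isolation(self, rng):
        # a = 0 and phi0 = 0 leaves exactly the layer amplitude
        st = es.make_toy(4, seed=9)
        sm = SolventModel(method="voxel", phi0=0.0, phi0_layer=1.0,
                          voxel_size=0.1, layer_thickness=0.2,
                          solvent_only=True)
        grid = voxelize(st, sm)
        q = random_qvecs(rng, 10, 15.0)
        assert es.solvated_amplitude(st, sm, q, voxel_grid=grid) == \
            pytest.approx(voxel_amplitude(grid, "layer", q))

    def test_layer_without_thickness_errors(self):
        st = es.make_toy(3, seed=1)
        sm = SolventModel(method="dummy_atom", phi0=1.0, phi0_layer=2.0)
        with pytest.raises(ValueError, match="layer"):
            es.solvated_amplitude(st, sm, [1.0, 0.0, 0.0])


class TestGeometric:
    def test_sphere_volume_limit(self):
        gm = es.GeometricModel.sphere(2.0, 3.0)
        amp = es.geometric_amplitude(gm, [1e-7, 0, 0])
        assert amp.real == pytest.approx(3.0 * 4 / 3 * np.pi * 8.0, rel=1e-6)

    def test_sphere_first_zero(self):
        from scipy.optimize import brentq
        gm = es.GeometricModel.sphere(1.0, 1.0)
        root = brentq(lambda q: es.geometric_amplitude(gm, [q, 0, 0]).real,
                      3.5, 5.5)
        assert root == pytest.approx(4.4934, abs=1e-3)

    def test_uniform_core_shell_equals_sphere(self, rng):
        cs = es.GeometricModel.core_shell(1.0, 2.0, 5.0, 5.0)
        sp = es.GeometricModel.sphere(2.0, 5.0)
        q = random_qvecs(rng, 20, 10.0)
        assert es.geometric_amplitude(cs, q) == pytest.approx(
            es.geometric_amplitude(sp, q))

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            es.GeometricModel((2.0, 1.0), (1.0, 1.0))


class TestReciprocalGrid:
    def test_exact_at_sample_nodes(self):
        src = es.geometric_source(es.GeometricModel.sphere(1.0, 1.0))
        grid = es.build_grid(src, qmax=10.0, n_shells=10)
        # node: shell 4, theta index 3, phi index 0
        r = 4 * 10.0 / 10
        th = grid.theta[3]
        node = np.array([r * np.sin(th), 0.0, r * np.cos(th)])
        assert es.grid_interpolate(grid, node) == grid.values[4, 3, 0]

    def test_constant_source_reproduced_everywhere(self, rng):
        grid = es.build_grid(lambda q: np.full(len(q), 2.5 + 0j), 5.0, 8)
        q = random_qvecs(rng, 100, 4.99)
        assert es.grid_interpolate(grid, q) == pytest.approx(
            np.full(100, 2.5 + 0j), rel=1e-12)

    def test_out_of_range_rejected(self):
        grid = es.build_grid(lambda q: np.zeros(len(q), complex), 5.0, 8)
        with pytest.raises(GridRangeError):
            es.grid_interpolate(grid, [6.0, 0.0, 0.0])

    def test_convergence_with_shell_doubling(self, rng):
        src = es.atomic_source(es.make_toy(2, seed=5))
        q = random_qvecs(rng, 300, 29.0)
        ref = src(q)
        errs = [np.abs(es.build_grid(src, 30.0, n)(q) - ref).max()
                for n in (20, 40, 80)]
        assert errs[1] < errs[0] and errs[2] < errs[1]

    def test_cartesian_fallback_agrees(self, rng):
        src = es.atomic_source(es.make_toy(3, seed=6))
        q = random_qvecs(rng, 200, 8.0)
        ref = src(q)
        grid = es.build_grid(src, 10.0, 40, layout="cartesian")
        err = np.abs(grid(q) - ref).max()
        assert err < 0.05 * np.abs(ref).max()

    def test_declared_tolerance_at_suggested_settings(self, rng):
        st = es.center_structure(es.make_toy(12, seed=8))
        qmax = 30.0
        settings = suggest_parameters(st, qmax)
        src = es.atomic_source(st)
        grid = es.build_grid(src, qmax, settings.n_shells)
        q = random_qvecs(rng, 500, qmax * 0.999)
        ref = src(q)
        rms = np.sqrt(np.mean(np.abs(ref) ** 2))
        assert np.abs(grid(q) - ref).max() <= GRID_RELATIVE_TOLERANCE * rms


class TestSuggestParameters:
    def test_point_structure_minimum_grid(self):
        st = es.AtomicStructure(("C",), [[0, 0, 0]])
        assert suggest_parameters(st, 50.0).n_shells == 8

    def test_doubling_diameter_doubles_shells(self):
        a = es.AtomicStructure(("C", "C"), [[0, 0, 0], [1.0, 0, 0]])
        b = es.AtomicStructure(("C", "C"), [[0, 0, 0], [2.0, 0, 0]])
        sa = suggest_parameters(a, 40.0).n_shells - 8
        sb = suggest_parameters(b, 40.0).n_shells - 8
        assert sb >= 2 * sa
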