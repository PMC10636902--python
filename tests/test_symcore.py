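"""Point-group operations, the CSM objective and the optimal-axis solve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from csmkit.molstruct import Molecule, equivalence_classes, normalization_factor
from csmkit.symcore import (
    CI,
    CS,
    Permutation,
    PointGroupSpec,
    csm_value,
    fibonacci_lattice,
    initial_direction_guesses,
    nearest_symmetric_structure,
    operation_matrix,
    optimal_axis,
    parse_group,
    symmetry_objective,
)
from csmkit import synthgen

Z = np.array([0.0, 0.0, 1.0])


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestGroupSpecs:
    @pytest.mark.parametrize("text,family,n,order", [
        ("c2", "C", 2, 2), ("c5", "C", 5, 5), ("cs", "S", 1, 2),
        ("ci", "S", 2, 2), ("s4", "S", 4, 4), ("s6", "S", 6, 6),
    ])
    def test_parse_and_order(self, text, family, n, order):
        g = parse_group(text)
        assert (g.family, g.n, g.group_order) == (family, n, order)

    @pytest.mark.parametrize("bad", ["c1", "s3", "s5", "d2", "x"])
    def test_invalid_requests_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_group(bad)


class TestOperationMatrix:
    def test_inversion_is_minus_identity(self):
        op = operation_matrix(CI, [0.2, 0.5, -0.3])
        assert np.allclose(op.matrix, -np.eye(3), atol=1e-12)

    def test_c2_about_z(self):
        op = operation_matrix(parse_group("c2"), Z)
        assert np.allclose(op.matrix, np.diag([-1.0, -1.0, 1.0]), atol=1e-12)

    def test_reflection_through_xy_plane(self):
        op = operation_matrix(CS, Z)
        assert np.allclose(op.matrix, np.diag([1.0, 1.0, -1.0]), atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           group=st.sampled_from(["c2", "c3", "c5", "cs", "ci", "s4", "s6"]))
    def test_orthogonal_with_correct_determinant_and_order(self, seed, group):
        rng = np.random.default_rng(seed)
        spec = parse_group(group)
        op = operation_matrix(spec, rng.normal(size=3))
        t = op.matrix
        assert np.allclose(t @ t.T, np.eye(3), atol=1e-12)
        det = np.linalg.det(t)
        assert det == pytest.approx(1.0 if spec.proper else -1.0, abs=1e-12)
        assert np.allclose(np.linalg.matrix_power(t, spec.group_order),
                           np.eye(3), atol=1e-9)

    def test_c5_trace_identity(self):
        op = operation_matrix(parse_group("c5"), unit([1.0, -2.0, 0.5]))
        assert np.trace(op.matrix) == pytest.approx(
            1.0 + 2.0 * math.cos(2.0 * math.pi / 5.0), abs=1e-12)


class TestObjective:
    def test_perfect_ring_rotation_is_zero(self, ring5):
        op = operation_matrix(parse_group("c5"), Z)
        perm = Permutation((1, 2, 3, 4, 0))
        assert symmetry_objective(ring5, perm, op, "full") < 1e-10

    def test_inversion_with_identity_permutation_gives_s_100(self):
        mol = synthgen.make_two_element_pair()
        op = operation_matrix(CI, Z)
        m = symmetry_objective(mol, Permutation.identity(2), op, "full")
        d = normalization_factor(mol)
        assert csm_value(m, d) == 100.0

    def test_full_matches_brute_force_sum(self):
        mol = synthgen.distort(synthgen.make_ring(4), 0.1, 9)
        spec = parse_group("c4")
        axis = unit([0.2, 0.1, 0.95])
        op = operation_matrix(spec, axis)
        perm = Permutation((1, 2, 3, 0))
        q = mol.centered_coords()
        total = 0.0  # term-by-term evaluation of the cycle average
        p = list(perm.mapping)
        for i in range(1, 5):
            ti = np.linalg.matrix_power(op.matrix, i)
            pi = list(range(4))
            for _ in range(i):
                pi = [p[k] for k in pi]
            for k in range(4):
                total += float(np.sum((ti @ q[k] - q[pi[k]]) ** 2))
        assert symmetry_objective(mol, perm, op, "full") == pytest.approx(
            total / 8.0, abs=1e-12)

    def test_single_equals_full_for_order_two_involutions(self):
        mol = synthgen.distort(synthgen.make_prism(3), 0.1, 2)
        op = operation_matrix(CS, unit([0.3, -0.2, 0.93]))
        perm = Permutation((3, 4, 5, 0, 1, 2))  # mirror pairing, an involution
        full = symmetry_objective(mol, perm, op, "full")
        single = symmetry_objective(mol, perm, op, "single")
        assert single == pytest.approx(full, abs=1e-9)

    @pytest.mark.parametrize("m,d,expected", [(0.0, 5.0, 0.0),
                                              (5.0, 5.0, 100.0),
                                              (1.0, 4.0, 25.0)])
    def test_csm_value_scaling(self, m, d, expected):
        assert csm_value(m, d) == expected

    def test_csm_value_requires_positive_d(self):
        with pytest.raises(ValueError):
            csm_value(1.0, 0.0)


class TestNearestStructure:
    def test_projection_is_identity_on_symmetric_input(self, ring5):
        op = operation_matrix(parse_group("c5"), Z)
        perm = Permutation((1, 2, 3, 4, 0))
        p = nearest_symmetric_structure(ring5, perm, op)
        assert np.allclose(p, ring5.centered_coords(), atol=1e-10)

    def test_identity_inversion_orbit_collapses_to_center(self):
        mol = synthgen.make_chiral_toy(0)
        op = operation_matrix(CI, Z)
        p = nearest_symmetric_structure(mol, Permutation.identity(4), op)
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_t_invariance_and_objective_consistency(self):
        mol = synthgen.distort(synthgen.make_prism(4), 0.1, 5)
        spec = parse_group("s4")
        axis = unit([0.1, 0.2, 0.97])
        op = operation_matrix(spec, axis)
        perm = Permutation((1, 2, 3, 0, 5, 6, 7, 4))
        p = nearest_symmetric_structure(mol, perm, op)
        assert np.allclose(p[perm.array], p @ op.matrix.T, atol=1e-9)
        q = mol.centered_coords()
        assert float(np.sum((q - p) ** 2)) == pytest.approx(
            symmetry_objective(mol, perm, op, "full"), abs=1e-9)

    def test_matches_quadratic_minimizer_for_fixed_t_and_pi(self):
        mol = Molecule(("C", "C"), [[0.9, 0.1, 1.1], [-1.0, 0.2, -0.8]])
        op = operation_matrix(parse_group("c2"), Z)
        perm = Permutation((1, 0))
        p = nearest_symmetric_structure(mol, perm, op)
        q = mol.centered_coords()

        def cost(x):  # T-invariant pair parametrized by its first atom
            p0 = x.reshape(1, 3)
            p1 = p0 @ op.matrix.T
            return float(np.sum((q[0] - p0) ** 2) + np.sum((q[1] - p1) ** 2))

        res = minimize(cost, q[0], method="BFGS", options={"gtol": 1e-12})
        assert cost(p[0].copy()) == pytest.approx(res.fun, abs=1e-10)


class TestOptimalAxis:
    def test_recovers_true_c2_axis(self):
        mol = synthgen.make_prism(4)  # C4 prism: z is also a C2 axis
        perm = Permutation((2, 3, 0, 1, 6, 7, 4, 5))  # rotation by 180 deg
        axis = optimal_axis(mol, perm, parse_group("c2"))
        assert abs(axis @ Z) == pytest.approx(1.0, abs=1e-8)

    def test_inversion_axis_convention(self):
        mol = synthgen.make_chiral_toy(1)
        assert np.allclose(optimal_axis(mol, Permutation.identity(4), CI), Z)

    @pytest.mark.parametrize("group,seed", [("c3", 0), ("cs", 1), ("s4", 2)])
    def test_beats_dense_grid_oracle(self, group, seed):
        spec = parse_group(group)
        mol = synthgen.distort(synthgen.make_ring(6), 0.1, seed)
        perm = Permutation((1, 2, 3, 4, 5, 0)) if group != "cs" \
            else Permutation((1, 0, 5, 4, 3, 2))

        def f(v):
            v = unit(v)
            return symmetry_objective(mol, perm, operation_matrix(spec, v),
                                      "single")

        axis = optimal_axis(mol, perm, spec)
        grid = fibonacci_lattice(10_000).vectors
        vals = [f(v) for v in grid]
        start = grid[int(np.argmin(vals))]
        ref = minimize(f, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15})
        assert f(axis) <= ref.fun + 1e-8


class TestFibonacciLattice:
    def test_endpoints(self):
        vecs = fibonacci_lattice(7).vectors
        assert np.allclose(vecs[0], [1, 0, 0], atol=1e-12)
        assert np.allclose(vecs[-1], [-1, 0, 0], atol=1e-12)

    def test_500_vectors_unit_and_distinct(self):
        vecs = fibonacci_lattice(500).vectors
        assert len(vecs) == 500
        assert np.allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-12)
        dots = np.clip(vecs @ vecs.T, -1.0, 1.0)
        np.fill_diagonal(dots, -1.0)
        assert np.arccos(dots.max()) > 0.0

    def test_small_lattice_rejected(self):
        with pytest.raises(ValueError):
            fibonacci_lattice(1)


class TestInitialGuesses:
    def test_planar_ring_yields_ring_axis(self):
        # two concentric rings of different elements: two planar centroids
        a = synthgen.make_ring(6, radius=1.0)
        b = synthgen.make_ring(6, radius=2.0, element="N")
        mol = Molecule(a.elements + b.elements,
                       np.vstack([a.coords, b.coords + [0.1, 0, 0]]))
        part = equivalence_classes(mol)
        vecs = initial_direction_guesses(mol, part).vectors
        assert any(abs(v @ Z) > 1.0 - 1e-6 for v in vecs)

    def test_collinear_centroids_yield_line_direction(self):
        mol = Molecule(("C", "N", "O"),
                       [[0, 0, 0], [0, 0, 1.3], [0, 0, 2.6]])
        part = equivalence_classes(mol)
        vecs = initial_direction_guesses(mol, part).vectors
        assert any(abs(v @ Z) > 1.0 - 1e-8 for v in vecs)

    def test_single_class_falls_back_to_coordinate_axes(self, ring6):
        part = equivalence_classes(ring6)
        vecs = initial_direction_guesses(ring6, part).vectors
        assert len(vecs) == 3 and np.allclose(np.abs(vecs), np.eye(3))

    def test_outlier_centroid_removed_from_plane_fit(self):
        rng = np.random.default_rng(12)
        els = ("C", "N", "O", "F", "P", "S", "Cl", "B", "Si", "Br", "I")
        ang = 2.0 * math.pi * np.arange(10) / 10
        pts = np.column_stack([2 * np.cos(ang), 2 * np.sin(ang),
                               rng.normal(scale=0.02, size=10)])
        coords = np.vstack([pts, [[0.5, 0.4, 3.0]]])  # planted outlier
        mol = Molecule(els, coords)
        part = equivalence_classes(mol)
        vecs = initial_direction_guesses(mol, part).vectors
        best = max(abs(v @ Z) for v in vecs)
        assert math.degrees(math.acos(min(best, 1.0))) < 5.0
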