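"""Integral layer: erf/1F1 evaluation, pair factors, ERIs, one-electron
matrices, and the combinatorial ERI count."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobehf import (build_basis, build_pair_table, count_unique_eris,
                    erf_approx, eri_contracted, f11_half,
                    one_electron_matrices, pair_factor, eri_primitive)
from lobehf.fixtures import make_named_small
from lobehf.integrals import eri_tensor_dense
from lobehf.reference import reference_integrals

from oracles import eri_primitive_quadrature


class TestErfApprox:
    def test_at_zero(self):
        assert abs(erf_approx(0.0)) <= 1.5e-7

    def test_shortcut_region_exact_one(self):
        assert erf_approx(4.0) == 1.0
        assert erf_approx(17.3) == 1.0

    def test_tail_bounds_match_printed_values(self):
        assert 1.0 - math.erf(4.0) == pytest.approx(1.5e-8, rel=0.05)
        assert 1.0 - math.erf(5.0) == pytest.approx(1.5e-12, rel=0.05)

    def test_dense_scan_against_library_erf(self):
        x = np.linspace(0.0, 6.0, 100_000)
        approx = np.array([erf_approx(v) for v in x])
        exact = np.array([math.erf(v) for v in x])
        assert np.abs(approx - exact).max() <= 2e-7

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            erf_approx(-0.1)


class TestF11Half:
    def test_limit_at_zero(self):
        assert f11_half(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_value_at_one(self):
        expected = math.sqrt(math.pi) * math.erf(1.0) / 2.0
        assert f11_half(1.0) == pytest.approx(expected, abs=1e-9)

    def test_monotone_decreasing(self):
        xs = np.linspace(0.0, 50.0, 400)
        vals = [f11_half(x) for x in xs]
        assert np.all(np.diff(vals) < 0)


class TestPairFactor:
    def test_equal_exponents_center_midpoint_symmetry(self):
        r = np.array([0.3, -0.1, 0.7])
        rec = pair_factor(1.0, 2.0, r, 1.0, 2.0, r)
        assert np.allclose(rec.center, r)

    def test_coincident_unit_value(self):
        rec = pair_factor(1.0, 1.0, np.zeros(3), 1.0, 1.0, np.zeros(3))
        expected = math.sqrt(2.0) * math.pi ** 1.25 * 2.0 ** -1.5
        assert rec.overlap == pytest.approx(expected, rel=1e-12)

    def test_decay_with_distance(self):
        prev = np.inf
        for d in (1.0, 2.0, 4.0, 8.0):
            rec = pair_factor(1.0, 1.0, np.zeros(3), 1.0, 1.0,
                              np.array([d, 0, 0]))
            assert 0 < rec.overlap < prev
            prev = rec.overlap

    def test_center_on_segment(self):
        rec = pair_factor(1.0, 3.0, np.zeros(3), 1.0, 1.0,
                          np.array([2.0, 0, 0]))
        assert 0 <= rec.center[0] <= 2.0
        assert rec.center[0] == pytest.approx(0.5)  # pulled to tighter prim


class TestEriPrimitive:
    def test_coincident_composite_centers(self):
        a = pair_factor(1.0, 1.2, np.zeros(3), 1.0, 0.8, np.zeros(3))
        b = pair_factor(1.0, 0.5, np.zeros(3), 1.0, 0.9, np.zeros(3))
        p = a.alpha_sum * b.alpha_sum / (a.alpha_sum + b.alpha_sum)
        assert eri_primitive(a, b) == pytest.approx(
            a.overlap * b.overlap * math.sqrt(p), rel=1e-12)

    @pytest.mark.parametrize("centers", [
        (np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)),
        (np.zeros(3), np.array([0.8, 0, 0]), np.array([2.0, 1.0, 0]),
         np.array([2.5, 1.0, -0.5])),
        (np.zeros(3), np.array([0.2, 0.4, 0.1]), np.array([5.0, 0, 0]),
         np.array([5.5, 0.3, 0])),
    ])
    def test_against_quadrature_oracle(self, centers):
        ra, rb, rc, rd = centers
        al = (1.0, 0.7, 0.9, 1.3)
        got = eri_primitive(pair_factor(1.0, al[0], ra, 1.0, al[1], rb),
                            pair_factor(1.0, al[2], rc, 1.0, al[3], rd))
        want = eri_primitive_quadrature(1.0, al[0], ra, 1.0, al[1], rb,
                                        1.0, al[2], rc, 1.0, al[3], rd)
        assert got == pytest.approx(want, rel=1e-6)

    def test_translation_invariance(self):
        shift = np.array([3.0, -2.0, 1.0])
        ra, rb = np.zeros(3), np.array([1.0, 0, 0])
        rc, rd = np.array([0, 1.5, 0]), np.array([0.5, 1.5, 0.5])
        v1 = eri_primitive(pair_factor(1, 1.0, ra, 1, 0.8, rb),
                           pair_factor(1, 0.6, rc, 1, 1.2, rd))
        v2 = eri_primitive(pair_factor(1, 1.0, ra + shift, 1, 0.8, rb + shift),
                           pair_factor(1, 0.6, rc + shift, 1, 1.2, rd + shift))
        assert v1 == pytest.approx(v2, rel=1e-13)


class TestEriContracted:
    def test_h2_against_reference_implementation(self, h2):
        basis = build_basis(h2)
        table = build_pair_table(basis)
        ref = reference_integrals(h2)
        for (i, j, k, l) in [(0, 0, 0, 0), (0, 1, 0, 1), (0, 0, 1, 1),
                             (0, 0, 0, 1), (1, 1, 1, 1)]:
            got = eri_contracted(i, j, k, l, basis, table)
            assert got == pytest.approx(ref.eri[i, j, k, l], abs=1e-10)

    def test_eightfold_symmetry_dense_tensor(self, water):
        basis = build_basis(water)
        eri = eri_tensor_dense(basis)
        rng = np.random.default_rng(0)
        for _ in range(40):
            i, j, k, l = rng.integers(0, 7, size=4)
            v = eri[i, j, k, l]
            for perm in ((j, i, k, l), (i, j, l, k), (k, l, i, j),
                         (l, k, j, i)):
                assert eri[perm] == v  # bit-identical by construction

    def test_carbon_pp_against_reference(self):
        # lobe-represented p ERIs agree with the conventional Cartesian
        # route within the lobe-fitting budget
        sys_ = make_named_small("CH4")
        basis = build_basis(sys_)
        table = build_pair_table(basis)
        ref = reference_integrals(sys_)
        # (2px 2px | 2px 2px) on carbon: functions 2..4 are 2p
        got = eri_contracted(2, 2, 2, 2, basis, table)
        assert got == pytest.approx(ref.eri[2, 2, 2, 2], rel=2e-2)


class TestOneElectron:
    def test_h2_matches_reference_to_machine_precision(self, h2):
        ints = one_electron_matrices(build_basis(h2))
        ref = reference_integrals(h2)
        assert np.abs(ints.overlap - ref.S).max() < 1e-10
        assert np.abs(ints.kinetic - ref.T).max() < 1e-10
        assert np.abs(ints.nuclear - ref.V).max() < 1e-10

    def test_overlap_diagonal_unit(self, water):
        ints = one_electron_matrices(build_basis(water))
        assert np.allclose(np.diag(ints.overlap), 1.0, atol=1e-3)

    def test_kinetic_positive_definite(self, water):
        ints = one_electron_matrices(build_basis(water))
        assert np.linalg.eigvalsh(ints.kinetic).min() > 0


class TestCountUniqueEris:
    def test_paper_scale_case(self):
        assert count_unique_eris(256) == 541_089_856

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 6)])
    def test_small_cases_explicit(self, n, expected):
        assert count_unique_eris(n) == expected

    @given(st.integers(min_value=1, max_value=12))
    @settings(deadline=None, max_examples=12)
    def test_matches_bruteforce_enumeration(self, n):
        seen = set()
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    for l in range(n):
                        canon = min((i, j, k, l), (j, i, k, l), (i, j, l, k),
                                    (j, i, l, k), (k, l, i, j), (l, k, i, j),
                                    (k, l, j, i), (l, k, j, i))
                        seen.add(canon)
        assert count_unique_eris(n) == len(seen)
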