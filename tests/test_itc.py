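import numpy as np
import pytest
import sympy

from asdlmri import (
    Dictionary,
    SparseCodeMatrix,
    atom_powers,
    ebic,
    erml,
    model_complexity,
    representation_rmse,
    select_candidate_size,
    sort_dictionary_by_power,
)
from .conftest import unit_norm_dictionary


def ebic_highprec(rmse, Q, P, N, n, s):
    r, q = sympy.Rational(str(rmse)), sympy.Integer(Q)
    val = (
        2 * sympy.log(r)
        + sympy.log(q) / q * P
        + sympy.Rational(2 * N, Q) * sympy.log(sympy.binomial(n, s))
    )
    return float(sympy.N(val, 40))


def erml_highprec(rmse, Q, P, N, n, s, dx):
    r = sympy.Rational(str(rmse))
    dxr = sympy.Rational(str(dx))
    val = (
        (Q - P) * sympy.log(r**2 / (Q - P))
        + P * sympy.log(dxr / (sympy.Integer(Q) * P))
        + sympy.log(sympy.Integer(P) * (Q - P))
        + 2 * N * sympy.log(sympy.binomial(n, s))
    )
    return float(sympy.N(val, 40))


class TestRMSE:
    def test_exact_fit_is_zero(self, rng):
        D = unit_norm_dictionary(rng, 6, 8)
        X = rng.standard_normal((8, 20))
        assert representation_rmse(D @ X, D, X) == pytest.approx(0.0, abs=1e-12)

    def test_unit_error_normalization(self):
        # Y - DX the all-ones matrix -> ||E||_F = sqrt(Q) -> RMSE = 1
        D = np.eye(4)
        X = np.zeros((4, 10))
        Y = np.ones((4, 10))
        assert representation_rmse(Y, D, X) == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementwise_sum_oracle(self, rng):
        D = unit_norm_dictionary(rng, 8, 12)
        X = rng.standard_normal((12, 50))
        Y = rng.standard_normal((8, 50))
        E = Y - D @ X
        oracle = np.sqrt(sum(abs(e) ** 2 for e in E.ravel()) / E.size)
        assert representation_rmse(Y, D, X) == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            representation_rmse(np.zeros((0, 0)), np.eye(2), np.zeros((2, 0)))


class TestComplexityAndCriteria:
    @pytest.mark.parametrize(
        "s,N,m,n,expected",
        [(5, 100, 36, 64, 2740), (0, 7, 9, 11, 88), (3, 10, 1, 50, 30)],
    )
    def test_complexity_count(self, s, N, m, n, expected):
        assert model_complexity(s, N, m, n) == expected

    def test_ebic_binomial_term_vanishes_when_n_equals_s(self):
        Q, P, N = 3600, 2740, 100
        val = ebic(0.1, Q, P, N, n=5, s=5)
        assert val == pytest.approx(2 * np.log(0.1) + np.log(Q) / Q * P, abs=1e-12)

    def test_ebic_first_term_vanishes_at_unit_rmse(self):
        val = ebic(1.0, 100, 0, 10, n=8, s=2)
        assert val == pytest.approx((2 * 10 / 100) * np.log(28), abs=1e-12)

    @pytest.mark.parametrize(
        "rmse,N,m,n,s",
        [
            (0.1, 100, 36, 64, 5),
            (0.37, 200, 16, 100, 4),
            (1.7, 50, 36, 128, 6),
            (0.004, 400, 25, 80, 3),
        ],
    )
    def test_ebic_matches_arbitrary_precision(self, rmse, N, m, n, s):
        Q = m * N
        P = model_complexity(s, N, m, n)
        assert ebic(rmse, Q, P, N, n, s) == pytest.approx(
            ebic_highprec(rmse, Q, P, N, n, s), abs=1e-9
        )

    def test_ebic_perfect_fit_warns_and_dominates(self):
        with pytest.warns(RuntimeWarning):
            assert ebic(0.0, 100, 10, 10, 8, 2) == -np.inf

    def test_erml_last_term_vanishes_when_n_equals_s(self):
        Q, P, N = 3600, 2740, 100
        val = erml(0.1, Q, P, N, n=5, s=5, dx_frob_sq=360.0)
        expected = (
            (Q - P) * np.log(0.01 / (Q - P))
            + P * np.log(360.0 / (Q * P))
            + np.log(P * (Q - P))
        )
        assert val == pytest.approx(expected, abs=1e-9)

    def test_erml_boundary_algebra_at_q_equals_p_plus_one(self):
        Q, P = 101, 100
        val = erml(0.3, Q, P, N=10, n=2, s=2, dx_frob_sq=5.0)
        expected = np.log(0.3**2) + P * np.log(5.0 / (Q * P)) + np.log(P)
        assert val == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "rmse,N,m,n,s,dx",
        [(0.1, 100, 36, 64, 5, 360.0), (0.02, 300, 16, 90, 4, 1234.5)],
    )
    def test_erml_matches_arbitrary_precision(self, rmse, N, m, n, s, dx):
        Q = m * N
        P = model_complexity(s, N, m, n)
        assert erml(rmse, Q, P, N, n, s, dx) == pytest.approx(
            erml_highprec(rmse, Q, P, N, n, s, dx), abs=1e-9
        )

    def test_erml_overparameterized_candidate_is_infeasible(self):
        assert erml(0.1, 100, 200, 10, 8, 2, 5.0) == np.inf

    def test_ebic_monotone_in_complexity_and_rmse(self):
        Q, N, n, s = 3600, 100, 64, 5
        vals_P = [ebic(0.1, Q, P, N, n, s) for P in (100, 500, 1000, 2000)]
        assert all(b > a for a, b in zip(vals_P, vals_P[1:]))
        vals_r = [ebic(r, Q, 500, N, n, s) for r in (0.01, 0.1, 0.5, 2.0)]
        assert all(b > a for a, b in zip(vals_r, vals_r[1:]))


class TestAtomPowerSorting:
    def test_power_is_row_two_norm(self):
        X = np.zeros((3, 4))
        X[1, 0], X[1, 2] = 3.0, 4.0
        powers = atom_powers(X)
        np.testing.assert_allclose(powers, [0.0, 5.0, 0.0])
        # column permutations leave powers unchanged
        np.testing.assert_allclose(atom_powers(X[:, ::-1]), powers)

    def test_sort_permutation_and_product_invariance(self, rng):
        D = Dictionary(atoms=unit_norm_dictionary(rng, 6, 3))
        data = np.diag([1.0, 3.0, 2.0]) @ rng.standard_normal((3, 10))
        data /= np.linalg.norm(data, axis=1, keepdims=True)
        data *= np.array([[1.0], [3.0], [2.0]])
        X = SparseCodeMatrix(data, 3, np.full(10, 3))
        Ds, Xs, perm = sort_dictionary_by_power(D, X)
        np.testing.assert_array_equal(perm, [1, 2, 0])
        assert np.linalg.norm(D.atoms @ X.data - Ds.atoms @ Xs.data) < 1e-12

    def test_sorted_input_gives_identity_permutation(self, rng):
        D = Dictionary(atoms=unit_norm_dictionary(rng, 6, 3))
        data = np.array([[3.0], [2.0], [1.0]]) * np.ones((3, 5))
        X = SparseCodeMatrix(data, 3, np.full(5, 3))
        _, _, perm = sort_dictionary_by_power(D, X)
        np.testing.assert_array_equal(perm, [0, 1, 2])


class TestCandidateSelection:
    def _nested_fixture(self, rng, n=12, h_star=6, m=8, N=60):
        D = unit_norm_dictionary(rng, m, n)
        X = np.zeros((n, N))
        X[:h_star] = rng.standard_normal((h_star, N))
        # scale rows so power is strictly decreasing (already sorted)
        X *= (n - np.arange(n))[:, None]
        Y = D[:, :h_star] @ X[:h_star]
        Ds = Dictionary(atoms=D, sorted_by_power=True)
        Xs = SparseCodeMatrix(X, h_star, np.full(N, h_star))
        return Ds, Xs, Y

    def test_nested_fixture_selects_smallest_sufficient_size(self, rng):
        Ds, Xs, Y = self._nested_fixture(rng)
        ev = select_candidate_size(Ds, Xs, Y, s=2, n_min=2, n_cand=20)
        # every candidate >= h* fits exactly; complexity prefers the smallest
        assert ev.n_itc == min(h for h in ev.candidate_sizes if h >= 6)

    def test_exhaustive_grid_when_n_cand_large(self, rng):
        Ds, Xs, Y = self._nested_fixture(rng)
        ev = select_candidate_size(Ds, Xs, Y, s=2, n_min=8, n_cand=50)
        np.testing.assert_array_equal(ev.candidate_sizes, np.arange(8, 13))

    def test_single_candidate_case(self, rng):
        Ds, Xs, Y = self._nested_fixture(rng)
        ev = select_candidate_size(Ds, Xs, Y, s=2, n_min=12, n_cand=5)
        assert ev.n_itc == 12

    def test_truncated_errors_match_bruteforce(self, rng):
        D = Dictionary(atoms=unit_norm_dictionary(rng, 8, 12), sorted_by_power=True)
        X = SparseCodeMatrix(rng.standard_normal((12, 40)), 12, np.full(40, 12))
        Y = rng.standard_normal((8, 40))
        ev = select_candidate_size(D, X, Y, s=2, n_min=8, n_cand=50)
        Q = 8 * 40
        for h, val in zip(ev.candidate_sizes, ev.criterion_values):
            rmse = np.linalg.norm(Y - D.atoms[:, :h] @ X.data[:h]) / np.sqrt(Q)
            P = model_complexity(2, 40, 8, int(h))
            assert val == pytest.approx(ebic(rmse, Q, P, 40, int(h), 2), abs=1e-9)

    def test_unsorted_dictionary_rejected(self, rng):
        D = Dictionary(atoms=unit_norm_dictionary(rng, 8, 12), sorted_by_power=False)
        X = SparseCodeMatrix(rng.standard_normal((12, 20)), 12, np.full(20, 12))
        with pytest.raises(ValueError):
            select_candidate_size(D, X, rng.standard_normal((8, 20)), 2, 8, 5)

    def test_zero_power_atoms_do_not_change_rmse_and_smaller_wins(self, rng):
        Ds, Xs, Y = self._nested_fixture(rng, n=10, h_star=4, m=4)
        ev = select_candidate_size(Ds, Xs, Y, s=2, n_min=4, n_cand=50)
        assert ev.n_itc == 4
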