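"""Growth-division operator assembly, shift bound and eigen-solver."""

import math

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse
from hypothesis import given, settings
from hypothesis import strategies as st

from tumoreq.size_dynamics import (
    AnalyticCase,
    EigenPair,
    GrowthDivisionSpec,
    InvalidSpecError,
    MitosisKernel,
    SizeGrid,
    TabulatedKernel,
    UniformKernel,
    analytic_eigenpair,
    assemble_shifted_operator,
    choose_shift,
    compute_eigenpair,
    eigen_errors,
    mitosis_series_profile,
    shift_lower_bound,
    solve_leading_eigenpair,
)

MITOSIS = AnalyticCase("mitosis_const", a0=4.0, V0=0.6)


def brute_force_bound(spec, grid):
    """Literal loop evaluation of the invertibility-bound formula."""
    z, zh, h, I = grid.z, grid.z_half, grid.h, grid.n_cells
    K = spec.kernel.discrete(grid)
    if scipy.sparse.issparse(K):
        K = K.toarray()
    a = spec.a(z)
    Vh = spec.V(zh)
    s = []
    for k in range(I):
        acc = 0.0
        for j in range(k, I):
            acc += a[j] * K[k, j]
        s.append(h * acc)
    return max(abs(Vh)) / min(abs(Vh)) * max(s) - min(a)


class TestShiftBound:
    def test_matches_literal_summation_mitosis(self):
        grid = SizeGrid(5.0, 1000)
        spec = MITOSIS.spec()
        assert shift_lower_bound(spec, grid) == pytest.approx(
            brute_force_bound(spec, grid), rel=1e-12)

    def test_constant_velocity_ratio_collapses(self):
        # with V constant the velocity ratio is 1: bound = max_k s_k - min a
        grid = SizeGrid(5.0, 50)
        spec = GrowthDivisionSpec(0.7, lambda z: 0.5 + z, UniformKernel())
        got = shift_lower_bound(spec, grid)
        K = spec.kernel.discrete(grid)
        s = grid.h * (K * spec.a(grid.z)[None, :]).sum(axis=1)
        assert got == pytest.approx(s.max() - spec.a(grid.z).min(), rel=1e-12)

    def test_bounded_kernel_gives_bound_below_a(self):
        # kernel with h sum_j a k <= 2a on a 10-point grid: bound <= a
        grid = SizeGrid(2.0, 10)
        R = grid.r_max
        kernel = TabulatedKernel(lambda z, zp: np.full(
            np.broadcast_shapes(np.shape(z), np.shape(zp)), 2.0 / R))
        spec = GrowthDivisionSpec(1.0, 0.5, kernel)
        row_sums = [grid.h * sum(0.5 * 2.0 / R
                                 for _ in range(k, grid.n_cells))
                    for k in range(grid.n_cells)]
        assert max(row_sums) <= 2 * 0.5 + 1e-12
        assert shift_lower_bound(spec, grid) <= 0.5

    def test_nonpositive_growth_rejected(self):
        grid = SizeGrid(5.0, 20)
        spec = GrowthDivisionSpec(lambda z: z - 2.0, 1.0, UniformKernel())
        with pytest.raises(InvalidSpecError):
            shift_lower_bound(spec, grid)

    def test_refinement_insensitive(self):
        # the bound depends on h only through quadrature error
        spec = MITOSIS.spec()
        b1 = shift_lower_bound(spec, SizeGrid(5.0, 500))
        b2 = shift_lower_bound(spec, SizeGrid(5.0, 2000))
        assert b1 == pytest.approx(b2, rel=5e-3)


class TestAssembly:
    def test_zero_rates_give_h_identity(self):
        grid = SizeGrid(1.0, 8)
        spec = GrowthDivisionSpec(0.0, 0.0, UniformKernel())
        op = assemble_shifted_operator(spec, grid, 1.0, check_shift=False)
        assert np.allclose(op.todense(), grid.h * np.eye(8))

    def test_dirichlet_mode_first_row_identity(self):
        grid = SizeGrid(1.0, 8)
        spec = GrowthDivisionSpec(0.0, 0.0, UniformKernel())
        op = assemble_shifted_operator(spec, grid, 1.0, boundary="dirichlet",
                                       check_shift=False)
        T = op.todense()
        assert np.allclose(T[0], np.eye(8)[0])
        assert np.allclose(T[1:], (grid.h * np.eye(8))[1:])

    def test_mitosis_direct_gain_hits_single_column(self):
        # node-aligned grid: the Dirac gain selects column 2i with -4 h a
        grid = SizeGrid(4.0, 16, centered=False)
        a, V, lam = 0.8, 1.0, 10.0
        spec = GrowthDivisionSpec(V, a, MitosisKernel(mode="direct"))
        T = assemble_shifted_operator(spec, grid, lam,
                                      check_shift=False).todense()
        h = grid.h
        for i in range(1, 16):          # rows, 0-based
            gain_cols = [j for j in range(16)
                         if j > i and not math.isclose(T[i, j], 0.0)]
            if 2 * (i + 1) <= 16:
                assert gain_cols == [2 * (i + 1) - 1]
                assert T[i, gain_cols[0]] == pytest.approx(-4 * h * a)
            else:
                assert gain_cols == []

    def test_uniform_kernel_entries_match_hand_evaluation(self):
        # I = 5, a(z) = z, V = 1, Lambda = 3: every entry from the formula
        grid = SizeGrid(1.0, 5)
        spec = GrowthDivisionSpec(1.0, lambda z: z, UniformKernel())
        T = assemble_shifted_operator(spec, grid, 3.0,
                                      check_shift=False).todense()
        h, z, zh = grid.h, grid.z, grid.z_half
        expect = np.zeros((5, 5))
        for i in range(5):
            expect[i, i] += zh[i] / zh[i]          # V_{i+1/2} = 1
            if i > 0:
                expect[i, i - 1] -= 1.0            # -V_{i-1/2}
            expect[i, i] += h * (3.0 + z[i])
            for j in range(i, 5):
                expect[i, j] -= h * h * z[j] * (2.0 / z[j])
        assert np.allclose(T, expect, atol=1e-14)

    def test_low_shift_refused(self):
        grid = SizeGrid(5.0, 100)
        spec = MITOSIS.spec()
        bound = choose_shift(spec, grid, safety=1.0)
        with pytest.raises(InvalidSpecError):
            assemble_shifted_operator(spec, grid, 0.5 * bound)

    def test_direct_mapping_requires_node_grid(self):
        with pytest.raises(InvalidSpecError):
            MitosisKernel(mode="direct").discrete(SizeGrid(5.0, 10))


class TestInversePower:
    def test_seed_independent_eigenvalue(self):
        grid = SizeGrid(5.0, 300)
        spec = MITOSIS.spec()
        p1 = compute_eigenpair(spec, grid, eps=1e-8, seed=1)
        p2 = compute_eigenpair(spec, grid, eps=1e-8, seed=77)
        assert p1.lam == pytest.approx(p2.lam, rel=1e-8)

    @pytest.mark.parametrize("case", [
        MITOSIS,
        AnalyticCase("uniform_Vconst_alinear", a0=4.0, V0=0.6),
    ], ids=["mitosis", "uniform"])
    def test_matches_dense_eigensolver(self, case):
        # same matrix, independent algorithm: full dense eigendecomposition
        grid = SizeGrid(5.0, 200)
        spec = case.spec()
        shift = choose_shift(spec, grid)
        op = assemble_shifted_operator(spec, grid, shift, check_shift=False)
        pair = solve_leading_eigenpair(op, eps=1e-13, seed=0, max_iter=100000)
        eigs = np.linalg.eigvals(op.todense() / grid.h)
        lam_dense = shift - eigs[np.argmin(np.abs(eigs))]
        assert abs(lam_dense.imag) < 1e-10
        assert pair.lam == pytest.approx(lam_dense.real, rel=1e-10)

    def test_positive_profile_and_normalization(self):
        grid = SizeGrid(5.0, 500)
        pair = compute_eigenpair(MITOSIS.spec(), grid, eps=1e-8, seed=2)
        assert np.all(pair.profile >= 0)
        assert np.all(pair.profile[1:] > 0)     # strict beyond the boundary
        assert grid.h * pair.profile.sum() == pytest.approx(1.0, abs=1e-12)

    def test_truncation_radius_insensitive(self):
        spec = MITOSIS.spec()
        lam5 = compute_eigenpair(spec, SizeGrid(5.0, 1000), eps=1e-8,
                                 seed=0).lam
        lam7 = compute_eigenpair(spec, SizeGrid(7.0, 1400), eps=1e-8,
                                 seed=0).lam
        assert lam7 == pytest.approx(lam5, rel=1e-6)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(a0=st.floats(0.5, 6.0), v0=st.floats(0.2, 2.0))
    def test_mitosis_eigenvalue_is_division_rate(self, a0, v0):
        # lambda = a for binary division with constant rates, any (a, V)
        r_max = max(5.0 * v0 / a0, 1.0)     # profile decays on scale V/(2a)
        grid = SizeGrid(r_max, 600)
        pair = compute_eigenpair(GrowthDivisionSpec(v0, a0, MitosisKernel()),
                                 grid, eps=1e-8, seed=3)
        assert pair.lam == pytest.approx(a0, rel=2e-3)
        assert np.all(pair.profile >= 0)


class TestAnalyticCatalog:
    @pytest.mark.parametrize("case,expected", [
        (MITOSIS, 4.0),
        (AnalyticCase("uniform_Vconst_alinear", a0=4.0, V0=0.6),
         math.sqrt(2.4)),
        (AnalyticCase("uniform_Vlinear_apower", a0=4.0, V0=0.6, n=1), 0.6),
        (AnalyticCase("uniform_Vlinear_apower", a0=4.0, V0=0.6, n=2), 0.6),
    ], ids=["mitosis", "ex1", "ex2n1", "ex2n2"])
    def test_closed_form_eigenvalue_and_normalization(self, case, expected):
        grid = SizeGrid(5.0, 400)
        pair = analytic_eigenpair(case, grid)
        assert pair.lam == pytest.approx(expected, rel=1e-12)
        assert grid.h * pair.profile.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_case_rejected(self):
        with pytest.raises(InvalidSpecError):
            AnalyticCase("fibonacci", a0=1.0, V0=1.0)

    def test_series_boundary_value_vanishes(self):
        # the alternating series encodes N(0) = 0
        assert mitosis_series_profile(np.array([0.0]), 4.0, 0.6)[0] == \
            pytest.approx(0.0, abs=1e-9)

    def test_series_consistent_with_division_balance(self):
        # d(VN)/dz + a N = 4 a N(2z) pointwise away from the tail
        z = np.linspace(0.05, 1.5, 400)
        a, V = 4.0, 0.6
        N = mitosis_series_profile(z, a, V)
        dz = z[1] - z[0]
        lhs = V * np.gradient(N, dz) + 2 * a * N
        rhs = 4 * a * mitosis_series_profile(2 * z, a, V)
        assert np.allclose(lhs[2:-2], rhs[2:-2], rtol=5e-3,
                           atol=5e-4 * np.max(np.abs(rhs)))


class TestEigenErrors:
    def test_identity_gives_zero(self):
        grid = SizeGrid(5.0, 100)
        p = analytic_eigenpair(MITOSIS, grid)
        assert eigen_errors(p, p) == (0.0, 0.0)

    def test_single_cell_perturbation_moves_l1_error_by_h_delta(self):
        grid = SizeGrid(5.0, 100)
        p = analytic_eigenpair(MITOSIS, grid)
        q = EigenPair(p.lam, p.profile.copy(), grid)
        delta = 0.037
        q.profile[40] += delta
        _, ev = eigen_errors(q, p)
        assert ev == pytest.approx(grid.h * delta, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        p = analytic_eigenpair(MITOSIS, SizeGrid(5.0, 100))
        q = analytic_eigenpair(MITOSIS, SizeGrid(5.0, 200))
        with pytest.raises(ValueError):
            eigen_errors(p, q)
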