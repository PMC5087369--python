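"""Unit and property tests for the Gaussian RBF network core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiqp import (
    DegenerateSignalError,
    InvalidInputError,
    InvalidParameterError,
    PartialSelectionError,
    design_matrix,
    fit_rbfnn,
    gaussian_rbf,
    ols_select_centers,
    solve_weights,
)


class TestGaussianRBF:
    def test_identity_at_center(self):
        assert gaussian_rbf(5, 5, 3.0) == 1.0

    @pytest.mark.parametrize("c,sigma", [(0, 1.0), (10, 3.0), (50, 0.5)])
    def test_one_spread_away(self, c, sigma):
        assert gaussian_rbf(c + sigma, c, sigma) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self):
        d = np.linspace(0.1, 20, 17)
        np.testing.assert_allclose(
            gaussian_rbf(7 + d, 7, 2.5), gaussian_rbf(7 - d, 7, 2.5)
        )

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_spread_rejected(self, sigma):
        with pytest.raises(InvalidParameterError):
            gaussian_rbf(1, 1, sigma)


class TestDesignMatrix:
    def test_single_center_column(self):
        phi = design_matrix(3, [2], 1.0)
        np.testing.assert_allclose(
            phi[:, 0], [np.exp(-0.5), 1.0, np.exp(-0.5)]
        )

    def test_huge_spread_rank_deficient_limit(self):
        phi = design_matrix(4, [1, 4], 1e8)
        np.testing.assert_allclose(phi, np.ones((4, 2)), atol=1e-12)

    def test_column_max_at_center_row(self):
        centers = [50, 100, 150]
        phi = design_matrix(200, centers, 10.0)
        for j, c in enumerate(centers):
            assert np.argmax(phi[:, j]) == c - 1
            assert phi[c - 1, j] == 1.0

    def test_center_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            design_matrix(10, [0], 1.0)
        with pytest.raises(InvalidParameterError):
            design_matrix(10, [11], 1.0)


class TestSolveWeights:
    def test_exact_single_rbf_representation(self):
        phi = design_matrix(32, [16], 3.0)
        y = 3.0 * phi[:, 0]
        w = solve_weights(phi, y)
        assert w == pytest.approx([3.0])
        assert np.sum((y - phi @ w) ** 2) < 1e-20

    def test_zero_signal_gives_zero_weights(self):
        phi = design_matrix(16, [4, 12], 2.0)
        w = solve_weights(phi, np.zeros(16))
        np.testing.assert_allclose(w, 0.0)

    def test_residual_orthogonal_to_columns(self, rng):
        phi = design_matrix(32, [5, 13, 21, 29], 3.0)
        y = rng.normal(size=32)
        # independent oracle: solve the normal equations directly
        w_oracle = np.linalg.solve(phi.T @ phi, phi.T @ y)
        w = solve_weights(phi, y)
        np.testing.assert_allclose(w, w_oracle, rtol=1e-8)
        resid = y - phi @ w
        for j in range(phi.shape[1]):
            bound = 1e-8 * np.linalg.norm(y) * np.linalg.norm(phi[:, j])
            assert abs(phi[:, j] @ resid) < bound

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            solve_weights(design_matrix(8, [4], 2.0), np.zeros(9))


class TestOLSSelection:
    def test_signal_in_span_of_one_column(self):
        phi = design_matrix(64, [25], 4.0)
        y = 7.0 * phi[:, 0]
        model, trace = ols_select_centers(y, 4.0, 3)
        assert model.centers[0] == 25
        assert trace.err_ratios[0] == pytest.approx(1.0, abs=1e-9)
        resid = y - design_matrix(64, model.centers, 4.0) @ model.weights
        assert np.sqrt(np.mean(resid**2)) < 1e-9

    def test_triangular_ramp_matches_exhaustive_oracle(self, greedy_refit_oracle):
        n = np.arange(1, 17)
        y = np.minimum(n, 17 - n).astype(float)
        model, _ = ols_select_centers(y, 2.0, 3)
        assert model.centers.tolist() == greedy_refit_oracle(y, 2.0, 3)

    @pytest.mark.parametrize("alpha", [-3.0, 0.25, 10.0])
    def test_scale_invariant_selection_and_err_ratios(self, qrs, alpha):
        m1, t1 = ols_select_centers(qrs.samples, 10.0, 8)
        m2, t2 = ols_select_centers(alpha * qrs.samples, 10.0, 8)
        assert m1.centers.tolist() == m2.centers.tolist()
        np.testing.assert_allclose(t1.err_ratios, t2.err_ratios, rtol=1e-9)

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ols_select_centers(np.zeros(16), 2.0, 2)

    def test_m_larger_than_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            ols_select_centers(np.ones(8), 2.0, 9)

    def test_partial_selection_reports_placed_count(self):
        # a huge spread makes all columns nearly identical: the candidate
        # pool degenerates after very few accepted centers
        y = np.sin(np.linspace(0, np.pi, 30))
        with pytest.raises(PartialSelectionError) as exc:
            ols_select_centers(y, 1e6, 30)
        assert 0 < exc.value.n_placed < 30

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle_on_random_instances(self, greedy_refit_oracle, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(6, 33))
        sigma = float(rng.choice([1.0, 2.0, 4.0]))
        M = int(rng.integers(1, min(6, p) + 1))
        y = rng.normal(size=p)
        model, _ = ols_select_centers(y, sigma, M)
        assert model.centers.tolist() == greedy_refit_oracle(y, sigma, M)


class TestFitProperties:
    def test_exact_sum_of_rbfs_recovered(self):
        phi = design_matrix(100, [30, 55, 80], 6.0)
        y = phi @ np.array([120.0, -40.0, 65.0])
        _, result, _ = fit_rbfnn(y, 3, 6.0)
        assert result.aqr < 1e-6

    def test_energy_conservation(self, qrs, rng):
        cases = [
            (qrs.samples, 20, 10.0),
            (qrs.samples, 20, 12.0),
            (qrs.samples, 40, 10.0),
            (qrs.samples, 10, 2.0),
            (rng.normal(size=64), 12, 3.0),
        ]
        for y, M, sigma in cases:
            _, result, trace = fit_rbfnn(y, M, sigma)
            yty = float(np.asarray(y) @ np.asarray(y))
            lhs = trace.explained_energy() + result.sse
            assert abs(lhs - yty) <= 1e-9 * yty

    def test_sse_monotone_in_neuron_count(self, qrs):
        sses = [fit_rbfnn(qrs.samples, M, 10.0)[1].sse for M in range(2, 31, 4)]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(sses, sses[1:]))

    def test_err_ratios_bounded_and_sum_below_one(self, qrs):
        _, _, trace = fit_rbfnn(qrs.samples, 30, 8.0)
        assert np.all(trace.err_ratios >= 0)
        assert np.all(trace.err_ratios <= 1 + 1e-12)
        assert np.sum(trace.err_ratios) <= 1 + 1e-9

    def test_residual_scales_linearly_and_aqr_unchanged(self, qrs):
        _, r1, _ = fit_rbfnn(qrs.samples, 20, 10.0)
        _, r2, _ = fit_rbfnn(2.0 * qrs.samples, 20, 10.0)
        np.testing.assert_allclose(r2.residual, 2.0 * r1.residual, rtol=1e-9)
        assert r2.aiqp == pytest.approx(2.0 * r1.aiqp, rel=1e-9)
        assert r2.aqr == pytest.approx(r1.aqr, rel=1e-9)

    def test_interpolation_limit_all_centers(self, qrs):
        for sigma in (2.0, 5.0, 10.0):
            model, result, _ = fit_rbfnn(qrs, qrs.p, sigma)
            assert model.M == qrs.p
            assert result.aqr < 1e-4

    def test_interpolation_trace_conserves_energy(self, qrs):
        # the no-selection M = p path keeps Eq.-22-style bookkeeping valid
        # over its accepted orthogonal columns
        model, _, trace = fit_rbfnn(qrs, qrs.p, 5.0)
        phi = design_matrix(qrs.p, model.centers, 5.0)
        # decomposition residual: project y on the accepted orthogonal set
        yty = float(qrs.samples @ qrs.samples)
        captured = trace.explained_energy()
        assert captured <= yty * (1 + 1e-9)
        assert captured >= yty * (1 - 1e-6)  # smooth signal: nearly all energy

    def test_aqr_bounded_by_one(self, rng):
        for _ in range(5):
            y = rng.normal(size=50)
            _, result, _ = fit_rbfnn(y, 5, 2.0)
            assert 0.0 <= result.aqr <= 1.0 + 1e-12
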