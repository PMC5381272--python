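"""MSM estimation against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from glycoclam import msm
from glycoclam.msm import (
    CountMatrix,
    cluster_features,
    count_transitions,
    estimate_transition_matrix,
    implied_timescales,
    its_convergence,
    largest_connected_set,
    slowest_timescale,
    tica_timescales,
)


def _cm(counts, lag_frames=1, dt=1.0):
    return CountMatrix(counts=np.asarray(counts), lag_frames=lag_frames, lag_ns=lag_frames * dt)


class TestClustering:
    def test_two_separated_gaussians_recover_hidden_states(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, size=4000)
        x = np.where(states == 1, 3.7, 4.7) + 0.15 * rng.standard_normal(4000)
        model, (labels,) = cluster_features([x], k=2, seed=0)
        # label permutation allowed
        match = max(np.mean(labels == states), np.mean(labels == 1 - states))
        assert match >= 0.99

    def test_single_cluster_labels_all_zero(self):
        _, (labels,) = cluster_features([np.array([1.0, 2.0, 3.0])], k=1, seed=0)
        assert set(labels) == {0}

    def test_same_seed_gives_identical_centers(self):
        x = np.random.default_rng(3).uniform(3, 5, 500)
        m1, _ = cluster_features([x], k=10, seed=5)
        m2, _ = cluster_features([x], k=10, seed=5)
        assert np.array_equal(m1.centers, m2.centers)

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cluster_features([np.array([3.7, 3.7, 4.7, 4.7])], k=3, seed=0)


class TestCounting:
    def test_hand_enumerated_lag_one(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0])], lag_frames=1, dt=1.0)
        assert np.array_equal(cm.counts, [[1, 1], [1, 1]])

    def test_hand_enumerated_lag_two(self):
        cm = count_transitions([np.array([0, 1, 0, 1])], lag_frames=2, dt=1.0)
        assert np.array_equal(cm.counts, [[1, 0], [0, 1]])

    def test_constant_trajectory_counts_on_diagonal(self):
        cm = count_transitions([np.zeros(17, dtype=int)], lag_frames=1, dt=1.0)
        assert cm.counts[0, 0] == 16

    def test_short_trajectories_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped 1"):
            cm = count_transitions([np.array([0, 1]), np.array([0, 1, 0, 1])], lag_frames=3, dt=1.0)
        assert cm.counts.sum() == 1

    def test_all_short_is_an_error(self):
        with pytest.raises(ValueError, match="shorter than the lag"):
            count_transitions([np.array([0, 1])], lag_frames=5, dt=1.0)

    def test_lag_ns_reflects_frame_spacing(self):
        cm = count_transitions([np.array([0, 1, 0, 1])], lag_frames=2, dt=0.2)
        assert cm.lag_ns == pytest.approx(0.4)


class TestConnectedSet:
    def test_fully_connected_keeps_identity(self):
        cm = _cm([[5, 5], [5, 5]])
        trimmed, active = largest_connected_set(cm)
        assert active.tolist() == [0, 1]
        assert np.array_equal(trimmed.counts, cm.counts)

    def test_block_diagonal_keeps_heavier_block(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:2, :2] = [[50, 50], [50, 50]]  # 200 total
        counts[2:, 2:] = [[5, 5], [5, 5]]  # 10 total
        _, active = largest_connected_set(_cm(counts))
        assert active.tolist() == [0, 1]

    def test_isolated_state_dropped(self):
        counts = [[5, 5, 0], [5, 5, 0], [0, 0, 0]]
        _, active = largest_connected_set(_cm(counts))
        assert active.tolist() == [0, 1]

    def test_one_way_state_excluded_from_strong_component(self):
        # state 2 is reachable but never leaves back: not strongly connected
        counts = [[5, 5, 1], [5, 5, 0], [0, 0, 2]]
        _, active = largest_connected_set(_cm(counts))
        assert 2 not in active.tolist()


class TestTransitionMatrix:
    def test_symmetric_counts_give_symmetric_matrix_and_uniform_pi(self):
        model = estimate_transition_matrix(_cm([[8, 2], [2, 8]]), reversible=True)
        assert np.allclose(model.transition_matrix, [[0.8, 0.2], [0.2, 0.8]], atol=1e-9)
        assert np.allclose(model.stationary_distribution, [0.5, 0.5], atol=1e-9)

    def test_analytic_stationary_distribution(self):
        # counts exactly 10x the rows of T = [[0.9,0.1],[0.2,0.8]]
        model = estimate_transition_matrix(_cm([[90, 10], [20, 80]]), reversible=False)
        assert np.allclose(model.transition_matrix, [[0.9, 0.1], [0.2, 0.8]], atol=1e-12)
        assert np.allclose(model.stationary_distribution, [2 / 3, 1 / 3], atol=1e-10)

    def test_reversible_estimate_satisfies_detailed_balance(self):
        rng = np.random.default_rng(1)
        C = rng.integers(1, 50, size=(5, 5))
        model = estimate_transition_matrix(_cm(C), reversible=True)
        pi, T = model.stationary_distribution, model.transition_matrix
        flux = pi[:, None] * T
        assert np.abs(flux - flux.T).max() < 1e-8
        assert np.abs(T.sum(axis=1) - 1).max() < 1e-10
        assert np.abs(pi @ T - pi).max() < 1e-8

    @pytest.mark.parametrize("n_states", [2, 3, 4])
    def test_reversible_mle_matches_exhaustive_maximization(self, n_states):
        """Independent oracle: directly maximize the transition likelihood over
        the reversible parametrization T_ij = x_ij / sum_j x_ij, x symmetric."""
        rng = np.random.default_rng(n_states)
        C = rng.integers(1, 40, size=(n_states, n_states)).astype(float)
        model = estimate_transition_matrix(_cm(C.astype(int)), reversible=True)

        iu = np.triu_indices(n_states)

        def negloglik(log_x_flat):
            x = np.zeros((n_states, n_states))
            x[iu] = np.exp(log_x_flat)
            x = x + np.triu(x, 1).T
            T = x / x.sum(axis=1, keepdims=True)
            return -np.sum(C * np.log(T))

        x0 = np.log((C + C.T)[iu])
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"maxiter": 200000, "xatol": 1e-12, "fatol": 1e-14})
        x = np.zeros((n_states, n_states))
        x[iu] = np.exp(res.x)
        x = x + np.triu(x, 1).T
        T_oracle = x / x.sum(axis=1, keepdims=True)
        assert np.abs(model.transition_matrix - T_oracle).max() < 1e-6

    def test_nonconvergence_reports_residual(self):
        with pytest.raises(RuntimeError, match="residual"):
            estimate_transition_matrix(_cm([[90, 10], [2, 8]]), reversible=True, max_iter=1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_stochastic_and_stationary_invariants(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        C = rng.integers(1, 30, size=(k, k))
        for reversible in (True, False):
            model = estimate_transition_matrix(_cm(C), reversible=reversible)
            T, pi = model.transition_matrix, model.stationary_distribution
            assert np.abs(T.sum(axis=1) - 1).max() < 1e-10
            assert np.abs(pi @ T - pi).max() < 1e-8
            assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # T = [[0.9,0.1],[0.2,0.8]]: trace 1.7, det 0.70 -> lambda_2 = 0.7
        model = estimate_transition_matrix(
            _cm([[90, 10], [20, 80]], lag_frames=1, dt=1.0), reversible=False
        )
        ts = implied_timescales(model)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.7), rel=1e-10)

    def test_identity_matrix_has_no_finite_timescale(self):
        model = estimate_transition_matrix(_cm([[10, 0], [0, 10]]))
        # identity trims to a single absorbing state: no relaxation process
        assert np.isnan(slowest_timescale(model))

    def test_definition_at_reference_lag(self):
        # lambda_2 = e^-1 at lag 256 ns -> timescale exactly 256 ns
        lam = np.exp(-1)
        p = (1 - lam) / 2
        T = np.array([[1 - p, p], [p, 1 - p]])
        C = np.round(T * 1e6).astype(int)
        model = estimate_transition_matrix(_cm(C, lag_frames=1280, dt=0.2), reversible=False)
        assert slowest_timescale(model) == pytest.approx(256.0, rel=1e-4)


class TestITSGrid:
    def test_markovian_chain_flat_in_lag_and_two_rows(self, small_ensemble):
        spec, ens = small_ensemble
        table = its_convergence(ens, lags_ns=[2.0, 4.0], k=6, seed=0)
        assert len(table) == 2
        t1, t2 = table["slowest_timescale_ns"]
        assert t1 == pytest.approx(t2, rel=0.15)  # flat up to estimator noise
        assert t1 == pytest.approx(spec.relaxation_time, rel=0.15)


class TestTICA:
    def test_1d_eigenvalue_equals_lag_autocorrelation(self, small_ensemble):
        _, ens = small_ensemble
        lag = 10
        model = tica_timescales(ens, lag_frames=lag)
        # direct autocorrelation of the centered series, same symmetrized
        # estimator definition
        xs = [x[:, None] for x in ens.d]
        n = sum(2 * (len(x) - lag) for x in xs)
        mean = sum(x[:-lag].sum() + x[lag:].sum() for x in xs) / n
        num = sum(((x[:-lag] - mean) * (x[lag:] - mean)).sum() * 2 for x in xs)
        den = sum(
            ((x[:-lag] - mean) ** 2).sum() + ((x[lag:] - mean) ** 2).sum() for x in xs
        )
        assert model.eigenvalues[0] == pytest.approx(num / den, rel=1e-8)

    def test_alternating_series_flagged_undefined(self):
        x = np.tile([1.0, -1.0], 50)
        model = tica_timescales([x], lag_frames=1, dt=1.0)
        assert model.eigenvalues[0] == pytest.approx(-1.0, abs=1e-9)
        assert np.isnan(model.timescales[0])

    def test_ornstein_uhlenbeck_correlation_time_recovered(self):
        # exact AR(1) discretization of an OU process with correlation time theta
        theta, dt, n = 10.0, 1.0, 200_000  # sampling 20000 x theta
        rho = np.exp(-dt / theta)
        rng = np.random.default_rng(12)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = np.sqrt(1 - rho**2) * rng.standard_normal(n - 1)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t - 1]
        model = tica_timescales([x], lag_frames=5, dt=dt)
        assert model.slowest_timescale == pytest.approx(theta, rel=0.10)
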