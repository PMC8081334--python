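"""Forward-backward inference, dynamics updates and the EM fits."""

import numpy as np
import pytest

from hmmpca import (
    FitOptions,
    StateTimeCourses,
    TimeSeriesDataset,
    fit_hmm_gaussian,
    fit_hmm_pca,
    fit_mix_pca,
    forward_backward,
    held_out_log_evidence,
    m_step_dynamics,
    pca_project,
    ppca_closed_form,
    weighted_covariance,
)
from hmmpca.models import _ppca_loglik

from conftest import brute_force_forward_backward


def random_stochastic(rng, K):
    Theta = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    return Theta, pi


class TestForwardBackward:
    def test_single_state(self):
        logB = np.array([[-1.0], [-2.0], [-0.5]])
        stc, ev = forward_backward(logB, np.eye(1), np.ones(1), [1])
        np.testing.assert_allclose(stc.gamma, 1.0)
        assert ev == pytest.approx(-3.5)

    def test_symmetry_gives_uniform_posteriors(self):
        T, K = 6, 3
        logB = np.full((T, K), -1.3)
        Theta = np.full((K, K), 1 / K)
        stc, _ = forward_backward(logB, Theta, np.full(K, 1 / K), [1])
        np.testing.assert_allclose(stc.gamma, 1 / K, atol=1e-12)

    def test_two_step_example(self):
        """Two time points, two states — checked against full path enumeration."""
        logB = np.log(np.array([[1.0, 0.5], [0.5, 1.0]]))
        Theta = np.array([[0.9, 0.1], [0.1, 0.9]])
        stc, ev = forward_backward(logB, Theta, np.array([0.5, 0.5]), [1])
        assert stc.gamma[0, 0] == pytest.approx(0.53659, abs=1e-5)
        assert stc.gamma[1, 0] == pytest.approx(0.46341, abs=1e-5)
        assert np.exp(ev) == pytest.approx(0.5125, abs=1e-10)

    @pytest.mark.parametrize("T,K,n_sessions", [(4, 2, 1), (6, 2, 2), (8, 3, 1), (7, 3, 2)])
    def test_matches_brute_force_enumeration(self, rng, T, K, n_sessions):
        for _ in range(5):
            logB = rng.normal(scale=1.5, size=(T, K))
            Theta, pi = random_stochastic(rng, K)
            starts = [1] if n_sessions == 1 else [1, T // 2 + 1]
            stc, ev = forward_backward(logB, Theta, pi, starts)
            g0, xi0, ev0 = brute_force_forward_backward(logB, Theta, pi, starts)
            np.testing.assert_allclose(stc.gamma, g0, atol=1e-10)
            np.testing.assert_allclose(stc.pairwise, xi0, atol=1e-10)
            assert ev == pytest.approx(ev0, abs=1e-10)

    def test_session_reset_equals_separate_evaluation(self, rng):
        """Concatenating sessions and summing per-session evidences agree."""
        K = 2
        logB = rng.normal(size=(10, K))
        Theta, pi = random_stochastic(rng, K)
        _, ev_joint = forward_backward(logB, Theta, pi, [1, 6])
        _, ev_a = forward_backward(logB[:5], Theta, pi, [1])
        _, ev_b = forward_backward(logB[5:], Theta, pi, [1])
        assert ev_joint == pytest.approx(ev_a + ev_b, abs=1e-10)

    def test_underflow_resistant_at_long_T(self, rng):
        T = 100_000
        logB = rng.normal(loc=-700.0, size=(T, 2))
        Theta, pi = random_stochastic(rng, 2)
        stc, ev = forward_backward(logB, Theta, pi, [1])
        assert np.isfinite(ev)
        assert np.all(np.isfinite(stc.gamma))

    def test_impossible_observation_raises(self):
        logB = np.array([[0.0, 0.0], [-np.inf, -np.inf]])
        with pytest.raises(FloatingPointError, match="2"):
            forward_backward(logB, np.full((2, 2), 0.5), np.full(2, 0.5), [1])


class TestDynamicsUpdate:
    def test_deterministic_alternation(self):
        gamma = np.zeros((6, 2))
        gamma[::2, 0] = 1.0
        gamma[1::2, 1] = 1.0
        xi = np.zeros((2, 2))
        for t in range(5):
            xi += np.outer(gamma[t], gamma[t + 1])
        Theta, pi = m_step_dynamics(StateTimeCourses(gamma, xi), [1])
        np.testing.assert_allclose(Theta, [[0, 1], [1, 0]], atol=1e-12)
        np.testing.assert_allclose(pi, [1, 0], atol=1e-12)

    def test_uniform_gamma_gives_uniform_dynamics(self):
        gamma = np.full((8, 2), 0.5)
        xi = np.full((2, 2), 7 / 4)
        Theta, pi = m_step_dynamics(StateTimeCourses(gamma, xi), [1])
        np.testing.assert_allclose(Theta, 0.5)
        np.testing.assert_allclose(pi, 0.5)

    def test_known_count_table(self):
        gamma = np.full((4, 2), 0.5)
        xi = np.array([[8.0, 2.0], [1.0, 9.0]])
        Theta, _ = m_step_dynamics(StateTimeCourses(gamma, xi), [1])
        np.testing.assert_allclose(Theta, [[0.8, 0.2], [0.1, 0.9]])

    def test_zero_outgoing_mass_warns_uniform(self):
        gamma = np.column_stack([np.ones(4), np.zeros(4)])
        xi = np.array([[3.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            Theta, _ = m_step_dynamics(StateTimeCourses(gamma, xi), [1])
        np.testing.assert_allclose(Theta[1], 0.5)


class TestFits:
    def test_hmm_pca_recovers_two_states(self, scenario1_small):
        from hmmpca import permutation_accuracy

        data, truth = scenario1_small
        opts = FitOptions(n_states=2, n_components=2, n_restarts=2, seed=0)
        model, stc = fit_hmm_pca(data, opts)
        assert permutation_accuracy(stc, truth.state_path) > 0.95
        trace = np.asarray(model.fit_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_single_state_matches_closed_form(self, small_dataset):
        opts = FitOptions(
            n_states=1, n_components=2, n_restarts=1, seed=0, standardize=True
        )
        model, _ = fit_hmm_pca(small_dataset, opts)
        D = small_dataset.standardized().values
        ref = ppca_closed_form(weighted_covariance(D, np.ones(D.shape[0])), 2)
        np.testing.assert_allclose(
            model.states[0].covariance, ref.covariance, atol=1e-4
        )
        assert model.states[0].noise_variance == pytest.approx(
            ref.noise_variance, abs=1e-4
        )

    def test_mix_pca_single_state_matches_closed_form(self, small_dataset):
        opts = FitOptions(n_states=1, n_components=2, n_restarts=1, seed=0)
        model, _ = fit_mix_pca(small_dataset, opts)
        D = small_dataset.standardized().values
        ref = ppca_closed_form(weighted_covariance(D, np.ones(D.shape[0])), 2)
        np.testing.assert_allclose(
            model.states[0].covariance, ref.covariance, atol=1e-4
        )

    def test_equal_rows_hmm_equals_mixture_posterior(self, small_dataset, rng):
        """An HMM whose transition rows all equal w is an independent mixture
        with weights w: posteriors must coincide."""
        D = small_dataset.standardized().values
        states = [
            ppca_closed_form(weighted_covariance(D, w), 2)
            for w in rng.dirichlet(np.ones(2), size=D.shape[0]).T
        ]
        w = np.array([0.3, 0.7])
        logB = _ppca_loglik(D, states)
        Theta = np.vstack([w, w])
        stc, _ = forward_backward(logB, Theta, w, small_dataset.session_starts)
        mix = np.exp(logB + np.log(w))
        mix /= mix.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(stc.gamma, mix, atol=1e-8)

    def test_gaussian_single_state_is_sample_covariance(self, small_dataset):
        opts = FitOptions(
            n_states=1, n_components=2, n_restarts=1, seed=0, standardize=False
        )
        model, _ = fit_hmm_gaussian(small_dataset, opts)
        D = small_dataset.values
        S = D.T @ D / D.shape[0]
        np.testing.assert_allclose(model.states[0], S, rtol=1e-4, atol=1e-6)

    def test_em_monotone_all_models(self, small_dataset):
        opts = FitOptions(
            n_states=2, n_components=2, n_restarts=1, seed=3, max_iterations=40
        )
        for fitter in (fit_hmm_pca, fit_mix_pca, fit_hmm_gaussian):
            model, _ = fitter(small_dataset, opts)
            trace = np.asarray(model.fit_trace)
            assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1])), fitter

    def test_held_out_on_training_data_matches_trace(self, small_dataset):
        opts = FitOptions(
            n_states=2, n_components=2, n_restarts=1, seed=1, max_iterations=30
        )
        for fitter in (fit_hmm_pca, fit_mix_pca):
            model, _ = fitter(small_dataset, opts)
            assert held_out_log_evidence(model, small_dataset) == pytest.approx(
                model.fit_trace[-1], abs=1e-8
            )

    def test_multi_state_beats_single_state_on_switching_data(self):
        """Model selection sanity: on data generated by a two-state process,
        the K=2 fit has higher held-out evidence than the K=1 fit on unseen
        sessions of the same process."""
        from hmmpca import generate_scenario1
        from hmmpca.metrics import _subset_sessions

        data, _ = generate_scenario1(
            p0=2, sessions=4, session_length=300, noise_sd=0.1, seed=7
        )
        train = _subset_sessions(data, [0, 1])
        test = _subset_sessions(data, [2, 3])
        m2, _ = fit_hmm_pca(train, FitOptions(n_states=2, n_components=2, n_restarts=2, seed=0))
        m1, _ = fit_hmm_pca(train, FitOptions(n_states=1, n_components=2, n_restarts=1, seed=0))
        assert held_out_log_evidence(m2, test) > held_out_log_evidence(m1, test)

    def test_dimension_mismatch_raises(self, small_dataset):
        opts = FitOptions(n_states=1, n_components=2, n_restarts=1, seed=0)
        model, _ = fit_hmm_pca(small_dataset, opts)
        bad = TimeSeriesDataset(np.random.default_rng(0).standard_normal((20, 3)))
        with pytest.raises(ValueError):
            held_out_log_evidence(model, bad)


class TestPCAProject:
    def test_full_rank_projection_is_lossless(self, small_dataset):
        proj, W, evs = pca_project(small_dataset, small_dataset.n_regions)
        centred = small_dataset.values - small_dataset.values.mean(axis=0)
        np.testing.assert_allclose(proj.values @ W.T, centred, atol=1e-10)

    def test_variance_ordering_and_orthogonality(self, small_dataset):
        proj, W, evs = pca_project(small_dataset, 4)
        var = proj.values.var(axis=0)
        assert np.all(np.diff(var) <= 1e-10)
        corr = np.corrcoef(proj.values.T)
        np.testing.assert_allclose(corr - np.diag(np.diag(corr)), 0.0, atol=1e-10)
        assert evs.shape == (small_dataset.n_regions,)

    def test_too_many_components_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            pca_project(small_dataset, small_dataset.n_regions + 1)


class TestDatasetValidation:
    def test_session_starts_must_begin_at_one(self, rng):
        with pytest.raises(ValueError):
            TimeSeriesDataset(rng.standard_normal((10, 2)), [2, 5])

    def test_short_session_rejected(self, rng):
        with pytest.raises(ValueError):
            TimeSeriesDataset(rng.standard_normal((10, 2)), [1, 10])

    def test_standardize_per_session(self, rng):
        ds = TimeSeriesDataset(5 + 3 * rng.standard_normal((40, 3)), [1, 21])
        std = ds.standardized()
        for sl in std.session_slices():
            np.testing.assert_allclose(std.values[sl].mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(std.values[sl].std(axis=0), 1.0, atol=1e-12)
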