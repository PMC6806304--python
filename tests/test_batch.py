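import numpy as np
import pytest

from semigait import (
    ObservationSequence,
    StateSpace,
    build_transition_mask,
    complete_stats,
    em_fit,
    init_from_labels,
    m_step,
    make_pseudo_imu,
    params_from_stats,
    random_params,
    sample_model,
    smooth,
)
from semigait.inference import PosteriorSet

from conftest import SMALL_SPACES, make_instance


def _posterior_from_labels(states, space, obs):
    """A degenerate PosteriorSet with all mass on a known composite path
    (ell = 0, so every transition is a free one)."""
    n = len(states)
    gamma = np.zeros((n, space.n_states))
    gamma[np.arange(n), states] = 1.0
    gamma_v = gamma.reshape(n, space.n_v, space.n_dur).sum(axis=2)
    resp = gamma_v[:, :, None]
    trans_free = np.zeros((space.n_v, space.n_v, space.n_dur))
    for a, b in zip(states[:-1], states[1:]):
        trans_free[a, b, 0] += 1.0
    return PosteriorSet(
        alpha_hat=gamma, beta_hat=np.ones_like(gamma),
        log_scale=np.zeros(n), gamma=gamma, gamma_v=gamma_v, resp=resp,
        trans_free=trans_free, loglik=0.0,
    )


class TestMStep:
    def test_single_state_recovers_sample_moments(self):
        """One cell, one component: the M-step is the sample mean and the
        biased (1/N) covariance (well-conditioned, so the eigenvalue floor
        leaves it untouched)."""
        space = StateSpace(r=1, tau=1, ell=0, kappa=1, w=3)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 0)
        _, obs = sample_model(params, space, 300, seed=1)
        post = smooth(obs, params, space)
        new = m_step(post, obs, space, mask)
        Y = obs.values
        np.testing.assert_allclose(new.means[0, 0], Y.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(new.covs[0, 0], np.cov(Y.T, ddof=0), atol=1e-10)

    def test_one_hot_responsibilities_pin_weights(self):
        """If all responsibility falls on component 1 the weights become
        (1, 0)."""
        space = StateSpace(r=1, tau=1, ell=0, kappa=2, w=1)
        mask = build_transition_mask(space)
        n = 10
        Y = np.random.default_rng(0).normal(size=(n, 1))
        obs = ObservationSequence(Y)
        gamma = np.ones((n, 1))
        resp = np.zeros((n, 1, 2))
        resp[:, 0, 0] = 1.0
        post = PosteriorSet(
            alpha_hat=gamma, beta_hat=gamma, log_scale=np.zeros(n),
            gamma=gamma, gamma_v=gamma, resp=resp,
            trans_free=np.full((1, 1, 1), float(n - 1)), loglik=0.0,
        )
        prev = random_params(space, mask, 1)
        new = m_step(post, obs, space, mask, prev=prev)
        np.testing.assert_allclose(new.weights[0], [1.0, 0.0], atol=1e-12)

    def test_fully_observed_path_gives_count_transitions(self):
        """One-hot posteriors from a hand-labelled 10-step toy path: pstar
        equals the empirical transition counts, normalized.

        Path over (act, phase) cells 0,0,1,1,1,0,0,1,0,0 with ell=0 gives
        counts row0 = {0->0: 3, 0->1: 2}, row1 = {1->0: 2, 1->1: 2}."""
        space = StateSpace(r=1, tau=2, ell=0, kappa=1, w=1)
        mask = build_transition_mask(space)
        states = np.array([0, 0, 1, 1, 1, 0, 0, 1, 0, 0])
        obs = ObservationSequence(np.random.default_rng(2).normal(size=(10, 1)))
        post = _posterior_from_labels(states, space, obs)
        new = m_step(post, obs, space, mask)
        np.testing.assert_allclose(new.pstar[0], [3 / 5, 2 / 5], atol=1e-12)
        np.testing.assert_allclose(new.pstar[1], [2 / 4, 2 / 4], atol=1e-12)

    def test_mask_zeros_preserved(self):
        space = StateSpace(r=2, tau=4, ell=1, kappa=1, w=2)
        mask = build_transition_mask(space)
        params, mask, _, obs = make_instance(space, seed=5, n=200)
        for _ in range(3):
            post = smooth(obs, params, space)
            params = m_step(post, obs, space, mask, prev=params)
            assert np.all(params.pstar[~mask.allowed] == 0.0)


class TestSufficientStats:
    @pytest.mark.parametrize("space_idx", range(len(SMALL_SPACES)))
    def test_remark_equivalence(self, space_idx):
        """params_from_stats(complete_stats(.)) reproduces the direct M-step
        field by field."""
        space = SMALL_SPACES[space_idx]
        params, mask, _, obs = make_instance(space, seed=60 + space_idx, n=40)
        post = smooth(obs, params, space)
        direct = m_step(post, obs, space, mask, prev=params)
        via_stats = params_from_stats(
            complete_stats(post, obs), space, mask, prev=params
        )
        for field in ("zeta", "pstar", "pdur", "weights", "means", "covs"):
            np.testing.assert_allclose(
                getattr(via_stats, field), getattr(direct, field), atol=1e-12,
                err_msg=field,
            )

    def test_component_occupancies_sum_to_cell_occupancy(self, small_instance):
        params, mask, _, obs = small_instance
        space = SMALL_SPACES[1]
        post = smooth(obs, params, space)
        stats = complete_stats(post, obs)
        np.testing.assert_allclose(stats.s3.sum(axis=1), stats.s2_marg, atol=1e-10)
        np.testing.assert_allclose(stats.s2.sum(), 1.0, atol=1e-10)
        assert np.allclose(stats.s5, np.swapaxes(stats.s5, 2, 3), atol=1e-12)


class TestEmFit:
    def test_monotone_loglik(self):
        for seed in range(5):
            space = SMALL_SPACES[seed % len(SMALL_SPACES)]
            params, mask, _, obs = make_instance(space, seed=100 + seed, n=80)
            init = random_params(space, mask, seed=200 + seed)
            report = em_fit(obs, init, space, mask, max_iter=15, tol=0.0)
            diffs = np.diff(report.loglik_trace)
            assert (diffs >= -1e-8 * np.maximum(1, np.abs(report.loglik_trace[:-1]))).all()

    def test_local_optimum_terminates_immediately(self):
        """Starting EM at a fixed point leaves the loglik flat and stops
        after one effective iteration."""
        space = StateSpace(r=1, tau=1, ell=0, kappa=1, w=2)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 0)
        _, obs = sample_model(params, space, 100, seed=1)
        post = smooth(obs, params, space)
        opt = m_step(post, obs, space, mask)  # exact MLE for this model
        report = em_fit(obs, opt, space, mask, max_iter=50, tol=1e-9)
        assert report.converged and report.n_iter == 2
        assert report.loglik_trace[1] == pytest.approx(report.loglik_trace[0], abs=1e-6)

    def test_trivial_model_matches_closed_form_mle_in_one_iteration(self):
        space = StateSpace(r=1, tau=1, ell=0, kappa=1, w=2)
        mask = build_transition_mask(space)
        truth = random_params(space, mask, 7)
        _, obs = sample_model(truth, space, 500, seed=8)
        init = random_params(space, mask, 9)
        report = em_fit(obs, init, space, mask, max_iter=2, tol=0.0)
        Y = obs.values
        np.testing.assert_allclose(report.params.means[0, 0], Y.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            report.params.covs[0, 0], np.cov(Y.T, ddof=0), atol=1e-8,
        )


class TestInitFromLabels:
    def test_kappa_one_moments_with_known_phases(self):
        """With true phase labels supplied and kappa=1, the per-cell means
        equal the per-cell feature means."""
        raw, labels, phases = make_pseudo_imu(
            [(0, 20.0), (1, 20.0)], rate=50.0, seed=0, noise=0.1
        )
        space = StateSpace(r=2, tau=4, ell=4, kappa=1, w=12)
        mask = build_transition_mask(space)
        params, obs = init_from_labels(
            raw, labels, space, mask, feature_window=8, phase_labels=phases
        )
        v = labels * 4 + phases
        for cell in range(space.n_v):
            np.testing.assert_allclose(
                params.means[cell, 0], obs.values[v == cell].mean(axis=0),
                atol=1e-8,
            )

    def test_pseudo_phases_better_than_chance_and_finite_loglik(self):
        raw, labels, phases = make_pseudo_imu(
            [(0, 30.0), (1, 30.0)], rate=50.0, seed=1, noise=0.1
        )
        space = StateSpace(r=2, tau=4, ell=4, kappa=2, w=12)
        mask = build_transition_mask(space)
        params, obs = init_from_labels(
            raw, labels, space, mask, feature_window=8, seed=0
        )
        # pseudo phases are only defined up to a rotation of the cycle:
        # check agreement maximized over the 4 rotations beats chance
        best = max(
            np.mean((obs.phase_labels + s) % 4 == phases) for s in range(4)
        )
        assert best > 0.3  # chance is 0.25
        post = smooth(obs, params, space)
        assert np.isfinite(post.loglik)

    def test_uniform_duration_recovery_from_runs(self):
        """Single activity, immediate-exit switch matrix, uniform sojourns:
        run lengths are d+1, so the run-length estimator recovers a roughly
        uniform pdur."""
        space = StateSpace(r=1, tau=4, ell=3, kappa=1, w=2)
        mask = build_transition_mask(space)
        params = random_params(space, mask, 3)
        for u in range(4):
            params.pstar[u] = 0.0
            params.pstar[u, (u + 1) % 4] = 1.0  # leave as soon as free
        params.pdur[:] = 0.25
        path, _ = sample_model(params, space, 20000, seed=4)
        from semigait.batch import _duration_from_runs

        pdur = _duration_from_runs(path.v(space), space.n_v, space.ell)
        np.testing.assert_allclose(pdur, 0.25, atol=0.03)

    def test_small_activity_aborts(self):
        raw, labels, phases = make_pseudo_imu([(0, 10.0)], rate=50.0, seed=0)
        labels = labels.copy()
        labels[:5] = 1  # activity 1 has only 5 samples
        space = StateSpace(r=2, tau=4, ell=2, kappa=2, w=12)
        mask = build_transition_mask(space)
        with pytest.raises(ValueError, match="activity 1"):
            init_from_labels(raw, labels, space, mask, feature_window=8)
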