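"""HMM estimator: oracle equivalence, EM behavior, parameter recovery."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

import rg4fret as r
from rg4fret.hmm import FitResult, GaussianHmm

from conftest import pure_emission_traces


def _path_log_probs(model: GaussianHmm, obs: np.ndarray) -> np.ndarray:
    """Log probability of every one of the K^T state paths (lexicographic)."""
    K, T = model.n_states, len(obs)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_distribution)
    logB = norm.logpdf(obs[:, None], model.means, model.sds)  # (T, K)
    paths = np.array(list(itertools.product(range(K), repeat=T)))  # (K^T, T)
    lp = logpi[paths[:, 0]] + logB[np.arange(T), paths].sum(axis=1)
    if T > 1:
        lp = lp + logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return lp


def brute_force_loglik(model: GaussianHmm, obs: np.ndarray) -> float:
    """Log marginal likelihood by explicit summation over all state paths."""
    return float(logsumexp(_path_log_probs(model, obs)))


def brute_force_viterbi(model: GaussianHmm, obs: np.ndarray) -> np.ndarray:
    """Argmax path by enumeration; ties resolved toward the lexicographically
    smallest path, matching the decoder's lower-state-index convention."""
    K, T = model.n_states, len(obs)
    lp = _path_log_probs(model, obs)
    best = int(np.flatnonzero(lp >= lp.max() - 1e-12)[0])
    return np.array(list(itertools.product(range(K), repeat=T)))[best]


def random_model(rng, K):
    means = np.sort(rng.uniform(0.1, 0.9, K)) + np.arange(K) * 1e-3
    sds = rng.uniform(0.03, 0.12, K)
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi0 = rng.dirichlet(np.ones(K))
    return GaussianHmm(means, sds, A, pi0)


class TestForward:
    def test_single_state_is_iid_gaussian(self):
        model = GaussianHmm([0.5], [0.06], [[1.0]], [1.0])
        rng = np.random.default_rng(0)
        obs = rng.normal(0.5, 0.06, 200)
        expected = norm.logpdf(obs, 0.5, 0.06).sum()
        assert r.forward_log_likelihood(model, obs) == pytest.approx(expected, abs=1e-9)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            K = rng.integers(2, 4)
            T = rng.integers(2, 6)
            model = random_model(rng, K)
            obs = rng.uniform(0, 1, T)
            assert r.forward_log_likelihood(model, obs) == pytest.approx(
                brute_force_loglik(model, obs), abs=1e-9
            )

    def test_long_trace_does_not_underflow(self):
        model = GaussianHmm([0.3, 0.7], [0.05, 0.05],
                            [[0.95, 0.05], [0.05, 0.95]], [0.5, 0.5])
        rng = np.random.default_rng(2)
        obs = rng.uniform(0, 1, 20_000)
        ll = r.forward_log_likelihood(model, obs)
        assert np.isfinite(ll)

    def test_state_duplication_never_decreases_likelihood(self):
        # splitting one state's mass across two identical copies leaves the
        # marginal likelihood unchanged, so the larger model nests the smaller
        rng = np.random.default_rng(3)
        model = GaussianHmm([0.3, 0.7], [0.05, 0.08],
                            [[0.9, 0.1], [0.2, 0.8]], [0.6, 0.4])
        obs = rng.uniform(0, 1, 12)
        A = model.transition_matrix
        A3 = np.array(
            [
                [A[0, 0], A[0, 1] / 2, A[0, 1] / 2],
                [A[1, 0], A[1, 1] / 2, A[1, 1] / 2],
                [A[1, 0], A[1, 1] / 2, A[1, 1] / 2],
            ]
        )
        dup = GaussianHmm([0.3, 0.7, 0.7], [0.05, 0.08, 0.08], A3, [0.6, 0.2, 0.2])
        ll2 = r.forward_log_likelihood(model, obs)
        ll3 = r.forward_log_likelihood(dup, obs)
        assert ll3 >= ll2 - 1e-9


class TestViterbi:
    def test_single_state_constant(self):
        model = GaussianHmm([0.5], [0.06], [[1.0]], [1.0])
        assert np.all(r.viterbi_decode(model, np.full(10, 0.5)) == 0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            model = random_model(rng, int(rng.integers(2, 4)))
            obs = rng.uniform(0, 1, int(rng.integers(2, 8)))
            np.testing.assert_array_equal(
                r.viterbi_decode(model, obs), brute_force_viterbi(model, obs)
            )

    def test_observations_at_state_mean_give_constant_path(self):
        model = GaussianHmm([0.2, 0.8], [0.03, 0.03],
                            [[0.98, 0.02], [0.02, 0.98]], [0.5, 0.5])
        assert np.all(r.viterbi_decode(model, np.full(30, 0.8)) == 1)

    def test_tie_breaks_toward_lower_state_index(self):
        # two indistinguishable states: every path probability ties
        model = GaussianHmm([0.5, 0.5 + 1e-12], [0.05, 0.05],
                            [[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5])
        assert np.all(r.viterbi_decode(model, np.full(6, 0.5)) == 0)


class TestBaumWelch:
    def test_single_state_mean_recovery(self):
        rng = np.random.default_rng(5)
        obs = [rng.normal(0.6, 0.05, 400) for _ in range(5)]
        fit = r.baum_welch_fit(obs, 1, seed=0)
        se = 0.05 / np.sqrt(2000)
        assert abs(fit.model.means[0] - 0.6) < 3 * se

    def test_three_state_recovery(self):
        obs, _ = pure_emission_traces(r.atrg3_model(), 120, 200, seed=6)
        fit = r.baum_welch_fit(obs, 3, n_restarts=3, seed=0)
        np.testing.assert_allclose(fit.model.means, [0.32, 0.50, 0.74], atol=0.02)
        assert fit.ll_history.size >= 2
        assert np.all(np.diff(fit.ll_history) >= -1e-8 * np.abs(fit.ll_history[:-1]))

    def test_transition_matrix_recovery(self):
        model = r.rg4_model()
        obs, _ = pure_emission_traces(model, 500, 200, seed=7)  # 1e5 pooled frames
        fit = r.baum_welch_fit(obs, 4, n_restarts=2, seed=1, tol=1e-5)
        P, A = model.transition_matrix, fit.model.transition_matrix
        n_from = 100_000 / 4  # roughly uniform stationary occupancy
        for i in range(4):
            for j in range(4):
                se = np.sqrt(max(P[i, j] * (1 - P[i, j]), 1e-9) / n_from)
                assert abs(A[i, j] - P[i, j]) < 3 * se + 2e-3

    def test_initialization_permutation_invariance(self):
        obs, _ = pure_emission_traces(r.atrg3_model(), 40, 150, seed=8)
        init = GaussianHmm(
            [0.3, 0.5, 0.75], [0.06] * 3,
            np.full((3, 3), 1 / 3), [1 / 3] * 3,
        )
        perm = [2, 0, 1]
        P = np.asarray(init.transition_matrix)[np.ix_(perm, perm)]
        init_perm = GaussianHmm(np.asarray(init.means)[perm], [0.06] * 3, P, [1 / 3] * 3)
        fit_a = r.baum_welch_fit(obs, 3, init=init, seed=0)
        fit_b = r.baum_welch_fit(obs, 3, init=init_perm, seed=0)
        np.testing.assert_allclose(fit_a.model.means, fit_b.model.means, atol=1e-6)
        np.testing.assert_allclose(
            fit_a.model.transition_matrix, fit_b.model.transition_matrix, atol=1e-5
        )

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="pooled observations"):
            r.baum_welch_fit([np.array([0.5, 0.6])], 3)

    def test_matches_hmmlearn_forward_score(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = GaussianHmm([0.32, 0.5, 0.74], [0.06, 0.05, 0.07],
                            [[0.9, 0.08, 0.02], [0.1, 0.8, 0.1], [0.02, 0.08, 0.9]],
                            [0.3, 0.4, 0.3])
        rng = np.random.default_rng(9)
        obs = rng.uniform(0, 1, 300)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = np.asarray(model.initial_distribution)
        ref.transmat_ = np.asarray(model.transition_matrix)
        ref.means_ = np.asarray(model.means)[:, None]
        ref.covars_ = np.asarray(model.sds)[:, None] ** 2
        assert r.forward_log_likelihood(model, obs) == pytest.approx(
            ref.score(obs[:, None]), abs=1e-6
        )


class TestStateCountSelection:
    def test_single_well_separated_state(self):
        rng = np.random.default_rng(10)
        obs = [np.clip(rng.normal(0.5, 0.05, 200), 0, 1) for _ in range(10)]
        sel = r.select_state_count(obs, range(1, 4), seed=0, n_restarts=2)
        assert sel.n_states == 1

    def test_bic_formula(self):
        fit = FitResult(
            model=GaussianHmm([0.3, 0.7], [0.05, 0.05],
                              [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5]),
            log_likelihood=-100.0, ll_history=np.array([-100.0]),
            n_iter=1, converged=True, n_observations=500,
        )
        assert fit.n_parameters == 2 * 2 + 2 * 2 - 1
        assert fit.bic == pytest.approx(200.0 + 7 * np.log(500))


class TestIdealize:
    def _fret(self, eff):
        eff = np.asarray(eff, float)
        return r.FretTrace(
            molecule_id="m", efficiency=eff, valid=np.ones(eff.size, bool),
            accepted=(0, eff.size),
        )

    def test_constant_path_single_segment(self):
        model = GaussianHmm([0.2, 0.8], [0.05, 0.05],
                            [[0.95, 0.05], [0.05, 0.95]], [0.5, 0.5])
        ideal = r.idealize(model, self._fret(np.full(40, 0.8)))
        assert ideal.segments == ((0, 40, 1),)

    def test_run_length_encoding(self):
        model = GaussianHmm([0.2, 0.8], [0.02, 0.02],
                            [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        eff = [0.2, 0.2, 0.2, 0.8, 0.8, 0.8, 0.2]
        ideal = r.idealize(model, self._fret(eff))
        assert ideal.segments == ((0, 3, 0), (3, 6, 1), (6, 7, 0))
        np.testing.assert_array_equal(ideal.state_path(), [0, 0, 0, 1, 1, 1, 0])

    def test_state_recovery_rate_on_simulated_traces(self):
        # separation (delta mean)/sd >= 3 for adjacent ATRG3 states
        model = r.atrg3_model()
        obs, paths = pure_emission_traces(model, 30, 300, seed=12)
        fit = r.baum_welch_fit(obs, 3, n_restarts=3, seed=0)
        correct = total = 0
        for o, p in zip(obs, paths):
            decoded = r.viterbi_decode(fit.model, o)
            correct += (decoded == p).sum()
            total += p.size
        assert correct / total >= 0.9
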