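"""Embedding, PCA, variational HMM, free energy, Viterbi, model transfer —
unit scale."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

import brainstates as bs
from brainstates.prep import ConcatenatedData
from brainstates.tdehmm import (
    EmbeddingConfig,
    HMMModel,
    _point_loglik_matrix,
    embed,
    pca_reduce,
)


def _cat(data, fs=250.0, boundaries=None):
    if boundaries is None:
        boundaries = [(0, data.shape[0])]
    return ConcatenatedData(
        data=np.asarray(data, float), boundaries=boundaries, fs=fs,
        subject_ids=[f"s{i}" for i in range(len(boundaries))],
    )


class TestEmbed:
    def test_stated_convention_single_channel(self):
        x = _cat(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        e, idx, bounds = embed(x, EmbeddingConfig(lags=[-1, 0, 1]))
        np.testing.assert_array_equal(e, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        np.testing.assert_array_equal(idx, [1, 2, 3])
        assert bounds == [(0, 3)]

    def test_zero_lag_identity(self, rng):
        x = _cat(rng.standard_normal((50, 3)))
        e, idx, _ = embed(x, EmbeddingConfig(lags=[0]))
        np.testing.assert_array_equal(e, x.data)
        np.testing.assert_array_equal(idx, np.arange(50))

    def test_default_embedded_dimension_for_39_parcels(self, rng):
        x = _cat(rng.standard_normal((100, 39)))
        e, _, _ = embed(x, EmbeddingConfig())
        assert e.shape[1] == 585  # 15 lags x 39 parcels

    def test_no_wraparound_across_subjects(self, rng):
        data = rng.standard_normal((40, 2))
        x = _cat(data, boundaries=[(0, 20), (20, 40)])
        e, idx, bounds = embed(x, EmbeddingConfig(lags=[-2, 0, 2]))
        assert e.shape[0] == 40 - 2 * 4
        assert bounds == [(0, 16), (16, 32)]
        # first embedded row of subject 2 must only use subject-2 samples
        np.testing.assert_array_equal(e[16, 0::3], data[20, :])

    def test_short_segment_names_subject(self, rng):
        x = _cat(rng.standard_normal((10, 2)), boundaries=[(0, 5), (5, 10)])
        with pytest.raises(ValueError, match="s0"):
            embed(x, EmbeddingConfig(lags=np.arange(-3, 4)))


class TestPCAReduce:
    def test_full_rank_reconstruction(self, rng):
        e = rng.standard_normal((200, 6))
        y, basis = pca_reduce(e, 6)
        recon = y @ basis.components.T + basis.mean
        assert np.linalg.norm(recon - e) / np.linalg.norm(e) < 1e-8

    def test_explained_variance_is_eigenvalues(self, rng):
        e = rng.standard_normal((500, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        _, basis = pca_reduce(e, 5)
        ec = e - e.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(ec.T @ ec / (len(e) - 1)))[::-1]
        np.testing.assert_allclose(basis.explained_variance, evals, rtol=1e-10)
        assert np.all(np.diff(basis.explained_variance) <= 1e-12)

    def test_components_orthonormal(self, rng):
        _, basis = pca_reduce(rng.standard_normal((300, 8)), 4)
        gram = basis.components.T @ basis.components
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_rank_exceeded_rejected(self, rng):
        e = np.tile(rng.standard_normal((100, 1)), (1, 4))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(e, 3)


def _two_regime_data(seed=0, T=3000, p=0.97):
    rng = np.random.default_rng(seed)
    z = np.zeros(T, dtype=int)
    for t in range(1, T):
        z[t] = z[t - 1] if rng.random() < p else 1 - z[t - 1]
    sd = np.where(z == 0, 1.0, 3.0)
    y = rng.standard_normal((T, 2)) * sd[:, None]
    return y, z


class TestFit:
    def test_single_state_degenerate(self, rng):
        y = rng.standard_normal((300, 3))
        res = bs.fit(y, K=1, restarts=1, max_cycles=10, seed=0)
        np.testing.assert_allclose(res.gamma.gamma, 1.0)
        assert res.free_energy_trace.size >= 1

    def test_two_variance_regimes_recovered(self):
        y, z = _two_regime_data(seed=3)
        res = bs.fit(y, K=2, restarts=3, max_cycles=80, tolerance=1e-8, seed=0)
        vp = bs.viterbi(res.model, y)
        acc = max(np.mean(vp.labels == z), np.mean(vp.labels == 1 - z))
        assert acc > 0.95

    def test_chosen_restart_has_minimal_free_energy(self):
        y, _ = _two_regime_data(seed=5, T=800)
        res = bs.fit(y, K=2, restarts=3, max_cycles=20, tolerance=1e-9, seed=1)
        assert res.chosen_restart == int(np.argmin(res.restart_free_energies))

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            bs.fit(rng.standard_normal((50, 2)), K=0)
        bad = rng.standard_normal((50, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            bs.fit(bad, K=2)

    def test_stochastic_mode_runs(self):
        y, z = _two_regime_data(seed=7, T=2000)
        bounds = [(i * 200, (i + 1) * 200) for i in range(10)]
        res = bs.fit(
            y, K=2, boundaries=bounds, restarts=1, max_cycles=15,
            batch_segments=4, seed=0,
        )
        assert res.gamma.gamma.shape == (2000, 2)
        np.testing.assert_allclose(res.gamma.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_gamma_rows_stochastic_and_permutation_equivariance(self):
        y, _ = _two_regime_data(seed=11, T=1000)
        res = bs.fit(y, K=2, restarts=1, max_cycles=15, seed=2)
        g = res.gamma.gamma
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-10)
        # permuting model states permutes gamma columns identically
        perm = np.array([1, 0])
        from brainstates.tdehmm import _estep

        g2, *_ = _estep(res.model.permuted(perm), y, [(0, 1000)])
        np.testing.assert_allclose(g2, g[:, perm], atol=1e-10)


class TestFreeEnergy:
    def test_full_batch_trace_monotone(self):
        y, _ = _two_regime_data(seed=13, T=1500)
        res = bs.fit(y, K=2, restarts=2, max_cycles=60, tolerance=1e-9, seed=0)
        tr = res.free_energy_trace
        assert np.all(np.diff(tr) <= 1e-6 * np.abs(tr[1:]))

    def test_components_sum_to_total(self):
        y, _ = _two_regime_data(seed=17, T=600)
        res = bs.fit(y, K=2, restarts=1, max_cycles=10, seed=0)
        fe = bs.free_energy(res.model, y)
        assert abs(fe.total - fe.components_sum()) < 1e-8

    def test_point_estimate_matches_forward_oracle(self):
        y, _ = _two_regime_data(seed=19, T=150)
        res = bs.fit(y, K=2, restarts=1, max_cycles=10, seed=0)
        fe = bs.free_energy(res.model, y, point_estimate=True)
        ll = _point_loglik_matrix(res.model, y)
        logA = np.log(res.model.transition_matrix)
        alpha = np.log(res.model.initial_probs) + ll[0]
        for t in range(1, len(y)):
            alpha = logsumexp(alpha[:, None] + logA, axis=0) + ll[t]
        assert abs(fe.total - (-logsumexp(alpha))) < 1e-8

    def test_true_K_beats_K1_on_synthetic(self):
        y, _ = _two_regime_data(seed=23, T=2000)
        f2 = bs.fit(y, K=2, restarts=2, max_cycles=40, tolerance=1e-8, seed=0)
        f1 = bs.fit(y, K=1, restarts=1, max_cycles=40, tolerance=1e-8, seed=0)
        assert f2.free_energy_trace[-1] < f1.free_energy_trace[-1]


def _random_model(rng, K, P=2):
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K))
    covs = np.empty((K, P, P))
    for k in range(K):
        M = rng.standard_normal((P, P))
        covs[k] = M @ M.T + 0.5 * np.eye(P)
    return HMMModel.from_point_estimates(covs, A, pi)


class TestViterbi:
    def test_single_state_constant(self, rng):
        m = _random_model(rng, 1)
        vp = bs.viterbi(m, rng.standard_normal((20, 2)))
        assert (vp.labels == 0).all()
        assert vp.binary.shape == (20, 1)

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(25):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 9))
            m = _random_model(rng, K)
            y = rng.standard_normal((T, 2)) * rng.uniform(0.5, 2.0)
            vp = bs.viterbi(m, y)
            ll = _point_loglik_matrix(m, y)
            logA = np.log(m.transition_matrix)
            logpi = np.log(m.initial_probs)
            best, best_path = -np.inf, None
            for path in itertools.product(range(K), repeat=T):
                lp = logpi[path[0]] + ll[0, path[0]]
                for t in range(1, T):
                    lp += logA[path[t - 1], path[t]] + ll[t, path[t]]
                if lp > best + 1e-12:
                    best, best_path = lp, path
            assert tuple(vp.labels) == best_path

    def test_emission_dominated_limit(self, rng):
        # near-deterministic emissions: path equals per-sample argmax
        covs = np.stack([np.eye(1) * 1e-6, np.eye(1) * 1.0])
        m = HMMModel.from_point_estimates(
            covs, np.full((2, 2), 0.5), np.full(2, 0.5)
        )
        y = np.array([[0.0], [3.0], [0.001], [2.5], [0.0]])
        vp = bs.viterbi(m, y)
        ll = _point_loglik_matrix(m, y)
        np.testing.assert_array_equal(vp.labels, ll.argmax(axis=1))


class TestApplyModel:
    def _train(self, tiny_gt, seed=0):
        subs = bs.simulate_dataset(tiny_gt, seed=seed)
        data = bs.prepare([s.parcels for s in subs])
        y, basis, sidx, bounds = bs.embed_and_reduce(data, EmbeddingConfig(fs=250.0))
        res = bs.fit(
            y, K=tiny_gt.K, boundaries=bounds, restarts=2, max_cycles=30,
            tolerance=1e-7, seed=seed, sample_indices=sidx,
        )
        return subs, data, y, basis, bounds, res

    def test_fixed_point_on_training_data(self, tiny_gt):
        _, data, y, basis, bounds, res = self._train(tiny_gt)
        sp = bs.apply_model(res.model, basis, EmbeddingConfig(fs=250.0), data)
        assert np.max(np.abs(sp.gamma - res.gamma.gamma)) < 1e-6

    def test_single_state_model_all_ones(self, rng):
        data = _cat(rng.standard_normal((400, 3)))
        y, basis, sidx, bounds = bs.embed_and_reduce(data, EmbeddingConfig(fs=250.0), P=5)
        res = bs.fit(y, K=1, restarts=1, max_cycles=5, seed=0)
        sp = bs.apply_model(res.model, basis, EmbeddingConfig(fs=250.0), data)
        np.testing.assert_allclose(sp.gamma, 1.0)

    def test_dimension_mismatch_rejected(self, tiny_gt, rng):
        _, data, y, basis, bounds, res = self._train(tiny_gt)
        wrong = _cat(rng.standard_normal((500, tiny_gt.n_parcels + 1)))
        with pytest.raises(ValueError, match=str(tiny_gt.n_parcels)):
            bs.apply_model(res.model, basis, EmbeddingConfig(fs=250.0), wrong)


class TestHmmlearnCrossCheck:
    """Independent reference: decoding and evidence agree with hmmlearn's
    Gaussian HMM when both use the same fixed parameters."""

    def _reference(self, m, K):
        from hmmlearn.hmm import GaussianHMM

        ref = GaussianHMM(n_components=K, covariance_type="full", init_params="")
        ref.startprob_ = m.initial_probs
        ref.transmat_ = m.transition_matrix
        ref.means_ = np.zeros((K, 2))
        ref.covars_ = m.state_covariances
        return ref

    def test_viterbi_and_loglik_match(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 4))
            m = _random_model(rng, K)
            y = rng.standard_normal((40, 2)) * rng.uniform(0.5, 2.0)
            ref = self._reference(m, K)
            ll_ref, path_ref = ref.decode(y, algorithm="viterbi")
            vp = bs.viterbi(m, y)
            np.testing.assert_array_equal(vp.labels, path_ref)
            fe = bs.free_energy(m, y, point_estimate=True)
            assert abs(-fe.total - ref.score(y)) < 1e-8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_viterbi_labels_valid_and_gamma_stochastic(seed):
    """For random small problems, gamma rows always sum to one and Viterbi
    labels stay within range."""
    rng = np.random.default_rng(seed)
    K = int(rng.integers(1, 4))
    y = rng.standard_normal((60, 2)) * rng.uniform(0.5, 3.0)
    res = bs.fit(y, K=K, restarts=1, max_cycles=5, seed=seed)
    assert np.all(res.gamma.gamma >= 0)
    np.testing.assert_allclose(res.gamma.gamma.sum(axis=1), 1.0, atol=1e-9)
    vp = bs.viterbi(res.model, y)
    assert vp.labels.min() >= 0 and vp.labels.max() < K
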