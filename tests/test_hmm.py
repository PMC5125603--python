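import itertools
import json

import numpy as np
import pytest

from harhmm.hmm import (
    GaussianMixtureHMM,
    ModelBank,
    SequenceBatch,
    forward_loglik,
    init_chmm,
)


def random_model(Q, M, O, rng, var_lo=0.2, var_hi=2.0):
    return GaussianMixtureHMM.from_params(
        rng.dirichlet(np.ones(Q)),
        rng.dirichlet(np.ones(Q), Q),
        rng.dirichlet(np.ones(M), Q),
        rng.normal(0, 1, (Q, M, O)),
        rng.uniform(var_lo, var_hi, (Q, M, O)),
    )


def brute_force_loglik(model, seq):
    """Sum P(path) * P(obs | path) over every hidden state path."""
    logB = model._frame_log_prob(seq)
    T = seq.shape[0]
    total = -np.inf
    for path in itertools.product(range(model.n_states), repeat=T):
        lp = np.log(model.startprob_[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transmat_[path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


class TestEmissionLogDensity:
    def test_standard_normal_at_its_mean(self):
        m = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[1.0]], [[[0.0]]], [[[1.0]]]
        )
        # N(0; 0, 1) = 1/sqrt(2 pi)
        assert m.emission_logdensity(np.array([0.0]), 0) == pytest.approx(
            -0.9189385332046727
        )

    def test_equal_mixture_components_collapse(self, rng):
        mu = rng.normal(0, 1, (1, 1, 3))
        var = rng.uniform(0.5, 1.5, (1, 1, 3))
        m1 = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[1.0]], mu, var
        )
        m2 = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[0.5, 0.5]],
            np.repeat(mu, 2, axis=1), np.repeat(var, 2, axis=1),
        )
        x = rng.normal(0, 1, 3)
        assert m2.emission_logdensity(x, 0) == pytest.approx(
            m1.emission_logdensity(x, 0)
        )

    def test_matches_naive_mixture_arithmetic(self, rng):
        """log-sum-exp value equals direct summation of Gaussian products."""
        m = random_model(2, 3, 2, rng)
        x = rng.normal(0, 1, 2)
        for q in range(2):
            direct = 0.0
            for k in range(3):
                mu, var = m.means_[q, k], m.variances_[q, k]
                dens = np.prod(
                    np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
                )
                direct += m.weights_[q, k] * dens
            assert m.emission_logdensity(x, q) == pytest.approx(np.log(direct))


class TestForward:
    def test_matches_path_enumeration(self, rng):
        for _ in range(10):
            Q, M, O = rng.integers(1, 4), rng.integers(1, 3), rng.integers(1, 3)
            T = int(rng.integers(1, 7))
            m = random_model(int(Q), int(M), int(O), rng)
            seq = rng.normal(0, 1, (T, int(O)))
            assert forward_loglik(m, seq) == pytest.approx(
                brute_force_loglik(m, seq), abs=1e-9
            )

    def test_single_state_reduces_to_framewise_sum(self, rng):
        m = random_model(1, 1, 2, rng)
        seq = rng.normal(0, 1, (6, 2))
        expected = sum(m.emission_logdensity(f, 0) for f in seq)
        assert m.score(seq) == pytest.approx(expected)

    def test_single_frame_closed_form(self, rng):
        m = random_model(3, 2, 2, rng)
        x = rng.normal(0, 1, 2)
        terms = [
            np.log(m.startprob_[q]) + m.emission_logdensity(x, q) for q in range(3)
        ]
        assert m.score(x[None]) == pytest.approx(
            np.logaddexp.reduce(terms)
        )

    def test_scaled_and_logspace_agree(self, rng):
        for _ in range(10):
            m = random_model(3, 2, 2, rng)
            seq = rng.normal(0, 1, (15, 2))
            assert m.score(seq) == pytest.approx(m.score_scaled(seq), abs=1e-8)

    def test_invariant_under_state_relabelling(self, rng):
        m = random_model(3, 2, 2, rng)
        perm = [2, 0, 1]
        m2 = GaussianMixtureHMM.from_params(
            m.startprob_[perm],
            m.transmat_[np.ix_(perm, perm)],
            m.weights_[perm],
            m.means_[perm],
            m.variances_[perm],
        )
        seq = rng.normal(0, 1, (8, 2))
        assert m.score(seq) == pytest.approx(m2.score(seq))

    def test_wrong_frame_dimension_rejected(self, rng):
        m = random_model(2, 1, 3, rng)
        with pytest.raises(ValueError):
            m.score(rng.normal(0, 1, (4, 2)))

    def test_matches_hmmlearn_oracle(self, rng):
        """Independent implementation check against hmmlearn's GMMHMM."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        m = random_model(3, 2, 2, rng, var_lo=0.5, var_hi=2.0)
        ref = hmmlearn.GMMHMM(
            n_components=3, n_mix=2, covariance_type="diag", init_params=""
        )
        ref.startprob_ = m.startprob_
        ref.transmat_ = m.transmat_
        ref.weights_ = m.weights_
        ref.means_ = m.means_
        ref.covars_ = m.variances_
        seq = rng.normal(0, 1, (12, 2))
        assert m.score(seq) == pytest.approx(ref.score(seq), abs=1e-6)


class TestInit:
    def test_degenerate_single_component(self, rng):
        data = rng.normal(0.5, 1.0, (4, 6, 2))
        m = init_chmm(1, 1, 2, seed=0, data=data)
        np.testing.assert_array_equal(m.startprob_, [1.0])
        np.testing.assert_array_equal(m.transmat_, [[1.0]])
        np.testing.assert_allclose(
            m.means_[0, 0], data.reshape(-1, 2).mean(axis=0)
        )

    def test_deterministic_per_seed(self, rng):
        data = rng.normal(0, 1, (6, 5, 3))
        m1 = init_chmm(2, 2, 3, seed=9, data=data)
        m2 = init_chmm(2, 2, 3, seed=9, data=data)
        np.testing.assert_array_equal(m1.means_, m2.means_)
        np.testing.assert_array_equal(m1.variances_, m2.variances_)

    def test_constant_data_hits_variance_floor(self):
        import warnings

        data = np.zeros((3, 4, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k-means on duplicate points
            m = init_chmm(2, 2, 2, seed=0, data=data)
        assert np.all(m.variances_ == m.variance_floor)
        assert np.isfinite(m.score(np.zeros((4, 2))))

    def test_too_few_frames_falls_back_with_warning(self):
        data = np.random.default_rng(0).normal(0, 1, (1, 2, 2))  # 2 frames
        with pytest.warns(RuntimeWarning, match="perturbed"):
            init_chmm(2, 2, 2, seed=0, data=data)


class TestBaumWelch:
    def test_loglik_nondecreasing(self, rng):
        data = rng.normal(0, 1, (10, 8, 2))
        m = GaussianMixtureHMM(2, 2, 2).initialize(data, seed=0)
        m.fit(data, max_iter=30, tol=0.0, seed=0)
        diffs = np.diff(m.history_)
        assert np.all(diffs >= -1e-8)

    def test_recovers_known_two_state_model(self):
        """Simulation + best-permutation matching within 0.05 / 0.1."""
        true = GaussianMixtureHMM.from_params(
            [0.7, 0.3],
            [[0.9, 0.1], [0.2, 0.8]],
            [[1.0], [1.0]],
            [[[0.0, 0.0]], [[2.0, 2.0]]],
            [[[0.3, 0.3]], [[0.3, 0.3]]],
        )
        seqs = np.stack([true.sample(50, seed=1000 + i) for i in range(200)])
        fit = GaussianMixtureHMM(2, 1, 2).initialize(seqs, seed=0)
        fit.fit(seqs, max_iter=100, tol=1e-6, seed=0)
        best = np.inf
        for perm in itertools.permutations(range(2)):
            terr = np.abs(
                fit.transmat_[np.ix_(perm, perm)] - true.transmat_
            ).max()
            merr = np.abs(fit.means_[list(perm)] - true.means_).max()
            best = min(best, max(terr / 0.05, merr / 0.1))
        assert best <= 1.0

    def test_single_state_trans_is_forced(self, rng):
        data = rng.normal(0, 1, (5, 6, 2))
        m = GaussianMixtureHMM(1, 2, 2).initialize(data, seed=0)
        m.fit(data, max_iter=5, seed=0)
        np.testing.assert_array_equal(m.transmat_, [[1.0]])

    def test_stochasticity_preserved_each_iteration(self, rng):
        data = rng.normal(0, 1, (8, 6, 2))
        m = GaussianMixtureHMM(3, 2, 2).initialize(data, seed=1)
        for _ in range(5):
            m.fit(data, max_iter=1, tol=0.0, seed=1)
            assert m.startprob_.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(m.transmat_.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(m.weights_.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(m.variances_ >= m.variance_floor - 1e-15)


class TestSample:
    def test_deterministic_per_seed(self, rng):
        m = random_model(2, 2, 3, rng)
        np.testing.assert_array_equal(m.sample(20, seed=4), m.sample(20, seed=4))

    def test_degenerate_emission_sticks_to_mean(self):
        m = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[1.0]], [[[0.7, -0.2]]], [[[1e-3, 1e-3]]]
        )
        frames = m.sample(50, seed=0)
        assert np.abs(frames - [0.7, -0.2]).max() < 0.2

    def test_empirical_transition_frequencies(self, rng):
        m = GaussianMixtureHMM.from_params(
            [0.5, 0.5],
            [[0.7, 0.3], [0.4, 0.6]],
            [[1.0], [1.0]],
            [[[-5.0]], [[5.0]]],  # states identifiable from the emission sign
            [[[0.1]], [[0.1]]],
        )
        frames = m.sample(100_000, seed=0)
        states = (frames[:, 0] > 0).astype(int)
        for i in (0, 1):
            for j in (0, 1):
                mask = states[:-1] == i
                freq = np.mean(states[1:][mask] == j)
                assert freq == pytest.approx(m.transmat_[i, j], abs=0.01)


class TestModelBank:
    def test_true_model_wins_on_its_own_samples(self, rng):
        a = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[1.0]], [[[0.0, 0.0]]], [[[0.5, 0.5]]]
        )
        b = GaussianMixtureHMM.from_params(
            [1.0], [[1.0]], [[1.0]], [[[7.0, 7.0]]], [[[0.5, 0.5]]]
        )
        bank = ModelBank({1: a, 2: b})
        label, scores = bank.classify(a.sample(10, seed=0))
        assert label == 1
        assert scores[1] > scores[2]

    def test_tie_broken_to_smallest_label(self, rng):
        m = random_model(1, 1, 2, rng)
        bank = ModelBank({3: m, 5: m})
        label, _ = bank.classify(rng.normal(0, 1, (4, 2)))
        assert label == 3

    def test_argmax_agrees_with_brute_force(self, rng):
        models = {r: random_model(2, 1, 2, rng) for r in (1, 2, 3)}
        bank = ModelBank(models)
        seq = rng.normal(0, 1, (4, 2))
        label, _ = bank.classify(seq)
        brute = {r: brute_force_loglik(m, seq) for r, m in models.items()}
        assert label == max(sorted(brute), key=lambda r: brute[r])

    def test_batch_and_single_classification_agree(self, rng):
        models = {r: random_model(2, 2, 2, rng) for r in (1, 2)}
        bank = ModelBank(models)
        obs = rng.normal(0, 1, (6, 5, 2))
        labels, scores = bank.classify_batch(obs)
        for i in range(6):
            single, smap = bank.classify(obs[i])
            assert labels[i] == single
            np.testing.assert_allclose(scores[i], [smap[1], smap[2]])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="frame dimension"):
            ModelBank({1: random_model(1, 1, 2, rng), 2: random_model(1, 1, 3, rng)})


def test_json_round_trip(tmp_path, rng):
    m = random_model(2, 2, 3, rng)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = GaussianMixtureHMM.load(path)
    seq = rng.normal(0, 1, (6, 3))
    assert m2.score(seq) == pytest.approx(m.score(seq), abs=1e-12)
    assert json.loads(path.read_text())["n_states"] == 2


def test_sequence_batch_validates_dimensions(rng):
    with pytest.raises(ValueError, match="frame dimension"):
        SequenceBatch([rng.normal(0, 1, (4, 3))], frame_dim=2)
    batch = SequenceBatch([rng.normal(0, 1, (4, 2)), rng.normal(0, 1, (7, 2))], 2)
    assert len(batch) == 2
    m = random_model(2, 1, 2, np.random.default_rng(0))
    scores = m.score_batch(batch)
    assert scores.shape == (2,)
    assert scores[0] == pytest.approx(m.score(batch.sequences[0]))
    assert scores[1] == pytest.approx(m.score(batch.sequences[1]))
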