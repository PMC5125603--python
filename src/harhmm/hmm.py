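"""Continuous hidden Markov models with Gaussian-mixture emissions.

The model is lambda = (A, B, pi): a Q-state Markov chain with initial
distribution pi and row-stochastic transition matrix A, where each state i
emits an O-dimensional frame from an M-component diagonal-covariance Gaussian
mixture b_i(o) = sum_m c_im prod_k N(o_k; mu_imk, sigma2_imk).

Likelihoods are computed with a log-space forward recursion (log-sum-exp), so
they stay finite at any sequence length; a classic scaled-forward
implementation is kept alongside as an internal cross-check.  Training is
Baum-Welch EM over batches of sequences.  Classification over a bank of
per-class models picks argmax_r log P(O | lambda^r).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "GaussianMixtureHMM",
    "SequenceBatch",
    "ModelBank",
    "init_chmm",
    "emission_logdensity",
    "forward_loglik",
    "baum_welch_fit",
    "sample",
    "classify",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class SequenceBatch:
    """A list of (T x O) frame matrices sharing the frame dimension O."""

    sequences: list[np.ndarray]
    frame_dim: int

    def __post_init__(self):
        seqs = []
        for s in self.sequences:
            s = np.atleast_2d(np.asarray(s, dtype=float))
            if s.shape[0] < 1:
                raise ValueError("every sequence needs at least one frame")
            if s.shape[1] != self.frame_dim:
                raise ValueError(
                    f"frame dimension {s.shape[1]} != declared {self.frame_dim}"
                )
            seqs.append(s)
        if not seqs:
            raise ValueError("empty sequence batch")
        self.sequences = seqs

    def __len__(self):
        return len(self.sequences)

    @classmethod
    def from_array(cls, obs: np.ndarray) -> "SequenceBatch":
        """Build from an (S, T, O) stack of equal-length sequences."""
        obs = np.asarray(obs, dtype=float)
        return cls(list(obs), obs.shape[-1])


def _as_stacks(sequences) -> list[np.ndarray]:
    """Group sequences by length into (S, T, O) stacks for vectorised math."""
    if isinstance(sequences, SequenceBatch):
        sequences = sequences.sequences
    elif isinstance(sequences, np.ndarray) and sequences.ndim == 3:
        return [sequences.astype(float)]
    by_len: dict[int, list[np.ndarray]] = {}
    for s in sequences:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        by_len.setdefault(s.shape[0], []).append(s)
    return [np.stack(group) for group in by_len.values()]


class GaussianMixtureHMM:
    """Q-state, M-mixture, diagonal-covariance continuous HMM.

    Parameters are held as plain arrays:

    - ``startprob_`` : (Q,) initial state distribution pi
    - ``transmat_``  : (Q, Q) row-stochastic transition matrix
    - ``weights_``   : (Q, M) row-stochastic mixture weights
    - ``means_``     : (Q, M, O)
    - ``variances_`` : (Q, M, O), every entry >= ``variance_floor``

    The variance floor (default 1e-3 on [-1, 1]-scaled data) prevents
    degenerate components from producing unbounded likelihoods.
    """

    def __init__(
        self,
        n_states: int,
        n_mix: int,
        n_features: int,
        variance_floor: float = 1e-3,
    ):
        if min(n_states, n_mix, n_features) < 1:
            raise ValueError("Q, M and O must all be >= 1")
        if variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        self.n_states = int(n_states)
        self.n_mix = int(n_mix)
        self.n_features = int(n_features)
        self.variance_floor = float(variance_floor)
        self.startprob_: np.ndarray | None = None
        self.transmat_: np.ndarray | None = None
        self.weights_: np.ndarray | None = None
        self.means_: np.ndarray | None = None
        self.variances_: np.ndarray | None = None
        self.history_: list[float] = []

    # ------------------------------------------------------------------ setup

    @classmethod
    def from_params(
        cls,
        startprob,
        transmat,
        weights,
        means,
        variances,
        variance_floor: float = 1e-3,
    ) -> "GaussianMixtureHMM":
        means = np.asarray(means, dtype=float)
        Q, M, O = means.shape
        model = cls(Q, M, O, variance_floor=variance_floor)
        model.startprob_ = np.asarray(startprob, dtype=float)
        model.transmat_ = np.asarray(transmat, dtype=float)
        model.weights_ = np.asarray(weights, dtype=float)
        model.means_ = means
        model.variances_ = np.maximum(
            np.asarray(variances, dtype=float), variance_floor
        )
        model._validate()
        return model

    def _validate(self):
        Q, M, O = self.n_states, self.n_mix, self.n_features
        assert self.startprob_.shape == (Q,)
        assert self.transmat_.shape == (Q, Q)
        assert self.weights_.shape == (Q, M)
        assert self.means_.shape == (Q, M, O)
        assert self.variances_.shape == (Q, M, O)
        for name, arr, axis in (
            ("startprob", self.startprob_, None),
            ("transmat", self.transmat_, 1),
            ("weights", self.weights_, 1),
        ):
            sums = arr.sum() if axis is None else arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1, got {sums}")
        if np.any(self.variances_ < self.variance_floor - 1e-15):
            raise ValueError("variances below the floor")

    def initialize(self, data, seed: int | None = 0) -> "GaussianMixtureHMM":
        """Data-driven initialization: uniform chain, k-means emission means.

        Means come from seeded k-means with Q*M centroids over the pooled
        frames; variances start at the pooled per-dimension variance
        (floored).  With fewer pooled frames than Q*M the means fall back to
        small seeded perturbations of the global mean.
        """
        stacks = _as_stacks(data)
        frames = np.concatenate([s.reshape(-1, s.shape[-1]) for s in stacks])
        if frames.shape[1] != self.n_features:
            raise ValueError(
                f"data frame dim {frames.shape[1]} != model O {self.n_features}"
            )
        Q, M, O = self.n_states, self.n_mix, self.n_features
        rng = np.random.default_rng(seed)
        k = Q * M
        if k == 1:
            centers = frames.mean(axis=0, keepdims=True)
        elif frames.shape[0] >= k:
            km = KMeans(
                n_clusters=k,
                n_init=3,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(frames)
            centers = km.cluster_centers_
        else:
            warnings.warn(
                f"only {frames.shape[0]} frames for {k} components; "
                "initializing means as perturbed global mean",
                RuntimeWarning,
            )
            centers = frames.mean(axis=0) + 0.01 * rng.standard_normal((k, O))
        self.startprob_ = np.full(Q, 1.0 / Q)
        self.transmat_ = np.full((Q, Q), 1.0 / Q)
        self.weights_ = np.full((Q, M), 1.0 / M)
        self.means_ = centers.reshape(Q, M, O).astype(float)
        pooled_var = np.maximum(frames.var(axis=0), self.variance_floor)
        self.variances_ = np.tile(pooled_var, (Q, M, 1))
        self._validate()
        return self

    # ------------------------------------------------------------- likelihood

    def _log_components(self, obs: np.ndarray) -> np.ndarray:
        """Per-component weighted log densities, shape (..., Q, M).

        Entry (..., q, m) is log c_qm + log N(o; mu_qm, diag sigma2_qm).
        """
        Q, M, O = self.n_states, self.n_mix, self.n_features
        out = np.empty(obs.shape[:-1] + (Q, M))
        logw = np.log(np.clip(self.weights_, 1e-300, None))
        for q in range(Q):
            for m in range(M):
                var = self.variances_[q, m]
                diff = obs - self.means_[q, m]
                ll = -0.5 * np.sum(
                    diff * diff / var + np.log(var) + _LOG_2PI, axis=-1
                )
                out[..., q, m] = ll + logw[q, m]
        return out

    def _frame_log_prob(self, obs: np.ndarray) -> np.ndarray:
        """log b_q(o) for every frame, shape obs.shape[:-1] + (Q,)."""
        return logsumexp(self._log_components(obs), axis=-1)

    def emission_logdensity(self, frame: np.ndarray, state: int) -> float:
        """log b_state(frame) via log-sum-exp over the mixture."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (self.n_features,):
            raise ValueError(f"frame must have shape ({self.n_features},)")
        if not 0 <= state < self.n_states:
            raise IndexError(f"state {state} out of range")
        return float(self._frame_log_prob(frame)[state])

    def _forward_batch(self, obs: np.ndarray) -> np.ndarray:
        """Log-space forward recursion over an (S, T, O) stack -> (S,)."""
        logB = self._frame_log_prob(obs)  # (S, T, Q)
        log_pi = np.log(np.clip(self.startprob_, 1e-300, None))
        log_A = np.log(np.clip(self.transmat_, 1e-300, None))
        log_alpha = log_pi + logB[:, 0]
        for t in range(1, obs.shape[1]):
            log_alpha = (
                logsumexp(log_alpha[:, :, None] + log_A[None], axis=1)
                + logB[:, t]
            )
        return logsumexp(log_alpha, axis=1)

    def score(self, sequence: np.ndarray) -> float:
        """Exact log P(O | lambda) of one (T x O) sequence."""
        seq = np.atleast_2d(np.asarray(sequence, dtype=float))
        if seq.shape[1] != self.n_features:
            raise ValueError(
                f"frame dim {seq.shape[1]} != model O {self.n_features}"
            )
        return float(self._forward_batch(seq[None])[0])

    def score_batch(self, sequences) -> np.ndarray:
        """Log-likelihood of each sequence (vectorised per length group)."""
        stacks = _as_stacks(sequences)
        if len(stacks) == 1:
            return self._forward_batch(stacks[0])
        # preserve input order across ragged groups
        if isinstance(sequences, SequenceBatch):
            sequences = sequences.sequences
        out = np.empty(len(sequences))
        done: dict[int, list[int]] = {}
        for i, s in enumerate(sequences):
            done.setdefault(np.atleast_2d(np.asarray(s)).shape[0], []).append(i)
        for stack, idx in zip(stacks, done.values()):
            out[idx] = self._forward_batch(stack)
        return out

    def score_scaled(self, sequence: np.ndarray) -> float:
        """Scaled-forward (Rabiner c_t normalization) log-likelihood.

        Numerically independent of :meth:`score`; the two agree to ~1e-8 and
        are cross-checked in the test suite.
        """
        seq = np.atleast_2d(np.asarray(sequence, dtype=float))
        B = np.exp(self._frame_log_prob(seq))  # (T, Q); may underflow for
        # pathological models, which is exactly what score() avoids
        alpha = self.startprob_ * B[0]
        loglik = 0.0
        for t in range(seq.shape[0]):
            if t > 0:
                alpha = (alpha @ self.transmat_) * B[t]
            c = alpha.sum()
            if c <= 0:
                return -np.inf
            alpha = alpha / c
            loglik += np.log(c)
        return float(loglik)

    # --------------------------------------------------------------- training

    def fit(
        self,
        data,
        max_iter: int = 100,
        tol: float = 1e-5,
        seed: int | None = 0,
    ) -> "GaussianMixtureHMM":
        """Baum-Welch EM over a batch of sequences.

        The per-iteration total log-likelihood is recorded in ``history_``
        and is non-decreasing up to numerical slack.  Stops when the relative
        improvement drops below ``tol``.  Components that receive no
        responsibility are re-seeded from a random frame.
        """
        stacks = _as_stacks(data)
        if self.startprob_ is None:
            self.initialize(stacks, seed=seed)
        rng = np.random.default_rng(seed)
        all_frames = np.concatenate(
            [s.reshape(-1, s.shape[-1]) for s in stacks]
        )
        self.history_ = []
        prev = -np.inf
        for _ in range(max_iter):
            total_ll, stats = self._em_step_accumulate(stacks)
            self.history_.append(total_ll)
            self._em_step_update(stats, all_frames, rng)
            if np.isfinite(prev):
                rel = (total_ll - prev) / max(1.0, abs(prev))
                if rel < tol:
                    break
            prev = total_ll
        return self

    def _em_step_accumulate(self, stacks):
        Q, M, O = self.n_states, self.n_mix, self.n_features
        log_pi = np.log(np.clip(self.startprob_, 1e-300, None))
        log_A = np.log(np.clip(self.transmat_, 1e-300, None))
        pi_acc = np.zeros(Q)
        trans_acc = np.zeros((Q, Q))
        w_acc = np.zeros((Q, M))
        mean_acc = np.zeros((Q, M, O))
        sq_acc = np.zeros((Q, M, O))
        total_ll = 0.0
        for obs in stacks:
            S, T, _ = obs.shape
            log_comp = self._log_components(obs)  # (S, T, Q, M)
            logB = logsumexp(log_comp, axis=-1)  # (S, T, Q)
            # forward
            log_alpha = np.empty((S, T, Q))
            log_alpha[:, 0] = log_pi + logB[:, 0]
            for t in range(1, T):
                log_alpha[:, t] = (
                    logsumexp(log_alpha[:, t - 1, :, None] + log_A[None], axis=1)
                    + logB[:, t]
                )
            ll = logsumexp(log_alpha[:, -1], axis=1)  # (S,)
            total_ll += float(ll.sum())
            # backward
            log_beta = np.empty((S, T, Q))
            log_beta[:, -1] = 0.0
            for t in range(T - 2, -1, -1):
                log_beta[:, t] = logsumexp(
                    log_A[None]
                    + (logB[:, t + 1] + log_beta[:, t + 1])[:, None, :],
                    axis=2,
                )
            log_gamma = log_alpha + log_beta - ll[:, None, None]
            gamma = np.exp(log_gamma)  # (S, T, Q)
            pi_acc += gamma[:, 0].sum(axis=0)
            if T > 1:
                # xi summed over sequences and time
                log_xi = (
                    log_alpha[:, :-1, :, None]
                    + log_A[None, None]
                    + (logB[:, 1:] + log_beta[:, 1:])[:, :, None, :]
                    - ll[:, None, None, None]
                )
                trans_acc += np.exp(logsumexp(log_xi, axis=(0, 1)))
            # per-mixture responsibilities
            log_gm = (
                log_gamma[..., None] + log_comp - logB[..., None]
            )  # (S, T, Q, M)
            gm = np.exp(log_gm)
            flat_gm = gm.reshape(-1, Q, M)
            flat_obs = obs.reshape(-1, O)
            w_acc += flat_gm.sum(axis=0)
            mean_acc += np.einsum("nqm,no->qmo", flat_gm, flat_obs)
            sq_acc += np.einsum("nqm,no->qmo", flat_gm, flat_obs**2)
        return total_ll, (pi_acc, trans_acc, w_acc, mean_acc, sq_acc)

    def _em_step_update(self, stats, all_frames, rng):
        pi_acc, trans_acc, w_acc, mean_acc, sq_acc = stats
        Q, M = self.n_states, self.n_mix
        self.startprob_ = pi_acc / pi_acc.sum()
        if Q == 1:
            self.transmat_ = np.ones((1, 1))
        else:
            rows = trans_acc.sum(axis=1, keepdims=True)
            new_trans = np.where(rows > 0, trans_acc / np.where(rows == 0, 1, rows), self.transmat_)
            self.transmat_ = new_trans / new_trans.sum(axis=1, keepdims=True)
        occ = w_acc.copy()  # (Q, M) total responsibility mass
        empty = occ <= 1e-12
        for q, m in zip(*np.nonzero(empty)):
            warnings.warn(
                f"mixture component (state {q}, mix {m}) starved; "
                "re-seeding from a random frame",
                RuntimeWarning,
            )
            frame = all_frames[rng.integers(0, all_frames.shape[0])]
            mean_acc[q, m] = frame
            sq_acc[q, m] = frame**2 + all_frames.var(axis=0)
            occ[q, m] = 1.0
            w_acc[q, m] = 1e-6
        self.weights_ = w_acc / w_acc.sum(axis=1, keepdims=True)
        means = mean_acc / occ[..., None]
        variances = sq_acc / occ[..., None] - means**2
        self.means_ = means
        self.variances_ = np.maximum(variances, self.variance_floor)

    # --------------------------------------------------------------- sampling

    def sample(self, T: int, seed: int | None = None) -> np.ndarray:
        """Draw a (T x O) sequence: chain states then mixture emissions."""
        if T < 1:
            raise ValueError("T must be >= 1")
        rng = np.random.default_rng(seed)
        Q, M, O = self.n_states, self.n_mix, self.n_features
        frames = np.empty((T, O))
        state = rng.choice(Q, p=self.startprob_)
        for t in range(T):
            if t > 0:
                state = rng.choice(Q, p=self.transmat_[state])
            m = rng.choice(M, p=self.weights_[state])
            frames[t] = rng.normal(
                self.means_[state, m], np.sqrt(self.variances_[state, m])
            )
        return frames

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_mix": self.n_mix,
            "n_features": self.n_features,
            "variance_floor": self.variance_floor,
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "variances": self.variances_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GaussianMixtureHMM":
        return cls.from_params(
            payload["startprob"],
            payload["transmat"],
            payload["weights"],
            payload["means"],
            payload["variances"],
            variance_floor=payload.get("variance_floor", 1e-3),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "GaussianMixtureHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class ModelBank:
    """One generative model per class label; classification is max likelihood.

    Ties are broken toward the smallest label code for determinism.
    """

    models: dict[int, GaussianMixtureHMM]

    def __post_init__(self):
        if not self.models:
            raise ValueError("a model bank needs at least one model")
        dims = {m.n_features for m in self.models.values()}
        if len(dims) != 1:
            raise ValueError(f"models disagree on frame dimension: {dims}")

    @property
    def labels(self) -> list[int]:
        return sorted(self.models)

    def classify(self, sequence) -> tuple[int, dict[int, float]]:
        scores = {r: self.models[r].score(sequence) for r in self.labels}
        if all(not np.isfinite(v) for v in scores.values()):
            raise ValueError("sequence unscorable: all models give -inf")
        best = max(self.labels, key=lambda r: (scores[r], -r))
        return best, scores

    def classify_batch(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Classify an (S, T, O) stack; returns labels and (S, R) scores."""
        labels = self.labels
        scores = np.column_stack(
            [self.models[r].score_batch(obs) for r in labels]
        )
        if np.any(~np.isfinite(scores).any(axis=1)):
            raise ValueError("some sequences unscorable: all models give -inf")
        # argmax with smallest-label tie-break: labels are sorted ascending
        # and np.argmax returns the first maximum.
        pick = np.argmax(scores, axis=1)
        return np.asarray(labels)[pick], scores


# ----------------------------------------------------------------- functional


def init_chmm(Q: int, M: int, O: int, seed: int, data) -> GaussianMixtureHMM:
    """Construct and data-initialize a Q-state, M-mixture CHMM."""
    return GaussianMixtureHMM(Q, M, O).initialize(data, seed=seed)


def emission_logdensity(model: GaussianMixtureHMM, frame, state: int) -> float:
    return model.emission_logdensity(frame, state)


def forward_loglik(model: GaussianMixtureHMM, sequence) -> float:
    return model.score(sequence)


def baum_welch_fit(
    model: GaussianMixtureHMM, data, max_iter: int = 100, tol: float = 1e-5
) -> GaussianMixtureHMM:
    return model.fit(data, max_iter=max_iter, tol=tol)


def sample(model: GaussianMixtureHMM, T: int, seed: int | None = None):
    return model.sample(T, seed=seed)


def classify(bank: ModelBank, sequence) -> tuple[int, dict[int, float]]:
    return bank.classify(sequence)
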