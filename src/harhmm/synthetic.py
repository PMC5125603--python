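"""Synthetic six-activity feature-window generator.

Each window emulates a UCI-HAR-style record: a length-p vector of named,
[-1, 1]-normalized channels summarising one sliding window of accelerometer
and gyroscope signal.  Windows are sampled from per-class Gaussian-mixture
CHMMs over ``n_frames`` frames of ``n_channels`` coordinates and flattened,
so the vector carries genuine hidden-state temporal structure.

The class layout mirrors the hierarchy the classifier assumes:

- moving {1, 2, 3} and stationary {4, 5, 6} are widely separated;
- upstairs (2) and downstairs (3) share *all* accelerometer-channel
  parameters and differ only in gyroscope channels — the accelerometer
  carries no information about stair direction;
- sitting (4) and standing (5) differ only along a dense low-dimensional
  direction, so a linear embedding is needed to separate them;
- laying (6) sits far from 4 and 5;
- two accelerometer and two gyroscope channels per frame are pure noise.
"""

from __future__ import annotations

import ast
import dataclasses

import numpy as np

from .hmm import GaussianMixtureHMM
from .io import FeatureDataset

__all__ = ["SyntheticSpec", "generate", "describe", "parse_describe"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the generator.

    ``p`` must equal ``n_frames * n_channels``; the first
    ``round(acc_fraction * n_channels)`` coordinates of every frame are
    accelerometer-named, the rest gyroscope-named.  ``separation`` scales all
    between-class mean offsets (0 collapses every class onto the same
    distribution); ``noise_sd`` is the within-component emission standard
    deviation per channel.
    """

    n_per_class: int = 60
    p: int = 60
    n_frames: int = 5
    n_channels: int = 12
    acc_fraction: float = 2.0 / 3.0
    separation: float = 1.0
    noise_sd: float = 0.25
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 4:
            raise ValueError("n_per_class must be >= 4")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.n_frames * self.n_channels != self.p:
            raise ValueError(
                f"p={self.p} must equal n_frames*n_channels="
                f"{self.n_frames * self.n_channels}"
            )
        if not 0.0 < self.acc_fraction < 1.0:
            raise ValueError("acc_fraction must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_acc_channels(self) -> int:
        return int(round(self.acc_fraction * self.n_channels))

    def feature_names(self) -> list[str]:
        """Per flattened index t*n_channels + c: Acc/Gyro by coordinate c."""
        n_acc = self.n_acc_channels
        names = []
        for t in range(self.n_frames):
            for c in range(self.n_channels):
                sensor = "Acc" if c < n_acc else "Gyro"
                names.append(f"tBody{sensor}-w{t}-c{c}")
        return names


def _class_models(spec: SyntheticSpec) -> dict[int, GaussianMixtureHMM]:
    """Six generative CHMMs over ``n_channels``-dimensional frames.

    Mean layout per coordinate (s = separation; acc = coords 0..n_acc-1,
    gyro = the rest; with the default 12 channels / 8 acc):

    - coords 0, 1: +-0.8 s moving/stationary split
    - coords 2, 3: +-0.7 s walking vs up/down (within moving) and
      laying vs sit/stand (within stationary)
    - coord 4:     anchor for sit/stand base
    - coords n_acc-2, n_acc-1: pure noise (acc)
    - first two gyro coords: +-0.7 s upstairs vs downstairs
    - last two gyro coords: pure noise
    - sitting/standing additionally differ by +-0.45 s along a dense unit
      direction confined to the informative coordinates.

    Classes 2 and 3 share the chain, weights, variances and all acc-channel
    means, so their accelerometer marginals are identical by construction.
    """
    C = spec.n_channels
    n_acc = spec.n_acc_channels
    s = spec.separation
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9151]))

    acc = np.arange(n_acc)
    gyro = np.arange(n_acc, C)
    noise_acc = acc[-2:] if n_acc >= 4 else acc[:0]
    noise_gyro = gyro[-2:] if gyro.size >= 4 else gyro[:0]
    info = np.setdiff1d(np.arange(C), np.concatenate([noise_acc, noise_gyro]))

    base = {c: np.zeros(C) for c in range(1, 7)}
    for c in (1, 2, 3):
        base[c][acc[:2]] = 0.8 * s
    for c in (4, 5, 6):
        base[c][acc[:2]] = -0.8 * s
    base[1][acc[2:4]] = 0.7 * s
    base[2][acc[2:4]] = -0.7 * s
    base[3][acc[2:4]] = -0.7 * s
    base[6][acc[2:4]] = 0.7 * s
    for c in (4, 5):
        base[c][acc[2:4]] = -0.7 * s
        base[c][acc[4:5]] = -0.5 * s
    # stair direction: gyroscope only
    base[2][gyro[:2]] = 0.7 * s
    base[3][gyro[:2]] = -0.7 * s
    # sitting vs standing: dense direction over informative coords
    u = rng.standard_normal(C)
    mask = np.zeros(C, dtype=bool)
    mask[info] = True
    u[~mask] = 0.0
    u /= np.linalg.norm(u)
    base[4] += 0.45 * s * u
    base[5] -= 0.45 * s * u

    # hidden-state and mixture modulation, shared across classes (keeps the
    # 2-vs-3 acc marginals identical)
    state_off = 0.25 * s * np.where(np.arange(C) % 2 == 0, 1.0, -1.0)
    state_off[noise_acc] = 0.0
    state_off[noise_gyro] = 0.0
    mix_off = 0.12 * np.where(np.arange(C) % 3 == 0, 1.0, -1.0)
    mix_off[noise_acc] = 0.0
    mix_off[noise_gyro] = 0.0

    transmat = np.array([[0.85, 0.15], [0.15, 0.85]])
    startprob = np.array([0.6, 0.4])
    weights = np.tile([0.55, 0.45], (2, 1))
    variances = np.full((2, 2, C), spec.noise_sd**2)

    models = {}
    for c in range(1, 7):
        means = np.empty((2, 2, C))
        for q in range(2):
            for m in range(2):
                means[q, m] = (
                    base[c]
                    + (2 * q - 1) * 0.5 * state_off
                    + (2 * m - 1) * 0.5 * mix_off
                )
        models[c] = GaussianMixtureHMM.from_params(
            startprob, transmat, weights, means, variances,
            variance_floor=min(1e-3, spec.noise_sd**2),
        )
    return models


def generate(spec: SyntheticSpec) -> tuple[FeatureDataset, FeatureDataset]:
    """Sample, normalize and split the synthetic corpus.

    Returns ``(train, test)`` with a per-class stratified
    ``train_fraction`` / remainder split.  Per-channel affine min-max
    normalization to [-1, 1] is computed on the training rows and applied to
    the test rows (clipped), as a deployed pipeline would.
    """
    models = _class_models(spec)
    root = np.random.SeedSequence([spec.seed, 40823])
    class_seeds = root.spawn(6)
    X_rows, y_rows = [], []
    for c in range(1, 7):
        rng = np.random.default_rng(class_seeds[c - 1])
        for _ in range(spec.n_per_class):
            frames = models[c].sample(
                spec.n_frames, seed=int(rng.integers(0, 2**31 - 1))
            )
            X_rows.append(frames.ravel())
            y_rows.append(c)
    X = np.asarray(X_rows)
    y = np.asarray(y_rows, dtype=int)

    # stratified split, deterministic per seed
    split_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 71]))
    train_mask = np.zeros(len(y), dtype=bool)
    for c in range(1, 7):
        idx = np.flatnonzero(y == c)
        idx = split_rng.permutation(idx)
        n_train = int(round(spec.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_mask[idx[:n_train]] = True

    lo = X[train_mask].min(axis=0)
    hi = X[train_mask].max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = np.clip(2.0 * (X - lo) / span - 1.0, -1.0, 1.0)

    names = spec.feature_names()
    train = FeatureDataset(
        Xn[train_mask], y[train_mask], names, split="train", normalized=True
    )
    test = FeatureDataset(
        Xn[~train_mask], y[~train_mask], names, split="test", normalized=True
    )
    return train, test


_DESCRIBE_FIELDS = [
    "n_per_class", "p", "n_frames", "n_channels", "acc_fraction",
    "separation", "noise_sd", "train_fraction", "seed",
]


def describe(spec: SyntheticSpec) -> str:
    """Human-readable provenance block (parseable back via parse_describe)."""
    lines = ["# synthetic activity-window generator"]
    for f in _DESCRIBE_FIELDS:
        lines.append(f"{f} = {getattr(spec, f)!r}")
    return "\n".join(lines) + "\n"


def parse_describe(text: str) -> SyntheticSpec:
    """Inverse of :func:`describe`."""
    kwargs = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key in _DESCRIBE_FIELDS:
            kwargs[key] = type(getattr(SyntheticSpec(), key))(
                ast.literal_eval(value.strip())
            )
    return SyntheticSpec(**kwargs)
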