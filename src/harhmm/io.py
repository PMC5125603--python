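"""Readers and writers for UCI-HAR-style feature-window files.

The on-disk layout is three plain-text files per split: a whitespace-delimited
numeric matrix (one window per row), a one-integer-per-line label file with
activity codes 1-6, and a one-name-per-line feature list whose names carry the
sensor of origin as an ``Acc``/``Gyro`` substring.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureDataset",
    "FormatError",
    "read_feature_matrix",
    "read_labels",
    "read_feature_names",
    "write_matrix",
    "write_labels",
    "write_feature_names",
    "load_dataset",
]

#: Activity codes used throughout: 1 Walking, 2 Upstairs, 3 Downstairs,
#: 4 Sitting, 5 Standing, 6 Laying.
VALID_LABELS = frozenset(range(1, 7))


class FormatError(ValueError):
    """A file violated the expected plain-text dialect."""


@dataclasses.dataclass
class FeatureDataset:
    """A labelled matrix of feature windows with named channels.

    Parameters
    ----------
    X : ndarray of shape (n_windows, n_features)
        Feature values; normalized data lies in [-1, 1].
    y : ndarray of shape (n_windows,)
        Integer activity codes in {1..6}.
    feature_names : sequence of str
        One name per column; ``Acc``/``Gyro`` substrings identify the sensor.
    split : {"train", "test", "unsplit"}
    normalized : bool
        True when every entry of ``X`` lies in [-1, 1].
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    split: str = "unsplit"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label count {len(self.y)} != row count {self.X.shape[0]}"
            )
        self.feature_names = [str(n) for n in self.feature_names]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.X.shape[1]} columns"
            )
        if self.split not in ("train", "test", "unsplit"):
            raise ValueError(f"unknown split tag {self.split!r}")
        bad = set(np.unique(self.y)) - VALID_LABELS
        if bad:
            raise ValueError(f"labels outside 1..6: {sorted(bad)}")
        if self.normalized and self.X.size and (
            self.X.min() < -1.0 or self.X.max() > 1.0
        ):
            raise ValueError("normalized flag set but values fall outside [-1, 1]")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, mask_or_index) -> "FeatureDataset":
        """Dataset restricted to the given rows (labels follow)."""
        return FeatureDataset(
            self.X[mask_or_index],
            self.y[mask_or_index],
            list(self.feature_names),
            split=self.split,
            normalized=self.normalized,
        )

    def subset_columns(self, indices: Sequence[int]) -> "FeatureDataset":
        """Dataset restricted to the given columns, names kept in order."""
        indices = np.asarray(indices, dtype=int)
        if indices.size and (indices.min() < 0 or indices.max() >= self.n_features):
            raise IndexError(
                f"column index out of range for p={self.n_features}: "
                f"{indices[(indices < 0) | (indices >= self.n_features)].tolist()}"
            )
        return FeatureDataset(
            self.X[:, indices],
            self.y,
            [self.feature_names[i] for i in indices],
            split=self.split,
            normalized=self.normalized,
        )


def read_feature_matrix(path) -> np.ndarray:
    """Parse a whitespace-delimited numeric matrix, preserving row order.

    Any run of spaces/tabs delimits; scientific notation is accepted.
    Ragged rows and non-numeric tokens raise :class:`FormatError` naming the
    offending 1-based line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank lines tolerated
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno}: "
                    f"{len(tokens)} tokens, expected {width}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric token at line {lineno}: {exc}"
                ) from None
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def read_labels(path, strict: bool = True) -> np.ndarray:
    """Parse a one-integer-per-line label file.

    With ``strict`` (the default) any code outside 1..6 is rejected.
    """
    path = Path(path)
    labels: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                value = int(token)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer label at line {lineno}: {token!r}"
                ) from None
            if strict and value not in VALID_LABELS:
                raise ValueError(
                    f"{path}: label {value} at line {lineno} outside 1..6"
                )
            labels.append(value)
    if not labels:
        raise FormatError(f"{path}: empty label file")
    return np.asarray(labels, dtype=int)


def read_feature_names(path) -> list[str]:
    """Parse a one-name-per-line feature list (UCI ``features.txt`` dialect).

    Lines of the form ``<index> <name>`` (the official file) or bare names are
    both accepted.
    """
    path = Path(path)
    names: list[str] = []
    with path.open() as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) >= 2 and tokens[0].isdigit():
                names.append(" ".join(tokens[1:]))
            else:
                names.append(" ".join(tokens))
    if not names:
        raise FormatError(f"{path}: empty feature-name file")
    return names


def write_matrix(path, X: np.ndarray, fmt: str = "%.6g") -> None:
    """Write a matrix in the whitespace dialect (single-space, %.6g)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    np.savetxt(Path(path), X, fmt=fmt, delimiter=" ")


def write_labels(path, y) -> None:
    np.savetxt(Path(path), np.asarray(y, dtype=int), fmt="%d")


def write_feature_names(path, names: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


def load_dataset(
    features_path,
    labels_path,
    names_path,
    split_tag: str = "unsplit",
    strict_labels: bool = True,
) -> FeatureDataset:
    """Assemble a :class:`FeatureDataset` from the three on-disk files.

    The normalized flag is set by scanning the value range; dimension
    mismatches raise with all three counts stated.
    """
    X = read_feature_matrix(features_path)
    y = read_labels(labels_path, strict=strict_labels)
    names = read_feature_names(names_path)
    if len(y) != X.shape[0] or len(names) != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix is {X.shape[0]}x{X.shape[1]}, "
            f"{len(y)} labels, {len(names)} feature names"
        )
    normalized = bool(X.size) and float(X.min()) >= -1.0 and float(X.max()) <= 1.0
    return FeatureDataset(X, y, names, split=split_tag, normalized=normalized)
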