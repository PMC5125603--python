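"""Locality preserving projections with a sparse reconstruction graph.

Classic LPP builds a k-nearest-neighbour heat-kernel affinity graph and finds
the linear map A minimising sum_ij ||A^T x_i - A^T x_j||^2 W_ij, i.e. the
smallest generalized eigenvectors of X^T L X a = lambda X^T D X a with
L = D - W the graph Laplacian.  The sparse variant replaces the manual
neighbourhood choice: row i of W is the nonnegative l1-penalised
reconstruction of x_i from the remaining samples,

    min_w ||x_i - X^T w||^2 + lambda * ||w||_1,   w >= 0, w_i = 0,

so the number and identity of each sample's neighbours is selected
adaptively by the sparsity penalty.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SparseGraph",
    "Projection",
    "nonnegative_lasso",
    "sparse_reconstruction_weights",
    "knn_heat_weights",
    "lpp_project",
    "transform",
    "SparseLPP",
    "LPP",
]


@dataclasses.dataclass
class SparseGraph:
    """Nonnegative affinity graph with degree matrix and Laplacian.

    ``W`` has zero diagonal and nonnegative entries; ``D`` is diagonal with
    the row sums of ``W``; ``L = D - W``.  ``builder`` records whether the
    weights came from the l1 sparse-reconstruction problem or the classic
    k-NN heat kernel.
    """

    W: np.ndarray
    symmetrized: bool
    builder: str
    lambda_l1: float | None = None

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("W must have an exactly zero diagonal")
        if np.any(W < 0):
            raise ValueError("W must be nonnegative")
        self.W = W

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def L(self) -> np.ndarray:
        return self.D - self.W

    def symmetrize(self) -> "SparseGraph":
        """Return the graph with W replaced by (W + W^T)/2."""
        if self.symmetrized:
            return self
        return SparseGraph(
            (self.W + self.W.T) / 2.0,
            symmetrized=True,
            builder=self.builder,
            lambda_l1=self.lambda_l1,
        )


@dataclasses.dataclass
class Projection:
    """A learned linear embedding x -> A^T x.

    ``A`` is p x d with columns ordered by ascending generalized eigenvalue;
    each column is scaled so a^T (X^T D X + ridge I) a = 1.
    """

    A: np.ndarray
    eigenvalues: np.ndarray
    d: int
    regularization: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.A.shape[0]:
            raise ValueError(
                f"expected {self.A.shape[0]} features, got {X.shape[1]}"
            )
        return X @ self.A


def nonnegative_lasso(
    A: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    free: np.ndarray | None = None,
) -> np.ndarray:
    """Coordinate descent for min_w ||y - A w||^2 + lam * sum(w), w >= 0.

    Under the nonnegativity constraint the l1 norm is the plain sum, so each
    coordinate has the closed-form update
    w_j <- max(0, (A_j^T r_j - lam/2) / ||A_j||^2) with r_j the partial
    residual.  ``free`` optionally restricts which coordinates may be
    nonzero.  Converges when no coordinate moves more than ``tol``.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    w = np.zeros(n)
    if free is None:
        free = np.arange(n)
    norms = np.einsum("ij,ij->j", A, A)
    resid = y.copy()
    half_lam = lam / 2.0
    for _ in range(max_iter):
        delta = 0.0
        for j in free:
            nj = norms[j]
            if nj <= 0.0:
                continue
            old = w[j]
            rho = A[:, j] @ resid + nj * old
            new = max(0.0, (rho - half_lam) / nj)
            if new != old:
                resid += A[:, j] * (old - new)
                w[j] = new
                delta = max(delta, abs(new - old))
        if delta <= tol:
            break
    return w


def sparse_reconstruction_weights(
    X: np.ndarray,
    lambda_l1: float = 0.1,
    solver_tol: float = 1e-8,
    max_iter: int = 10_000,
) -> SparseGraph:
    """Build the l1 sparse-reconstruction affinity graph over the rows of X.

    Row i of the returned W minimises ||x_i - X^T w||^2 + lambda ||w||_1
    subject to w >= 0 and w_i = 0.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to build a graph")
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be >= 0")
    if lambda_l1 == 0.0 and np.allclose(X, X[0]):
        warnings.warn(
            "all samples identical and lambda_l1=0: reconstruction weights "
            "are degenerate",
            RuntimeWarning,
        )
    basis = X.T  # p x n, columns are samples
    W = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        free = idx[idx != i]
        W[i] = nonnegative_lasso(
            basis, X[i], lambda_l1, tol=solver_tol, max_iter=max_iter, free=free
        )
        W[i, i] = 0.0
    return SparseGraph(W, symmetrized=False, builder="sparse_l1", lambda_l1=lambda_l1)


def knn_heat_weights(X: np.ndarray, k: int, sigma: float) -> SparseGraph:
    """Classic LPP affinity: heat-kernel weights on the symmetric k-NN graph.

    W_ij = exp(-||x_i - x_j||^2 / sigma) when j is among i's k nearest
    neighbours or vice versa; zero otherwise.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    order = np.argsort(d2, axis=1, kind="stable")
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        # skip self (distance 0 sorts first; ties with duplicates are fine
        # because the self column is removed explicitly)
        neigh = [j for j in order[i] if j != i][:k]
        adj[i, neigh] = True
    adj |= adj.T
    W = np.where(adj, np.exp(-d2 / sigma), 0.0)
    np.fill_diagonal(W, 0.0)
    return SparseGraph(W, symmetrized=True, builder="knn_heat")


def lpp_project(
    X: np.ndarray,
    graph: SparseGraph,
    d: int,
    ridge: float = 1e-6,
    zero_tol: float = 1e-10,
) -> Projection:
    """Solve X^T L X a = lambda X^T D X a for the d smallest eigenpairs.

    The graph is symmetrized first.  ``ridge`` scales with trace(X^T D X)/p
    and is added to the right-hand matrix so that rank-deficient problems
    (p > n, constant columns) remain solvable.  Eigenvalues below
    ``zero_tol`` (relative to the largest magnitude) are treated as
    degenerate directions and skipped when enough informative ones exist.
    """
    X = np.asarray(X, dtype=float)
    graph = graph.symmetrize()
    if graph.W.shape[0] != X.shape[0]:
        raise ValueError("graph and X disagree on the number of samples")
    p = X.shape[1]
    if d > p:
        raise ValueError(f"d={d} exceeds feature count p={p}")
    SL = X.T @ graph.L @ X
    SD = X.T @ graph.D @ X
    scale = np.trace(SD) / p if p else 1.0
    if scale <= 0:
        scale = 1.0
    reg = ridge * scale
    SDr = SD + reg * np.eye(p)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(SL, SDr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"generalized eigenproblem failed (rank-deficient X^T D X and "
            f"ridge={ridge}): {exc}"
        ) from exc
    # eigh returns ascending eigenvalues with B-orthonormal eigenvectors,
    # i.e. a^T SDr a = 1 — exactly the LPP scale constraint (up to ridge).
    finite = np.isfinite(eigvals)
    eigvals, eigvecs = eigvals[finite], eigvecs[:, finite]
    if eigvals.size < d:
        raise ValueError(
            f"only {eigvals.size} eigenpairs attainable, requested d={d}"
        )
    ref = np.abs(eigvals).max() if eigvals.size else 0.0
    informative = np.abs(eigvals) > zero_tol * ref
    keep = np.flatnonzero(informative)
    if keep.size < d:
        # not enough informative directions: fall back to the smallest d
        keep = np.arange(eigvals.size)
    keep = keep[:d]
    return Projection(
        A=eigvecs[:, keep],
        eigenvalues=eigvals[keep],
        d=d,
        regularization=reg,
    )


def transform(projection: Projection, X: np.ndarray) -> np.ndarray:
    """Embed rows of X: y_i = A^T x_i (row convention: X @ A)."""
    return projection.transform(X)


class _BaseLPP(TransformerMixin, BaseEstimator):
    """Shared fit/transform machinery for the two graph builders."""

    def _fit_graph(self, X) -> SparseGraph:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        X = validate_data(self, X)
        graph = self._fit_graph(X)
        proj = lpp_project(X, graph, self.n_components, ridge=self.ridge)
        self.graph_ = graph
        self.projection_ = proj
        self.components_ = proj.A
        self.eigenvalues_ = proj.eigenvalues
        return self

    def transform(self, X):
        check_is_fitted(self, "projection_")
        X = validate_data(self, X, reset=False)
        return self.projection_.transform(X)


class SparseLPP(_BaseLPP):
    """Sparse locality preserving projection transformer.

    Fits the l1 sparse-reconstruction graph on the training rows, solves the
    LPP generalized eigenproblem, and maps new data through the learned
    linear embedding (out-of-sample by construction).

    Parameters
    ----------
    n_components : int, default=13
        Embedding dimension d.
    lambda_l1 : float, default=0.1
        Sparsity penalty of the per-row reconstruction problem, on data
        normalized to [-1, 1].
    ridge : float, default=1e-6
        Trace-scaled regularization of X^T D X.
    solver_tol, max_iter :
        Coordinate-descent stopping parameters.
    """

    def __init__(
        self,
        n_components: int = 13,
        lambda_l1: float = 0.1,
        ridge: float = 1e-6,
        solver_tol: float = 1e-8,
        max_iter: int = 10_000,
    ):
        self.n_components = n_components
        self.lambda_l1 = lambda_l1
        self.ridge = ridge
        self.solver_tol = solver_tol
        self.max_iter = max_iter

    def _fit_graph(self, X):
        return sparse_reconstruction_weights(
            X, self.lambda_l1, solver_tol=self.solver_tol, max_iter=self.max_iter
        )


class LPP(_BaseLPP):
    """Classic locality preserving projection (k-NN heat-kernel graph)."""

    def __init__(
        self,
        n_components: int = 13,
        n_neighbors: int = 5,
        sigma: float = 1.0,
        ridge: float = 1e-6,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.sigma = sigma
        self.ridge = ridge

    def _fit_graph(self, X):
        return knn_heat_weights(X, self.n_neighbors, self.sigma)
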