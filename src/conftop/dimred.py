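"""Dimensionality reduction of conformation vectors: spherical PCA and Isomap.

Both methods project the M x 3N matrix of flattened conformations to a few
coordinates.  Spherical PCA rescales every data vector to unit norm before
a standard PCA, which bounds the leverage any outlier can exert.  Isomap
builds a K-nearest-neighbour graph (K chosen as the minimal value giving a
single connected component), measures geodesic distances along it, and
embeds them by classical multidimensional scaling; unlike a linear
projection it preserves the topology of a curved conformational manifold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .exceptions import DegenerateRowError, ParameterError

__all__ = [
    "EmbeddedCloud",
    "spherical_pca",
    "minimal_connected_k",
    "isomap_embed",
    "classical_mds",
]


@dataclass
class EmbeddedCloud:
    """Reduced-coordinate point cloud.

    ``points`` is M x d; ``explained_variance`` holds per-component variance
    fractions (non-increasing, each in [0, 1], summing to <= 1);
    ``source_indices`` maps rows back to the originating trajectory rows.
    """

    points: np.ndarray
    method: str
    explained_variance: np.ndarray
    source_indices: np.ndarray = field(default=None)
    n_neighbors: int | None = None
    components: np.ndarray | None = None  # principal directions (PCA-type methods)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.points))
        ev = self.explained_variance
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12):
            raise ValueError("explained_variance fractions must lie in [0, 1]")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        if ev.sum() > 1 + 1e-9:
            raise ValueError("explained_variance fractions must sum to <= 1")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry of each column positive."""
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return scores


def spherical_pca(
    X: np.ndarray,
    d: int,
    center_rows_first: bool = False,
    source_indices: np.ndarray | None = None,
) -> EmbeddedCloud:
    """Spherical PCA: rescale each data vector to unit norm, then standard PCA.

    Parameters
    ----------
    X : ndarray, shape (M, D)
        Data matrix, one conformation vector per row.
    d : int
        Number of components to keep (truncated to the data rank, with a
        warning, if larger).
    center_rows_first : bool
        If True, subtract the column mean before projecting rows onto the
        unit sphere.  The default follows the plain formulation: normalize
        the raw vectors, so rows that are already unit-norm reproduce
        standard PCA exactly.

    Notes
    -----
    Projecting onto the unit sphere caps the norm of every observation, so
    a distant outlier can no longer dominate the covariance — the robust
    property this variant is used for.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ParameterError("need an (M >= 2) x D data matrix")
    if center_rows_first:
        X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise DegenerateRowError(f"row {bad} has zero norm")
    U = X / norms[:, None]

    # rows are unit-norm, so an absolute tolerance is the right scale here
    rank = np.linalg.matrix_rank(U - U.mean(axis=0), tol=1e-9)
    n_comp = min(d, rank, len(U) - 1, U.shape[1])
    if n_comp < d:
        warnings.warn(
            f"requested {d} components but data rank is {n_comp}; truncating",
            stacklevel=2,
        )
    if n_comp == 0:  # no variance at all: empty embedding
        return EmbeddedCloud(
            points=np.zeros((len(U), 0)),
            method="sphpca",
            explained_variance=np.zeros(0),
            source_indices=source_indices,
            components=np.zeros((0, U.shape[1])),
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(U)
    return EmbeddedCloud(
        points=_fix_signs(scores),
        method="sphpca",
        explained_variance=pca.explained_variance_ratio_,
        source_indices=source_indices,
        components=pca.components_,
    )


def minimal_connected_k(X: np.ndarray) -> int:
    """Smallest K >= 1 whose symmetrized K-NN graph has one connected component.

    The graph keeps an edge when either endpoint lists the other among its
    K nearest neighbours (union rule).
    """
    X = np.asarray(X, dtype=float)
    m = len(X)
    if m < 2:
        raise ParameterError("need at least 2 points")
    for k in range(1, m):
        g = kneighbors_graph(X, k, mode="connectivity")
        sym = g.maximum(g.T)
        n_comp, _ = connected_components(sym, directed=False)
        if n_comp == 1:
            return k
    return m - 1


def classical_mds(D: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Returns the top-``d`` coordinates and variance fractions computed over
    the positive eigenvalues of the doubly-centred Gram matrix.  Warns when
    the negative eigenvalue mass rivals the positive mass (strongly
    non-Euclidean distances).
    """
    D = np.asarray(D, dtype=float)
    m = len(D)
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos_mass = float(evals[evals > 0].sum())
    n_pos = int(np.sum(evals > max(1e-12, 1e-12 * abs(evals[0]))))
    n_comp = min(d, n_pos) if n_pos else 0
    if n_comp < d:
        warnings.warn(f"only {n_comp} positive MDS eigenvalues; truncating", stacklevel=2)

    # a discarded negative eigenvalue rivalling the leading component means the
    # distances carry real non-Euclidean distortion, not just rounding noise
    neg_max = float(max(0.0, -evals[-1]))
    if n_comp > 0 and neg_max > 0.25 * evals[0]:
        warnings.warn(
            "geodesic distances are strongly non-Euclidean "
            f"(|lambda_min| = {neg_max:.3g} exceeds a retained component)",
            stacklevel=2,
        )

    lam = np.clip(evals[:n_comp], 0.0, None)
    coords = evecs[:, :n_comp] * np.sqrt(lam)
    frac = lam / pos_mass if pos_mass > 0 else np.zeros(n_comp)
    return _fix_signs(coords), frac


def isomap_embed(
    X: np.ndarray,
    d: int,
    k: int | None = None,
    source_indices: np.ndarray | None = None,
) -> EmbeddedCloud:
    """Isomap embedding: K-NN graph -> geodesic distances -> classical MDS.

    ``k`` defaults to :func:`minimal_connected_k`, the smallest neighbour
    count that joins the cloud into one component.  Edge weights are
    Euclidean distances, geodesics are exact Dijkstra shortest paths, and
    variance fractions come from the positive MDS eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < d + 1:
        raise ParameterError(f"need at least d+1={d + 1} points")
    if k is None:
        k = minimal_connected_k(X)
    g = kneighbors_graph(X, k, mode="distance")
    sym = g.maximum(g.T)
    D = shortest_path(sym, method="D", directed=False)
    if np.any(np.isinf(D)):
        raise ParameterError(f"K={k} does not connect the cloud")
    coords, frac = classical_mds(D, d)
    return EmbeddedCloud(
        points=coords,
        method="isomap",
        explained_variance=frac,
        source_indices=source_indices,
        n_neighbors=k,
    )
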