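"""Independent brute-force oracles used only by the test suite.

These deliberately take different algorithmic routes from the package:
Betti numbers from GF(2) boundary-matrix ranks (no persistence pairing),
single-linkage merge heights from scipy, and rigid superposition from
numerical optimization over rotation vectors (no Kabsch SVD).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def gf2_rank(M: np.ndarray) -> int:
    """Rank of a 0/1 matrix over the two-element field (Gaussian elimination)."""
    M = (np.asarray(M) % 2).astype(np.uint8).copy()
    rank = 0
    rows, cols = M.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if M[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        M[[rank, pivot]] = M[[pivot, rank]]
        for r in range(rows):
            if r != rank and M[r, c]:
                M[r] ^= M[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def betti_numbers(simplices: list[tuple[int, ...]], max_degree: int = 1) -> list[int]:
    """Betti numbers b_0..b_max of a simplicial complex via boundary ranks.

    ``b_k = #k-simplices - rank(d_k) - rank(d_{k+1})`` with d_k the
    boundary map from k-chains to (k-1)-chains over GF(2).
    """
    by_dim: dict[int, list[tuple[int, ...]]] = {}
    for s in simplices:
        by_dim.setdefault(len(s) - 1, []).append(tuple(sorted(s)))
    index = {d: {s: i for i, s in enumerate(sorted(ss))} for d, ss in by_dim.items()}

    def boundary_rank(k: int) -> int:
        if k < 1 or k not in by_dim or (k - 1) not in by_dim:
            return 0
        rows = index[k - 1]
        mat = np.zeros((len(rows), len(by_dim[k])), dtype=np.uint8)
        for j, s in enumerate(sorted(by_dim[k])):
            for face in itertools.combinations(s, k):
                mat[rows[face], j] = 1
        return gf2_rank(mat)

    out = []
    for k in range(max_degree + 1):
        nk = len(by_dim.get(k, []))
        out.append(nk - boundary_rank(k) - boundary_rank(k + 1))
    return out


def optimize_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 12, seed: int = 0) -> float:
    """Minimal RMSD by multi-start numerical optimization over rotation vectors."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    rng = np.random.default_rng(seed)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        d = P @ R.T - Q
        return np.sqrt((d * d).sum() / len(P))

    best = np.inf
    starts = [np.zeros(3)] + list(rng.uniform(-np.pi, np.pi, size=(n_starts - 1, 3)))
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    return float(best)
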