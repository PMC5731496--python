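"""Landmarks, filtered complexes and persistent homology (H0, H1).

The conformational cloud Z is summarized by a maxmin landmark subset Z0.
Scale-dependent connectivity among landmarks is encoded as a filtered
graph: for the lazy witness complex, an edge {z0, z1} appears at the
smallest t for which some witness y in Z satisfies
``max(d(y, z0), d(y, z1)) <= t + d(y)``, where d(y) is zero (nu = 0) or
the distance from y to its nearest landmark (nu = 1).  The complex is a
flag complex, so higher simplices appear at the maximum of their edges'
appearance values.  H0 barcodes come from union-find over edges sorted by
appearance value; H1 barcodes from standard boundary-matrix reduction over
the two-element field (an oracle-scale routine, guarded in size).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import ComplexSizeError, ParameterError

__all__ = [
    "LandmarkSet",
    "FilteredGraph",
    "FilteredComplex",
    "Barcode",
    "maxmin_landmarks",
    "coverage_radius",
    "rips_complex",
    "rips_graph",
    "lazy_witness_graph",
    "flag_expansion",
    "h0_barcode",
    "h1_barcode",
    "components_at_scale",
]


@dataclass
class LandmarkSet:
    """Ordered maxmin landmark indices into a cloud, with coverage radius.

    ``coverage_radius`` is R, the maximum over cloud points of the distance
    to the nearest landmark.
    """

    indices: np.ndarray
    coverage_radius: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("landmark indices must be distinct")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class FilteredGraph:
    """Graph on landmark vertices whose edges carry appearance scales.

    ``vertices`` are cloud indices of the landmarks; ``edges`` index into
    ``vertices`` (positions, not cloud indices); ``weights[e]`` is the
    scale t at which edge e appears.  The edge set at scale t is
    ``{e : weights[e] <= t}``, monotone in t by construction.
    """

    vertices: np.ndarray
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("appearance values must be non-negative")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges_at(self, t: float) -> np.ndarray:
        return self.edges[self.weights <= t]


@dataclass
class FilteredComplex:
    """Simplices (vertex-position tuples) with appearance values, flag-filtered."""

    vertices: np.ndarray
    simplices: list[tuple[int, ...]]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class Barcode:
    """Persistence intervals for one homology degree; death may be ``inf``."""

    degree: int
    intervals: np.ndarray  # (n, 2) birth/death

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if np.any(self.intervals[:, 0] > self.intervals[:, 1]):
            raise ValueError("birth must not exceed death")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def finite_deaths(self) -> np.ndarray:
        d = self.intervals[:, 1]
        return d[np.isfinite(d)]

    @property
    def n_infinite(self) -> int:
        return int(np.sum(np.isinf(self.intervals[:, 1])))

    def betti_at(self, t: float) -> int:
        """Number of intervals alive at scale t (birth <= t < death)."""
        b, d = self.intervals[:, 0], self.intervals[:, 1]
        return int(np.sum((b <= t) & (t < d)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": self.degree,
                "birth": self.intervals[:, 0],
                "death": self.intervals[:, 1],
            }
        )


# ---------------------------------------------------------------------------
# Landmark selection
# ---------------------------------------------------------------------------

def maxmin_landmarks(
    cloud: np.ndarray,
    n: int,
    seed: int | None = None,
    first: int | None = None,
) -> LandmarkSet:
    """Sequential maxmin landmark selection.

    The first landmark is drawn uniformly under ``seed`` (or forced with
    ``first``); each subsequent landmark is the cloud point maximizing the
    Euclidean distance to the already-chosen set.  Ties break toward the
    lowest index, making the selection deterministic under a fixed seed.
    """
    cloud = np.asarray(cloud, dtype=float)
    m = len(cloud)
    if n < 1:
        raise ParameterError("need n >= 1 landmarks")
    if n > m:
        warnings.warn(f"requested {n} landmarks from {m} points; capping at {m}", stacklevel=2)
        n = m
    if first is None:
        rng = np.random.default_rng(seed)
        first = int(rng.integers(m))
    chosen = [first]
    available = np.ones(m, dtype=bool)
    available[first] = False
    mindist = np.linalg.norm(cloud - cloud[first], axis=1)
    for _ in range(1, n):
        # mask chosen points so duplicate coordinates cannot be re-selected
        nxt = int(np.argmax(np.where(available, mindist, -1.0)))
        chosen.append(nxt)
        available[nxt] = False
        mindist = np.minimum(mindist, np.linalg.norm(cloud - cloud[nxt], axis=1))
    return LandmarkSet(
        indices=np.asarray(chosen), coverage_radius=float(mindist.max()), seed=seed
    )


def coverage_radius(cloud: np.ndarray, landmarks: LandmarkSet | np.ndarray) -> float:
    """R: the maximum distance of any cloud point from its nearest landmark."""
    idx = landmarks.indices if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks)
    if len(idx) == 0:
        raise ParameterError("landmark set is empty")
    cloud = np.asarray(cloud, dtype=float)
    d = cdist(cloud, cloud[idx])
    return float(d.min(axis=1).max())


# ---------------------------------------------------------------------------
# Complex construction
# ---------------------------------------------------------------------------

def rips_complex(points: np.ndarray, r: float, max_dim: int = 2) -> list[tuple[int, ...]]:
    """Vietoris-Rips complex at a single scale r (brute-force oracle).

    Simplices are all point subsets of size <= max_dim + 1 with every
    pairwise distance <= r, returned as sorted index tuples (vertices
    included as 1-tuples).
    """
    if r < 0:
        raise ParameterError("scale r must be >= 0")
    points = np.asarray(points, dtype=float)
    m = len(points)
    D = squareform(pdist(points)) if m > 1 else np.zeros((1, 1))
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i, j in itertools.combinations(range(m), 2):
        if D[i, j] <= r:
            g.add_edge(i, j)
    simplices: list[tuple[int, ...]] = []
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) > max_dim + 1:
            break
        simplices.append(tuple(sorted(clique)))
    return simplices


def rips_graph(points: np.ndarray) -> FilteredGraph:
    """Complete filtered graph whose edge appearance values are Euclidean distances.

    Flag-expanding this graph yields the Rips filtration of the point set.
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    edges = np.array(list(itertools.combinations(range(m), 2)), dtype=int).reshape(-1, 2)
    weights = pdist(points)
    return FilteredGraph(vertices=np.arange(m), edges=edges, weights=weights)


def lazy_witness_graph(
    cloud: np.ndarray,
    landmarks: LandmarkSet | np.ndarray,
    nu: int = 0,
) -> FilteredGraph:
    """1-skeleton of the lazy witness stream LW^nu over all scales.

    For each landmark pair (z0, z1) the appearance value is

        t_e = max(0, min over witnesses y of (max(d(y, z0), d(y, z1)) - d(y)))

    with d(y) = 0 for nu = 0 and the distance from y to its closest
    landmark for nu = 1.  Witnesses range over the entire cloud (landmarks
    included).  Edge appearance values are computed once; the stream at any
    t is a thresholding of this graph.
    """
    if nu not in (0, 1):
        raise ParameterError("nu must be 0 or 1")
    cloud = np.asarray(cloud, dtype=float)
    idx = landmarks.indices if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks)
    L = len(idx)
    D = cdist(cloud, cloud[idx])  # witness-to-landmark distances, M x L
    dv = np.zeros(len(cloud)) if nu == 0 else D.min(axis=1)
    pairs = np.array(list(itertools.combinations(range(L), 2)), dtype=int).reshape(-1, 2)
    weights = np.empty(len(pairs))
    for e, (i, j) in enumerate(pairs):
        weights[e] = np.min(np.maximum(D[:, i], D[:, j]) - dv)
    return FilteredGraph(vertices=idx, edges=pairs, weights=np.clip(weights, 0.0, None))


def flag_expansion(graph: FilteredGraph, max_dim: int = 2) -> FilteredComplex:
    """Flag (clique) expansion of a filtered graph up to ``max_dim``.

    Every k-clique of the full graph becomes a (k-1)-simplex appearing at
    the maximum of its edges' appearance values; vertices appear at 0.
    """
    if max_dim < 1:
        raise ParameterError("max_dim must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    wmap: dict[tuple[int, int], float] = {}
    for (i, j), w in zip(graph.edges, graph.weights):
        a, b = int(min(i, j)), int(max(i, j))
        wmap[(a, b)] = min(w, wmap.get((a, b), np.inf))
        g.add_edge(a, b)
    simplices: list[tuple[int, ...]] = []
    values: list[float] = []
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) > max_dim + 1:
            break
        simplex = tuple(sorted(clique))
        if len(simplex) == 1:
            val = 0.0
        else:
            val = max(
                wmap[(a, b)] for a, b in itertools.combinations(simplex, 2)
            )
        simplices.append(simplex)
        values.append(val)
    return FilteredComplex(
        vertices=graph.vertices, simplices=simplices, values=np.asarray(values)
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

class _UnionFind:
    """Union-find with elder-rule bookkeeping (smaller root index survives)."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        # all components are born at 0; keep the lower index as the elder
        if ra > rb:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True


def h0_barcode(graph: FilteredGraph) -> Barcode:
    """Degree-0 barcode of a filtered graph via union-find.

    Every vertex is born at scale 0.  Processing edges in order of
    appearance, each merge of two components kills one bar at that scale
    (elder rule); each component surviving to t -> infinity contributes one
    infinite bar.
    """
    n = graph.n_vertices
    uf = _UnionFind(n)
    deaths: list[float] = []
    order = np.argsort(graph.weights, kind="stable")
    for e in order:
        i, j = graph.edges[e]
        if uf.union(int(i), int(j)):
            deaths.append(float(graph.weights[e]))
    n_components = n - len(deaths)
    intervals = [(0.0, d) for d in deaths] + [(0.0, np.inf)] * n_components
    return Barcode(degree=0, intervals=np.asarray(intervals))


def _sorted_filtration(complex_: FilteredComplex) -> list[tuple[float, int, tuple[int, ...]]]:
    entries = [
        (float(v), len(s) - 1, s) for s, v in zip(complex_.simplices, complex_.values)
    ]
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return entries


def h1_barcode(complex_: FilteredComplex, max_simplices: int = 2000) -> Barcode:
    """Degree-1 barcode by boundary-matrix reduction over GF(2).

    Exact persistence pairing on a flag-filtered complex built to dimension
    >= 2.  Columns are stored as Python-integer bitmasks; the standard
    left-to-right reduction pairs each negative simplex with the positive
    simplex it kills.  This is an oracle-scale routine: complexes beyond
    ``max_simplices`` raise :class:`ComplexSizeError`.
    """
    if len(complex_) > max_simplices:
        raise ComplexSizeError(
            f"{len(complex_)} simplices exceeds the guard of {max_simplices}"
        )
    entries = _sorted_filtration(complex_)
    if not any(dim >= 2 for _, dim, _ in entries):
        warnings.warn("complex has no 2-simplices; all 1-cycles will be immortal", stacklevel=2)

    index = {s: i for i, (_, _, s) in enumerate(entries)}
    values = [v for v, _, _ in entries]
    dims = [d for _, d, _ in entries]

    columns: list[int] = []
    for _, dim, simplex in entries:
        col = 0
        if dim > 0:
            for face in itertools.combinations(simplex, dim):
                col ^= 1 << index[face]
        columns.append(col)

    low_to_col: dict[int, int] = {}
    pairs: dict[int, int] = {}  # birth simplex -> death simplex
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = col.bit_length() - 1
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        columns[j] = col
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = j
            pairs[low] = j

    paired_deaths = set(pairs.values())
    intervals = []
    for i, dim in enumerate(dims):
        if dim != 1:
            continue
        if i in paired_deaths:
            continue  # negative edge: kills an H0 class, not an H1 birth
        if columns[i] != 0:
            continue  # shouldn't occur for unpaired dims, defensive
        if i in pairs:
            birth, death = values[i], values[pairs[i]]
            if death > birth:
                intervals.append((birth, death))
        else:
            intervals.append((values[i], np.inf))
    return Barcode(degree=1, intervals=np.asarray(intervals).reshape(-1, 2))


def components_at_scale(graph: FilteredGraph, t: float) -> list[np.ndarray]:
    """Connected components of the edges present at scale t.

    Returns a partition of the landmark cloud-indices, as sorted arrays,
    ordered by their smallest member.  Covers every landmark (isolated
    vertices form singleton blocks).
    """
    if t < 0:
        raise ParameterError("scale t must be >= 0")
    n = graph.n_vertices
    uf = _UnionFind(n)
    for i, j in graph.edges_at(t):
        uf.union(int(i), int(j))
    groups: dict[int, list[int]] = {}
    for v in range(n):
        groups.setdefault(uf.find(v), []).append(v)
    blocks = [np.asarray(sorted(graph.vertices[g])) for g in groups.values()]
    blocks.sort(key=lambda b: int(b[0]))
    return blocks
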