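"""Barcode-driven hierarchical clustering of the reduced conformational cloud.

The number of landmarks is chosen by growing the landmark set in steps of
10 until the coverage radius R stabilizes (relative drop < 5%), averaged
over 5 seeded repetitions plus two standard deviations.  The number of
clusters is read off the H0 barcode of the lazy-witness filtration: the
finest level whose merge scale is separated from the next by more than the
bar-gap threshold (0.1 in reduced units).  Per-level partitions are the
connected components at the midpoint of the corresponding scale plateau;
because every level comes from one filtration the partitions nest, and the
resulting dendrogram is laminar by construction.  Clusters are finally
summarized by their member RMSDs to the two endpoint structures and a
medoid representative.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, EmptyResultError, ParameterError
from .structures import CalphaStructure, kabsch_rmsd
from .topology import (
    Barcode,
    FilteredGraph,
    LandmarkSet,
    components_at_scale,
    h0_barcode,
    lazy_witness_graph,
    maxmin_landmarks,
)

__all__ = [
    "ClusterLevel",
    "Dendrogram",
    "ClusterReport",
    "determine_landmark_count",
    "determine_cluster_count",
    "clusters_at_level",
    "prune_outliers",
    "build_hierarchy",
    "cluster_report",
]

#: Absolute bar-gap threshold (reduced-coordinate units) separating cluster levels.
BAR_GAP = 0.1


@dataclass
class ClusterLevel:
    """Partition of the landmarks into ``level`` blocks at filtration scale ``scale``."""

    level: int
    partition: list[np.ndarray]
    scale: float

    def __post_init__(self) -> None:
        self.partition = [np.asarray(sorted(b), dtype=int) for b in self.partition]
        all_members = np.concatenate(self.partition) if self.partition else np.array([], int)
        if len(np.unique(all_members)) != len(all_members):
            raise ConsistencyError("partition blocks overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.partition)

    def members(self) -> np.ndarray:
        return np.sort(np.concatenate(self.partition))

    def block_of(self, landmark: int) -> int:
        for b, block in enumerate(self.partition):
            if landmark in block:
                return b
        raise KeyError(landmark)


@dataclass
class DendrogramNode:
    id: int
    level: int
    block: frozenset
    parent: int | None = None


@dataclass
class Dendrogram:
    """Laminar family of cluster blocks with parent links across levels."""

    nodes: list[DendrogramNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        blocks = [n.block for n in self.nodes]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                inter = a & b
                if inter and not (a <= b or b <= a):
                    raise ConsistencyError("dendrogram blocks are not laminar")

    @property
    def leaves(self) -> list[DendrogramNode]:
        max_level = max(n.level for n in self.nodes)
        return [n for n in self.nodes if n.level == max_level]

    def children(self, node_id: int) -> list[DendrogramNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def is_laminar(self) -> bool:
        try:
            Dendrogram.__post_init__(self)
        except ConsistencyError:
            return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "id": n.id,
                    "level": n.level,
                    "parent": n.parent,
                    "members": sorted(n.block),
                }
                for n in self.nodes
            ],
            indent=2,
        )


@dataclass
class ClusterReport:
    """Per-cluster summary table plus representative conformation indices.

    ``table`` columns: cluster (1-based, sorted by mean RMSD to the
    designated endpoint), size, mean/sd RMSD to each endpoint (population
    sd, Angstrom) and the representative trajectory index (the member
    closest to the cluster's geometric centre in the reduced space).
    """

    table: pd.DataFrame
    members: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Landmark and cluster count heuristics
# ---------------------------------------------------------------------------

def determine_landmark_count(
    cloud: np.ndarray,
    seed: int = 0,
    step: int = 10,
    rel_tol: float = 0.05,
    n_repetitions: int = 5,
) -> int:
    """Choose the landmark count from the stabilization of the coverage radius R.

    For each of ``n_repetitions`` seeded runs, landmark counts step, 2*step,
    ... are tried until the relative drop in R between consecutive counts
    falls below ``rel_tol`` (a vanishing R counts as converged); the stop
    count is recorded.  Returns ceil(mean + 2*sd) over repetitions (population
    sd), capped at the cloud size.  Clouds smaller than ``step`` return their
    size with a warning.
    """
    cloud = np.asarray(cloud, dtype=float)
    m = len(cloud)
    if m < step:
        warnings.warn(f"cloud of {m} points is smaller than the first step; using {m}", stacklevel=2)
        return m
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_repetitions) % (2**31)
    stops = []
    for s in sub_seeds:
        r_prev = None
        count = step
        while True:
            r_cur = maxmin_landmarks(cloud, min(count, m), seed=int(s)).coverage_radius
            if r_prev is not None:
                converged = r_prev == 0.0 or (r_prev - r_cur) / r_prev < rel_tol
                if converged or count >= m:
                    stops.append(min(count, m))
                    break
            elif count >= m:
                stops.append(m)
                break
            r_prev = r_cur
            count += step
    n = math.ceil(float(np.mean(stops)) + 2.0 * float(np.std(stops)))
    return min(n, m)


def _descending_deaths(barcode: Barcode) -> np.ndarray:
    return np.sort(barcode.finite_deaths)[::-1]


def determine_cluster_count(
    cloud: np.ndarray,
    landmarks: LandmarkSet,
    max_levels: int = 20,
    gap: float = BAR_GAP,
    nu: int = 0,
    graph: FilteredGraph | None = None,
) -> int:
    """Number of clusters from gaps in the H0 barcode.

    With finite merge scales d_1 >= d_2 >= ... of the lazy-witness H0
    barcode (same landmark set throughout), the cluster count is i + 1 for
    the largest i <= max_levels - 1 with d_i - d_{i+1} > gap: the finest
    level of the filtration that is preceded by a bar gap larger than the
    threshold.  Returns 1 when no gap exceeds it or fewer than 2 landmarks
    exist.
    """
    if len(landmarks) < 2:
        return 1
    if graph is None:
        graph = lazy_witness_graph(cloud, landmarks, nu=nu)
    deaths = _descending_deaths(h0_barcode(graph))
    deaths = deaths[:max_levels]
    count = 1
    for i in range(len(deaths) - 1):
        if deaths[i] - deaths[i + 1] > gap:
            count = i + 2
    return count


def clusters_at_level(
    cloud: np.ndarray,
    landmarks: LandmarkSet,
    i: int,
    nu: int = 0,
    graph: FilteredGraph | None = None,
) -> ClusterLevel:
    """Partition the landmarks into exactly ``i`` components when achievable.

    The scale t is the midpoint of the plateau on which the filtration has
    exactly i components (between consecutive merge scales d_i and
    d_{i-1}).  Simultaneous merges can make a count unachievable; the
    nearest achievable partition is then returned with a warning.
    """
    L = len(landmarks)
    if not 1 <= i <= L:
        raise ParameterError(f"level i={i} outside [1, {L}]")
    if graph is None:
        graph = lazy_witness_graph(cloud, landmarks, nu=nu)
    deaths = _descending_deaths(h0_barcode(graph))  # d_1 >= d_2 >= ...
    if len(deaths) == 0:  # single landmark
        return ClusterLevel(level=1, partition=[landmarks.indices.copy()], scale=0.0)
    if i == 1:
        t = float(deaths[0]) * 1.5 + 1.0
    elif i > len(deaths):  # beyond the last merge: singleton regime
        t = float(deaths[-1]) / 2.0
    else:
        upper = deaths[i - 2] if i >= 2 else np.inf
        lower = deaths[i - 1]
        t = float((upper + lower) / 2.0) if np.isfinite(upper) else float(lower) + 1.0
    blocks = components_at_scale(graph, max(t, 0.0))
    if len(blocks) != i:
        warnings.warn(
            f"no scale yields exactly {i} components (simultaneous merges); "
            f"returning {len(blocks)}",
            stacklevel=2,
        )
    return ClusterLevel(level=len(blocks), partition=blocks, scale=max(t, 0.0))


def prune_outliers(level: ClusterLevel, min_size: int = 2) -> tuple[np.ndarray, ClusterLevel]:
    """Drop landmark blocks smaller than ``min_size`` at the selected level.

    Returns the retained landmark indices and the re-emitted partition.
    Raises :class:`EmptyResultError` if nothing survives.
    """
    kept = [b for b in level.partition if len(b) >= min_size]
    if not kept:
        raise EmptyResultError("outlier pruning removed every landmark")
    retained = np.sort(np.concatenate(kept))
    return retained, ClusterLevel(level=len(kept), partition=kept, scale=level.scale)


def build_hierarchy(levels: list[ClusterLevel]) -> Dendrogram:
    """Assemble per-level partitions (i = 1..k) into a laminar dendrogram.

    For consecutive levels, a block of level i that is the union of two or
    more blocks of level i+1 becomes their parent; blocks that persist
    unchanged are chained through identity links.  Violated nesting raises
    :class:`ConsistencyError` (impossible when all levels come from one
    filtration).
    """
    if not levels:
        raise ParameterError("no levels given")
    levels = sorted(levels, key=lambda lv: lv.n_blocks)
    nodes: list[DendrogramNode] = []
    prev_nodes: dict[frozenset, int] = {}
    next_id = 0
    for depth, lv in enumerate(levels):
        cur_nodes: dict[frozenset, int] = {}
        for block in lv.partition:
            fs = frozenset(int(x) for x in block)
            parent = None
            if depth > 0:
                supersets = [pid for pb, pid in prev_nodes.items() if fs <= pb]
                if not supersets:
                    raise ConsistencyError(
                        f"block {sorted(fs)} at level {lv.n_blocks} is not nested "
                        "in any block of the coarser level"
                    )
                parent = supersets[0]
            nodes.append(DendrogramNode(id=next_id, level=depth, block=fs, parent=parent))
            cur_nodes[fs] = next_id
            next_id += 1
        # every coarser block must be exactly covered by its children
        if depth > 0:
            for pb, pid in prev_nodes.items():
                covered: set = set()
                for n in nodes:
                    if n.parent == pid:
                        covered |= n.block
                if covered and covered != set(pb):
                    raise ConsistencyError(
                        f"children of block {sorted(pb)} do not cover it exactly"
                    )
        prev_nodes = cur_nodes
    return Dendrogram(nodes=nodes)


# ---------------------------------------------------------------------------
# Cluster statistics
# ---------------------------------------------------------------------------

def cluster_report(
    partition: list[np.ndarray] | ClusterLevel,
    structures: list[CalphaStructure],
    endpoint_a: CalphaStructure,
    endpoint_b: CalphaStructure,
    reduced_points: np.ndarray,
    source_indices: np.ndarray | None = None,
    order_by: str = "a",
) -> ClusterReport:
    """Summarize each cluster against the two endpoint structures.

    ``partition`` blocks contain cloud row indices; ``structures`` is the
    trajectory (cloud row -> conformation via ``source_indices``, identity
    by default).  For each cluster the report lists its size, the mean and
    population standard deviation of member C-alpha RMSDs to each endpoint,
    and a representative: the member nearest the cluster's geometric centre
    in the reduced space.  Clusters are renumbered 1..k by increasing mean
    RMSD to the designated endpoint (``order_by`` 'a' or 'b').
    """
    blocks = partition.partition if isinstance(partition, ClusterLevel) else partition
    if order_by not in ("a", "b"):
        raise ParameterError("order_by must be 'a' or 'b'")
    reduced_points = np.asarray(reduced_points, dtype=float)
    if source_indices is None:
        source_indices = np.arange(len(reduced_points))

    rows = []
    members_out = []
    for block in blocks:
        block = np.asarray(block, dtype=int)
        if len(block) == 0:
            warnings.warn("skipping empty cluster", stacklevel=2)
            continue
        traj_rows = source_indices[block]
        rmsd_a = np.array([kabsch_rmsd(structures[t], endpoint_a) for t in traj_rows])
        rmsd_b = np.array([kabsch_rmsd(structures[t], endpoint_b) for t in traj_rows])
        centre = reduced_points[block].mean(axis=0)
        rep_pos = int(np.argmin(np.linalg.norm(reduced_points[block] - centre, axis=1)))
        rows.append(
            {
                "size": len(block),
                "mean_rmsd_a": rmsd_a.mean(),
                "sd_rmsd_a": rmsd_a.std(),  # population sd
                "mean_rmsd_b": rmsd_b.mean(),
                "sd_rmsd_b": rmsd_b.std(),
                "representative": int(traj_rows[rep_pos]),
            }
        )
        members_out.append(block)

    table = pd.DataFrame(rows)
    key = "mean_rmsd_a" if order_by == "a" else "mean_rmsd_b"
    order = np.argsort(table[key].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "cluster", np.arange(1, len(table) + 1))
    members_out = [members_out[o] for o in order]
    return ClusterReport(table=table, members=members_out)
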