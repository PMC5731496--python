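"""End-to-end pipeline: sample -> embed -> landmarks -> barcode -> clusters -> report.

A single master seed fans out to per-stage sub-seeds by fixed offsets, so
stages are independently re-runnable and the whole run is reproducible.
Every run writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dimred, hierarchy, sampling, synthetic, topology
from .exceptions import ParameterError
from .structures import CalphaStructure, read_calpha_pdb, write_calpha_pdb

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("conftop")

# fixed per-stage seed offsets from the master seed
_STAGE_OFFSETS = {"sample": 11, "landmarks": 23, "chain": 37}
_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run; serializes losslessly to YAML."""

    # inputs: PDB paths, or a synthetic toy chain when both are None
    start_pdb: str | None = None
    goal_pdb: str | None = None
    chain: str | None = None
    toy_n_res: int = 10
    toy_n_perturbations: int = 20

    # sampling
    max_iterations: int = 60_000
    rotation_limit: float = 5.0
    scaling_factor_a: float = 1.0
    energy_threshold: float = 50.0
    skip_angle_tolerance: float = 1.0
    # run the full iteration budget by default: cluster analysis wants an
    # ensemble covering the pathway, not the earliest goal hit
    goal_rmsd_stop: float = 0.0
    parent_policy: str = "uniform"

    # reduction
    method: str = "isomap"  # or "sphpca"
    dim: int = 3

    # landmark / cluster heuristics
    landmark_step: int = 10
    landmark_rel_tol: float = 0.05
    landmark_repetitions: int = 5
    bar_gap: float = hierarchy.BAR_GAP
    min_cluster_size: int = 2
    max_levels: int = 20
    nu: int = 0

    out_dir: str = "results"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSETS[stage]) % _SEED_MOD

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """Handles to every stage artifact of one pipeline run."""

    config: PipelineConfig
    start: CalphaStructure
    goal: CalphaStructure
    trajectory: sampling.Trajectory
    cloud: dimred.EmbeddedCloud
    landmarks: topology.LandmarkSet
    barcode: topology.Barcode
    n_clusters: int
    levels: list[hierarchy.ClusterLevel]
    retained: np.ndarray
    dendrogram: hierarchy.Dendrogram
    report: hierarchy.ClusterReport
    out_dir: Path | None = None


def _load_endpoints(config: PipelineConfig) -> tuple[CalphaStructure, CalphaStructure]:
    if (config.start_pdb is None) != (config.goal_pdb is None):
        raise ParameterError("provide both endpoint PDBs or neither")
    if config.start_pdb is None:
        return synthetic.toy_chain_pair(
            config.toy_n_res,
            config.toy_n_perturbations,
            seed=config.stage_seed("chain"),
        )
    for path in (config.start_pdb, config.goal_pdb):
        if not Path(path).exists():
            raise FileNotFoundError(f"input stage: endpoint PDB not found: {path}")
    return (
        read_calpha_pdb(config.start_pdb, chain=config.chain),
        read_calpha_pdb(config.goal_pdb, chain=config.chain),
    )


def _restrict_level(level: hierarchy.ClusterLevel, retained: np.ndarray) -> hierarchy.ClusterLevel:
    keep = set(int(x) for x in retained)
    blocks = [b[np.isin(b, list(keep))] for b in level.partition]
    blocks = [b for b in blocks if len(b)]
    return hierarchy.ClusterLevel(level=len(blocks), partition=blocks, scale=level.scale)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage in order and (optionally) write all artifacts.

    Stages: conformational search, dimensionality reduction, landmark-count
    selection, maxmin landmarks, lazy-witness H0 barcode, cluster-count
    selection, per-level partitions, outlier pruning, dendrogram assembly,
    endpoint-RMSD cluster report.  Artifacts: traj.pdb / traj.csv,
    cloud.csv (+ cloud.json sidecar), barcode.csv, clusters.csv,
    hierarchy.json, report.csv, representative PDBs and config.yaml under
    ``config.out_dir``.
    """
    start, goal = _load_endpoints(config)
    logger.info("endpoints: %s -> %s (%d residues)", start.id, goal.id, len(start))

    params = sampling.SearchParams(
        max_iterations=config.max_iterations,
        rotation_limit=config.rotation_limit,
        scaling_factor_a=config.scaling_factor_a,
        energy_threshold=config.energy_threshold,
        skip_angle_tolerance=config.skip_angle_tolerance,
        goal_rmsd_stop=config.goal_rmsd_stop,
        seed=config.stage_seed("sample"),
        parent_policy=config.parent_policy,  # type: ignore[arg-type]
    )
    traj = sampling.run_search(start, goal, params)
    logger.info(
        "search: %d conformations from %d iterations (acceptance %.3f), best RMSD %.3f",
        len(traj), traj.n_iterations, sampling.acceptance_rate(traj), traj.best_rmsd,
    )

    X = traj.as_matrix()
    if config.method == "isomap":
        cloud = dimred.isomap_embed(X, config.dim)
        logger.info("isomap: K=%d", cloud.n_neighbors)
    elif config.method == "sphpca":
        cloud = dimred.spherical_pca(X, config.dim)
    else:
        raise ParameterError(f"unknown reduction method {config.method!r}")
    logger.info("explained variance: %s", np.round(cloud.explained_variance, 4))

    n_landmarks = hierarchy.determine_landmark_count(
        cloud.points,
        seed=config.stage_seed("landmarks"),
        step=config.landmark_step,
        rel_tol=config.landmark_rel_tol,
        n_repetitions=config.landmark_repetitions,
    )
    landmarks = topology.maxmin_landmarks(
        cloud.points, n_landmarks, seed=config.stage_seed("landmarks")
    )
    logger.info("landmarks: %d (coverage radius %.4f)", len(landmarks), landmarks.coverage_radius)

    graph = topology.lazy_witness_graph(cloud.points, landmarks, nu=config.nu)
    barcode = topology.h0_barcode(graph)
    n_clusters = hierarchy.determine_cluster_count(
        cloud.points, landmarks,
        max_levels=config.max_levels, gap=config.bar_gap, nu=config.nu, graph=graph,
    )
    logger.info("clusters: %d", n_clusters)

    levels = [
        hierarchy.clusters_at_level(cloud.points, landmarks, i, nu=config.nu, graph=graph)
        for i in range(1, n_clusters + 1)
    ]
    retained, pruned = hierarchy.prune_outliers(levels[-1], config.min_cluster_size)
    logger.info("retained %d of %d landmarks after pruning", len(retained), len(landmarks))
    dendrogram = hierarchy.build_hierarchy([_restrict_level(lv, retained) for lv in levels])

    structures = traj.structures()
    report = hierarchy.cluster_report(
        pruned, structures, start, goal, cloud.points,
        source_indices=cloud.source_indices, order_by="a",
    )

    out_dir = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        traj.write(out_dir / "traj.pdb", out_dir / "traj.csv")
        _write_cloud(cloud, out_dir)
        barcode.to_dataframe().to_csv(out_dir / "barcode.csv", index=False)
        _write_clusters(pruned, out_dir)
        (out_dir / "hierarchy.json").write_text(dendrogram.to_json())
        report.table.to_csv(out_dir / "report.csv", index=False)
        for _, row in report.table.iterrows():
            rep = structures[int(row["representative"])]
            write_calpha_pdb(rep, out_dir / f"representative_{int(row['cluster'])}.pdb")

    return PipelineResult(
        config=config, start=start, goal=goal, trajectory=traj, cloud=cloud,
        landmarks=landmarks, barcode=barcode, n_clusters=n_clusters, levels=levels,
        retained=retained, dendrogram=dendrogram, report=report, out_dir=out_dir,
    )


def _write_cloud(cloud: dimred.EmbeddedCloud, out_dir: Path) -> None:
    import pandas as pd

    cols = {f"c{j + 1}": cloud.points[:, j] for j in range(cloud.dim)}
    pd.DataFrame({"index": cloud.source_indices, **cols}).to_csv(
        out_dir / "cloud.csv", index=False
    )
    sidecar = {
        "method": cloud.method,
        "n_neighbors": cloud.n_neighbors,
        "explained_variance": [float(v) for v in cloud.explained_variance],
    }
    (out_dir / "cloud.json").write_text(json.dumps(sidecar, indent=2))


def _write_clusters(level: hierarchy.ClusterLevel, out_dir: Path) -> None:
    import pandas as pd

    rows = [
        {"landmark_index": int(m), "cluster": c}
        for c, block in enumerate(level.partition, start=1)
        for m in block
    ]
    pd.DataFrame(rows).to_csv(out_dir / "clusters.csv", index=False)
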