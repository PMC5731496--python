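"""Seeded synthetic generators: labelled point clouds and toy C-alpha chain pairs.

These generators make every pipeline stage testable at desk scale without
any external structure files: Gaussian blobs exercise cluster recovery,
noisy circles provide an analytically known H1 signal, and self-avoiding
toy chains stand in for endpoint PDB pairs in the conformational search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GenerationError, ParameterError
from .sampling import CLASH_DISTANCE, IDEAL_BOND
from .structures import CalphaStructure, apply_dihedral_rotation

__all__ = ["LabeledCloud", "gaussian_blobs", "circle_cloud", "toy_chain_pair"]


@dataclass
class LabeledCloud:
    """Point cloud with the generating-component label of every point."""

    points: np.ndarray
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels disagree in length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_components(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _polygon_centers(k: int, separation: float, dim: int) -> np.ndarray:
    """k centers with adjacent distance ``separation``: regular-polygon vertices."""
    if k == 1:
        return np.zeros((1, dim))
    if k == 2:
        centers = np.array([[0.0, 0.0], [separation, 0.0]])
    else:
        radius = separation / (2.0 * np.sin(np.pi / k))
        ang = 2.0 * np.pi * np.arange(k) / k
        centers = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if dim < 2:
        raise ParameterError("blob clouds need dim >= 2")
    out = np.zeros((k, dim))
    out[:, :2] = centers
    return out


def gaussian_blobs(
    k: int = 3,
    n_per: int = 50,
    centers: np.ndarray | None = None,
    separation: float = 1.0,
    sigma: float = 0.05,
    dim: int = 2,
    seed: int | None = None,
) -> LabeledCloud:
    """k isotropic Gaussian components with known labels.

    When ``centers`` is omitted they are placed on a regular polygon whose
    side length equals ``separation`` (a line for k <= 2), so adjacent
    components are exactly ``separation`` apart.  Defaults emulate the
    well-separated regime used for cluster-count recovery: separation ten
    times the bar-gap threshold and component spread twenty times smaller
    than the separation.
    """
    if k < 1 or n_per < 1:
        raise ParameterError("need k >= 1 and n_per >= 1")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if centers is None:
        if separation <= 0:
            raise ParameterError("separation must be > 0")
        centers = _polygon_centers(k, separation, dim)
    centers = np.asarray(centers, dtype=float)
    if len(centers) != k:
        raise ParameterError("need one centre per component")
    rng = np.random.default_rng(seed)
    points = np.concatenate(
        [c + sigma * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    labels = np.repeat(np.arange(k), n_per)
    return LabeledCloud(points=points, labels=labels, seed=seed)


def circle_cloud(
    n: int, radius: float = 1.0, noise: float = 0.0, seed: int | None = None
) -> LabeledCloud:
    """n points at uniform angles on a circle, with radial Gaussian noise."""
    if n < 3:
        raise ParameterError("need n >= 3 points")
    rng = np.random.default_rng(seed)
    ang = 2.0 * np.pi * np.arange(n) / n
    r = radius + (noise * rng.standard_normal(n) if noise > 0 else 0.0)
    points = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
    return LabeledCloud(points=points, labels=np.zeros(n, dtype=int), seed=seed)


def _min_nonlocal_distance(coords: np.ndarray) -> float:
    """Smallest distance between residues at least 3 apart in sequence."""
    n = len(coords)
    if n < 4:
        return np.inf
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    iu, ju = np.triu_indices(n, k=3)
    return float(dist[iu, ju].min())


def _self_avoiding_chain(n_res: int, rng: np.random.Generator, max_restarts: int = 200) -> np.ndarray:
    """Persistent random walk with 3.8 A bonds, clash-free beyond 2 neighbours."""
    for _ in range(max_restarts):
        coords = np.zeros((n_res, 3))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        coords[1] = coords[0] + IDEAL_BOND * direction
        ok = True
        for i in range(2, n_res):
            placed = False
            for _ in range(50):
                # bias toward the previous direction keeps the chain extended
                trial = direction + 0.7 * rng.standard_normal(3)
                trial /= np.linalg.norm(trial)
                cand = coords[i - 1] + IDEAL_BOND * trial
                back = coords[: max(i - 2, 0)]
                if len(back) == 0 or np.min(np.linalg.norm(back - cand, axis=1)) >= CLASH_DISTANCE:
                    coords[i] = cand
                    direction = trial
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok and _min_nonlocal_distance(coords) >= CLASH_DISTANCE:
            return coords
    raise GenerationError(f"could not build a self-avoiding {n_res}-residue chain")


def toy_chain_pair(
    n_res: int,
    n_perturbations: int = 20,
    seed: int | None = None,
    max_angle: float = 60.0,
) -> tuple[CalphaStructure, CalphaStructure]:
    """Start/goal toy C-alpha chain pair for desk-scale search experiments.

    The start is a self-avoiding chain with exact 3.8 A virtual bonds; the
    goal applies ``n_perturbations`` random pseudo-dihedral rotations of up
    to ``max_angle`` degrees, each re-drawn (bounded retries) until the
    chain stays clash-free (>= 4.0 A between residues 3+ apart).  Both
    endpoints are therefore valid under the default C-alpha energy.
    """
    if n_res < 6:
        raise ParameterError("need n_res >= 6")
    rng = np.random.default_rng(seed)
    start = CalphaStructure(
        id=f"toy{n_res}-start",
        residue_ids=np.arange(1, n_res + 1),
        coords=_self_avoiding_chain(n_res, rng),
    )
    goal = start.copy(new_id=f"toy{n_res}-goal")
    n_bonds = n_res - 3
    for _ in range(n_perturbations):
        for _ in range(100):
            bond = int(rng.integers(n_bonds))
            delta = float(rng.uniform(-max_angle, max_angle))
            cand = apply_dihedral_rotation(goal, bond, delta)
            if _min_nonlocal_distance(cand.coords) >= CLASH_DISTANCE:
                goal = cand
                break
        else:
            raise GenerationError("could not perturb the chain without clashes")
    return start, goal
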