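"""Biased coarse-grained Monte-Carlo search between two C-alpha endpoint structures.

The search grows a pool of conformations rooted at the start structure.
Each iteration picks a parent from the pool, rotates one pseudo-dihedral
whose value differs from the goal structure (bonds chosen with probability
proportional to that difference), filters the proposal by a C-alpha energy
threshold, and accepts it by a Metropolis-style criterion on the RMSD to
the goal: downhill moves (RMSD_new < RMSD_parent) are always accepted, and
uphill moves with probability exp(-(RMSD_new - RMSD_parent)/(a * RMSD_new))
for a scaling factor ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SearchConverged
from .structures import (
    CalphaStructure,
    apply_dihedral_rotation,
    kabsch_rmsd,
    pseudo_dihedrals,
    write_multimodel_pdb,
)

__all__ = [
    "SearchParams",
    "Trajectory",
    "calpha_energy",
    "select_bond",
    "accept_move",
    "parent_selection",
    "run_search",
]

#: Ideal virtual Calpha-Calpha bond length (Angstrom).
IDEAL_BOND = 3.8
#: Soft-sphere clash distance between residues >= 3 apart in sequence (Angstrom).
CLASH_DISTANCE = 4.0


@dataclass
class SearchParams:
    """Tunable parameters of the conformational search.

    ``max_iterations`` caps the number of proposal attempts (default 60,000,
    the production setting); ``rotation_limit`` bounds each random rotation
    to (-limit, +limit) degrees; ``scaling_factor_a`` softens the uphill
    acceptance penalty; ``energy_threshold`` rejects proposals whose
    C-alpha energy is not strictly below it; ``skip_angle_tolerance`` skips
    bonds whose pseudo-dihedral already matches the goal within that many
    degrees; the search stops early once some pool member is within
    ``goal_rmsd_stop`` Angstrom of the goal.
    """

    max_iterations: int = 60_000
    rotation_limit: float = 5.0
    scaling_factor_a: float = 1.0
    energy_threshold: float = 50.0
    skip_angle_tolerance: float = 1.0
    goal_rmsd_stop: float = 1.5
    seed: int = 0
    parent_policy: Literal["uniform", "goal_biased", "greedy"] = "uniform"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.rotation_limit <= 0:
            raise ParameterError("rotation_limit must be > 0")
        if self.scaling_factor_a <= 0:
            raise ParameterError("scaling_factor_a must be > 0")


@dataclass
class Trajectory:
    """Pool of accepted conformations with parent links, energies and goal RMSDs.

    The pool forms a forest rooted at the start conformation (index 0,
    parent -1).  Coordinates are stored as flat 3N vectors; ``template``
    carries the residue numbering shared by all members.
    """

    template: CalphaStructure
    vectors: list[np.ndarray] = field(default_factory=list)
    parents: list[int] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    rmsd_to_goal: list[float] = field(default_factory=list)
    n_iterations: int = 0
    n_proposals: int = 0

    def __len__(self) -> int:
        return len(self.vectors)

    def append(self, s: CalphaStructure, parent: int, energy: float, rmsd: float) -> int:
        self.vectors.append(s.coords.ravel().copy())
        self.parents.append(parent)
        self.energies.append(energy)
        self.rmsd_to_goal.append(rmsd)
        return len(self.vectors) - 1

    def structure(self, i: int) -> CalphaStructure:
        return self.template.with_coords(
            self.vectors[i].reshape(-1, 3), new_id=f"{self.template.id}|{i}"
        )

    def structures(self) -> list[CalphaStructure]:
        return [self.structure(i) for i in range(len(self))]

    @property
    def best_rmsd(self) -> float:
        return min(self.rmsd_to_goal)

    def as_matrix(self) -> np.ndarray:
        """Pool as an (M, 3N) matrix of conformation vectors."""
        return np.asarray(self.vectors)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": np.arange(len(self)),
                "parent": self.parents,
                "energy": self.energies,
                "rmsd_to_goal": self.rmsd_to_goal,
            }
        )

    def write(self, pdb_path, csv_path=None) -> None:
        write_multimodel_pdb(self.structures(), pdb_path)
        if csv_path is not None:
            self.to_dataframe().to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def calpha_energy(s: CalphaStructure) -> float:
    """Default coarse-grained C-alpha energy (arbitrary units).

    Sum of a harmonic virtual-bond term ``(d - 3.8)^2`` over consecutive
    C-alpha pairs and a soft-sphere repulsion ``(1 - d/4.0)^2 * 10`` for
    residue pairs at least 3 apart in sequence that approach below 4.0 A.
    Rigid-motion invariant by construction (depends on distances only).
    The search accepts any callable with this signature, so other
    coarse-grained potentials can be plugged in.
    """
    c = s.coords
    bond = np.linalg.norm(np.diff(c, axis=0), axis=1)
    e = float(np.sum((bond - IDEAL_BOND) ** 2))
    n = len(c)
    if n >= 4:
        diff = c[:, None, :] - c[None, :, :]
        dist = np.sqrt((diff * diff).sum(-1))
        iu, ju = np.triu_indices(n, k=3)
        d = dist[iu, ju]
        close = d < CLASH_DISTANCE
        if np.any(close):
            e += float(np.sum(10.0 * (1.0 - d[close] / CLASH_DISTANCE) ** 2))
    return e


# ---------------------------------------------------------------------------
# Elementary moves
# ---------------------------------------------------------------------------

def _wrapped_abs_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a - b| on the circle, wrapped to [0, 180] degrees."""
    d = np.abs(a - b) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def select_bond(
    current: CalphaStructure | np.ndarray,
    goal: CalphaStructure | np.ndarray,
    tol: float,
    rng: np.random.Generator,
) -> int:
    """Pick a rotatable virtual bond, biased toward large angular distance from the goal.

    Bond ``i`` is chosen with probability ``|delta_i| / sum_j |delta_j|``
    where ``delta_i`` is the start/goal pseudo-dihedral difference wrapped
    to [0, 180] degrees and the sum runs over bonds with ``|delta| > tol``
    (similar angles are skipped).

    Raises
    ------
    SearchConverged
        If every difference is within ``tol``.
    """
    cur = current if isinstance(current, np.ndarray) else pseudo_dihedrals(current)
    tgt = goal if isinstance(goal, np.ndarray) else pseudo_dihedrals(goal)
    delta = _wrapped_abs_diff(cur, tgt)
    candidates = delta > tol
    if not np.any(candidates):
        raise SearchConverged("all pseudo-dihedrals match the goal within tolerance")
    w = np.where(candidates, delta, 0.0)
    p = w / w.sum()
    return int(rng.choice(len(delta), p=p))


def accept_move(rmsd_new: float, rmsd_parent: float, a: float, r: float) -> bool:
    """Metropolis-style acceptance on RMSD-to-goal.

    Accept iff ``rmsd_new < rmsd_parent`` (downhill) or
    ``ln r < -(rmsd_new - rmsd_parent) / (a * rmsd_new)`` for the uniform
    draw ``r`` in (0, 1).  A proposal that lands exactly on the goal
    (``rmsd_new == 0``) is accepted outright.
    """
    if a <= 0:
        raise ParameterError("scaling factor a must be > 0")
    if rmsd_new < rmsd_parent:
        return True
    if rmsd_new == 0.0:
        return True
    return math.log(r) < -(rmsd_new - rmsd_parent) / (a * rmsd_new)


def parent_selection(
    pool: Trajectory,
    rng: np.random.Generator,
    policy: Literal["uniform", "goal_biased", "greedy"] = "uniform",
) -> int:
    """Choose a parent conformation index from the pool.

    ``uniform``: each member equally likely (default).  ``goal_biased``:
    probability proportional to ``1/(rmsd_to_goal + 0.1)``, favouring pool
    members close to the goal.  ``greedy``: always the member with minimal
    RMSD to the goal.
    """
    m = len(pool)
    if m == 1:
        return 0
    if policy == "uniform":
        return int(rng.integers(m))
    if policy == "greedy":
        return int(np.argmin(pool.rmsd_to_goal))
    if policy == "goal_biased":
        w = 1.0 / (np.asarray(pool.rmsd_to_goal) + 0.1)
        return int(rng.choice(m, p=w / w.sum()))
    raise ParameterError(f"unknown parent policy {policy!r}")


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def run_search(
    start: CalphaStructure,
    goal: CalphaStructure,
    params: SearchParams | None = None,
    energy_fn: Callable[[CalphaStructure], float] = calpha_energy,
) -> Trajectory:
    """Run the biased Monte-Carlo search from ``start`` toward ``goal``.

    Iterates parent selection -> biased bond selection -> random rotation in
    (-rotation_limit, +rotation_limit) degrees -> energy filter -> RMSD
    acceptance, until ``max_iterations`` proposals have been made, some pool
    member reaches ``goal_rmsd_stop``, or no bond differs from the goal by
    more than ``skip_angle_tolerance``.  Fully reproducible under
    ``params.seed``.

    The start conformation is stored unconditionally as the pool root; every
    grown member passed both the energy and the acceptance filters.
    """
    params = params or SearchParams()
    if not np.array_equal(start.residue_ids, goal.residue_ids):
        raise ParameterError("start and goal must share residue topology")
    rng = np.random.default_rng(params.seed)

    traj = Trajectory(template=start.copy())
    start_rmsd = kabsch_rmsd(start, goal)
    traj.append(start, parent=-1, energy=energy_fn(start), rmsd=start_rmsd)
    if start_rmsd <= params.goal_rmsd_stop:
        return traj

    goal_dih = pseudo_dihedrals(goal)
    # cache parent dihedrals alongside the pool to avoid recomputation
    dihedrals: list[np.ndarray] = [pseudo_dihedrals(start)]
    best = start_rmsd

    for it in range(params.max_iterations):
        traj.n_iterations = it + 1
        pi = parent_selection(traj, rng, params.parent_policy)
        parent_dih = dihedrals[pi]
        try:
            bond = select_bond(parent_dih, goal_dih, params.skip_angle_tolerance, rng)
        except SearchConverged:
            break
        delta = rng.uniform(-params.rotation_limit, params.rotation_limit)
        traj.n_proposals += 1
        new = apply_dihedral_rotation(traj.structure(pi), bond, delta)
        energy = energy_fn(new)
        if energy >= params.energy_threshold:
            continue
        rmsd_new = kabsch_rmsd(new, goal)
        r = rng.uniform()
        if r == 0.0:
            continue  # open-interval draw
        if accept_move(rmsd_new, traj.rmsd_to_goal[pi], params.scaling_factor_a, r):
            traj.append(new, parent=pi, energy=energy, rmsd=rmsd_new)
            new_dih = parent_dih.copy()
            new_dih[bond] = _wrap_angle(parent_dih[bond] + delta)
            dihedrals.append(new_dih)
            best = min(best, rmsd_new)
            if best <= params.goal_rmsd_stop:
                break
    return traj


def _wrap_angle(a: float) -> float:
    """Wrap a degree angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def acceptance_rate(traj: Trajectory) -> float:
    """Fraction of energy-passing proposals that entered the pool."""
    if traj.n_proposals == 0:
        return 0.0
    return (len(traj) - 1) / traj.n_proposals
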