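"""C-alpha trace structures: PDB I/O, Kabsch superposition/RMSD, pseudo-dihedral kinematics.

Proteins are represented by their C-alpha atoms only, one coordinate triple
per residue.  Conformational moves are rotations of the pseudo-dihedral
angles defined by four consecutive C-alpha atoms, about the virtual
Calpha(i+1)-Calpha(i+2) bond; virtual bond lengths and bond angles are
therefore preserved exactly by every move.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

from .exceptions import (
    ChainNotFoundError,
    ChainTooShortError,
    EmptyStructureError,
    PairingError,
)

__all__ = [
    "CalphaStructure",
    "ConformationVector",
    "read_calpha_pdb",
    "write_calpha_pdb",
    "write_multimodel_pdb",
    "kabsch_superpose",
    "kabsch_rmsd",
    "pseudo_dihedrals",
    "apply_dihedral_rotation",
]


@dataclass
class CalphaStructure:
    """An ordered C-alpha trace.

    Parameters
    ----------
    id : str
        Free-text label (PDB id, chain, or synthetic tag).
    residue_ids : ndarray of int, shape (N,)
        Strictly increasing residue numbers.
    coords : ndarray of float, shape (N, 3)
        C-alpha coordinates in Angstrom.
    """

    id: str
    residue_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        n = len(self.residue_ids)
        if n != len(self.coords):
            raise ValueError("residue_ids and coords disagree in length")
        if n < 2:
            raise EmptyStructureError(f"structure {self.id!r} has fewer than 2 residues")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        bond = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(bond == 0.0):
            raise ValueError("two consecutive C-alpha atoms coincide")

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def copy(self, new_id: str | None = None) -> "CalphaStructure":
        return CalphaStructure(
            new_id if new_id is not None else self.id,
            self.residue_ids.copy(),
            self.coords.copy(),
        )

    def to_vector(self) -> "ConformationVector":
        return ConformationVector(values=self.coords.ravel().copy(), source=self)

    def with_coords(self, coords: np.ndarray, new_id: str | None = None) -> "CalphaStructure":
        """Same trace topology with replacement coordinates."""
        return CalphaStructure(
            new_id if new_id is not None else self.id,
            self.residue_ids.copy(),
            np.asarray(coords, dtype=float),
        )


@dataclass
class ConformationVector:
    """Flat 3N coordinate vector (x1,y1,z1,x2,...) with a link to its source trace."""

    values: np.ndarray
    source: CalphaStructure | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) % 3 != 0:
            raise ValueError("conformation vector length must be divisible by 3")

    def to_structure(self, template: CalphaStructure | None = None) -> CalphaStructure:
        tpl = template if template is not None else self.source
        if tpl is None:
            raise ValueError("no template structure to rebuild from")
        return tpl.with_coords(self.values.reshape(-1, 3))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _select_calpha(residue):
    """Return the CA atom of a residue, resolving altlocs to highest occupancy."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        atom = max(children, key=lambda a: (a.get_occupancy() or 0.0))
    return atom


def read_calpha_pdb(source, chain: str | None = None, model: int = 0) -> CalphaStructure:
    """Extract the C-alpha trace of one chain from a PDB entry.

    Parameters
    ----------
    source : path, file-like, or PDB text
        A path to a PDB file, an open text handle, or a string containing
        raw PDB records (detected by an embedded newline).
    chain : str, optional
        Chain identifier.  ``None`` selects the first chain that contains at
        least one C-alpha atom.
    model : int
        Model index for multi-model files (default: first model).

    Notes
    -----
    Alternate locations are resolved to the highest-occupancy conformer.
    Residues with insertion codes are unsupported and skipped.  Only
    standard ``ATOM`` records (non-hetero residues) are considered.
    """
    if isinstance(source, str) and "\n" in source:
        handle: object = io.StringIO(source)
        label = "pdb"
    elif hasattr(source, "read"):
        handle = source
        label = getattr(source, "name", "pdb")
    else:
        handle = str(source)
        label = Path(source).stem

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label, handle)
    models = list(structure)
    if not models:
        raise EmptyStructureError("no models in PDB source")
    mdl = models[model]

    chains = list(mdl)
    if chain is not None:
        by_id = {c.id: c for c in chains}
        if chain not in by_id:
            raise ChainNotFoundError(
                f"chain {chain!r} not in entry (available: {sorted(by_id)})"
            )
        candidates = [by_id[chain]]
    else:
        candidates = chains

    for ch in candidates:
        residue_ids = []
        coords = []
        for res in ch:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue
            if icode.strip():
                continue  # insertion codes unsupported
            atom = _select_calpha(res)
            if atom is None:
                continue
            residue_ids.append(resseq)
            coords.append(atom.get_coord())
        if residue_ids:
            order = np.argsort(residue_ids)
            return CalphaStructure(
                id=f"{label}:{ch.id}",
                residue_ids=np.asarray(residue_ids)[order],
                coords=np.asarray(coords, dtype=float)[order],
            )
    raise EmptyStructureError("no C-alpha atoms found in the selected chain(s)")


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  {resname:>3s} {chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C  \n"
)


def _atom_lines(s: CalphaStructure, chain_id: str = "A") -> Iterable[str]:
    for i, (rid, xyz) in enumerate(zip(s.residue_ids, s.coords), start=1):
        yield _ATOM_FMT.format(
            serial=i, resname="ALA", chain=chain_id, resseq=int(rid),
            x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
        )


def write_calpha_pdb(s: CalphaStructure, path, chain_id: str = "A") -> None:
    """Write a C-alpha-only PDB file (ATOM records, residues typed as ALA)."""
    with open(path, "w") as fh:
        fh.writelines(_atom_lines(s, chain_id))
        fh.write("TER\nEND\n")


def write_multimodel_pdb(structures: Sequence[CalphaStructure], path, chain_id: str = "A") -> None:
    """Write a trajectory of C-alpha traces as a multi-model PDB (MODEL/ENDMDL)."""
    with open(path, "w") as fh:
        for m, s in enumerate(structures, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            fh.writelines(_atom_lines(s, chain_id))
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rotation of centered ``P`` onto centered ``Q`` and the resulting RMSD.

    Returns the proper rotation matrix ``R`` minimizing
    ``|| (P - mean(P)) R - (Q - mean(Q)) ||`` and the minimal RMSD.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise PairingError("coordinate sets must have identical shape")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = Pc @ R - Qc
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return R, rmsd


def shared_residue_coords(
    a: CalphaStructure, b: CalphaStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate subsets of ``a`` and ``b`` over their shared residue numbers."""
    common, ia, ib = np.intersect1d(a.residue_ids, b.residue_ids, return_indices=True)
    if len(common) == 0:
        raise PairingError(
            f"structures {a.id!r} and {b.id!r} share no residue numbers"
        )
    return common, a.coords[ia], b.coords[ib]


def kabsch_rmsd(a: CalphaStructure, b: CalphaStructure) -> float:
    """Minimal C-alpha RMSD (Angstrom) over all rigid-body superpositions.

    Structures are paired by intersecting residue numbers; the Kabsch
    algorithm gives the optimal proper rotation after centering both sets.
    Symmetric in its arguments and zero iff the paired traces are congruent.
    """
    _, pa, pb = shared_residue_coords(a, b)
    _, rmsd = kabsch_superpose(pa, pb)
    return rmsd


# ---------------------------------------------------------------------------
# Pseudo-dihedral kinematics
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees) of four points, IUPAC sign, in (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def pseudo_dihedrals(s: CalphaStructure) -> np.ndarray:
    """The N-3 pseudo-dihedral angles of a trace, in degrees, in (-180, 180].

    Angle ``k`` is defined by C-alpha atoms ``k, k+1, k+2, k+3`` and is the
    torsion about the virtual bond ``(k+1)-(k+2)``.
    """
    n = len(s)
    if n < 4:
        raise ChainTooShortError(f"need at least 4 residues, got {n}")
    c = s.coords
    return np.array([_dihedral(c[k], c[k + 1], c[k + 2], c[k + 3]) for k in range(n - 3)])


def apply_dihedral_rotation(
    s: CalphaStructure, bond_index: int, delta: float
) -> CalphaStructure:
    """Rotate the C-terminal side of virtual bond ``bond_index`` by ``delta`` degrees.

    ``bond_index`` uses the same indexing as :func:`pseudo_dihedrals`: bond
    ``k`` is the Calpha(k+1)-Calpha(k+2) axis, and the rotation changes
    pseudo-dihedral ``k`` by ``+delta`` while leaving every other
    pseudo-dihedral, and every inter-atomic distance within each side,
    unchanged.  Atoms with index ``>= k+2`` move; the N-terminal side is
    returned bit-identical.
    """
    n = len(s)
    n_bonds = n - 3
    if not 0 <= bond_index < n_bonds:
        raise IndexError(f"bond_index {bond_index} out of range [0, {n_bonds})")
    coords = s.coords.copy()
    if delta == 0.0:
        return s.with_coords(coords)
    origin = coords[bond_index + 1]
    axis = coords[bond_index + 2] - origin
    axis = axis / np.linalg.norm(axis)
    # IUPAC sign: a positive delta increases the torsion, which corresponds
    # to a negative right-hand rotation of the C-terminal side about the axis
    rot = Rotation.from_rotvec(np.radians(-delta) * axis)
    moving = slice(bond_index + 2, n)
    coords[moving] = rot.apply(coords[moving] - origin) + origin
    return s.with_coords(coords)
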