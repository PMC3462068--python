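"""Rigid-body superposition of matched substructures.

The transform minimizing the RMSD between two corresponded point sets is
computed with the Kabsch algorithm: subtract centroids, build the 3x3
covariance matrix, take its SVD, and correct the determinant sign so the
rotation is proper.  Reflections are refused outright — an improper
overlay would silently invert chirality.

The transform is fit on the common-substructure atoms only but applied to
the *entire* moving molecule, positioning parent B in parent A's frame.
Parent A's frame is the output frame for all merged products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chem_model import Atom, Molecule
from .mcs_search import SubstructureMatch, _pair_distances


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(rotation=Rinv, translation=-Rinv @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(rotation=np.eye(3), translation=np.zeros(3))


def kabsch(coords_ref: np.ndarray, coords_mov: np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rotation + translation taking
    ``coords_mov`` onto ``coords_ref``.

    Rows must correspond (row k of each array is the same mapped atom
    pair) and n must be at least 3.  Collinear point sets trigger a
    warning — the rotation about the line is arbitrary but the returned
    solution is still RMSD-optimal.
    """
    P = np.asarray(coords_mov, dtype=float)
    Q = np.asarray(coords_ref, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 corresponded points are required")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        warnings.warn("collinear point set: rotation about the line is arbitrary")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(rotation=R, translation=t)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def apply_transform(mol: Molecule, t: RigidTransform) -> Molecule:
    """Map every atom position through ``t``; bonds and elements unchanged."""
    new_coords = t.apply(mol.coords)
    atoms = tuple(
        Atom(index=a.index, element=a.element, position=new_coords[a.index],
             source_name=a.source_name)
        for a in mol.atoms
    )
    return replace(
        mol,
        atoms=atoms,
        provenance=mol.provenance + ("rigid transform applied",),
    )


def _mapping_is_verified(
    mol_a: Molecule,
    mol_b: Molecule,
    atoms_a: Sequence[int],
    mapping: Sequence[int],
    tol: float,
) -> bool:
    if len(atoms_a) != len(mapping):
        return False
    for i, j in zip(atoms_a, mapping):
        if mol_a.atoms[i].element != mol_b.atoms[j].element:
            return False
    da = _pair_distances(mol_a.coords, atoms_a)
    db = _pair_distances(mol_b.coords, mapping)
    # small numerical headroom over the match tolerance
    return bool(np.all(np.abs(da - db) <= tol + 1e-9))


def superpose_on_mcs(
    mol_a: Molecule,
    mol_b: Molecule,
    match: SubstructureMatch,
    mapping: Sequence[int],
) -> tuple[Molecule, float]:
    """Superpose parent B onto parent A via one MCS atom assignment.

    The Kabsch fit uses the MCS atoms only (A as reference); the transform
    is then applied to all of ``mol_b``.  Returns the transformed copy of
    B and the achieved RMSD over the MCS atoms.
    """
    mapping = tuple(mapping)
    if not _mapping_is_verified(mol_a, mol_b, match.atoms_a, mapping,
                                match.tolerance):
        raise ValueError(
            "mapping is not a verified assignment for this substructure match"
        )
    ref = mol_a.coords[list(match.atoms_a)]
    mov = mol_b.coords[list(mapping)]
    t = kabsch(ref, mov)
    moved = apply_transform(mol_b, t)
    achieved = rmsd(ref, moved.coords[list(mapping)])
    return moved, achieved
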