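"""Maximum common substructure search on 3D molecular graphs.

The search proceeds in the order a chemist would sketch it:

1.  Enumerate *stretches* — simple paths in each molecule's heavy-atom
    bond graph — and bucket them by their element sequence, ignoring
    geometry.  A shared element sequence is necessary but not sufficient
    for a common substructure; geometry decides later.  The shortest
    stretch considered is three atoms, since single atoms or bonded pairs
    are not distinctive.
2.  Compare geometry with a *distance fingerprint*: the sorted list of all
    pairwise interatomic distances within a stretch.  Two stretches are
    geometrically identical when all fingerprint entries agree within a
    tolerance.  The fingerprint is invariant under rigid motion and atom
    permutation, which makes it a cheap pre-filter; an explicit
    atom-to-atom check (:func:`verify_mappings`) is authoritative.
3.  Work downward from the largest candidate size; the first size at
    which any stretch pair passes both checks defines the MCS.
4.  Enumerate every symmetry-equivalent atom assignment between the two
    matched atom sets (e.g. the two-fold flip of a toluene, the twelve
    dihedral assignments of a bare benzene) by backtracking.

Hydrogens must be stripped before any of this (see
:func:`ligmerge.chem_model.strip_hydrogens`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .chem_model import Molecule
from .errors import NoMCSFoundError

DEFAULT_TOLERANCE = 0.1  # Å, per pairwise distance
MIN_STRETCH = 3


@dataclass(frozen=True)
class AtomPath:
    """A simple path through the bond graph of one parent molecule.

    ``element_key`` is orientation-independent: the lexicographic minimum
    of the forward and reversed element sequences, "-"-joined.
    """

    molecule_id: str
    atom_sequence: tuple[int, ...]
    element_key: str

    def __len__(self) -> int:
        return len(self.atom_sequence)


@dataclass(frozen=True)
class SubstructureMatch:
    """A geometrically verified common substructure.

    ``atoms_a`` and ``atoms_b`` are sorted index tuples of equal length n.
    ``mappings`` holds one or more bijections, each a tuple aligned with
    ``atoms_a`` (``mappings[k][i]`` is the parent-B atom matched to
    ``atoms_a[i]``); multiple entries encode symmetry-equivalent
    assignments.  Every mapping is element-preserving and satisfies
    ``|d_A(i, j) - d_B(m(i), m(j))| <= tolerance`` for all atom pairs.
    """

    atoms_a: tuple[int, ...]
    atoms_b: tuple[int, ...]
    mappings: tuple[tuple[int, ...], ...]
    tolerance: float
    fingerprint: tuple[float, ...]

    @property
    def size(self) -> int:
        return len(self.atoms_a)


def _element_key(elements: Sequence[str]) -> str:
    fwd = "-".join(elements)
    rev = "-".join(reversed(elements))
    return min(fwd, rev)


def enumerate_paths(
    mol: Molecule,
    min_len: int = MIN_STRETCH,
    max_len: int | None = None,
    molecule_id: str | None = None,
) -> list[AtomPath]:
    """All simple paths with ``min_len <= length <= max_len``, each once.

    A path and its reversal are the same path; the orientation whose
    endpoint indices compare lexicographically smaller is kept.  Output is
    sorted, hence deterministic.
    """
    if max_len is None:
        max_len = mol.n_atoms
    if max_len < min_len:
        raise ValueError(f"max_len ({max_len}) < min_len ({min_len})")
    mid = molecule_id if molecule_id is not None else mol.name
    adj = {i: mol.neighbors(i) for i in range(mol.n_atoms)}
    elements = mol.elements
    seen: set[tuple[int, ...]] = set()

    def dfs(path: list[int], visited: set[int]) -> None:
        if len(path) >= min_len:
            tup = tuple(path)
            canon = tup if tup[0] <= tup[-1] else tup[::-1]
            seen.add(canon)
        if len(path) >= max_len:
            return
        for nb in adj[path[-1]]:
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(path, visited)
                path.pop()
                visited.remove(nb)

    for start in range(mol.n_atoms):
        dfs([start], {start})

    return [
        AtomPath(
            molecule_id=mid,
            atom_sequence=seq,
            element_key=_element_key([elements[i] for i in seq]),
        )
        for seq in sorted(seen)
    ]


def group_paths_by_key(paths: Sequence[AtomPath]) -> dict[tuple[int, str], list[AtomPath]]:
    """Bucket paths by (length, element_key), preserving sorted order."""
    out: dict[tuple[int, str], list[AtomPath]] = {}
    for p in paths:
        out.setdefault((len(p), p.element_key), []).append(p)
    return out


def fingerprint(mol: Molecule, atom_set: Sequence[int]) -> np.ndarray:
    """Sorted pairwise distances (Å) among ``atom_set``.

    Invariant under rigid transforms and under atom-order permutation.
    """
    atoms = list(atom_set)
    if len(set(atoms)) != len(atoms):
        raise ValueError("duplicate atom indices in fingerprint request")
    if len(atoms) < 2:
        raise ValueError("fingerprint needs at least two atoms")
    coords = mol.coords[atoms]
    return np.sort(pdist(coords))


def fingerprints_match(fa: np.ndarray, fb: np.ndarray, tol: float) -> bool:
    """True iff equal length and element-wise ``|fa[k] - fb[k]| <= tol``."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape:
        return False
    return bool(np.all(np.abs(fa - fb) <= tol))


def _pair_distances(coords: np.ndarray, seq: Sequence[int]) -> np.ndarray:
    pts = coords[list(seq)]
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def verify_mappings(
    mol_a: Molecule,
    path_a: AtomPath,
    mol_b: Molecule,
    path_b: AtomPath,
    tol: float,
) -> list[tuple[int, ...]]:
    """Atom-to-atom bijections between two stretches that survive the
    unsorted distance check.

    The sorted fingerprint discards atom correspondence, so an explicit
    mapping is required before superposition.  The forward alignment
    (position i to position i) is tested whenever the element sequences
    agree; the reversed alignment is tested whenever the element sequence
    equals its reverse.  A mapping is returned iff it is
    element-preserving and every corresponding (unsorted) pairwise
    distance agrees within ``tol``.  Returned mappings are tuples aligned
    with ``path_a.atom_sequence``.
    """
    seq_a = path_a.atom_sequence
    seq_b = path_b.atom_sequence
    if len(seq_a) != len(seq_b):
        raise ValueError("path length mismatch")
    ea = [mol_a.atoms[i].element for i in seq_a]
    eb = [mol_b.atoms[i].element for i in seq_b]

    candidates: list[tuple[int, ...]] = []
    if ea == eb:
        candidates.append(tuple(seq_b))
    if ea == eb[::-1]:
        rev = tuple(reversed(seq_b))
        if rev not in candidates:
            candidates.append(rev)

    da = _pair_distances(mol_a.coords, seq_a)
    cb = mol_b.coords
    out = []
    for cand in candidates:
        db = _pair_distances(cb, cand)
        if np.all(np.abs(da - db) <= tol):
            out.append(cand)
    return out


def _canonical_match_entry(
    seq_a: Sequence[int], mapped_b: Sequence[int]
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Re-express a path-aligned mapping against sorted atoms_a."""
    atoms_a = tuple(sorted(seq_a))
    lookup = dict(zip(seq_a, mapped_b))
    return atoms_a, tuple(lookup[i] for i in atoms_a)


def find_mcs_candidates(
    mol_a: Molecule,
    mol_b: Molecule,
    min_size: int = MIN_STRETCH,
    tol: float = DEFAULT_TOLERANCE,
    max_size: int | None = None,
) -> list[SubstructureMatch]:
    """All size-maximal common substructures, largest-first search.

    Candidate sizes run from ``min(n_A, n_B)`` down to ``min_size``; for
    each element key present in both parents at the current size, all
    stretch pairs are compared — sorted fingerprints as a pre-filter,
    :func:`verify_mappings` as the authority.  The first size at which any
    pair passes defines the MCS; all passing pairs at that size are
    collected, deduplicated by atom-set pair, each carrying every verified
    mapping.  Processing order is lexicographic, so the result is
    deterministic.
    """
    if min_size < MIN_STRETCH:
        raise ValueError(f"min_size must be >= {MIN_STRETCH}")
    cap = min(mol_a.n_atoms, mol_b.n_atoms)
    if max_size is not None:
        cap = min(cap, max_size)
    if cap < min_size:
        raise NoMCSFoundError(
            f"no common substructure possible: fewer than {min_size} atoms"
        )

    groups_a = group_paths_by_key(enumerate_paths(mol_a, min_size, cap, "A"))
    groups_b = group_paths_by_key(enumerate_paths(mol_b, min_size, cap, "B"))

    fp_cache_a: dict[frozenset, np.ndarray] = {}
    fp_cache_b: dict[frozenset, np.ndarray] = {}

    def fp(mol: Molecule, seq: tuple[int, ...], cache: dict) -> np.ndarray:
        key = frozenset(seq)
        if key not in cache:
            cache[key] = fingerprint(mol, sorted(key))
        return cache[key]

    for size in range(cap, min_size - 1, -1):
        keys = sorted(
            k[1] for k in groups_a if k[0] == size and k in groups_b
        )
        found: dict[tuple, set[tuple[int, ...]]] = {}
        for key in keys:
            for pa in groups_a[(size, key)]:
                fa = fp(mol_a, pa.atom_sequence, fp_cache_a)
                for pb in groups_b[(size, key)]:
                    fb = fp(mol_b, pb.atom_sequence, fp_cache_b)
                    if not fingerprints_match(fa, fb, tol):
                        continue
                    for mapped in verify_mappings(mol_a, pa, mol_b, pb, tol):
                        atoms_a, mapping = _canonical_match_entry(
                            pa.atom_sequence, mapped
                        )
                        setkey = (atoms_a, tuple(sorted(mapping)))
                        found.setdefault(setkey, set()).add(mapping)
        if found:
            matches = []
            for (atoms_a, atoms_b), mappings in sorted(found.items()):
                matches.append(
                    SubstructureMatch(
                        atoms_a=atoms_a,
                        atoms_b=atoms_b,
                        mappings=tuple(sorted(mappings)),
                        tolerance=tol,
                        fingerprint=tuple(
                            fp(mol_a, atoms_a, fp_cache_a).tolist()
                        ),
                    )
                )
            return matches
    raise NoMCSFoundError(
        f"no common substructure of at least {min_size} atoms within "
        f"tolerance {tol} Å"
    )


def find_mcs(
    mol_a: Molecule,
    mol_b: Molecule,
    min_size: int = MIN_STRETCH,
    tol: float = DEFAULT_TOLERANCE,
    max_size: int | None = None,
) -> SubstructureMatch:
    """The first (lexicographically smallest) size-maximal match.

    See :func:`find_mcs_candidates` for the full tie set.
    """
    return find_mcs_candidates(mol_a, mol_b, min_size, tol, max_size)[0]


def enumerate_symmetry_mappings(
    match: SubstructureMatch,
    mol_a: Molecule,
    mol_b: Molecule,
    tol: float | None = None,
) -> list[tuple[int, ...]]:
    """Every element-preserving, distance-preserving bijection
    ``atoms_a -> atoms_b`` found by backtracking.

    For a toluene-shaped MCS at ideal geometry there are exactly two
    (identity-like and the ring flip about the methyl-phenyl axis); for a
    bare n-cycle of identical elements there are 2n.  The result is a
    superset of ``match.mappings``, deduplicated, in deterministic
    (sorted) order.
    """
    if tol is None:
        tol = match.tolerance
    A = list(match.atoms_a)
    B = list(match.atoms_b)
    n = len(A)
    ca, cb = mol_a.coords, mol_b.coords
    da = _pair_distances(ca, A)
    db = _pair_distances(cb, B)
    ea = [mol_a.atoms[i].element for i in A]
    eb = [mol_b.atoms[i].element for i in B]

    results: set[tuple[int, ...]] = set(match.mappings)
    assigned: list[int] = []  # positions into B

    def backtrack(k: int) -> None:
        if k == n:
            results.add(tuple(B[j] for j in assigned))
            return
        for j in range(n):
            if j in assigned or eb[j] != ea[k]:
                continue
            if all(abs(da[k, i] - db[j, assigned[i]]) <= tol for i in range(k)):
                assigned.append(j)
                backtrack(k + 1)
                assigned.pop()

    backtrack(0)
    return sorted(results)
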