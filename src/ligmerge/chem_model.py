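"""Heavy-atom molecular data model and PDB I/O.

A :class:`Molecule` is a lightweight immutable container holding element
labels, Cartesian coordinates in Å, and an undirected bond graph.  Bond
*orders* are deliberately not modelled: PDB files carry no order
information and no downstream step of the merge pipeline needs it; merged
products are heavy-atom skeletons intended for downstream protonation.

PDB v3.3 fixed-column ATOM/HETATM/CONECT/END records are the only
supported interchange format.  Connectivity may come from CONECT records,
from distance-based perception against a covalent-radius table
(:func:`perceive_bonds`), or from the union of both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, EmptyModelError, PDBFormatError

#: Single-bond covalent radii in Å (Cordero et al., Dalton Trans., 2008).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "HE": 0.28,
    "LI": 1.28, "BE": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NE": 0.58,
    "NA": 1.66, "MG": 1.41, "AL": 1.21, "SI": 1.11, "P": 1.07, "S": 1.05,
    "CL": 1.02, "AR": 1.06,
    "K": 2.03, "CA": 1.76, "FE": 1.32, "ZN": 1.22, "AS": 1.19, "SE": 1.20,
    "BR": 1.20, "I": 1.39,
}

#: Default extra distance beyond the sum of covalent radii below which a
#: heavy-atom pair is considered bonded.
DEFAULT_BOND_SLACK = 0.45

_HYDROGEN = {"H", "D"}
# Two-letter symbols that commonly appear in small-molecule PDB atom names.
_TWO_LETTER = {s for s in COVALENT_RADII if len(s) == 2}


def canonical_element(symbol: str) -> str:
    """Uppercase, whitespace-stripped element symbol (``"Cl"`` -> ``"CL"``)."""
    return symbol.strip().upper()


def covalent_radius(element: str) -> float:
    el = canonical_element(element)
    try:
        return COVALENT_RADII[el]
    except KeyError:
        raise ConfigurationError(
            f"element {el!r} has no entry in the covalent-radius table"
        ) from None


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom.

    ``index`` is the 0-based position of the atom inside its molecule and
    is stable for the lifetime of that molecule; ``source_name`` keeps the
    original PDB atom-name string for provenance only.
    """

    index: int
    element: str
    position: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        el = canonical_element(self.element)
        if el not in COVALENT_RADII:
            raise ConfigurationError(
                f"element {el!r} has no entry in the covalent-radius table"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        object.__setattr__(self, "element", el)
        object.__setattr__(self, "position", pos)


def _normalize_bonds(bonds: Iterable[tuple[int, int]], n_atoms: int) -> frozenset:
    out = set()
    for a, b in bonds:
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-bond on atom {a}")
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise ValueError(f"bond ({a},{b}) references a missing atom")
        out.add((min(a, b), max(a, b)))
    return frozenset(out)


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of atoms plus an undirected bond set.

    Bonds are stored as sorted index pairs, so ``(a, b)`` and ``(b, a)``
    are the same bond and duplicates collapse.
    """

    name: str
    atoms: tuple[Atom, ...]
    bonds: frozenset = frozenset()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        for i, a in enumerate(atoms):
            if a.index != i:
                raise ValueError(
                    f"atom at position {i} carries index {a.index}; indices "
                    "must be consecutive from 0"
                )
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "bonds", _normalize_bonds(self.bonds, len(atoms)))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in Å (a fresh copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.atoms[i].position - self.atoms[j].position))

    def distance_matrix(self) -> np.ndarray:
        if self.n_atoms < 2:
            return np.zeros((self.n_atoms, self.n_atoms))
        return squareform(pdist(self.coords))

    def with_provenance(self, note: str) -> "Molecule":
        return replace(self, provenance=self.provenance + (note,))

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph()) if self.n_atoms else False


def molecule_from_arrays(
    name: str,
    elements: Sequence[str],
    coords: np.ndarray,
    bonds: Iterable[tuple[int, int]] = (),
    provenance: Sequence[str] = (),
) -> Molecule:
    """Convenience constructor from parallel element/coordinate arrays."""
    coords = np.asarray(coords, dtype=float)
    atoms = tuple(
        Atom(index=i, element=el, position=coords[i])
        for i, el in enumerate(elements)
    )
    return Molecule(name=name, atoms=atoms, bonds=frozenset(_normalize_bonds(bonds, len(atoms))),
                    provenance=tuple(provenance))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom-name field (columns 13-16)."""
    alpha = "".join(c for c in name.strip() if c.isalpha())
    if not alpha:
        raise PDBFormatError(f"cannot infer element from atom name {name!r}")
    two = alpha[:2].upper()
    if two in _TWO_LETTER:
        return two
    return alpha[0].upper()


def read_pdb(path: str | Path) -> Molecule:
    """Read a small-molecule model from a PDB file.

    One :class:`Atom` is created per ATOM/HETATM record; coordinates are
    taken from the fixed columns 31-54, the element from columns 77-78 when
    present and otherwise inferred from the atom-name field.  CONECT
    records, if any, populate the bond set (deduplicated, symmetric).  Only
    the first MODEL of a multi-model file is read; alternate-location
    indicators other than blank or 'A' are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    conect_pairs: set[tuple[int, int]] = set()
    models_seen = 0
    reading_atoms = True

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "MODEL":
                models_seen += 1
                if models_seen > 1:
                    warnings.warn(
                        f"{path.name}: multiple MODELs; only the first is read"
                    )
                    reading_atoms = False
            elif rec == "ENDMDL":
                reading_atoms = False
            elif rec in ("ATOM", "HETATM") and reading_atoms:
                altloc = raw[16:17]
                if altloc not in (" ", "", "A"):
                    continue
                try:
                    serial = int(raw[6:11])
                except ValueError:
                    serial = len(atoms) + 1
                try:
                    x = float(raw[30:38])
                    y = float(raw[38:46])
                    z = float(raw[46:54])
                except (ValueError, IndexError):
                    raise PDBFormatError(
                        f"{path.name}, line {lineno}: unparseable coordinates: "
                        f"{raw.rstrip()!r}"
                    ) from None
                name = raw[12:16]
                element = raw[76:78].strip() if len(raw) >= 77 else ""
                if not element:
                    element = _element_from_name(name)
                atoms.append(
                    Atom(
                        index=len(atoms),
                        element=element,
                        position=np.array([x, y, z]),
                        source_name=name.strip(),
                    )
                )
                serial_to_index[serial] = atoms[-1].index
            elif rec == "CONECT":
                fields = raw.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError:
                    raise PDBFormatError(
                        f"{path.name}, line {lineno}: bad CONECT record: "
                        f"{raw.rstrip()!r}"
                    ) from None
                if len(serials) >= 2:
                    base = serials[0]
                    for other in serials[1:]:
                        conect_pairs.add((min(base, other), max(base, other)))

    if not atoms:
        raise EmptyModelError(f"{path.name}: empty model (no ATOM/HETATM records)")

    bonds = set()
    for sa, sb in conect_pairs:
        if sa in serial_to_index and sb in serial_to_index:
            ia, ib = serial_to_index[sa], serial_to_index[sb]
            if ia != ib:
                bonds.add((min(ia, ib), max(ia, ib)))

    return Molecule(
        name=path.stem,
        atoms=tuple(atoms),
        bonds=frozenset(bonds),
        provenance=(f"read from {path.name}",),
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(mol: Molecule, path: str | Path) -> None:
    """Write ``mol`` as HETATM records plus CONECT connectivity and END.

    Coordinates are emitted in %8.3f fields, the element right-justified in
    columns 77-78.  Reading the file back reproduces elements, bonds, and
    coordinates to 0.001 Å.
    """
    if mol.n_atoms == 0:
        raise EmptyModelError("refusing to write a molecule with no atoms")
    path = Path(path)
    counts: dict[str, int] = {}
    lines = []
    for atom in mol.atoms:
        counts[atom.element] = counts.get(atom.element, 0) + 1
        name = f"{atom.element}{counts[atom.element]}"[:4]
        field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = atom.position
        lines.append(
            f"HETATM{atom.index + 1:>5d} {field:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}"
        )
    neighbor_map: dict[int, list[int]] = {}
    for a, b in sorted(mol.bonds):
        neighbor_map.setdefault(a, []).append(b)
        neighbor_map.setdefault(b, []).append(a)
    for i in sorted(neighbor_map):
        partners = "".join(f"{j + 1:>5d}" for j in sorted(neighbor_map[i]))
        lines.append(f"CONECT{i + 1:>5d}{partners}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Structure manipulation
# ---------------------------------------------------------------------------

def perceive_bonds(mol: Molecule, slack: float = DEFAULT_BOND_SLACK) -> Molecule:
    """Add distance-based bonds: pair (i, j) is bonded iff
    ``d(i, j) <= r_cov(i) + r_cov(j) + slack``.

    Pre-existing bonds (e.g. from CONECT records) are kept — the result is
    the union.  The perception is deterministic, symmetric, and invariant
    under rigid transforms of the coordinates.
    """
    if mol.n_atoms == 0:
        raise EmptyModelError("cannot perceive bonds on an empty molecule")
    if slack < 0:
        raise ValueError("slack must be >= 0")
    radii = np.array([covalent_radius(el) for el in mol.elements])
    bonds = set(mol.bonds)
    if mol.n_atoms >= 2:
        dm = mol.distance_matrix()
        cutoff = radii[:, None] + radii[None, :] + slack
        ii, jj = np.nonzero(np.triu(dm <= cutoff, k=1))
        bonds.update(zip(ii.tolist(), jj.tolist()))
    return replace(
        mol,
        bonds=frozenset(bonds),
        provenance=mol.provenance + (f"perceive_bonds(slack={slack})",),
    )


def strip_hydrogens(mol: Molecule) -> Molecule:
    """Remove all H/D atoms and their incident bonds, reindexing the rest.

    Idempotent.  Raises :class:`EmptyModelError` if nothing but hydrogen
    remains.
    """
    keep = [a.index for a in mol.atoms if a.element not in _HYDROGEN]
    if not keep:
        raise EmptyModelError(f"{mol.name}: only hydrogen atoms present")
    if len(keep) == mol.n_atoms:
        return mol
    return submolecule(mol, keep, note="strip_hydrogens")


def submolecule(mol: Molecule, indices: Sequence[int], name: str | None = None,
                note: str = "submolecule") -> Molecule:
    """Induced submolecule over ``indices``, atoms reindexed consecutively.

    The old-to-new index mapping is recorded in the provenance.
    """
    indices = list(indices)
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate atom indices")
    old_to_new = {old: new for new, old in enumerate(indices)}
    atoms = tuple(
        Atom(
            index=new,
            element=mol.atoms[old].element,
            position=mol.atoms[old].position,
            source_name=mol.atoms[old].source_name,
        )
        for old, new in ((old, old_to_new[old]) for old in indices)
    )
    bonds = frozenset(
        (min(old_to_new[a], old_to_new[b]), max(old_to_new[a], old_to_new[b]))
        for a, b in mol.bonds
        if a in old_to_new and b in old_to_new
    )
    return Molecule(
        name=name if name is not None else mol.name,
        atoms=atoms,
        bonds=bonds,
        provenance=mol.provenance + (f"{note}: kept {indices}",),
    )


def largest_component(mol: Molecule) -> Molecule:
    """Return the largest connected component of the bond graph.

    Warns when the input is disconnected; the common-substructure search
    is undefined across disconnected pieces, so downstream stages operate
    on the dominant one.  Ties break toward the component containing the
    lowest atom index.
    """
    comps = sorted(
        nx.connected_components(mol.graph()),
        key=lambda c: (-len(c), min(c)),
    )
    if len(comps) <= 1:
        return mol
    warnings.warn(
        f"{mol.name}: bond graph has {len(comps)} components; "
        "keeping the largest"
    )
    return submolecule(mol, sorted(comps[0]), note="largest_component")
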