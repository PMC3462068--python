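"""Synthetic test molecules with analytically known merge structure.

Real co-crystallized ligand pairs have no closed-form ground truth, so
this module builds toy molecules — a shared scaffold at ideal geometry
plus per-parent substituents — for which the maximum common substructure
size, the symmetry-assignment count, the handle count, and the
substituent-plan count are all computable combinatorially from the
specification, without running the pipeline.

Scaffolds are regular polygons (rings), evenly spaced chains, or a ring
with an exocyclic methyl carbon ("ring_plus_methyl", the toluene shape).
Substituents point radially outward from the ring centroid, or sideways
from a chain, which keeps inter-substituent distances analytic for clash
tests.  Coordinate jitter, when requested, is seeded and is applied to
the scaffold once *before* decoration, so the shared substructure stays
exactly common between the two parents.

Two validity rules keep the combinatorial ground truth exact:

* within one parent, at most one payload per scaffold position (a bridge
  occupies both of its positions);
* payload elements must be disjoint from the scaffold elements and
  between the two parents, so the common substructure cannot silently
  extend into a substituent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_model import Molecule, molecule_from_arrays

DEFAULT_BOND = 1.5  # Å, generic single-bond length used throughout

_PAYLOAD_SIZES = {"atom": 1, "chain2": 2, "branch3": 3, "bridge": 1}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometry recipe for the shared core.

    ``size`` counts the base scaffold atoms (ring atoms or chain atoms);
    ``ring_plus_methyl`` appends one exocyclic carbon at position 0, so
    its total atom count is ``size + 1``.  ``elements`` must have length
    ``size``.
    """

    kind: str  # linear_chain | ring | ring_plus_methyl
    size: int
    elements: tuple[str, ...]
    bond_length: float = DEFAULT_BOND
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_chain", "ring", "ring_plus_methyl"):
            raise ValueError(f"unknown scaffold kind {self.kind!r}")
        if self.size < 3:
            raise ValueError("scaffold size must be >= 3")
        if len(self.elements) != self.size:
            raise ValueError("elements must match scaffold size")
        object.__setattr__(self, "elements",
                           tuple(e.upper() for e in self.elements))

    @property
    def n_atoms(self) -> int:
        return self.size + (1 if self.kind == "ring_plus_methyl" else 0)


@dataclass(frozen=True)
class SubstituentSpec:
    """One substituent payload on a scaffold position.

    Kinds: ``atom`` (one atom), ``chain2`` (two-atom chain, optionally
    tilted in-plane by ``tilt_deg`` toward increasing ring angle —
    useful for constructing deliberate steric clashes), ``branch3``
    (one atom carrying two branch atoms out of plane), and ``bridge``
    (a single atom bonded to *two* distinct scaffold positions: a
    multiple-handle fragment).
    """

    handle_position: int
    kind: str
    elements: tuple[str, ...]
    second_position: int | None = None
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _PAYLOAD_SIZES:
            raise ValueError(f"unknown payload kind {self.kind!r}")
        if len(self.elements) != _PAYLOAD_SIZES[self.kind]:
            raise ValueError(
                f"{self.kind} payload needs {_PAYLOAD_SIZES[self.kind]} "
                f"element(s), got {len(self.elements)}"
            )
        if self.kind == "bridge":
            if self.second_position is None:
                raise ValueError("bridge payload must name a second position")
            if self.second_position == self.handle_position:
                raise ValueError("bridge positions must be distinct")
        object.__setattr__(self, "elements",
                           tuple(e.upper() for e in self.elements))

    @property
    def positions(self) -> tuple[int, ...]:
        if self.kind == "bridge":
            return tuple(sorted((self.handle_position, self.second_position)))
        return (self.handle_position,)


# ---------------------------------------------------------------------------
# Scaffold geometry
# ---------------------------------------------------------------------------

def _scaffold_geometry(spec: ScaffoldSpec, rng: np.random.Generator):
    """Elements, jittered coordinates, bonds, and the ring-atom count."""
    L = spec.bond_length
    n = spec.size
    elements = list(spec.elements)
    if spec.kind == "linear_chain":
        coords = np.array([[i * L, 0.0, 0.0] for i in range(n)])
        bonds = [(i, i + 1) for i in range(n - 1)]
    else:
        R = L / (2.0 * math.sin(math.pi / n))
        coords = np.array(
            [
                [R * math.cos(2 * math.pi * k / n),
                 R * math.sin(2 * math.pi * k / n), 0.0]
                for k in range(n)
            ]
        )
        bonds = [(i, (i + 1) % n) for i in range(n)]
        if spec.kind == "ring_plus_methyl":
            elements.append("C")
            direction = coords[0] / np.linalg.norm(coords[0])
            coords = np.vstack([coords, coords[0] + L * direction])
            bonds.append((0, n))
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    return elements, coords, bonds


def _outward_direction(spec: ScaffoldSpec, coords: np.ndarray, pos: int) -> np.ndarray:
    """Unit vector along which a payload leaves the scaffold at ``pos``."""
    if spec.kind == "linear_chain":
        if pos == 0:
            d = coords[0] - coords[1]
        elif pos == spec.size - 1:
            d = coords[pos] - coords[pos - 1]
        else:
            d = np.array([0.0, 1.0, 0.0])
    else:
        centroid = coords[: spec.size].mean(axis=0)
        d = coords[pos] - centroid
    return d / np.linalg.norm(d)


def _tangential_direction(spec: ScaffoldSpec, coords: np.ndarray, pos: int,
                          outward: np.ndarray) -> np.ndarray:
    """In-plane unit vector perpendicular to ``outward`` (counterclockwise
    for rings), used to tilt chain2 payloads."""
    z = np.array([0.0, 0.0, 1.0])
    t = np.cross(z, outward)
    norm = np.linalg.norm(t)
    if norm < 1e-12:  # outward along z: fall back to x
        t = np.array([1.0, 0.0, 0.0])
        norm = 1.0
    return t / norm


def _decorate(
    spec: ScaffoldSpec,
    elements: list[str],
    coords_list: list[np.ndarray],
    bonds: list[tuple[int, int]],
    sub: SubstituentSpec,
) -> None:
    """Append payload atoms and bonds for one substituent, in place."""
    L = spec.bond_length
    scaffold_coords = np.vstack(coords_list[: spec.n_atoms])
    pos = sub.handle_position
    u = _outward_direction(spec, scaffold_coords, pos)
    base = scaffold_coords[pos]

    def add(element: str, position: np.ndarray) -> int:
        elements.append(element)
        coords_list.append(np.asarray(position, dtype=float))
        return len(elements) - 1

    if sub.kind == "atom":
        i = add(sub.elements[0], base + L * u)
        bonds.append((pos, i))
    elif sub.kind == "chain2":
        t = _tangential_direction(spec, scaffold_coords, pos, u)
        tau = math.radians(sub.tilt_deg)
        i1 = add(sub.elements[0], base + L * u)
        d2 = math.cos(tau) * u + math.sin(tau) * t
        i2 = add(sub.elements[1], coords_list[i1] + L * d2)
        bonds.extend([(pos, i1), (i1, i2)])
    elif sub.kind == "branch3":
        z = np.array([0.0, 0.0, 1.0])
        i1 = add(sub.elements[0], base + L * u)
        stem = np.asarray(coords_list[i1])
        i2 = add(sub.elements[1], stem + L * (0.5 * u + (math.sqrt(3) / 2) * z))
        i3 = add(sub.elements[2], stem + L * (0.5 * u - (math.sqrt(3) / 2) * z))
        bonds.extend([(pos, i1), (i1, i2), (i1, i3)])
    elif sub.kind == "bridge":
        if spec.kind == "linear_chain":
            raise ValueError("bridge payloads require a ring scaffold")
        q = sub.second_position
        cp, cq = scaffold_coords[pos], scaffold_coords[q]
        d = float(np.linalg.norm(cp - cq))
        if d >= 2 * L:
            raise ValueError(
                f"bridge positions {pos},{q} are {d:.2f} Å apart; cannot "
                f"reach both with {L} Å bonds"
            )
        mid = 0.5 * (cp + cq)
        centroid = scaffold_coords[: spec.size].mean(axis=0)
        out = mid - centroid
        out = out / np.linalg.norm(out)
        height = math.sqrt(L * L - (d / 2.0) ** 2)
        i = add(sub.elements[0], mid + height * out)
        bonds.extend([(pos, i), (q, i)])


# ---------------------------------------------------------------------------
# Combinatorial ground truth
# ---------------------------------------------------------------------------

def scaffold_symmetry_count(spec: ScaffoldSpec) -> int:
    """Number of element- and distance-preserving self-assignments of the
    (noise-free) scaffold point set.

    Chains: 2 when the element sequence is palindromic, else 1.  Rings:
    the dihedral necklace automorphisms (2n for n identical elements).
    ring_plus_methyl: the exocyclic carbon pins position 0, leaving the
    identity plus, when the element sequence allows, the reflection
    through the methyl axis.
    """
    e = list(spec.elements)
    n = spec.size
    if spec.kind == "linear_chain":
        return 2 if e == e[::-1] else 1
    count = 0
    rotations = range(n) if spec.kind == "ring" else (0,)
    for k in rotations:
        if all(e[(i + k) % n] == e[i] for i in range(n)):
            count += 1
    reflections = range(n) if spec.kind == "ring" else (0,)
    for m in reflections:
        if all(e[(m - i) % n] == e[i] for i in range(n)):
            count += 1
    return count


def _expected_plan_count(
    subs_a: Sequence[SubstituentSpec], subs_b: Sequence[SubstituentSpec]
) -> tuple[int, int]:
    """(handle count, consistent plan count) from the specs alone."""
    handles = sorted(
        {p for s in (*subs_a, *subs_b) for p in s.positions}
    )
    bridges = [
        (parent, frozenset(s.positions))
        for parent, subs in (("A", subs_a), ("B", subs_b))
        for s in subs
        if s.kind == "bridge"
    ]
    count = 0
    for combo in itertools.product("AB", repeat=len(handles)):
        choice = dict(zip(handles, combo))
        ok = True
        for parent, positions in bridges:
            picks = {choice[p] for p in positions}
            if parent in picks and picks != {parent}:
                ok = False
                break
        if ok:
            count += 1
    return len(handles), count


def _validate_subs(spec: ScaffoldSpec,
                   subs_a: Sequence[SubstituentSpec],
                   subs_b: Sequence[SubstituentSpec]) -> None:
    scaffold_elements = set(spec.elements) | (
        {"C"} if spec.kind == "ring_plus_methyl" else set()
    )
    payload_elements = {"A": set(), "B": set()}
    for parent, subs in (("A", subs_a), ("B", subs_b)):
        occupied: set[int] = set()
        for s in subs:
            for p in s.positions:
                if not (0 <= p < spec.size):
                    raise ValueError(f"payload position {p} outside scaffold")
                if spec.kind == "ring_plus_methyl" and p == 0:
                    raise ValueError(
                        "position 0 carries the scaffold methyl; payloads "
                        "must use other positions"
                    )
                if p in occupied:
                    raise ValueError(
                        f"parent {parent}: two payloads on position {p}"
                    )
                occupied.add(p)
            payload_elements[parent].update(s.elements)
    overlap = (payload_elements["A"] | payload_elements["B"]) & scaffold_elements
    if overlap:
        raise ValueError(
            f"payload elements {sorted(overlap)} also occur in the scaffold; "
            "the expected MCS size would no longer be exact"
        )
    shared = payload_elements["A"] & payload_elements["B"]
    if shared:
        raise ValueError(
            f"payload elements {sorted(shared)} occur in both parents; "
            "the expected MCS size would no longer be exact"
        )


# ---------------------------------------------------------------------------
# Public builders
# ---------------------------------------------------------------------------

def build_molecule(
    spec: ScaffoldSpec,
    subs: Sequence[SubstituentSpec],
    name: str,
    rng: np.random.Generator | None = None,
) -> Molecule:
    """One decorated parent.  ``rng`` drives scaffold jitter only."""
    if rng is None:
        rng = np.random.default_rng(0)
    elements, coords, bonds = _scaffold_geometry(spec, rng)
    coords_list = [coords[i] for i in range(len(elements))]
    for sub in sorted(subs, key=lambda s: s.positions):
        _decorate(spec, elements, coords_list, bonds, sub)
    return molecule_from_arrays(
        name, elements, np.vstack(coords_list), bonds,
        provenance=(f"synthetic fixture: {spec.kind}({spec.size})",),
    )


def build_pair(
    scaffold: ScaffoldSpec,
    subs_a: Sequence[SubstituentSpec],
    subs_b: Sequence[SubstituentSpec],
    seed: int = 0,
    names: tuple[str, str] = ("parentA", "parentB"),
) -> tuple[Molecule, Molecule, dict]:
    """Two parents sharing an identical scaffold, plus ground truth.

    Returns ``(mol_a, mol_b, expected)`` where ``expected`` holds
    ``mcs_size``, ``symmetry_count``, ``handle_count`` and ``plan_count``
    — all derived combinatorially, never by running the pipeline.
    ``symmetry_count`` describes the noise-free scaffold; with
    ``noise_sigma > 0`` only the identity assignment is guaranteed to
    survive, so tests under jitter should rely on ``mcs_size`` alone.
    """
    _validate_subs(scaffold, subs_a, subs_b)
    rng = np.random.default_rng(seed)
    elements, coords, bonds = _scaffold_geometry(scaffold, rng)

    mols = []
    for name, subs in zip(names, (subs_a, subs_b)):
        el = list(elements)
        cl = [coords[i].copy() for i in range(len(elements))]
        bl = list(bonds)
        for sub in sorted(subs, key=lambda s: s.positions):
            _decorate(scaffold, el, cl, bl, sub)
        mols.append(
            molecule_from_arrays(
                name, el, np.vstack(cl), bl,
                provenance=(f"synthetic fixture: {scaffold.kind}"
                            f"({scaffold.size}), seed={seed}",),
            )
        )

    handle_count, plan_count = _expected_plan_count(subs_a, subs_b)
    expected = {
        "mcs_size": scaffold.n_atoms,
        "symmetry_count": scaffold_symmetry_count(scaffold),
        "handle_count": handle_count,
        "plan_count": plan_count,
    }
    return mols[0], mols[1], expected


_RANDOM_SCAFFOLD_ELEMENTS = ("C", "N", "O")
_RANDOM_PAYLOAD_POOL = ("F", "CL", "BR", "I", "P", "S", "B", "SI")


def random_pair(seed: int) -> tuple[Molecule, Molecule, dict]:
    """A randomized fixture pair (<= 14 heavy atoms per parent).

    Scaffold kind, size, elements, payload positions and payload kinds
    are all drawn from the seed; payload elements are drawn without
    replacement across both parents so the MCS is exactly the scaffold.
    """
    rng = np.random.default_rng(seed)
    kind = ("linear_chain", "ring", "ring_plus_methyl")[int(rng.integers(3))]
    size = int(rng.integers(4, 7 if kind == "ring_plus_methyl" else 8))
    elements = tuple(
        _RANDOM_SCAFFOLD_ELEMENTS[int(rng.integers(3))] for _ in range(size)
    )
    scaffold = ScaffoldSpec(kind=kind, size=size, elements=elements)

    pool = list(_RANDOM_PAYLOAD_POOL)
    rng.shuffle(pool)
    pool_iter = iter(pool)

    def draw_subs() -> list[SubstituentSpec]:
        n_subs = int(rng.integers(1, 3))
        lo = 1 if kind == "ring_plus_methyl" else 0
        available = list(range(lo, size))
        subs = []
        for _ in range(n_subs):
            if not available:
                break
            pos = available.pop(int(rng.integers(len(available))))
            if kind == "linear_chain":
                # keep neighbouring mid-chain payloads apart
                available = [p for p in available if abs(p - pos) >= 2]
            payload_kind = ("atom", "chain2")[int(rng.integers(2))]
            n_el = _PAYLOAD_SIZES[payload_kind]
            subs.append(
                SubstituentSpec(
                    handle_position=pos,
                    kind=payload_kind,
                    elements=tuple(next(pool_iter) for _ in range(n_el)),
                )
            )
        return subs

    subs_a = draw_subs()
    subs_b = draw_subs()
    return build_pair(scaffold, subs_a, subs_b, seed=seed)
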