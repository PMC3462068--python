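"""Substituent extraction and combinatorial fragment merging.

Once the two parents are superimposed on their maximum common
substructure, every connected set of non-MCS heavy atoms is a
*fragment* (moiety); the MCS atoms it bonds to are *handle atoms*.
Hybrid products arise by choosing, per handle, which parent's
substituents occupy that position.  A fragment bonded to two or more
distinct handles (a *multiple-handle fragment*) fixes the parent choice
at all of its handles at once; choice vectors violating that are never
emitted.  Combinations placing heavy atoms of two different fragments
closer than a steric cutoff are skipped.

The handle-choice model: each handle selects a PARENT (A or B) and
inherits that parent's full substituent set there.  This keeps "mixing
and matching" well defined when a parent has zero or several fragments
on one handle; a bare choice (the chosen parent has no fragment at the
handle) leaves an implicit open valence for downstream protonation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .chem_model import (
    Atom,
    Molecule,
    largest_component,
    perceive_bonds,
    strip_hydrogens,
    submolecule,
)
from .errors import StructureError
from .mcs_search import (
    SubstructureMatch,
    enumerate_symmetry_mappings,
    find_mcs_candidates,
)
from .superposition import superpose_on_mcs

DEFAULT_CLASH_CUTOFF = 2.0  # Å between heavy atoms of different fragments

_QUANT = 1e-3  # Å quantum used when hashing fragment geometry


def _content_key(mol: Molecule, atom_indices: Sequence[int]) -> tuple:
    """Geometry-based identity of a fragment: sorted, quantized
    (element, x, y, z) rows.  Two fragments with the same atoms at the
    same (frame-aligned) positions collapse to the same key."""
    rows = []
    for i in atom_indices:
        a = mol.atoms[i]
        rows.append((a.element,) + tuple(int(round(v / _QUANT)) for v in a.position))
    return tuple(sorted(rows))


@dataclass(frozen=True)
class Fragment:
    """A connected set of non-MCS heavy atoms of one parent.

    ``anchors`` lists ``(handle_position, fragment_atom)`` pairs, one per
    bond crossing from the fragment into the MCS, where
    ``handle_position`` indexes the MCS atom list of the match.
    """

    parent: str  # "A" or "B"
    atom_indices: tuple[int, ...]
    anchors: tuple[tuple[int, int], ...]
    content_key: tuple = ()

    @property
    def handle_positions(self) -> tuple[int, ...]:
        return tuple(sorted({pos for pos, _ in self.anchors}))

    @property
    def is_multiple_handle(self) -> bool:
        return len(self.handle_positions) >= 2


@dataclass(frozen=True)
class HandleAtom:
    """An MCS atom carrying at least one substituent in either parent."""

    mcs_position: int
    options_a: tuple[Fragment, ...]
    options_b: tuple[Fragment, ...]


@dataclass(frozen=True)
class MergePlan:
    """Per-handle assignment of which parent's substituents are kept.

    ``choice`` is a sorted tuple of ``(handle_position, parent)`` pairs.
    """

    choice: tuple[tuple[int, str], ...]
    mcs_candidate_id: int = 0
    symmetry_mapping_id: int = 0
    plan_index: int = 0

    def choice_dict(self) -> dict[int, str]:
        return dict(self.choice)


@dataclass(frozen=True)
class MergedMolecule:
    """A hybrid product plus the bookkeeping that produced it.

    ``fragment_groups`` holds, per chosen fragment, the frozenset of atom
    indices it occupies in ``molecule`` — the unit over which steric
    clashes are assessed.
    """

    molecule: Molecule
    plan: MergePlan
    fragment_groups: tuple[frozenset, ...]
    provenance: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        p = self.plan
        return f"mcs{p.mcs_candidate_id}_map{p.symmetry_mapping_id}_plan{p.plan_index}"


@dataclass(frozen=True)
class MergeOptions:
    min_mcs_size: int = 3
    tolerance: float = 0.1
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    all_symmetry_relations: bool = True
    all_substituent_combinations: bool = True
    output_mcs: bool = False
    rng_seed: int = 0
    bond_slack: float = 0.45


@dataclass
class MergeResult:
    molecules: list[MergedMolecule]
    matches: list[SubstructureMatch]
    mcs_molecule: Molecule | None
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fragment extraction and handles
# ---------------------------------------------------------------------------

def extract_fragments(
    mol: Molecule,
    mcs_atoms: Sequence[int],
    parent: str = "A",
) -> tuple[Fragment, ...]:
    """Connected components of the non-MCS atom graph, with their anchors.

    ``mcs_atoms`` is the ordered MCS atom list of this parent; positions
    in that list index the handle atoms.  Every non-MCS atom belongs to
    exactly one fragment.  A non-MCS component with no bond into the MCS
    means the input was disconnected — a structural error.
    """
    mcs_list = list(mcs_atoms)
    mcs_set = set(mcs_list)
    if not mcs_set.issubset(range(mol.n_atoms)):
        raise ValueError("mcs_atoms reference atoms outside the molecule")
    pos_of = {atom: pos for pos, atom in enumerate(mcs_list)}
    rest = [i for i in range(mol.n_atoms) if i not in mcs_set]
    if not rest:
        return ()
    g = mol.graph().subgraph(rest)
    fragments = []
    for comp in sorted(nx.connected_components(g), key=min):
        comp = set(comp)
        anchors = sorted(
            (pos_of[v], u)
            for a, b in mol.bonds
            for u, v in ((a, b), (b, a))
            if u in comp and v in mcs_set
        )
        if not anchors:
            raise StructureError(
                f"{mol.name}: fragment {sorted(comp)} has no bond into the "
                "common substructure (disconnected input?)"
            )
        fragments.append(
            Fragment(
                parent=parent,
                atom_indices=tuple(sorted(comp)),
                anchors=tuple(anchors),
                content_key=_content_key(mol, sorted(comp)),
            )
        )
    return tuple(fragments)


def build_handles(
    fragments_a: Sequence[Fragment],
    fragments_b: Sequence[Fragment],
) -> tuple[HandleAtom, ...]:
    """Handle atoms: MCS positions anchored by >= 1 fragment in either parent."""
    positions = sorted(
        {pos for f in (*fragments_a, *fragments_b) for pos in f.handle_positions}
    )
    out = []
    for pos in positions:
        out.append(
            HandleAtom(
                mcs_position=pos,
                options_a=tuple(f for f in fragments_a if pos in f.handle_positions),
                options_b=tuple(f for f in fragments_b if pos in f.handle_positions),
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# Plan enumeration
# ---------------------------------------------------------------------------

def _is_consistent(choice: dict[int, str], handles: Sequence[HandleAtom]) -> bool:
    """Multiple-handle fragments must be taken at all of their handles."""
    frags = {
        f
        for h in handles
        for f in (h.options_a if choice[h.mcs_position] == "A" else h.options_b)
    }
    for f in frags:
        for pos in f.handle_positions:
            if pos in choice and choice[pos] != f.parent:
                return False
    return True


def _plan_signature(choice: dict[int, str], handles: Sequence[HandleAtom]) -> tuple:
    sig = []
    for h in handles:
        opts = h.options_a if choice[h.mcs_position] == "A" else h.options_b
        sig.append((h.mcs_position, frozenset(f.content_key for f in opts)))
    return tuple(sig)


def enumerate_plans(
    handles: Sequence[HandleAtom],
    all_combinations: bool = True,
    rng_seed: int = 0,
    mcs_candidate_id: int = 0,
    symmetry_mapping_id: int = 0,
) -> tuple[MergePlan, ...]:
    """Consistent per-handle parent choices.

    With ``all_combinations`` the full cross-product of per-handle {A, B}
    choices is generated (a handle where one parent has no substituent
    still admits that parent, yielding a bare position), filtered by
    multiple-handle consistency and deduplicated by effective
    fragment-content signature.  Otherwise exactly one uniformly random
    consistent plan is drawn with ``rng_seed`` — deterministic given the
    seed.  Zero handles yield the single empty plan.
    """
    positions = [h.mcs_position for h in handles]
    plans: list[MergePlan] = []
    seen: set[tuple] = set()
    idx = 0
    for combo in itertools.product("AB", repeat=len(positions)):
        choice = dict(zip(positions, combo))
        if not _is_consistent(choice, handles):
            continue
        sig = _plan_signature(choice, handles)
        if sig in seen:
            continue
        seen.add(sig)
        plans.append(
            MergePlan(
                choice=tuple(sorted(choice.items())),
                mcs_candidate_id=mcs_candidate_id,
                symmetry_mapping_id=symmetry_mapping_id,
                plan_index=idx,
            )
        )
        idx += 1
    if all_combinations:
        return tuple(plans)
    rng = np.random.default_rng(rng_seed)
    return (plans[int(rng.integers(len(plans)))],)


# ---------------------------------------------------------------------------
# Assembly and clash filtering
# ---------------------------------------------------------------------------

def _chosen_fragments(
    plan: MergePlan, handles: Sequence[HandleAtom]
) -> list[Fragment]:
    choice = plan.choice_dict()
    chosen: dict[tuple, Fragment] = {}
    for h in handles:
        opts = h.options_a if choice[h.mcs_position] == "A" else h.options_b
        for f in opts:
            chosen[(f.parent, f.atom_indices)] = f
    return [chosen[k] for k in sorted(chosen)]


def assemble_merged(
    mol_a: Molecule,
    superposed_b: Molecule,
    match: SubstructureMatch,
    mapping: Sequence[int],
    plan: MergePlan,
    fragments_a: Sequence[Fragment] | None = None,
    fragments_b: Sequence[Fragment] | None = None,
) -> MergedMolecule:
    """Build one hybrid: MCS atoms at parent-A coordinates, chosen
    A-fragments verbatim, chosen B-fragments with superposed coordinates,
    anchor bonds restored between handle atoms and fragment atoms."""
    mapping = tuple(mapping)
    if fragments_a is None:
        fragments_a = extract_fragments(mol_a, match.atoms_a, parent="A")
    if fragments_b is None:
        fragments_b = extract_fragments(superposed_b, mapping, parent="B")
    handles = build_handles(fragments_a, fragments_b)
    choice = plan.choice_dict()
    if set(choice) != {h.mcs_position for h in handles} or not _is_consistent(
        choice, handles
    ):
        raise ValueError("inconsistent or mismatched merge plan")

    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()

    # MCS atoms, parent-A coordinates, in atoms_a order
    mcs_new: dict[int, int] = {}
    for pos, a_idx in enumerate(match.atoms_a):
        src = mol_a.atoms[a_idx]
        mcs_new[pos] = len(atoms)
        atoms.append(
            Atom(index=len(atoms), element=src.element, position=src.position,
                 source_name=src.source_name)
        )
    a_pos = {a_idx: pos for pos, a_idx in enumerate(match.atoms_a)}
    for a, b in mol_a.bonds:
        if a in a_pos and b in a_pos:
            bonds.add(tuple(sorted((mcs_new[a_pos[a]], mcs_new[a_pos[b]]))))

    groups: list[frozenset] = []
    for frag in _chosen_fragments(plan, handles):
        source = mol_a if frag.parent == "A" else superposed_b
        new_of: dict[int, int] = {}
        for i in frag.atom_indices:
            src = source.atoms[i]
            new_of[i] = len(atoms)
            atoms.append(
                Atom(index=len(atoms), element=src.element, position=src.position,
                     source_name=src.source_name)
            )
        frag_set = set(frag.atom_indices)
        for a, b in source.bonds:
            if a in frag_set and b in frag_set:
                bonds.add(tuple(sorted((new_of[a], new_of[b]))))
        for pos, fatom in frag.anchors:
            bonds.add(tuple(sorted((mcs_new[pos], new_of[fatom]))))
        groups.append(frozenset(new_of.values()))

    choice_sig = ",".join(f"{pos}:{parent}" for pos, parent in plan.choice)
    merged = Molecule(
        name=f"{mol_a.name}__{superposed_b.name}__{plan.mcs_candidate_id}_"
             f"{plan.symmetry_mapping_id}_{plan.plan_index}",
        atoms=tuple(atoms),
        bonds=frozenset(bonds),
        provenance=(
            f"merged from {mol_a.name} (A) and {superposed_b.name} (B)",
            f"mcs_candidate={plan.mcs_candidate_id} "
            f"mapping={plan.symmetry_mapping_id} choice=[{choice_sig}]",
        ),
    )
    return MergedMolecule(
        molecule=merged,
        plan=plan,
        fragment_groups=tuple(groups),
        provenance=merged.provenance,
    )


def has_clash(merged: MergedMolecule, clash_cutoff: float = DEFAULT_CLASH_CUTOFF) -> bool:
    """True iff heavy atoms of two *different* chosen fragments come
    closer than ``clash_cutoff``.  MCS-fragment and intra-fragment pairs
    are exempt (anchor bonds are legitimately short)."""
    if clash_cutoff <= 0:
        raise ValueError("clash_cutoff must be > 0")
    coords = merged.molecule.coords
    groups = [sorted(g) for g in merged.fragment_groups]
    for gi, gj in itertools.combinations(groups, 2):
        diff = coords[gi][:, None, :] - coords[gj][None, :, :]
        if np.any((diff ** 2).sum(-1) < clash_cutoff ** 2):
            return True
    return False


# ---------------------------------------------------------------------------
# Whole-pair pipeline
# ---------------------------------------------------------------------------

def _molecule_identity(mol: Molecule) -> tuple:
    """Order-independent geometric hash used for global product dedup."""
    rows = sorted(
        (a.element, round(a.position[0], 6), round(a.position[1], 6),
         round(a.position[2], 6))
        for a in mol.atoms
    )
    return tuple((el,) for el, *_ in rows), np.array(
        [xyz for _, *xyz in rows], dtype=float
    ), len(mol.bonds)


def _is_duplicate(candidate: tuple, accepted: list[tuple], atol: float = 1e-3) -> bool:
    els_c, xyz_c, nb_c = candidate
    for els, xyz, nb in accepted:
        if els == els_c and nb == nb_c and xyz.shape == xyz_c.shape:
            if np.allclose(xyz, xyz_c, atol=atol):
                return True
    return False


def prepare(mol: Molecule, bond_slack: float = 0.45) -> Molecule:
    """Standard input conditioning: strip hydrogens, perceive bonds when
    the model carries none, and keep the largest connected component."""
    m = strip_hydrogens(mol)
    if not m.bonds:
        m = perceive_bonds(m, bond_slack)
    if not m.is_connected():
        m = largest_component(m)
    return m


def merge_pair(
    mol_a: Molecule,
    mol_b: Molecule,
    options: MergeOptions | None = None,
    **overrides,
) -> MergeResult:
    """Full merge pipeline for one ligand pair.

    Strip hydrogens and condition both inputs, find all size-maximal
    common substructures, enumerate symmetry assignments (all of them, or
    one drawn deterministically from the seed), superpose B onto A per
    assignment, enumerate consistent substituent plans, assemble hybrids,
    drop sterically clashing combinations, and deduplicate globally
    across assignments and MCS candidates.  The clash-skipped count is
    reported in ``summary``.
    """
    if options is None:
        options = MergeOptions(**overrides)
    elif overrides:
        raise TypeError("pass either options or keyword overrides, not both")

    a = prepare(mol_a, options.bond_slack)
    b = prepare(mol_b, options.bond_slack)

    matches = find_mcs_candidates(
        a, b, min_size=options.min_mcs_size, tol=options.tolerance
    )
    mcs_molecule = None
    if options.output_mcs:
        mcs_molecule = submolecule(
            a, matches[0].atoms_a, name=f"{a.name}__{b.name}__mcs",
            note="maximum common substructure",
        )

    products: list[MergedMolecule] = []
    identities: list[tuple] = []
    n_mappings_total = 0
    plans_enumerated = 0
    clash_skipped = 0

    for ci, match in enumerate(matches):
        mappings = enumerate_symmetry_mappings(match, a, b, options.tolerance)
        if options.all_symmetry_relations:
            selected = list(enumerate(mappings))
        else:
            rng = np.random.default_rng([options.rng_seed, ci])
            mi = int(rng.integers(len(mappings)))
            selected = [(mi, mappings[mi])]
        n_mappings_total += len(mappings)

        for mi, mapping in selected:
            sup_b, _ = superpose_on_mcs(a, b, match, mapping)
            frags_a = extract_fragments(a, match.atoms_a, parent="A")
            frags_b = extract_fragments(sup_b, mapping, parent="B")
            handles = build_handles(frags_a, frags_b)
            plans = enumerate_plans(
                handles,
                all_combinations=options.all_substituent_combinations,
                rng_seed=int(
                    np.random.default_rng([options.rng_seed, ci, mi]).integers(2**31)
                ),
                mcs_candidate_id=ci,
                symmetry_mapping_id=mi,
            )
            plans_enumerated += len(plans)
            for plan in plans:
                merged = assemble_merged(
                    a, sup_b, match, mapping, plan,
                    fragments_a=frags_a, fragments_b=frags_b,
                )
                if has_clash(merged, options.clash_cutoff):
                    clash_skipped += 1
                    continue
                ident = _molecule_identity(merged.molecule)
                if _is_duplicate(ident, identities):
                    continue
                identities.append(ident)
                products.append(merged)

    if not products:
        warnings.warn(
            f"{a.name}/{b.name}: every fragment combination was skipped "
            "(steric clashes); no merged molecules emitted"
        )
    summary = {
        "mcs_size": matches[0].size,
        "n_candidates": len(matches),
        "n_mappings": n_mappings_total,
        "plans_enumerated": plans_enumerated,
        "clash_skipped": clash_skipped,
        "n_products": len(products),
    }
    return MergeResult(
        molecules=products,
        matches=matches,
        mcs_molecule=mcs_molecule,
        summary=summary,
    )
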