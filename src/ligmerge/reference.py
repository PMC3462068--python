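"""Brute-force reference search for the largest geometric common
connected substructure.

This is an exhaustive backtracking search over element-preserving,
distance-preserving partial atom maps, independent of the stretch-based
production search in :mod:`ligmerge.mcs_search`.  It exists purely for
validation: on small molecules (roughly <= 14 heavy atoms) its maximum
is ground truth against which the fast search is checked.

The search grows a mapping one parent-A atom at a time, restricted to
atoms adjacent to the already-mapped set (so the A-side subgraph stays
connected), and at each step branches on the smallest frontier atom:
either map it to some compatible parent-B atom or exclude it for good.
That include/exclude discipline visits every connected subset exactly
once instead of once per traversal order.
"""

from __future__ import annotations

from .chem_model import Molecule


def max_common_substructure_size(
    mol_a: Molecule,
    mol_b: Molecule,
    tol: float = 0.1,
) -> int:
    """Size of the largest element- and geometry-preserving common
    connected substructure (0 if even a single atom cannot be matched).

    Exponential in the worst case; intended for small validation inputs
    only.
    """
    n_a, n_b = mol_a.n_atoms, mol_b.n_atoms
    ea, eb = mol_a.elements, mol_b.elements
    da = mol_a.distance_matrix()
    db = mol_b.distance_matrix()
    adj = {i: set(mol_a.neighbors(i)) for i in range(n_a)}

    best = 0

    def extend(mapping: dict[int, int], used_b: set[int], excluded: set[int]) -> None:
        nonlocal best
        best = max(best, len(mapping))
        # prune: even mapping every remaining A atom cannot beat best
        if len(mapping) + (n_a - len(mapping) - len(excluded)) <= best:
            return
        if mapping:
            frontier = (
                {nb for a in mapping for nb in adj[a]}
                - mapping.keys()
                - excluded
            )
        else:
            frontier = set(range(n_a)) - excluded
        if not frontier:
            return
        a = min(frontier)
        for b in range(n_b):
            if b in used_b or eb[b] != ea[a]:
                continue
            if all(
                abs(da[a, ap] - db[b, bp]) <= tol for ap, bp in mapping.items()
            ):
                mapping[a] = b
                used_b.add(b)
                extend(mapping, used_b, excluded)
                del mapping[a]
                used_b.remove(b)
        excluded.add(a)
        extend(mapping, used_b, excluded)
        excluded.remove(a)

    extend({}, set(), set())
    return best
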