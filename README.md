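# ligmerge

Geometric maximum-common-substructure search and fragment recombination
for 3D small-molecule models.

Medicinal chemists optimizing a lead compound often have several known
binders for the same target and want candidates that recombine their
chemical moieties. `ligmerge` automates that ligand-based hybridization:
given two 3D ligand models (PDB format, e.g. docked or crystallographic
poses), it

1. **finds the maximum common substructure (MCS)** — the largest set of
   heavy atoms occurring in both molecules with the same element
   sequence along the bond graph *and* the same 3D geometry, found by
   enumerating connected atom stretches (three atoms or longer),
   bucketing them by element sequence, and comparing their distance
   fingerprints (the sorted list of all pairwise interatomic distances)
   within a tolerance, largest candidates first;
2. **superimposes** the two molecules on the MCS with the Kabsch
   algorithm (the closed-form SVD solution for the proper rotation *R*
   and translation *t* minimizing RMSD between corresponded point sets),
   once per symmetry-equivalent atom assignment — a toluene-shaped MCS,
   for instance, admits exactly two;
3. **mixes and matches substituents**: every connected non-MCS fragment
   hangs off one or more MCS "handle atoms"; each handle chooses which
   parent's substituents to keep, fragments spanning several handles fix
   the choice at all of them, combinations that put two fragments'
   heavy atoms closer than a steric cutoff (default 2.0 Å) are skipped,
   and each surviving hybrid is written to its own PDB file.

The method treats molecules as rigid: use docked/crystallographic poses
or molecules with rigid cores. Products are heavy-atom skeletons meant
for downstream protonation and minimization before docking.

## Worked example

```python
from ligmerge import merge_pair, MergeOptions
from ligmerge.fixtures import ScaffoldSpec, SubstituentSpec, build_pair

# two parents sharing a toluene core: parent A carries a fluorine at ring
# position 2, parent B a chlorine at position 3
spec = ScaffoldSpec("ring_plus_methyl", 6, ("C",) * 6)
mol_a, mol_b, _ = build_pair(
    spec,
    [SubstituentSpec(2, "atom", ("F",))],
    [SubstituentSpec(3, "atom", ("CL",))],
    names=("tolA", "tolB"),
)

result = merge_pair(mol_a, mol_b, MergeOptions(output_mcs=True))
print(result.summary)
for m in result.molecules:
    print(m.label, sorted(m.molecule.elements))
```

prints

```
{'mcs_size': 7, 'n_candidates': 1, 'n_mappings': 2, 'plans_enumerated': 8, 'clash_skipped': 0, 'n_products': 4}
mcs0_map0_plan0 ['C', 'C', 'C', 'C', 'C', 'C', 'C', 'F']
mcs0_map0_plan1 ['C', 'C', 'C', 'C', 'C', 'C', 'C', 'CL', 'F']
mcs0_map0_plan2 ['C', 'C', 'C', 'C', 'C', 'C', 'C']
mcs0_map0_plan3 ['C', 'C', 'C', 'C', 'C', 'C', 'C', 'CL']
```

The shared toluene core (7 heavy atoms) admits two symmetry assignments
(`n_mappings`); over both overlays eight substituent plans were
enumerated, collapsing to four unique products: parent A's pattern
(`…F`), parent B's (`…CL`), the bare core, and the novel hybrid carrying
both halogens. None clashed.

## Command line

```sh
# one pair
ligmerge --ligand-a A.pdb --ligand-b B.pdb --out outdir --output-mcs

# every unordered pair of PDB files in a directory
ligmerge --ligands-dir ligands/ --out outdir --seed 0
```

Options: `--min-mcs-size` (floor 3), `--tolerance` (Å per pairwise
distance, default 0.1), `--clash-cutoff` (default 2.0 Å),
`--one-symmetry` / `--all-symmetry-relations`, `--single-random` /
`--all-substituent-combinations`, `--output-mcs`, `--seed`. Single-dash
spellings such as `-ligands_dir` and `-output_mcs` are accepted as
aliases. Batch mode writes a per-pair `ligmerge_summary.tsv` (MCS size,
mapping count, plans, clash skips, files written) and continues past
pairs with no common substructure.

## Testing

```sh
python -m pytest -q tests/
```

The suite exercises every stage against analytic fixtures (the
`ligmerge.fixtures` module builds scaffold-plus-substituent molecule
pairs whose MCS size, symmetry count, handle count and product count are
known combinatorially) and cross-checks the stretch-based MCS search
against an exhaustive backtracking reference (`ligmerge.reference`).

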