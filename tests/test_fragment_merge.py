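"""Fragment extraction, plan enumeration, clash filtering, merging."""

import numpy as np
import pytest

from ligmerge import (
    MergeOptions,
    StructureError,
    assemble_merged,
    build_handles,
    enumerate_plans,
    extract_fragments,
    find_mcs,
    has_clash,
    merge_pair,
    molecule_from_arrays,
    prepare,
    superpose_on_mcs,
)
from ligmerge.fixtures import ScaffoldSpec, SubstituentSpec, build_pair

from conftest import ASYM_CHAIN7, molecule_signature, same_molecule


def _pipeline_products(a, b, **kw):
    return merge_pair(a, b, MergeOptions(**kw))


class TestExtractFragments:
    def test_toluene_methyl_is_one_fragment(self, toluene):
        frags = extract_fragments(toluene, mcs_atoms=list(range(6)))
        assert len(frags) == 1
        assert frags[0].atom_indices == (6,)
        assert frags[0].anchors == ((0, 6),)
        assert not frags[0].is_multiple_handle

    def test_para_substituents_are_two_fragments(self, benzene):
        coords = np.vstack([
            benzene.coords,
            benzene.coords[0] * 2.0,  # radial payloads at positions 0 and 3
            benzene.coords[3] * 2.0,
        ])
        mol = molecule_from_arrays(
            "para", list(benzene.elements) + ["F", "CL"], coords,
            bonds=list(benzene.bonds) + [(0, 6), (3, 7)],
        )
        frags = extract_fragments(mol, mcs_atoms=list(range(6)))
        assert len(frags) == 2
        assert sorted(f.handle_positions for f in frags) == [(0,), (3,)]
        handles = build_handles(frags, ())
        assert len(handles) == 2

    def test_bridge_is_multiple_handle(self, bridge_pair):
        a, _, _ = bridge_pair
        frags = extract_fragments(a, mcs_atoms=list(range(6)))
        assert len(frags) == 1
        assert frags[0].handle_positions == (0, 1)
        assert frags[0].is_multiple_handle

    def test_unanchored_component_is_structural_error(self):
        mol = molecule_from_arrays(
            "iso", ["C", "C", "C", "O"],
            [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [50, 0, 0]],
            bonds=[(0, 1), (1, 2)],
        )
        with pytest.raises(StructureError):
            extract_fragments(mol, mcs_atoms=[0, 1, 2])

    def test_every_nonmcs_atom_in_exactly_one_fragment(self, two_handle_pair):
        a, _, _ = two_handle_pair
        frags = extract_fragments(a, mcs_atoms=list(range(5)))
        covered = sorted(i for f in frags for i in f.atom_indices)
        assert covered == list(range(5, a.n_atoms))


class TestEnumeratePlans:
    def _handles(self, pair):
        a, b, _ = pair
        pa, pb = prepare(a), prepare(b)
        match = find_mcs(pa, pb)
        mapping = match.mappings[0]
        sup_b, _ = superpose_on_mcs(pa, pb, match, mapping)
        fa = extract_fragments(pa, match.atoms_a, parent="A")
        fb = extract_fragments(sup_b, mapping, parent="B")
        return build_handles(fa, fb)

    def test_two_single_handle_fragments_give_four_plans(self, two_handle_pair):
        handles = self._handles(two_handle_pair)
        plans = enumerate_plans(handles)
        assert len(plans) == 4
        choices = {tuple(p for _, p in plan.choice) for plan in plans}
        assert choices == {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}

    def test_multiple_handle_fragment_blocks_mixed_plans(self, bridge_pair):
        handles = self._handles(bridge_pair)
        plans = enumerate_plans(handles)
        assert len(plans) == 2
        choices = {tuple(p for _, p in plan.choice) for plan in plans}
        assert choices == {("A", "A"), ("B", "B")}

    def test_single_random_mode_is_deterministic(self, two_handle_pair):
        handles = self._handles(two_handle_pair)
        one = enumerate_plans(handles, all_combinations=False, rng_seed=123)
        two = enumerate_plans(handles, all_combinations=False, rng_seed=123)
        assert len(one) == 1 and one == two
        assert one[0] in enumerate_plans(handles)
        assert one[0].choice == enumerate_plans(
            handles, all_combinations=False, rng_seed=123
        )[0].choice

    def test_zero_handles_yield_one_empty_plan(self):
        plans = enumerate_plans(())
        assert len(plans) == 1 and plans[0].choice == ()


class TestAssembleAndClash:
    def _setup(self, pair):
        a, b, _ = pair
        pa, pb = prepare(a), prepare(b)
        match = find_mcs(pa, pb)
        mapping = match.mappings[0]
        sup_b, _ = superpose_on_mcs(pa, pb, match, mapping)
        return pa, pb, sup_b, match, mapping

    def test_all_a_plan_recovers_parent(self, two_handle_pair):
        pa, _, sup_b, match, mapping = self._setup(two_handle_pair)
        plans = {
            tuple(p for _, p in plan.choice): plan
            for plan in enumerate_plans(
                build_handles(
                    extract_fragments(pa, match.atoms_a, "A"),
                    extract_fragments(sup_b, mapping, "B"),
                )
            )
        }
        merged = assemble_merged(pa, sup_b, match, mapping, plans[("A", "A")])
        assert same_molecule(merged.molecule, pa)
        assert len(merged.molecule.bonds) == len(pa.bonds)

    def test_all_b_plan_matches_superposed_parent(self, two_handle_pair):
        pa, _, sup_b, match, mapping = self._setup(two_handle_pair)
        plans = {
            tuple(p for _, p in plan.choice): plan
            for plan in enumerate_plans(
                build_handles(
                    extract_fragments(pa, match.atoms_a, "A"),
                    extract_fragments(sup_b, mapping, "B"),
                )
            )
        }
        merged = assemble_merged(pa, sup_b, match, mapping, plans[("B", "B")])
        # MCS atoms sit at A's coordinates, each within tolerance of B's
        _, xm = molecule_signature(merged.molecule)
        _, xb = molecule_signature(sup_b)
        assert np.abs(xm - xb).max() <= match.tolerance

    def test_mixed_plan_atom_count(self, two_handle_pair):
        pa, _, sup_b, match, mapping = self._setup(two_handle_pair)
        handles = build_handles(
            extract_fragments(pa, match.atoms_a, "A"),
            extract_fragments(sup_b, mapping, "B"),
        )
        plans = {
            tuple(p for _, p in plan.choice): plan
            for plan in enumerate_plans(handles)
        }
        merged = assemble_merged(pa, sup_b, match, mapping, plans[("A", "B")])
        assert merged.molecule.n_atoms == match.size + 2  # one atom per handle
        assert len(merged.fragment_groups) == 2

    def test_single_fragment_never_clashes(self, toluene_pair):
        pa, _, sup_b, match, mapping = self._setup(toluene_pair)
        handles = build_handles(
            extract_fragments(pa, match.atoms_a, "A"),
            extract_fragments(sup_b, mapping, "B"),
        )
        for plan in enumerate_plans(handles):
            merged = assemble_merged(pa, sup_b, match, mapping, plan)
            if len(merged.fragment_groups) <= 1:
                assert has_clash(merged, clash_cutoff=100.0) is False

    def test_clash_depends_on_cutoff(self, clash_pair):
        pa, _, sup_b, match, mapping = self._setup(clash_pair)
        handles = build_handles(
            extract_fragments(pa, match.atoms_a, "A"),
            extract_fragments(sup_b, mapping, "B"),
        )
        both = {
            tuple(p for _, p in plan.choice): plan
            for plan in enumerate_plans(handles)
        }[("A", "B")]
        merged = assemble_merged(pa, sup_b, match, mapping, both)
        assert has_clash(merged, clash_cutoff=2.0) is True  # tips ~1.5 Å apart
        assert has_clash(merged, clash_cutoff=1.0) is False

    def test_inconsistent_plan_rejected(self, bridge_pair):
        pa, _, sup_b, match, mapping = self._setup(bridge_pair)
        bad_choice = tuple(sorted({0: "A", 1: "B"}.items()))
        from ligmerge import MergePlan

        with pytest.raises(ValueError):
            assemble_merged(
                pa, sup_b, match, mapping, MergePlan(choice=bad_choice)
            )


class TestMergePair:
    def test_self_merge_recovers_parent(self, toluene):
        result = merge_pair(toluene, toluene)
        assert any(same_molecule(m.molecule, toluene) for m in result.molecules)
        parent_elements = sorted(toluene.elements)
        for m in result.molecules:
            assert sorted(m.molecule.elements) == parent_elements

    def test_two_handle_fixture_gives_four_products(self, two_handle_pair):
        a, b, expected = two_handle_pair
        result = merge_pair(a, b)
        assert len(result.molecules) == expected["plan_count"] == 4
        sigs = [molecule_signature(m.molecule) for m in result.molecules]
        assert any(same_molecule(m.molecule, prepare(a)) for m in result.molecules)
        # two products are novel hybrids (neither parent's pattern)
        novel = [
            m for m in result.molecules
            if not same_molecule(m.molecule, prepare(a))
            and sorted(m.molecule.elements) != sorted(prepare(b).elements)
        ]
        assert len(sigs) == len(result.molecules)
        assert len(novel) == 2

    def test_multiple_handle_fixture_gives_two_products(self, bridge_pair):
        a, b, expected = bridge_pair
        result = merge_pair(a, b)
        assert expected["plan_count"] == 2
        assert len(result.molecules) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_single_random_mode_is_subset(self, two_handle_pair, seed):
        a, b, _ = two_handle_pair
        full = merge_pair(a, b)
        single = merge_pair(
            a, b,
            MergeOptions(all_substituent_combinations=False, rng_seed=seed),
        )
        assert len(single.molecules) == 1
        assert any(
            same_molecule(single.molecules[0].molecule, m.molecule)
            for m in full.molecules
        )

    def test_clash_cutoff_monotonicity(self, clash_pair):
        a, b, _ = clash_pair
        counts = [
            len(merge_pair(a, b, MergeOptions(clash_cutoff=c)).molecules)
            for c in (0.5, 1.0, 2.0, 3.5)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the sweep actually crosses the contact

    @pytest.mark.parametrize("n_handles", [1, 2, 3])
    def test_count_law_for_single_handle_fragments(self, n_handles):
        spec = ScaffoldSpec("linear_chain", 7, ASYM_CHAIN7)
        positions = [1, 3, 5][:n_handles]
        pool_a = ["F", "CL", "BR"]
        pool_b = ["I", "P", "S"]
        subs_a = [
            SubstituentSpec(p, "atom", (pool_a[i],))
            for i, p in enumerate(positions)
        ]
        subs_b = [
            SubstituentSpec(p, "atom", (pool_b[i],))
            for i, p in enumerate(positions)
        ]
        a, b, expected = build_pair(spec, subs_a, subs_b)
        result = merge_pair(a, b)
        assert expected["plan_count"] == 2 ** n_handles
        assert len(result.molecules) == 2 ** n_handles

    def test_output_mcs(self, toluene_pair):
        a, b, expected = toluene_pair
        result = merge_pair(a, b, MergeOptions(output_mcs=True))
        assert result.mcs_molecule is not None
        assert result.mcs_molecule.n_atoms == expected["mcs_size"] == 7

    def test_summary_counts_are_consistent(self, toluene_pair):
        a, b, _ = toluene_pair
        s = merge_pair(a, b).summary
        assert s["n_products"] <= s["plans_enumerated"] - s["clash_skipped"]
        assert s["mcs_size"] == 7 and s["n_mappings"] == 2

    def test_merged_molecule_invariants(self, two_handle_pair):
        a, b, _ = two_handle_pair
        result = merge_pair(a, b)
        for m in result.molecules:
            mol = m.molecule
            # connected, bonds valid, every fragment group disjoint
            assert mol.is_connected()
            groups = list(m.fragment_groups)
            flat = [i for g in groups for i in g]
            assert len(flat) == len(set(flat))
            assert not has_clash(m, clash_cutoff=2.0)
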