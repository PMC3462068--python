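"""Shared fixtures: analytically constructed molecule pairs."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligmerge import RigidTransform, molecule_from_arrays
from ligmerge.fixtures import ScaffoldSpec, SubstituentSpec, build_molecule, build_pair

#: mixed-element hexagon whose necklace has no non-trivial automorphism
ASYM_RING = ("C", "C", "C", "N", "O", "C")
#: non-palindromic 7-atom chain
ASYM_CHAIN7 = ("C", "C", "N", "O", "O", "C", "N")


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    return RigidTransform(
        rotation=Rotation.random(rng=rng).as_matrix(),
        translation=rng.uniform(-10.0, 10.0, 3),
    )


def molecule_signature(mol):
    """Order-independent (elements, sorted coordinates) pair."""
    rows = sorted(
        (a.element, round(a.position[0], 4), round(a.position[1], 4),
         round(a.position[2], 4))
        for a in mol.atoms
    )
    elements = tuple(r[0] for r in rows)
    xyz = np.array([r[1:] for r in rows], dtype=float)
    return elements, xyz


def same_molecule(m1, m2, atol=1e-3) -> bool:
    e1, x1 = molecule_signature(m1)
    e2, x2 = molecule_signature(m2)
    return e1 == e2 and x1.shape == x2.shape and np.allclose(x1, x2, atol=atol)


@pytest.fixture
def benzene():
    """Bare benzene ring at ideal geometry (C-C 1.5 Å)."""
    return build_molecule(
        ScaffoldSpec("ring", 6, ("C",) * 6), [], "benzene"
    )


@pytest.fixture
def toluene():
    """Toluene heavy atoms: hexagon plus exocyclic methyl carbon."""
    return build_molecule(
        ScaffoldSpec("ring_plus_methyl", 6, ("C",) * 6), [], "toluene"
    )


@pytest.fixture
def toluene_pair():
    """Parents sharing a full toluene; distinct halogens at ring positions."""
    spec = ScaffoldSpec("ring_plus_methyl", 6, ("C",) * 6)
    return build_pair(
        spec,
        [SubstituentSpec(2, "atom", ("F",))],
        [SubstituentSpec(3, "atom", ("CL",))],
        names=("tolA", "tolB"),
    )


@pytest.fixture
def benzene_pair():
    """Parents sharing a bare benzene scaffold (12-fold symmetric MCS)."""
    spec = ScaffoldSpec("ring", 6, ("C",) * 6)
    return build_pair(
        spec,
        [SubstituentSpec(0, "atom", ("F",))],
        [SubstituentSpec(1, "atom", ("CL",))],
        names=("benzA", "benzB"),
    )


@pytest.fixture
def two_handle_pair():
    """Asymmetric chain scaffold; one single-atom substituent per parent
    per handle at non-adjacent positions — four clash-free hybrids."""
    spec = ScaffoldSpec("linear_chain", 5, ("C", "C", "N", "O", "O"))
    return build_pair(
        spec,
        [SubstituentSpec(1, "atom", ("F",)),
         SubstituentSpec(3, "atom", ("CL",))],
        [SubstituentSpec(1, "atom", ("BR",)),
         SubstituentSpec(3, "atom", ("I",))],
        names=("chainA", "chainB"),
    )


@pytest.fixture
def bridge_pair():
    """Parent A carries a fragment bridging two adjacent ring positions
    (a multiple-handle fragment); parent B has one substituent per
    position.  Only the all-A and all-B plans are consistent."""
    spec = ScaffoldSpec("ring", 6, ASYM_RING)
    return build_pair(
        spec,
        [SubstituentSpec(0, "bridge", ("F",), second_position=1)],
        [SubstituentSpec(0, "atom", ("CL",)),
         SubstituentSpec(1, "atom", ("BR",))],
        names=("bridgeA", "bridgeB"),
    )


@pytest.fixture
def clash_pair():
    """Two-atom substituent chains on adjacent (ortho) ring positions,
    tilted toward each other so their tips approach to 1.5 Å."""
    spec = ScaffoldSpec("ring", 6, ASYM_RING)
    return build_pair(
        spec,
        [SubstituentSpec(0, "chain2", ("F", "F"), tilt_deg=60.0)],
        [SubstituentSpec(1, "chain2", ("BR", "BR"), tilt_deg=-60.0)],
        names=("orthoA", "orthoB"),
    )


def chain_molecule(name, elements, spacing=1.5):
    """Evenly spaced chain along x, explicit bonds."""
    n = len(elements)
    coords = np.array([[i * spacing, 0.0, 0.0] for i in range(n)])
    bonds = [(i, i + 1) for i in range(n - 1)]
    return molecule_from_arrays(name, elements, coords, bonds)
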