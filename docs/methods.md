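# Methods

## The model

`ligmerge` hybridizes two rigid 3D ligand models by (i) locating their
maximum common substructure (MCS), (ii) superimposing them on it, and
(iii) recombining the substituent fragments attached to it. The working
assumptions are:

* **Rigidity.** Geometric comparison ignores conformational flexibility
  entirely; two atoms sets "match" only if their internal distances
  agree within a fixed tolerance. Inputs should therefore be docked or
  crystallographic poses, or molecules whose shared core is rigid
  (rings, fused systems).
* **Heavy atoms only.** Hydrogens are stripped before any analysis and
  are never restored; products are heavy-atom skeletons with implicit
  open valences, intended for downstream protonation/minimization.
* **No bond orders.** PDB input carries no order information and no
  pipeline stage needs it; connectivity is a plain undirected graph.

## MCS search

**Stretch enumeration.** "Common substructure candidates" are *simple
paths* in each molecule's bond graph, bucketed by their element
sequence (orientation-independent). A path-based reading means the MCS
atom set must be traceable by one simple path — rings, chains, and
ring-plus-tail shapes qualify; a star-branched common core with three
or more leaves would be missed. This trade-off is deliberate: paths
give a complete, deterministic enumeration with a cheap sequence-level
pre-filter, and typical shared scaffolds (rings, fused ring systems,
chains) are path-traceable. The shortest stretch considered is three
atoms; single atoms or bonded pairs are not distinctive enough to
anchor an overlay, so three is also the floor for the user-settable
minimum MCS size.

**Geometry filter.** Each stretch is summarized by its distance
fingerprint — the sorted list of all n(n−1)/2 pairwise distances —
which is invariant under rigid motion and atom permutation. Fingerprint
agreement (element-wise, within tolerance) is necessary but not
sufficient, because sorting discards correspondence; the authoritative
check (`verify_mappings`) tests the explicit forward and, for
palindromic element sequences, reversed atom alignments against the
*unsorted* distance matrices. Since sorting is 1-Lipschitz in the sup
norm, the sorted pre-filter can never reject a pair the unsorted check
would accept.

**Largest-first search.** Candidate sizes run from min(n_A, n_B)
downward; the first size with a verified pair defines the MCS. All
verified pairs at that size are kept (deduplicated by atom-set pair),
so equally sized tie candidates each drive merge generation. Keys and
pairs are processed in lexicographic order: results are deterministic.

**Symmetry.** The sorted/verified machinery yields at least one atom
assignment, but a symmetric MCS admits several (two for a toluene
shape, 2n for an n-cycle of identical elements). A backtracking
enumeration over element-preserving, distance-preserving bijections
recovers all of them; merging runs once per assignment (or once for a
seed-chosen single assignment).

**Tolerance.** The default is 0.1 Å per pairwise distance: tight enough
to distinguish 5- from 6-ring geometries and chair/boat-scale
differences, loose enough to absorb minimization jitter in structures
that should match. It is a per-distance bound, not an RMSD bound.

## Superposition

The optimal overlay is the Kabsch closed form: subtract centroids, SVD
the 3×3 covariance, fix the determinant sign, recompose. The sign fix
is load-bearing — improper (reflective) "rotations" are refused at the
type level (`RigidTransform` requires det +1), since a reflected
overlay would silently invert chirality. The fit uses the MCS atoms
only but is applied to the whole moving molecule; parent A's frame is
the fixed output frame for all products. Collinear point sets (e.g. an
all-chain MCS) produce a warning: the rotation about the line is
arbitrary, though still RMSD-optimal.

## Fragment merging

Fragments are connected components of the non-MCS atom graph; anchors
are the bonds crossing into the MCS. Each handle atom selects a
*parent* (A or B) and inherits that parent's complete substituent set
at that position — this keeps the combinatorics well defined when a
parent has zero or several fragments on one handle; choosing a parent
with nothing there yields a bare position. A fragment anchored at
several handles ("multiple-handle") forces all of its handles to its
parent; inconsistent choice vectors are filtered before assembly.
Plans are deduplicated by effective fragment *content* (element +
quantized coordinates), so e.g. self-merges collapse the A/B choices.

**Clash filter.** A combination is skipped when heavy atoms of two
*different* chosen fragments come closer than the cutoff (default
2.0 Å — just above covalent bond lengths, well below nonbonded contact
distances). MCS–fragment and intra-fragment pairs are exempt: anchor
bonds are legitimately short. The count of skipped combinations is
reported per pair.

**Global dedup.** Products from different symmetry assignments or tie
MCS candidates may coincide; products are deduplicated by an
order-independent geometric hash (sorted element/coordinate rows,
compared within 10⁻³ Å).

**Random single-compound mode.** With all-combinations off, one
uniformly random consistent plan is drawn per overlay from a seeded
generator (default seed 0), so "random" runs are still reproducible;
the output is always a member of the all-combinations output.

## Input handling

PDB v3.3 fixed columns; ATOM and HETATM records both accepted; only the
first MODEL of a multi-model file; altloc other than blank/'A' skipped.
Connectivity comes from CONECT records when present; molecules arriving
with no bonds get distance-based perception — bonded iff
d ≤ r_cov(i) + r_cov(j) + slack, with Cordero single-bond covalent
radii and a 0.45 Å slack, the standard distance heuristic — and CONECT
and perceived bonds are unioned. Disconnected inputs trigger a warning
and proceed on the largest connected component, since a common
substructure "stretch" cannot cross components. Writing emits HETATM +
CONECT + END; write→read round-trips elements, bonds and coordinates to
0.001 Å.

## Synthetic fixtures

Real ligand pairs have no analytic ground truth, so `ligmerge.fixtures`
generates scaffold-plus-substituent toys for which every pipeline-level
quantity is computable combinatorially: regular-polygon rings, evenly
spaced chains (1.5 Å generic bond length), and ring-plus-methyl
(toluene-shaped) scaffolds, decorated with single-atom, two-atom-chain
(optionally tilted, to manufacture steric clashes at known distances),
three-atom-branch, or two-handle bridge payloads placed radially
outward. Both parents share the *identical* scaffold coordinates
(seeded jitter, when requested, is applied once before decoration), so
expected MCS size equals the scaffold atom count, the symmetry count is
the scaffold necklace-automorphism count, and plan counts follow from
the bridge-consistency case analysis. Two validity rules keep that
ground truth exact: one payload per position per parent, and payload
elements disjoint from the scaffold and between parents.

What these fixtures do *not* emulate: realistic valence and bond-length
chemistry, aromatic geometry subtleties, conformational noise between
the two parents, and MCS shapes that are not path-traceable. Passing
tests therefore demonstrate algorithmic correctness under the stated
rigid-geometry model, not chemical validity of products on real data.

## Validation reference

`ligmerge.reference` implements an exhaustive backtracking search for
the largest element- and distance-preserving *connected* common
substructure, growing a partial map atom-by-atom with an
include/exclude branch on the smallest frontier atom (each connected
subset visited once). It shares no code with the production search and
serves as ground truth on randomized fixtures (≤ 14 heavy atoms, where
exhaustive search is fast).

## Numerical choices

* Distance tolerance 0.1 Å (per pair), user-configurable; verification
  allows 10⁻⁹ Å headroom over it when re-checking a mapping.
* Bond perception slack 0.45 Å; clash cutoff 2.0 Å.
* Fragment-content quantization 10⁻³ Å; product dedup at 10⁻³ Å after
  sorting rows rounded to 10⁻⁶ Å.
* Kabsch degenerate case (rank < 2 centered cloud) warns, still solves.
* All randomness flows through `numpy.random.default_rng` seeded from
  user-supplied integers; batch runs are byte-reproducible.

## Problem sizes

Tests and the acceptance script run on fixtures of ≤ 14 heavy atoms per
molecule, 50 randomized pairs for the reference comparison, and 1000
random rigid transforms for the Monte-Carlo optimality check — sizes at
which the exhaustive reference is exact and the whole suite completes
in seconds.

## Known limitations

* Branched common cores with ≥ 3 leaves are found only via the longest
  path through them (smaller than the true common subgraph).
* Path enumeration is exponential in pathological dense graphs; typical
  drug-like bond graphs (degree ≤ 4, sparse rings) are unproblematic,
  but there is no hard cap.
* No valence/chemical-sanity repair, scoring, or minimization of
  products; no SDF/MOL/SMILES input (convert to PDB first).
* The handle model offers parent A's or parent B's substituents at each
  handle — there is no "drop both" option at a doubly occupied handle.
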