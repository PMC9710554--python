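# Methods

This note documents the models, numerical conventions and design choices
behind `pocketgraft`, in the spirit of a package reference manual: what is
computed, under which assumptions, and where the behaviour is a deliberate
choice among several defensible ones.

## Ligand-centric internal frames

Every analysis is anchored on single ligand side chains.  A ligand
residue's frame places Cα at the origin, Cβ on the positive x-axis, the
carbonyl C in the xy-plane and the amide N at negative z.  The
"C in plane" condition leaves a two-fold ambiguity which the N-below-plane
condition resolves; for exactly planar backbones (numerically never
observed) the positive branch is kept.  Frames are orthonormal to 1e-9 and
right-handed; degenerate geometry (Cα=Cβ, or carbonyl C collinear with the
Cα–Cβ axis) raises an error, and the affected datapoint is skipped with a
warning rather than imputed.

**Virtual Cβ.**  Glycine (and residues with truncated side chains) receives
a virtual Cβ at 1.53 Å from Cα making the ideal tetrahedral angle
(109.47°) with both the Cα→N and Cα→C bonds.  Two mirror placements
satisfy these constraints; the L-amino-acid branch is used, matching the
empirical Cβ-reconstruction constants used in structure prediction to
within 0.05 Å on an idealized backbone.  The construction is therefore
equivariant under rotations and translations but — like the amino acids
themselves — chiral: reflecting the backbone selects the other enantiomer's
Cβ.  This choice makes the similarity score total over all 20 residue
types, glycine included.

## Spatial similarity

Residues R1, R2 expressed in one frame are compared by

s = f_d·‖Cα1−Cα2‖ + f_o·∠(primary orientations) + f_s·∠(secondary orientations)

where the primary orientation is Cα→Cβ and the secondary is Cα→carbonyl-C.
**Angles are in radians.**  This is a deliberate convention: with the
default weights (f_d = 1.0 Å⁻¹, f_o = f_s = 2.0) radians keep the distance
and orientation terms commensurate (both of order a few units for typical
mismatches), whereas degrees would let orientation dominate by two orders
of magnitude.  The score is symmetric, non-negative, zero iff positions
coincide and both orientation pairs are parallel, and invariant under a
joint rigid motion of both poses.

## Contact model

Atom pairs interact when their distance is within the radius of their
chemical class, evaluated in the order ionic (8.0 Å) → aromatic (6.0 Å) →
hydrogen bond (6.0 Å) → other (4.0 Å); the first class whose predicate and
radius both match wins.  The class table (charged atoms, aromatic ring
carbons, donors/acceptors) ships as data
(`pocketgraft.chem.DEFAULT_CHEMICAL_CLASSES`) and can be overridden from a
JSON file.  Conventions worth noting:

* Histidine counts as both charged and aromatic; ionic takes precedence.
* With `skip_backbone_atoms` (default, matching the reference parameter
  set) only side-chain atoms participate, Cβ included.  **Glycine keeps
  its Cα as a side-chain surrogate** so every residue type can appear on
  both sides of a contact; without this, glycine pages and maps would be
  structurally empty, contradicting the full 20-page / 400-map partition
  the atlas is defined to support.  Cation–π interactions are not modelled;
  an Arg–Trp pair at ring distance only registers if some atom pair falls
  within the 4.0 Å "other" radius.
* A residue pair with several qualifying atom contacts yields **one**
  datapoint carrying the set of interaction kinds.
* Unknown atom names are classified "other" with a once-per-name warning.

## Preprocessing

Chains pair into complexes by length: binder candidates ≥ 40 residues,
ligand candidates ≥ 3 (configurable; no upper ligand cap at this stage —
the atlas stage applies its own 3–20 window).  A pair qualifies when at
least one ligand Cα is within 8.0 Å of a binder Cα.  Ligand chains are
trimmed at the termini only — contiguous leading/trailing residues out of
contact range are dropped, interior residues never — so ligands remain
contiguous peptides, and splitting is idempotent.  One binder chain per
complex; pockets spanning several binder chains are a known limitation.

Secondary-structure content is classified per residue from backbone
dihedrals (helix: φ∈[−100°,−30°], ψ∈[−80°,−5°]; strand: φ∈[−180°,−90°],
ψ∈[90°,180°]∪[−180°,−170°]; else coil).  This avoids an external DSSP
dependency; because hydrogen bonding is ignored, boundary residues can be
labelled differently than DSSP would label them, and chain termini (with
undefined φ or ψ) count as coil.

## Pocket mining

*Natural pockets* group all datapoints sharing one physical ligand residue.
Their binder-type **multisets are collapsed to sets** for mining (standard
a-priori semantics; a pocket with two Asp contacts supports {D} once);
duplicates re-enter at extraction, where for each itemset type the
tightest-contact datapoint (smallest internal-frame Cα distance to the
origin, ties broken by binder origin) is retained.

Support of an itemset is the fraction of natural pockets (of one ligand
type) containing it.  The **cardinality adjustment**
`support · base^(size − min_pocket_size)` (default base 1.21, min size 3)
boosts larger itemsets so that multi-residue pockets survive ranking
despite inherently lower raw support; base 1 recovers plain a-priori.
Because the adjustment is not antimonotone, level-wise pruning uses the
conservative bound `threshold / base^(max_transaction_size − min_size)`,
which preserves exactness.  The **confidence threshold** (default 0.02) is
implemented as an any-antecedent confidence: the minimum, over single-item
removals, of `support(S) / support(S∖{i})`; 0 disables it.  Results are
ranked by adjusted support (ties: larger first, then lexicographic) and
truncated to 10 pockets per ligand type.

## Clustering and representatives

Superimposed pocket members are compared with the **assignment distance**:
residues are matched one-to-one within equal binder types to minimize the
summed spatial similarity (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`); mismatched type multisets are an
error.  Cluster centroids are synthetic pose sets — per-type mean Cα plus
renormalized mean orientation unit vectors — used only for distances.
Cluster variance is the mean member-to-centroid distance.

k-means uses farthest-point seeding from a seeded RNG and Lloyd iteration
(cap 100).  The number of clusters is chosen one of two ways:

* **auto (default)** — k grows from 1 and clustering reruns at k+1 while
  any cluster's variance exceeds the threshold (default 5.0 score units),
  coupling model size to the variance bound deterministically;
* **fixed `n_clusters`** — k stays put and noise reduction activates:
  clusters over the threshold greedily shed their most distant member
  (recomputing the centroid) until compliant; removed members are recorded
  as noise.  Singleton clusters are trivially compliant.

A very large variance threshold (the reference mining run uses 9999)
effectively disables noise reduction.  Each cluster's representative
(medioid) is the member with the least assignment distance to the
centroid, first-in-order on ties.

## Grafting

Scaffold mutable residues and the pocket instance are expressed in the
frame of the selected scaffold ligand residue; the full score matrix is
computed and pairs are consumed in ascending score order (ties broken by
position index, then pocket residue id).  A pair is applied iff its score
is ≤ θd (default 12.0) and neither member is already consumed; since the
list is ascending, the first over-threshold score terminates the scan.
Mutations change the residue type and copy the pocket residue's side-chain
atoms into the scaffold frame; backbones are kept.  Grafted side-chain
atoms carry occupancy 0.00 in written PDBs to mark them un-minimized —
side-chain repacking is deliberately out of scope and expected from
external tools.

`quick_graft` builds one candidate graft per (ligand selection, pocket
cluster representative), enumerates combinations exhaustively, discards any
mutating a binder position twice, and ranks by cumulative score over
applied mutations; a graft applying zero mutations counts as +∞ so empty
grafts rank last.  Infeasibility (no conflict-free combination) raises an
error listing the contested positions.  Only cluster representatives are
used as graft sources by default; any single pocket instance can be passed
explicitly.

## Synthetic data

The generator emulates what the toolchain's contracts need from real
structures: canonical heavy-atom inventories and names, ideal backbone
geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard angles,
NeRF-built chains at requested φ/ψ), and binder residues placed at exact
contact distances (atom–atom, or minimum inter-group distance via a
convergent translation loop) with seeded orientation jitter.  Binder chains
are padded to the 40-residue minimum with a distant poly-Ala helix.

It does **not** emulate rotamer statistics, steric packing, crystallographic
noise, multi-chain pockets, or realistic amino-acid composition — side
chains are idealized extended trees.  Passing tests therefore demonstrate
the correctness of the geometry, bookkeeping and mining/grafting logic, not
the biological plausibility of mined pockets; atlases built from real PDB
collections are needed for the latter.

Default study conditions used in tests and the acceptance script: the
full-coverage collection (400 one-contact complexes, one per ligand×binder
type pair, contact distance 3.5 Å, jitter 6°) and the demo collection
(five Arg-pocket complexes with Asp 3.4 / Glu 3.8 / Trp 3.8 Å contacts and
Ser/Asn flank contacts at 3.2 Å, jitter 10°).  These sizes keep the entire
suite within seconds while still exercising every code path, including a
frequent multi-residue itemset and a non-trivial cluster.

## Numerical conventions

* Frames orthonormal to 1e-9; frame postconditions hold to 1e-6 Å after
  arbitrary rigid motions.
* Atlas/pocket JSON stores coordinates rounded to 1e-6 Å and is serialized
  with sorted keys, making artifacts byte-stable across identical runs
  (the pipeline determinism contract).
* PDB output uses fixed-format ATOM records written by the package itself,
  so a zero-mutation design reproduces its scaffold's ATOM records
  byte-identically.
* All randomness (fixture jitter, k-means seeding) flows from explicit
  integer seeds; derived sub-seeds stay below 2^31.

## Known limitations

* One binder chain per complex; no multi-chain pockets.
* No cation–π or water-mediated interaction classes.
* Ligand-type mutations in designs keep only the backbone (+Cβ); grafted
  side chains are un-minimized by design.
* The dihedral secondary-structure classifier is coarser than DSSP.
* mmCIF input, structure retrieval and fold-database searches are out of
  scope; the tool consumes user-supplied PDB files.
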