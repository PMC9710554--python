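# pocketgraft

Atlas-based analysis and editing of protein–peptide binding pockets.

Protein designers who want to change *what* a protein binds often start
from interaction motifs that nature has already optimized.  `pocketgraft`
makes those motifs searchable and reusable: it extracts every pairwise
interaction between a peptide **ligand** residue and the surrounding
**binder** residues from a collection of complex structures, organizes them
into an **atlas**, mines frequently co-occurring groups of binder residues
(**pockets**) with frequent-itemset mining, and **grafts** mined pockets
onto a new scaffold complex by mutating its best-matching binder positions.
It is aimed at structural bioinformaticians and protein engineers working
on peptide-binding interfaces (for example modular repeat-protein binders).

## The model

Every ligand residue defines an internal coordinate frame: Cα at the
origin, Cβ on the +x axis, the carbonyl C in the xy-plane, the amide N at
negative z (glycine receives an ideal virtual Cβ).  Each interacting
(ligand residue, binder residue) pair — at least one atom pair within a
class-specific radius: ionic 8.0 Å, aromatic 6.0 Å, hydrogen bond 6.0 Å,
other 4.0 Å — becomes one atlas datapoint, stored in that frame.  The atlas
partitions into ≤20 *pages* (ligand residue type) and ≤400 *maps* (ligand ×
binder type).

Two residues R1, R2 in a common frame are compared with a
distance–orientation score

```
s(R1, R2) = f_d ·‖Cα1 − Cα2‖ + f_o ·∠(Cβ1−Cα1, Cβ2−Cα2) + f_s ·∠(C1−Cα1, C2−Cα2)
```

with angles in radians and defaults f_d = 1.0 Å⁻¹, f_o = f_s = 2.0.
Lower is more similar; 0 means identical placement and orientation.

Pocket mining groups datapoints by their physical ligand residue (*natural
pockets*), reduces them to binder-type itemsets, and runs level-wise
a-priori with a cardinality-adjusted support
`support · base^(size − min_size)` (default base 1.21) so larger pockets
survive ranking.  Matching natural pockets are superimposed, clustered by a
variance-bounded k-means under the Hungarian assignment distance (summed
pairwise scores over type-respecting matchings), and each cluster elects
the member closest to its centroid (medioid) as representative.

Grafting expresses a scaffold's mutable binder residues in the frame of a
chosen scaffold ligand residue, scores them against a pocket instance, and
applies mutations greedily in ascending score order subject to the distance
threshold θd = 12.0 and one-to-one consumption of positions and pocket
residues.  `quick_graft` extends this across several ligand positions,
returning the best mutually conflict-free combinations by cumulative score.
Grafted side chains are copied un-minimized (occupancy 0.00 in output PDBs);
external side-chain repacking is recommended afterwards.

## Worked example

The synthetic generator builds fully controlled complexes, so the whole
toolchain runs without external data:

```sh
python examples/build_atlas.py
python examples/mine_pockets.py
python examples/graft_pocket.py
```

`build_atlas.py` creates five toy complexes whose Arg ligand residue is
contacted by Asp, Glu and Trp (plus flanking Ser/Asn contacts) and prints:

```
complexes: 5
datapoints: 33  pages: 2  maps: 7
top interaction partners of the Arg page:
  ASP: 5
  GLU: 5
  SER: 5
  TRP: 5
```

— twenty of the 33 pairwise interactions sit on the Arg page, five per
partner type.  `mine_pockets.py` then finds the engineered motif:

```
ARG-DESW: support 1.00 (adjusted 1.21), 5 instances, clusters [5], variance [4.14]
```

i.e. an Asp+Glu+Ser+Trp pocket present around every Arg ligand residue,
forming one cluster whose mean member-to-centroid distance is 4.14 score
units.  `graft_pocket.py` grafts its representative onto a scaffold whose
Arg sits in a non-polar first shell:

```
applied 3 mutations (total score 14.91):
  binder 1 -> ASP  score 1.72
  binder 2 -> GLU  score 5.99
  binder 3 -> TRP  score 7.20
```

Each line is a proposed mutation with its spatial-similarity score (lower =
better geometric match; all within θd = 12.0).

The same workflow is available as a CLI:

```sh
pocketgraft fixtures make --kind demo --seed 3 --out coll
pocketgraft pipeline --collection coll --out run \
    --scaffold coll/demo_00.pdb --selections "B:2=ARG" --mutable "A:1,A:2,A:3"
```

which writes `atlas.json`, `pockets.json`, design PDBs and a manifest;
re-running with the same seed reproduces byte-identical artifacts.

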