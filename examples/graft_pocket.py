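"""Graft a mined pocket onto a scaffold complex.

The scaffold is a fresh synthetic complex whose Arg ligand residue is
surrounded by non-polar binder residues; grafting the mined Asp/Glu/Trp/Ser
pocket mutates the best-matching mutable positions, copying side-chain
coordinates from the pocket instance (flagged un-minimized via occupancy
0.00 in the written PDB).
"""

from pathlib import Path

from pocketgraft import build_atlas, demo_collection
from pocketgraft.grafting import GraftingParams, graft, write_design
from pocketgraft.pockets import (ClusteringParams, MiningParams,
                                 cluster_pocket, extract_pockets, mine_atlas)
from pocketgraft.synth import ComplexSpec, ContactSpec, build_complex

# mine pockets from the demo collection
atlas = build_atlas(demo_collection(seed=3))
frequent = mine_atlas(atlas, MiningParams())["ARG"]
pocket = cluster_pocket(extract_pockets(atlas, frequent)[0],
                        ClusteringParams(seed=1))
print(f"grafting pocket {pocket.pocket_id} "
      f"({len(pocket.superimposed)} instances)")

# scaffold with an Arg ligand but a non-polar first shell
scaffold = build_complex(ComplexSpec(
    ligand_sequence=["ALA", "ARG", "ALA"],
    contacts=[ContactSpec("LEU", 1, 3.6), ContactSpec("VAL", 1, 4.2),
              ContactSpec("ALA", 1, 3.9), ContactSpec("SER", 0, 3.2),
              ContactSpec("ASN", 2, 3.2)],
    source_id="scaffold"), seed=99)

representative = pocket.member(pocket.clusters[0].representative)
design = graft(scaffold, ligand_position="2", pocket_member=representative,
               mutable_positions=["1", "2", "3"], params=GraftingParams())

print(f"applied {len(design.mutations)} mutations "
      f"(total score {design.total_score:.2f}):")
for m in design.mutations:
    print(f"  binder {m.position} -> {m.new_type}  score {m.score:.2f}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_design(design, out / "design.pdb")
print(f"wrote {out / 'design.pdb'} (+ .json metadata sidecar)")

# Scores are spatial-similarity values (lower = better geometric match);
# every applied mutation scores within the distance threshold 12.0.
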