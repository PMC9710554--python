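"""Mine frequent binding pockets from an atlas.

Natural pockets (all datapoints around one physical ligand residue) are
reduced to itemsets of binder residue types; a-priori mining finds the
frequent ones; matching natural pockets are superimposed, clustered under
the assignment distance, and each cluster elects a representative
(medioid) instance.
"""

from pocketgraft import build_atlas, demo_collection
from pocketgraft.pockets import (ClusteringParams, MiningParams,
                                 cluster_pocket, extract_pockets, mine_atlas)

atlas = build_atlas(demo_collection(seed=3))
mined = mine_atlas(atlas, MiningParams())

for ligand_type, frequent in mined.items():
    if not frequent:
        continue
    print(f"ligand {ligand_type}: {len(frequent)} frequent itemset(s)")
    for pocket in extract_pockets(atlas, frequent):
        pocket = cluster_pocket(pocket, ClusteringParams(seed=1))
        sizes = [len(c.member_ids) for c in pocket.clusters]
        print(f"  {pocket.pocket_id}: support {pocket.support:.2f} "
              f"(adjusted {pocket.adjusted_support:.2f}), "
              f"{len(pocket.superimposed)} instances, "
              f"clusters {sizes}, "
              f"variance {[round(c.variance, 2) for c in pocket.clusters]}")

# Support is the fraction of natural pockets (per ligand type) containing
# the itemset; the adjusted value boosts larger itemsets so multi-residue
# pockets survive the ranking.  Variance is the mean assignment distance of
# cluster members to the cluster centroid (score units).
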