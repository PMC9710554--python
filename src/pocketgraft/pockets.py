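"""Pocket mining: from atlas datapoints to clustered, representative pockets.

Pipeline:

1. *Itemset extraction* — datapoints sharing one physical ligand residue
   (same origin) form a **natural pocket**; its **itemset** is the set of
   binder residue types it touches.
2. *Frequent itemset mining* — level-wise a-priori over the natural
   itemsets of one ligand type.  Support of an itemset is the fraction of
   natural pockets containing it.  A cardinality adjustment
   ``support * base**(size - min_pocket_size)`` boosts larger pockets so
   they survive ranking despite inherently lower raw support; with
   ``base = 1`` plain a-priori is recovered.
3. *Pocket extraction* — every natural pocket whose type set is a superset
   of a frequent itemset joins that pocket's superimposed collection; per
   itemset type, the tightest-contact datapoint is retained.
4. *Clustering* — a k-means variant under the assignment distance (Hungarian
   matching of equal-type residues by spatial similarity).  Cluster
   variance is the mean member-to-centroid distance; clusters exceeding
   the variance threshold shed their most distant members as noise.  Each
   cluster's medioid (member closest to the centroid) is its
   representative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .atlas import Atlas, AtlasDatapoint, Origin
from .errors import AssignmentError, SchemaVersionError
from .geometry import (ResiduePose, SimilarityWeights, spatial_similarity,
                       virtual_cbeta)

log = logging.getLogger(__name__)

POCKETS_SCHEMA_VERSION = 1


@dataclass
class NaturalPocket:
    """All datapoints around one physical ligand residue."""

    ligand_type: str
    ligand_origin: Origin
    members: list[AtlasDatapoint]

    @property
    def binder_types(self) -> frozenset[str]:
        return frozenset(dp.binder_type for dp in self.members)


@dataclass(frozen=True)
class Itemset:
    ligand_type: str
    items: frozenset[str]

    def __post_init__(self):
        if not self.items:
            raise ValueError("itemset must contain at least one binder type")


@dataclass
class MiningParams:
    support_threshold: float = 0.01
    confidence_threshold: float = 0.02
    min_pocket_size: int = 3
    max_pockets_per_ligand_type: int = 10
    cardinality_base: float = 1.21

    def __post_init__(self):
        if not 0 < self.support_threshold <= 1:
            raise ValueError("support_threshold must be in (0, 1]")
        if self.confidence_threshold > 1:
            raise ValueError("confidence_threshold must be <= 1")
        if self.min_pocket_size < 1:
            raise ValueError("min_pocket_size must be >= 1")
        if self.cardinality_base < 1:
            raise ValueError("cardinality_base must be >= 1")


@dataclass
class ClusteringParams:
    """``n_clusters=None`` grows k from 1 until every cluster satisfies the
    variance threshold; a fixed ``n_clusters`` keeps k and instead removes
    out-of-threshold members as noise."""

    variance_threshold: float = 5.0
    weights: SimilarityWeights = field(default_factory=SimilarityWeights)
    max_iterations: int = 100
    seed: int = 0
    n_clusters: int | None = None

    def __post_init__(self):
        if self.variance_threshold <= 0:
            raise ValueError("variance_threshold must be positive")


@dataclass
class FrequentItemset:
    itemset: Itemset
    support: float
    adjusted_support: float


@dataclass
class PocketMember:
    """One natural pocket reduced to the itemset's types (one datapoint per
    type, all in the member's own ligand frame)."""

    natural_id: Origin
    datapoints: dict[str, AtlasDatapoint]  # binder type -> datapoint


@dataclass
class Cluster:
    member_ids: list[Origin]
    variance: float
    representative: Origin | None
    noise_ids: list[Origin] = field(default_factory=list)


@dataclass
class Pocket:
    ligand_type: str
    itemset: Itemset
    support: float
    adjusted_support: float
    superimposed: list[PocketMember]
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def pocket_id(self) -> str:
        return f"{self.ligand_type}-" + "".join(
            sorted(_one_letter(t) for t in self.itemset.items))

    def member(self, natural_id: Origin) -> PocketMember:
        for m in self.superimposed:
            if m.natural_id == natural_id:
                return m
        raise KeyError(natural_id)


def _one_letter(three: str) -> str:
    from .chem import THREE_TO_ONE
    return THREE_TO_ONE.get(three, "X")


# --- itemset extraction --------------------------------------------------

def extract_itemsets(atlas: Atlas) -> list[tuple[NaturalPocket, Itemset]]:
    """Group datapoints by ligand origin into natural pockets plus their
    itemsets (multisets collapsed to sets for mining)."""
    groups: dict[Origin, list[AtlasDatapoint]] = {}
    for dp in atlas.datapoints:
        groups.setdefault(dp.ligand_origin, []).append(dp)
    out = []
    for origin in sorted(groups):
        members = groups[origin]
        np_ = NaturalPocket(ligand_type=members[0].ligand_type,
                            ligand_origin=origin, members=members)
        out.append((np_, Itemset(np_.ligand_type, np_.binder_types)))
    return out


# --- a-priori ------------------------------------------------------------

def _apriori_levels(transactions: list[frozenset], min_count: float):
    """Level-wise frequent itemset counts with downward-closure pruning.

    Returns {itemset(frozenset): absolute count} for all itemsets with
    count >= min_count.
    """
    counts: dict[frozenset, int] = {}
    items = sorted({i for t in transactions for i in t})
    level = []
    for i in items:
        c = sum(1 for t in transactions if i in t)
        if c >= min_count:
            s = frozenset([i])
            counts[s] = c
            level.append(s)
    k = 1
    while level:
        k += 1
        seen = set(level)
        candidates = set()
        for a, b in combinations(level, 2):
            u = a | b
            if len(u) != k:
                continue
            # downward closure: every (k-1)-subset must be frequent
            if all(u - {x} in seen for x in u):
                candidates.add(u)
        nxt = []
        for cand in sorted(candidates, key=sorted):
            c = sum(1 for t in transactions if cand <= t)
            if c >= min_count:
                counts[cand] = c
                nxt.append(cand)
        level = nxt
    return counts


def mine_frequent_itemsets(itemsets: list[Itemset],
                           params: MiningParams | None = None
                           ) -> list[FrequentItemset]:
    """A-priori over the itemsets of one ligand type.

    Returns itemsets of size >= ``min_pocket_size`` whose cardinality-
    adjusted support meets the support threshold (and, when enabled, the
    any-antecedent confidence threshold), ranked by adjusted support and
    truncated to ``max_pockets_per_ligand_type``.
    """
    params = params or MiningParams()
    if not itemsets:
        return []
    lig_types = {s.ligand_type for s in itemsets}
    if len(lig_types) != 1:
        raise ValueError(f"itemsets span multiple ligand types: {lig_types}")
    lig_type = lig_types.pop()
    transactions = [s.items for s in itemsets]
    n = len(transactions)
    max_size = max((len(t) for t in transactions), default=0)
    # Safe level-wise pruning bound: the cardinality adjustment can raise a
    # superset's adjusted support by at most base**(max_size - min_size).
    boost = params.cardinality_base ** max(0, max_size - params.min_pocket_size)
    min_count = params.support_threshold / boost * n
    counts = _apriori_levels(transactions, min_count)

    def support(s: frozenset) -> float:
        if s in counts:
            return counts[s] / n
        return sum(1 for t in transactions if s <= t) / n

    out = []
    for s, c in counts.items():
        if len(s) < params.min_pocket_size:
            continue
        sup = c / n
        adj = sup * params.cardinality_base ** (len(s) - params.min_pocket_size)
        if adj < params.support_threshold:
            continue
        if params.confidence_threshold > 0 and len(s) > 1:
            conf = min(support(s) / support(s - {x}) for x in s
                       if support(s - {x}) > 0)
            if conf < params.confidence_threshold:
                continue
        out.append(FrequentItemset(Itemset(lig_type, s), sup, adj))
    out.sort(key=lambda f: (-f.adjusted_support, -len(f.itemset.items),
                            tuple(sorted(f.itemset.items))))
    return out[:params.max_pockets_per_ligand_type]


def mine_atlas(atlas: Atlas, params: MiningParams | None = None
               ) -> dict[str, list[FrequentItemset]]:
    """Frequent itemsets per ligand type over a whole atlas."""
    params = params or MiningParams()
    by_type: dict[str, list[Itemset]] = {}
    for _, itemset in extract_itemsets(atlas):
        by_type.setdefault(itemset.ligand_type, []).append(itemset)
    return {t: mine_frequent_itemsets(sets, params)
            for t, sets in sorted(by_type.items())}


# --- pocket extraction ---------------------------------------------------

def _pose_of_datapoint(dp: AtlasDatapoint) -> ResiduePose:
    atoms = dp.binder_atoms
    ca = atoms.get("CA")
    c = atoms.get("C")
    n = atoms.get("N")
    if ca is None or c is None or n is None:
        raise AssignmentError(
            f"datapoint {dp.binder_origin} lacks backbone atoms")
    cb = atoms.get("CB")
    if cb is None:
        cb = virtual_cbeta(n, ca, c)
    return ResiduePose(calpha=np.asarray(ca), cbeta=np.asarray(cb),
                       carbonyl_c=np.asarray(c), amide_n=np.asarray(n),
                       residue_type=dp.binder_type,
                       all_atoms={k: np.asarray(v) for k, v in atoms.items()})


def _tightest(datapoints: list[AtlasDatapoint]) -> AtlasDatapoint:
    """Best-scoring datapoint of one binder type: smallest internal-frame
    Cα distance to the ligand origin, ties broken by binder origin."""
    return min(datapoints,
               key=lambda dp: (float(np.linalg.norm(dp.binder_atoms["CA"]))
                               if "CA" in dp.binder_atoms else np.inf,
                               dp.binder_origin))


def extract_pockets(atlas: Atlas, frequent: list[FrequentItemset]
                    ) -> list[Pocket]:
    """Superimpose the natural pockets matching each frequent itemset.

    A natural pocket matches when its binder-type set is a superset of the
    itemset; only datapoints of itemset types are retained, one per type.
    """
    naturals = [np_ for np_, _ in extract_itemsets(atlas)]
    pockets = []
    for freq in frequent:
        items = freq.itemset.items
        members = []
        for natural in naturals:
            if natural.ligand_type != freq.itemset.ligand_type:
                continue
            if not items <= natural.binder_types:
                continue
            chosen: dict[str, AtlasDatapoint] = {}
            for btype in sorted(items):
                of_type = [dp for dp in natural.members
                           if dp.binder_type == btype]
                chosen[btype] = _tightest(of_type)
            members.append(PocketMember(natural_id=natural.ligand_origin,
                                        datapoints=chosen))
        pockets.append(Pocket(
            ligand_type=freq.itemset.ligand_type, itemset=freq.itemset,
            support=freq.support, adjusted_support=freq.adjusted_support,
            superimposed=members))
    return pockets


# --- assignment distance and clustering ----------------------------------

PoseSet = dict[str, list[ResiduePose]]  # binder type -> poses


def _member_poses(member: PocketMember) -> PoseSet:
    return {t: [_pose_of_datapoint(dp)]
            for t, dp in sorted(member.datapoints.items())}


def _poses_distance(p1: PoseSet, p2: PoseSet, w: SimilarityWeights) -> float:
    if sorted(p1) != sorted(p2) or any(len(p1[t]) != len(p2[t]) for t in p1):
        raise AssignmentError(
            f"residue type multisets differ: {sorted(p1)} vs {sorted(p2)}")
    total = 0.0
    for t in p1:
        a, b = p1[t], p2[t]
        if len(a) == 1:
            total += spatial_similarity(a[0], b[0], w)
            continue
        cost = np.array([[spatial_similarity(x, y, w) for y in b] for x in a])
        rows, cols = linear_sum_assignment(cost)
        total += float(cost[rows, cols].sum())
    return total


def assignment_distance(m1, m2, w: SimilarityWeights = SimilarityWeights()
                        ) -> float:
    """Minimal total spatial similarity over type-respecting one-to-one
    assignments (Hungarian algorithm).  Accepts PocketMembers or pose sets."""
    p1 = _member_poses(m1) if isinstance(m1, PocketMember) else m1
    p2 = _member_poses(m2) if isinstance(m2, PocketMember) else m2
    return _poses_distance(p1, p2, w)


def _mean_pose(poses: list[ResiduePose]) -> ResiduePose:
    ca = np.mean([p.calpha for p in poses], axis=0)

    def mean_dir(vectors):
        u = np.mean([v / np.linalg.norm(v) for v in vectors], axis=0)
        n = np.linalg.norm(u)
        return u / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])

    prim = mean_dir([p.primary_orientation for p in poses])
    sec = mean_dir([p.secondary_orientation for p in poses])
    return ResiduePose(calpha=ca, cbeta=ca + 1.53 * prim,
                       carbonyl_c=ca + 1.52 * sec, amide_n=None,
                       residue_type=poses[0].residue_type)


def _centroid(members: list[PoseSet]) -> PoseSet:
    """Synthetic per-type mean pose set (used only for distances)."""
    out: PoseSet = {}
    for t in members[0]:
        k = len(members[0][t])
        out[t] = [_mean_pose([m[t][i] for m in members]) for i in range(k)]
    return out


def _farthest_point_init(pose_sets, k, w, rng):
    chosen = [int(rng.integers(len(pose_sets)))]
    while len(chosen) < k:
        best, best_d = None, -1.0
        for i in range(len(pose_sets)):
            if i in chosen:
                continue
            d = min(_poses_distance(pose_sets[i], pose_sets[j], w)
                    for j in chosen)
            if d > best_d:
                best, best_d = i, d
        chosen.append(best)
    return chosen


def _kmeans(pose_sets, k, params: ClusteringParams):
    rng = np.random.default_rng(params.seed)
    w = params.weights
    init = _farthest_point_init(pose_sets, k, w, rng)
    centroids = [_centroid([pose_sets[i]]) for i in init]
    assign = [-1] * len(pose_sets)
    for _ in range(params.max_iterations):
        new_assign = []
        for ps in pose_sets:
            d = [_poses_distance(ps, c, w) for c in centroids]
            new_assign.append(int(np.argmin(d)))
        if new_assign == assign:
            break
        assign = new_assign
        for ci in range(k):
            members = [pose_sets[i] for i in range(len(pose_sets))
                       if assign[i] == ci]
            if members:
                centroids[ci] = _centroid(members)
    return assign, centroids


def _cluster_variance(indices, pose_sets, centroid, w) -> float:
    if not indices:
        return 0.0
    return float(np.mean([_poses_distance(pose_sets[i], centroid, w)
                          for i in indices]))


def cluster_pocket(pocket: Pocket, params: ClusteringParams | None = None
                   ) -> Pocket:
    """Cluster a pocket's superimposed members; fills ``pocket.clusters``.

    Conservation: every superimposed member ends up either in exactly one
    cluster or in that cluster's noise list.
    """
    params = params or ClusteringParams()
    members = pocket.superimposed
    if not members:
        pocket.clusters = []
        return pocket
    pose_sets = [_member_poses(m) for m in members]
    w = params.weights
    n = len(members)

    if params.n_clusters is not None:
        k_values = [min(params.n_clusters, n)]
    else:
        k_values = range(1, n + 1)

    assign = centroids = None
    k_used = 1
    for k in k_values:
        assign, centroids = _kmeans(pose_sets, k, params)
        k_used = k
        variances = [
            _cluster_variance([i for i in range(n) if assign[i] == ci],
                              pose_sets, centroids[ci], w)
            for ci in range(k)]
        if all(v <= params.variance_threshold for v in variances):
            break

    clusters: list[Cluster] = []
    for ci in range(k_used):
        idx = [i for i in range(n) if assign[i] == ci]
        if not idx:
            continue
        centroid = centroids[ci]
        noise: list[int] = []
        var = _cluster_variance(idx, pose_sets, centroid, w)
        # noise reduction: drop the most distant member until compliant
        while var > params.variance_threshold and len(idx) > 1:
            dists = [_poses_distance(pose_sets[i], centroid, w) for i in idx]
            worst = idx[int(np.argmax(dists))]
            idx.remove(worst)
            noise.append(worst)
            centroid = _centroid([pose_sets[i] for i in idx])
            var = _cluster_variance(idx, pose_sets, centroid, w)
        rep = select_representative([pose_sets[i] for i in idx], centroid, w)
        clusters.append(Cluster(
            member_ids=[members[i].natural_id for i in idx],
            variance=var,
            representative=members[idx[rep]].natural_id,
            noise_ids=[members[i].natural_id for i in noise]))
    pocket.clusters = clusters
    return pocket


def select_representative(member_pose_sets: list[PoseSet], centroid: PoseSet,
                          w: SimilarityWeights = SimilarityWeights()) -> int:
    """Index of the medioid: the member closest to the centroid (first wins
    ties)."""
    if not member_pose_sets:
        raise ValueError("empty cluster")
    dists = [_poses_distance(ps, centroid, w) for ps in member_pose_sets]
    return int(np.argmin(dists))


# --- serialization -------------------------------------------------------

def _dp_key(dp: AtlasDatapoint) -> list:
    return [list(dp.ligand_origin), list(dp.binder_origin)]


def pockets_to_dict(pockets: list[Pocket], atlas: Atlas) -> dict:
    index = {(dp.ligand_origin, dp.binder_origin): i
             for i, dp in enumerate(atlas.datapoints)}
    return {
        "schema": "pockets",
        "schema_version": POCKETS_SCHEMA_VERSION,
        "pockets": [
            {
                "pocket_id": p.pocket_id,
                "ligand_type": p.ligand_type,
                "itemset": sorted(p.itemset.items),
                "support": round(p.support, 9),
                "adjusted_support": round(p.adjusted_support, 9),
                "superimposed": [
                    {
                        "natural_id": list(m.natural_id),
                        "datapoints": {
                            t: index[(dp.ligand_origin, dp.binder_origin)]
                            for t, dp in sorted(m.datapoints.items())
                        },
                    }
                    for m in p.superimposed
                ],
                "clusters": [
                    {
                        "member_ids": [list(i) for i in c.member_ids],
                        "variance": round(c.variance, 9),
                        "representative": list(c.representative)
                        if c.representative else None,
                        "noise_ids": [list(i) for i in c.noise_ids],
                    }
                    for c in p.clusters
                ],
            }
            for p in pockets
        ],
    }


def save_pockets(pockets: list[Pocket], atlas: Atlas, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pockets_to_dict(pockets, atlas),
                                     indent=1, sort_keys=True) + "\n")


def pockets_from_dict(data: dict, atlas: Atlas) -> list[Pocket]:
    if data.get("schema") != "pockets":
        raise SchemaVersionError("not a pockets artifact")
    if data.get("schema_version") != POCKETS_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"pockets schema version {data.get('schema_version')!r} unsupported")
    out = []
    for p in data["pockets"]:
        members = [
            PocketMember(
                natural_id=tuple(m["natural_id"]),
                datapoints={t: atlas.datapoints[i]
                            for t, i in m["datapoints"].items()},
            )
            for m in p["superimposed"]
        ]
        clusters = [
            Cluster(member_ids=[tuple(i) for i in c["member_ids"]],
                    variance=c["variance"],
                    representative=tuple(c["representative"])
                    if c["representative"] else None,
                    noise_ids=[tuple(i) for i in c["noise_ids"]])
            for c in p["clusters"]
        ]
        out.append(Pocket(
            ligand_type=p["ligand_type"],
            itemset=Itemset(p["ligand_type"], frozenset(p["itemset"])),
            support=p["support"], adjusted_support=p["adjusted_support"],
            superimposed=members, clusters=clusters))
    return out


def load_pockets(path: str | Path, atlas: Atlas) -> list[Pocket]:
    with open(path) as fh:
        return pockets_from_dict(json.load(fh), atlas)
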