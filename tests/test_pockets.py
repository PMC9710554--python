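"""Pocket mining, clustering, assignment distance and representatives."""

from itertools import combinations, permutations

import numpy as np
import pytest

from conftest import make_datapoint, make_member
from pocketgraft.atlas import Atlas
from pocketgraft.errors import AssignmentError
from pocketgraft.geometry import SimilarityWeights
from pocketgraft.pockets import (ClusteringParams, FrequentItemset, Itemset,
                                 MiningParams, _centroid, _member_poses,
                                 assignment_distance, cluster_pocket,
                                 extract_itemsets, extract_pockets,
                                 mine_atlas, mine_frequent_itemsets,
                                 select_representative)


def brute_force_frequent(transactions, support_threshold):
    """Exhaustive subset enumeration oracle for a-priori."""
    items = sorted({i for t in transactions for i in t})
    n = len(transactions)
    out = {}
    for k in range(1, len(items) + 1):
        for comb in combinations(items, k):
            s = frozenset(comb)
            sup = sum(1 for t in transactions if s <= t) / n
            if sup >= support_threshold:
                out[s] = sup
    return out


class TestExtractItemsets:
    def test_single_ligand_multiple_partners(self):
        dps = [make_datapoint("ARG", t, ("s", "B", "1"), ("s", "A", str(i)))
               for i, t in enumerate(["ASP", "GLU", "TRP"])]
        atlas = Atlas(datapoints=dps)
        out = extract_itemsets(atlas)
        assert len(out) == 1
        natural, itemset = out[0]
        assert itemset.items == frozenset({"ASP", "GLU", "TRP"})
        assert len(natural.members) == 3

    def test_one_pocket_per_ligand_origin(self, demo_atlas):
        out = extract_itemsets(demo_atlas)
        origins = {dp.ligand_origin for dp in demo_atlas.datapoints}
        assert len(out) == len(origins)
        # group-by oracle: member counts per origin
        for natural, _ in out:
            expected = [dp for dp in demo_atlas.datapoints
                        if dp.ligand_origin == natural.ligand_origin]
            assert len(natural.members) == len(expected)


class TestMining:
    def test_worked_example(self):
        """Transactions {D,E,W},{D,E},{D,W} at support 0.5, min size 2:
        exactly {D,E} and {D,W}, each with support 2/3."""
        sets_ = [Itemset("ARG", frozenset(s))
                 for s in ({"D", "E", "W"}, {"D", "E"}, {"D", "W"})]
        params = MiningParams(support_threshold=0.5, confidence_threshold=0.0,
                              min_pocket_size=2, cardinality_base=1.0,
                              max_pockets_per_ligand_type=100)
        out = mine_frequent_itemsets(sets_, params)
        got = {f.itemset.items: f.support for f in out}
        assert got == {frozenset({"D", "E"}): pytest.approx(2 / 3),
                       frozenset({"D", "W"}): pytest.approx(2 / 3)}

    def test_single_transaction(self):
        sets_ = [Itemset("ARG", frozenset({"D", "E", "W"}))]
        out = mine_frequent_itemsets(sets_, MiningParams(
            support_threshold=1.0, confidence_threshold=0.0,
            min_pocket_size=3, cardinality_base=1.0))
        assert [f.itemset.items for f in out] == [frozenset({"D", "E", "W"})]

    def test_support_one_requires_all_transactions(self):
        sets_ = [Itemset("ARG", frozenset({"D", "E"})),
                 Itemset("ARG", frozenset({"D"}))]
        out = mine_frequent_itemsets(sets_, MiningParams(
            support_threshold=1.0, confidence_threshold=0.0,
            min_pocket_size=1, cardinality_base=1.0))
        assert {f.itemset.items for f in out} == {frozenset({"D"})}

    def test_oracle_equivalence_seeded(self):
        """A-priori with cardinality base 1 equals exhaustive subset
        enumeration, including supports, on 50 random transaction sets."""
        rng = np.random.default_rng(1234)
        items = list("ABCDEF")
        for _ in range(50):
            n = int(rng.integers(1, 13))
            transactions = [
                frozenset(rng.choice(items, size=int(rng.integers(1, 7)),
                                     replace=False))
                for _ in range(n)]
            thr = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
            params = MiningParams(support_threshold=thr,
                                  confidence_threshold=0.0,
                                  min_pocket_size=1, cardinality_base=1.0,
                                  max_pockets_per_ligand_type=10_000)
            out = mine_frequent_itemsets(
                [Itemset("X", t) for t in transactions], params)
            got = {f.itemset.items: round(f.support, 9) for f in out}
            exp = {s: round(v, 9)
                   for s, v in brute_force_frequent(transactions, thr).items()}
            assert got == exp

    def test_downward_closure(self):
        rng = np.random.default_rng(7)
        items = list("ABCDE")
        transactions = [
            frozenset(rng.choice(items, size=int(rng.integers(2, 6)),
                                 replace=False))
            for _ in range(10)]
        params = MiningParams(support_threshold=0.2, confidence_threshold=0.0,
                              min_pocket_size=2, cardinality_base=1.0,
                              max_pockets_per_ligand_type=10_000)
        out = mine_frequent_itemsets([Itemset("X", t) for t in transactions],
                                     params)
        returned = {f.itemset.items for f in out}
        n = len(transactions)
        for s in returned:
            for x in s:
                sub = s - {x}
                if len(sub) >= params.min_pocket_size:
                    sup = sum(1 for t in transactions if sub <= t) / n
                    assert sup >= params.support_threshold

    def test_cardinality_base_boosts_large_itemsets(self):
        """With base > 1 a large itemset can pass the threshold its raw
        support misses; ranking puts it above equal-support smaller sets."""
        sets_ = ([Itemset("X", frozenset({"A", "B", "C", "D"}))] * 2
                 + [Itemset("X", frozenset({"A", "E"}))] * 8)
        params = MiningParams(support_threshold=0.25,
                              confidence_threshold=0.0, min_pocket_size=2,
                              cardinality_base=1.5,
                              max_pockets_per_ligand_type=100)
        got = {f.itemset.items: f.adjusted_support
               for f in mine_frequent_itemsets(sets_, params)}
        big = frozenset({"A", "B", "C", "D"})
        assert big in got  # raw 0.2 < 0.25, adjusted 0.2*1.5^2 = 0.45
        assert got[big] == pytest.approx(0.45)
        params1 = MiningParams(support_threshold=0.25,
                               confidence_threshold=0.0,
                               min_pocket_size=2, cardinality_base=1.0,
                               max_pockets_per_ligand_type=100)
        out1 = {f.itemset.items for f in mine_frequent_itemsets(sets_, params1)}
        assert big not in out1  # plain a-priori drops it

    def test_max_pockets_cap(self):
        rng = np.random.default_rng(3)
        items = list("ABCDEF")
        transactions = [
            frozenset(rng.choice(items, size=4, replace=False))
            for _ in range(12)]
        params = MiningParams(support_threshold=0.05,
                              confidence_threshold=0.0, min_pocket_size=1,
                              cardinality_base=1.0,
                              max_pockets_per_ligand_type=5)
        out = mine_frequent_itemsets([Itemset("X", t) for t in transactions],
                                     params)
        assert len(out) == 5
        adj = [f.adjusted_support for f in out]
        assert adj == sorted(adj, reverse=True)

    def test_mixed_ligand_types_rejected(self):
        with pytest.raises(ValueError):
            mine_frequent_itemsets([Itemset("ARG", frozenset("D")),
                                    Itemset("ILE", frozenset("D"))])


class TestExtractPockets:
    def test_superset_rule_and_retention(self):
        dps = []
        # natural pocket 1: {ASP, GLU, TRP}; pocket 2: {ASP, TRP}
        for i, t in enumerate(["ASP", "GLU", "TRP"]):
            dps.append(make_datapoint("ARG", t, ("s1", "B", "1"),
                                      ("s1", "A", str(i)), ca=(3 + i, 0, 0)))
        for i, t in enumerate(["ASP", "TRP"]):
            dps.append(make_datapoint("ARG", t, ("s2", "B", "1"),
                                      ("s2", "A", str(i)), ca=(3 + i, 1, 0)))
        atlas = Atlas(datapoints=dps)
        freq = [FrequentItemset(Itemset("ARG", frozenset({"ASP", "GLU"})),
                                0.5, 0.5)]
        pockets = extract_pockets(atlas, freq)
        assert len(pockets) == 1
        members = pockets[0].superimposed
        assert [m.natural_id for m in members] == [("s1", "B", "1")]
        assert len(members[0].datapoints) == 2  # exactly |itemset|

    def test_duplicate_type_keeps_tightest(self):
        """Two Asp contacts in one natural pocket: the closer one is kept."""
        dps = [make_datapoint("ARG", "ASP", ("s", "B", "1"), ("s", "A", "1"),
                              ca=(5.0, 0, 0)),
               make_datapoint("ARG", "ASP", ("s", "B", "1"), ("s", "A", "2"),
                              ca=(3.0, 0, 0))]
        atlas = Atlas(datapoints=dps)
        freq = [FrequentItemset(Itemset("ARG", frozenset({"ASP"})), 1.0, 1.0)]
        member = extract_pockets(atlas, freq)[0].superimposed[0]
        assert member.datapoints["ASP"].binder_origin == ("s", "A", "2")

    def test_pocket_subset_of_atlas(self, demo_atlas):
        """Every retained datapoint exists verbatim in the source atlas."""
        mined = mine_atlas(demo_atlas, MiningParams())
        ids = {id(dp) for dp in demo_atlas.datapoints}
        for lig_type, freq in mined.items():
            for pocket in extract_pockets(demo_atlas, freq):
                for member in pocket.superimposed:
                    assert len(member.datapoints) == len(pocket.itemset.items)
                    for dp in member.datapoints.values():
                        assert id(dp) in ids


class TestAssignmentDistance:
    def test_identity_zero(self):
        m = make_member(("s", "B", "1"), {
            "ASP": ((3, 0, 0), (1, 0, 0), (0, 1, 0)),
            "GLU": ((0, 4, 0), (0, 1, 0), (1, 0, 0))})
        assert assignment_distance(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_cross_pairing_cheaper(self):
        """2x2 case where swapping beats the identity assignment."""
        m1 = make_member(("a", "B", "1"), {
            "ASP": ((0, 0, 0), (1, 0, 0), (0, 1, 0)),
        })
        # two ASP residues per member: build pose sets directly
        w = SimilarityWeights()
        p1 = {"ASP": [_member_poses(make_member(("a", "B", "1"), {
            "ASP": ((0, 0, 0), (1, 0, 0), (0, 1, 0))}))["ASP"][0],
            _member_poses(make_member(("a", "B", "2"), {
                "ASP": ((10, 0, 0), (1, 0, 0), (0, 1, 0))}))["ASP"][0]]}
        p2 = {"ASP": [_member_poses(make_member(("b", "B", "1"), {
            "ASP": ((10, 0, 0), (1, 0, 0), (0, 1, 0))}))["ASP"][0],
            _member_poses(make_member(("b", "B", "2"), {
                "ASP": ((0, 0, 0), (1, 0, 0), (0, 1, 0))}))["ASP"][0]]}
        # identity pairing costs 20 (two 10 Å moves), cross pairing 0
        assert assignment_distance(p1, p2, w) == pytest.approx(0.0, abs=1e-9)

    def test_matches_factorial_enumeration(self, rng):
        """Hungarian result equals the exhaustive minimum over all
        type-respecting permutations for up to 4 residues."""
        w = SimilarityWeights()
        from pocketgraft.geometry import ResiduePose, spatial_similarity

        def random_pose():
            ca = rng.uniform(-6, 6, 3)
            prim = rng.normal(size=3)
            sec = rng.normal(size=3)
            return ResiduePose(calpha=ca, cbeta=ca + prim, carbonyl_c=ca + sec,
                               amide_n=None)

        for _ in range(100):
            n_types = int(rng.integers(1, 3))
            sizes = [int(rng.integers(1, 5 - n_types)) for _ in range(n_types)]
            types = [f"T{i}" for i in range(n_types)]
            p1 = {t: [random_pose() for _ in range(k)]
                  for t, k in zip(types, sizes)}
            p2 = {t: [random_pose() for _ in range(k)]
                  for t, k in zip(types, sizes)}
            got = assignment_distance(p1, p2, w)
            best = 0.0
            for t in types:
                costs = [[spatial_similarity(a, b, w) for b in p2[t]]
                         for a in p1[t]]
                best += min(sum(costs[i][pi] for i, pi in enumerate(perm))
                            for perm in permutations(range(len(p1[t]))))
            assert got == pytest.approx(best, abs=1e-9)
            assert got <= best + 1e-9  # valid assignment cost bound

    def test_type_mismatch_raises(self):
        m1 = make_member(("a", "B", "1"),
                         {"ASP": ((0, 0, 0), (1, 0, 0), (0, 1, 0))})
        m2 = make_member(("b", "B", "1"),
                         {"GLU": ((0, 0, 0), (1, 0, 0), (0, 1, 0))})
        with pytest.raises(AssignmentError):
            assignment_distance(m1, m2)


def _pocket_with_members(members):
    from pocketgraft.pockets import Pocket
    types = sorted(members[0].datapoints)
    return Pocket(ligand_type="ARG",
                  itemset=Itemset("ARG", frozenset(types)),
                  support=1.0, adjusted_support=1.0, superimposed=members)


def _member_at(tag, shift, jitter=0.0, rng=None):
    base = {
        "ASP": ((3.0, 0.0, 0.0), (1, 0, 0), (0, 1, 0)),
        "GLU": ((0.0, 4.0, 0.0), (0, 1, 0), (1, 0, 0)),
    }
    poses = {}
    for t, (ca, prim, sec) in base.items():
        ca = np.asarray(ca, float) + np.asarray(shift, float)
        if jitter and rng is not None:
            ca = ca + rng.normal(scale=jitter, size=3)
        poses[t] = (tuple(ca), prim, sec)
    return make_member(("src", "B", tag), poses)


class TestClustering:
    def test_identical_members_single_cluster(self):
        members = [_member_at(str(i), (0, 0, 0)) for i in range(4)]
        pocket = cluster_pocket(_pocket_with_members(members),
                                ClusteringParams(seed=0))
        assert len(pocket.clusters) == 1
        c = pocket.clusters[0]
        assert c.variance == pytest.approx(0.0, abs=1e-9)
        assert c.noise_ids == [] and len(c.member_ids) == 4

    def test_two_groups_recovered(self, rng):
        """Two tight groups far apart at k=2 coincide with the optimal
        exhaustive 2-partition."""
        members = ([_member_at(f"a{i}", (0, 0, 0), 0.1, rng)
                    for i in range(3)]
                   + [_member_at(f"b{i}", (40, 0, 0), 0.1, rng)
                      for i in range(3)])
        pocket = cluster_pocket(_pocket_with_members(members),
                                ClusteringParams(seed=0, n_clusters=2))
        got = sorted(tuple(sorted(i[2] for i in c.member_ids))
                     for c in pocket.clusters)
        # exhaustive 2-partition oracle: minimize within-cluster variance sum
        pose_sets = [_member_poses(m) for m in members]
        w = SimilarityWeights()
        from pocketgraft.pockets import _cluster_variance
        best, best_split = None, None
        n = len(members)
        for mask in range(1, 2 ** (n - 1)):
            g1 = [i for i in range(n) if mask & (1 << i)]
            g2 = [i for i in range(n) if not mask & (1 << i)]
            if not g1 or not g2:
                continue
            tot = sum(
                _cluster_variance(g, pose_sets,
                                  _centroid([pose_sets[i] for i in g]), w)
                for g in (g1, g2))
            if best is None or tot < best:
                best, best_split = tot, (g1, g2)
        expected = sorted(tuple(sorted(members[i].natural_id[2] for i in g))
                          for g in best_split)
        assert got == expected

    def test_outlier_removed_as_noise(self):
        """With a fixed single cluster, the far outlier is shed until the
        variance threshold is met."""
        members = [_member_at(str(i), (0, 0, 0)) for i in range(5)]
        members.append(_member_at("out", (60, 0, 0)))
        pocket = cluster_pocket(
            _pocket_with_members(members),
            ClusteringParams(seed=0, n_clusters=1, variance_threshold=5.0))
        assert len(pocket.clusters) == 1
        c = pocket.clusters[0]
        assert ("src", "B", "out") in c.noise_ids
        assert c.variance <= 5.0

    def test_conservation_and_variance_bound(self, rng):
        members = [_member_at(str(i), (0, 0, 0), 2.0, rng)
                   for i in range(8)]
        params = ClusteringParams(seed=1, variance_threshold=5.0)
        pocket = cluster_pocket(_pocket_with_members(members), params)
        seen = []
        for c in pocket.clusters:
            assert c.variance <= params.variance_threshold + 1e-9
            seen.extend(c.member_ids)
            seen.extend(c.noise_ids)
        assert sorted(seen) == sorted(m.natural_id for m in members)

    def test_deterministic_under_seed(self, rng):
        members = [_member_at(str(i), (0, 0, 0), 3.0, rng) for i in range(6)]
        p1 = cluster_pocket(_pocket_with_members(members),
                            ClusteringParams(seed=5))
        p2 = cluster_pocket(_pocket_with_members(members),
                            ClusteringParams(seed=5))
        assert [(c.member_ids, c.representative) for c in p1.clusters] == \
            [(c.member_ids, c.representative) for c in p2.clusters]

    def test_empty_pocket(self):
        pocket = cluster_pocket(_pocket_with_members(
            [_member_at("0", (0, 0, 0))]), ClusteringParams())
        assert len(pocket.clusters) == 1


class TestRepresentative:
    def test_singleton(self):
        m = _member_at("0", (0, 0, 0))
        ps = [_member_poses(m)]
        assert select_representative(ps, _centroid(ps)) == 0

    def test_member_at_centroid_wins(self):
        ms = [_member_at("0", (0, 0, 0)), _member_at("1", (6, 0, 0)),
              _member_at("2", (-6, 0, 0))]
        ps = [_member_poses(m) for m in ms]
        centroid = _centroid(ps)
        assert select_representative(ps, centroid) == 0

    def test_matches_exhaustive_argmin(self, rng):
        from pocketgraft.pockets import _poses_distance
        w = SimilarityWeights()
        for _ in range(20):
            ms = [_member_at(str(i), rng.uniform(-5, 5, 3), 1.0, rng)
                  for i in range(5)]
            ps = [_member_poses(m) for m in ms]
            centroid = _centroid(ps)
            got = select_representative(ps, centroid, w)
            dists = [_poses_distance(p, centroid, w) for p in ps]
            assert got == int(np.argmin(dists))
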