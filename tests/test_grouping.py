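import itertools

import numpy as np
import pytest

from dicore.collaboration import CollaborationMatrix
from dicore.exceptions import MembershipError, ParameterError
from dicore.grouping import (
    Group,
    GroupingParams,
    _merge_to_fixpoint,
    cohesiveness,
    discover_groups,
    grow_group,
    groups_to_gmt,
    overlap_score,
)


def random_collab(rng, n, density=0.4, scale=1.0):
    S = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < density) * scale
    S = np.triu(S, 1)
    S = S + S.T
    return CollaborationMatrix([f"v{i:02d}" for i in range(n)], S)


def pair_sum_oracle(members, M, alpha):
    """Direct unordered-pair summation of Eq-style cohesiveness."""
    members = set(members)
    w_int = sum(
        M.scores[M.index_of(a), M.index_of(b)]
        for a, b in itertools.combinations(sorted(members), 2)
    )
    w_ext = sum(
        M.scores[M.index_of(a), M.index_of(b)]
        for a in members for b in M.ids if b not in members
    )
    denom = w_int + w_ext + alpha * len(members)
    return w_int / denom if denom > 0 else 0.0


def naive_grow(seed, M, alpha):
    """Brute-force greedy grower recomputing cohesiveness from scratch.

    Same move rule and tie-breaks as the production path: single best
    strictly-improving addition or removal, additions first, then smallest
    ID; the seed is never removable.
    """
    members = {seed}
    while True:
        cur = cohesiveness(members, M, alpha)
        candidates = []
        for v in M.ids:
            if v in members:
                continue
            conn = sum(M.scores[M.index_of(v), M.index_of(u)] for u in members)
            if conn <= 0:
                continue
            candidates.append((cohesiveness(members | {v}, M, alpha), 0, v))
        if len(members) > 1:
            for u in members - {seed}:
                candidates.append((cohesiveness(members - {u}, M, alpha), 1, u))
        if not candidates:
            return members
        cs, kind, v = min(candidates, key=lambda t: (-t[0], t[1], t[2]))
        if cs <= cur:
            return members
        members = members | {v} if kind == 0 else members - {v}


class TestCohesiveness:
    def test_direct_substitution_example(self):
        # C = {a, b}: s_ab = 2, external sum = 1, alpha = 2 -> 2 / (2+1+4)
        S = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        M = CollaborationMatrix(["a", "b", "c"], S)
        assert cohesiveness({"a", "b"}, M, alpha=2.0) == pytest.approx(2 / 7)

    def test_isolated_clique_alpha_zero_scores_one(self):
        S = np.ones((4, 4)) - np.eye(4)
        M = CollaborationMatrix(list("abcd"), S)
        assert cohesiveness(set("abcd"), M, alpha=0.0) == 1.0

    def test_singleton_no_edges_positive_alpha_scores_zero(self):
        M = CollaborationMatrix(["a", "b"], np.zeros((2, 2)))
        assert cohesiveness({"a"}, M, alpha=2.0) == 0.0

    def test_unknown_member_rejected(self):
        M = CollaborationMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(MembershipError):
            cohesiveness({"zzz"}, M, alpha=1.0)

    def test_matches_pair_summation_oracle_on_random_subsets(self, rng):
        M = random_collab(rng, 12)
        for _ in range(50):
            k = int(rng.integers(1, 10))
            members = set(rng.choice(M.ids, size=k, replace=False))
            alpha = float(rng.uniform(0, 3))
            assert cohesiveness(members, M, alpha) == pytest.approx(
                pair_sum_oracle(members, M, alpha), abs=1e-12
            )


class TestGrowGroup:
    def test_two_disjoint_cliques_recovers_seed_clique(self):
        ids = ["c0", "c1", "c2", "d0", "d1", "d2"]
        S = np.zeros((6, 6))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        np.fill_diagonal(S, 0.0)
        M = CollaborationMatrix(ids, S)
        g = grow_group("c0", M, GroupingParams(alpha=0.0, min_size=1))
        assert g.member_ids == frozenset({"c0", "c1", "c2"})
        assert g.cohesiveness == 1.0

    def test_star_graph_matches_brute_force(self):
        ids = ["hub"] + [f"leaf{i}" for i in range(5)]
        S = np.zeros((6, 6))
        S[0, 1:] = S[1:, 0] = 1.0
        M = CollaborationMatrix(ids, S)
        for alpha in (0.0, 0.5, 2.0):
            g = grow_group("hub", M, GroupingParams(alpha=alpha, min_size=1))
            assert g.member_ids == frozenset(naive_grow("hub", M, alpha))

    def test_isolated_seed_stays_singleton(self):
        M = CollaborationMatrix(["a", "b"], np.zeros((2, 2)))
        g = grow_group("a", M, GroupingParams(alpha=1.0, min_size=1))
        assert g.member_ids == frozenset({"a"})

    def test_matches_brute_force_on_random_graphs(self, rng):
        """Incremental bookkeeping agrees with from-scratch greedy growth."""
        for trial in range(10):
            M = random_collab(rng, 9, density=0.5)
            alpha = float(rng.uniform(0, 2))
            seed = str(rng.choice(M.ids))
            g = grow_group(seed, M, GroupingParams(alpha=alpha, min_size=1))
            assert g.member_ids == frozenset(naive_grow(seed, M, alpha))

    def test_never_below_seed_cohesiveness(self, rng):
        M = random_collab(rng, 10)
        for seed in M.ids:
            g = grow_group(seed, M, GroupingParams(alpha=1.0, min_size=1))
            assert g.cohesiveness >= cohesiveness({seed}, M, 1.0) - 1e-15


class TestOverlapAndMerge:
    def test_overlap_score_formula(self):
        a = frozenset(f"x{i}" for i in range(10))
        b = frozenset(list(a)[:9] + ["y"])
        assert overlap_score(a, b) == pytest.approx(81 / 100)

    def test_merge_at_threshold(self):
        ids = [f"x{i}" for i in range(10)] + ["y"]
        M = CollaborationMatrix(ids, np.zeros((11, 11)))
        a = Group(frozenset(ids[:10]), 0.0, "mirna")
        b = Group(frozenset(ids[1:11]), 0.0, "mirna")
        merged = _merge_to_fixpoint([a, b], M, GroupingParams(alpha=1.0,
                                                             min_size=1,
                                                             merge_overlap=0.8),
                                    "mirna")
        assert len(merged) == 1
        assert merged[0].member_ids == frozenset(ids)

    def test_no_merge_below_threshold(self):
        ids = [f"x{i}" for i in range(6)]
        M = CollaborationMatrix(ids, np.zeros((6, 6)))
        a = Group(frozenset(ids[:3]), 0.0, "mirna")
        b = Group(frozenset(ids[3:]), 0.0, "mirna")
        merged = _merge_to_fixpoint([a, b], M, GroupingParams(alpha=1.0,
                                                             min_size=1), "mirna")
        assert len(merged) == 2


class TestDiscoverGroups:
    def test_planted_two_blocks_recovered(self, two_blocks):
        groups = discover_groups(two_blocks,
                                 GroupingParams(alpha=0.0, min_size=3))
        assert {g.member_ids for g in groups} == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_undersized_block_filtered(self):
        ids = ["a0", "a1", "b0", "b1", "b2"]
        S = np.zeros((5, 5))
        S[0, 1] = S[1, 0] = 1.0
        S[2:, 2:] = 1.0
        np.fill_diagonal(S, 0.0)
        M = CollaborationMatrix(ids, S)
        groups = discover_groups(M, GroupingParams(alpha=0.0, min_size=3))
        assert {g.member_ids for g in groups} == {frozenset({"b0", "b1", "b2"})}

    def test_k_cliques_found_exactly(self, rng):
        """Disjoint equal cliques, alpha=0: output equals connected components."""
        K, size = 4, 3
        n = K * size
        S = np.zeros((n, n))
        for k in range(K):
            S[k * size:(k + 1) * size, k * size:(k + 1) * size] = 1.0
        np.fill_diagonal(S, 0.0)
        M = CollaborationMatrix([f"v{i:02d}" for i in range(n)], S)
        groups = discover_groups(M, GroupingParams(alpha=0.0, min_size=size))
        expected = {
            frozenset(f"v{i:02d}" for i in range(k * size, (k + 1) * size))
            for k in range(K)
        }
        assert {g.member_ids for g in groups} == expected

    def test_stored_cohesiveness_equals_recomputed(self, rng):
        M = random_collab(rng, 15, density=0.5)
        params = GroupingParams(alpha=1.0, min_size=2)
        for g in discover_groups(M, params):
            assert g.cohesiveness == pytest.approx(
                cohesiveness(g.member_ids, M, params.alpha), abs=1e-12
            )

    def test_size_filter_compliance_and_determinism(self, rng):
        M = random_collab(rng, 20, density=0.4)
        params = GroupingParams(alpha=0.5, min_size=2, max_size=6)
        g1 = discover_groups(M, params)
        g2 = discover_groups(M, params)
        assert [(g.member_ids, g.cohesiveness) for g in g1] == \
               [(g.member_ids, g.cohesiveness) for g in g2]
        for g in g1:
            assert 2 <= len(g) <= 6

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GroupingParams(alpha=-1.0)
        with pytest.raises(ParameterError):
            GroupingParams(min_size=5, max_size=3)


def test_gmt_serialization(two_blocks):
    groups = discover_groups(two_blocks, GroupingParams(alpha=0.0, min_size=3))
    gmt = groups_to_gmt(groups, prefix="m")
    lines = gmt.strip().split("\n")
    assert len(lines) == 2
    fields = lines[0].split("\t")
    assert fields[0] == "m1" and float(fields[1]) == 1.0
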