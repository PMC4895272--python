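"""Greedy overlapping clustering of features by cohesiveness.

Groups are grown by neighborhood expansion in the collaboration graph,
maximizing the cohesiveness objective

    cs(C) = w_int(C) / (w_int(C) + w_ext(C) + alpha * |C|)

where w_int sums collaboration scores over internal (both endpoints in C)
unordered pairs, w_ext over boundary pairs (exactly one endpoint in C), and
the alpha * |C| penalty posits that every member has alpha additional
interactions missed by the experiment. The procedure adapts the greedy
overlapping neighborhood-expansion strategy of ClusterONE (protein-complex
detection) to collaboration graphs: seeds are taken in descending
total-collaboration order among vertices not yet covered by a grown group;
each seed is expanded by the single addition or removal (the seed itself is
never removable) that most increases cohesiveness, until a local maximum;
size-filtered groups with pairwise overlap score |A∩B|^2/(|A||B|) at or
above the merge threshold are merged to a fixpoint.

All tie-breaks are fixed and documented (additions before removals, then
lexicographically smallest ID), so the module is fully deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .collaboration import CollaborationMatrix, total_collaboration_ranking
from .exceptions import MembershipError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GroupingParams:
    """Clustering parameters.

    alpha : penalty per member in the cohesiveness denominator (default 2).
    min_size / max_size : group size bounds (miRNA default 3/unbounded,
        mRNA default 5/500).
    merge_overlap : overlap-score threshold omega for merging redundant
        groups (default 0.8, adopted from ClusterONE).
    min_density : optional floor on w_int / (|C| choose 2); None disables.
    """

    alpha: float = 2.0
    min_size: int = 3
    max_size: int | float = math.inf
    merge_overlap: float = 0.8
    min_density: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.min_size < 1:
            raise ParameterError("min_size must be a positive integer")
        if self.max_size < self.min_size:
            raise ParameterError("min_size must not exceed max_size")
        if not 0.0 < self.merge_overlap <= 1.0:
            raise ParameterError("merge_overlap must lie in (0, 1]")

    @classmethod
    def for_mirnas(cls, **kw) -> "GroupingParams":
        kw.setdefault("min_size", 3)
        kw.setdefault("max_size", math.inf)
        return cls(**kw)

    @classmethod
    def for_mrnas(cls, **kw) -> "GroupingParams":
        kw.setdefault("min_size", 5)
        kw.setdefault("max_size", 500)
        return cls(**kw)


@dataclass
class Group:
    """A set of same-side features with its cohesiveness score."""

    member_ids: frozenset[str]
    cohesiveness: float
    side: str = "mirna"

    def __post_init__(self) -> None:
        self.member_ids = frozenset(self.member_ids)
        if not self.member_ids:
            raise ParameterError("a group must have at least one member")

    def __len__(self) -> int:
        return len(self.member_ids)

    def sorted_members(self) -> list[str]:
        return sorted(self.member_ids)


def cohesiveness(C: Iterable[str], M: CollaborationMatrix, alpha: float) -> float:
    """Cohesiveness of member set C under collaboration matrix M.

    Returns 0 when the denominator is 0 (possible only at alpha = 0 for a
    fully isolated set).
    """
    members = set(C)
    if not members:
        raise ParameterError("cohesiveness of an empty set is undefined")
    unknown = members - set(M.ids)
    if unknown:
        raise MembershipError(f"members not in collaboration matrix: {sorted(unknown)}")
    idx = np.array([M.index_of(m) for m in sorted(members)], dtype=int)
    mask = np.zeros(M.n, dtype=bool)
    mask[idx] = True
    sub = M.scores[np.ix_(idx, idx)]
    w_int = sub.sum() / 2.0
    w_ext = M.scores[np.ix_(idx, ~mask)].sum()
    denom = w_int + w_ext + alpha * len(members)
    return float(w_int / denom) if denom > 0 else 0.0


def overlap_score(a: frozenset[str], b: frozenset[str]) -> float:
    """omega(A, B) = |A ∩ B|^2 / (|A| * |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


class _GrowState:
    """Incremental cohesiveness bookkeeping for one growing group.

    Maintains conn[v] = sum of collaboration scores between v and current
    members, plus w_int; w_ext follows as conn.sum() over non-members,
    which equals total member connectivity minus twice w_int.
    """

    def __init__(self, M: CollaborationMatrix, seed_idx: int, alpha: float):
        self.M = M
        self.S = M.scores
        self.alpha = alpha
        self.n = M.n
        self.in_group = np.zeros(self.n, dtype=bool)
        self.conn = self.S[seed_idx].copy()
        self.in_group[seed_idx] = True
        self.w_int = 0.0
        self.seed_idx = seed_idx

    @property
    def size(self) -> int:
        return int(self.in_group.sum())

    def w_ext(self) -> float:
        return float(self.conn[~self.in_group].sum())

    def cohesiveness(self) -> float:
        denom = self.w_int + self.w_ext() + self.alpha * self.size
        return self.w_int / denom if denom > 0 else 0.0

    def candidate_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Cohesiveness after each possible single addition / removal.

        Returns (add_cs, rem_cs), both length-n arrays with -inf at
        inadmissible positions (non-adjacent externals, the seed, vertices
        on the wrong side of the membership boundary).
        """
        w_ext = self.w_ext()
        size = self.size
        add_cs = np.full(self.n, -np.inf)
        ext = ~self.in_group
        adj = ext & (self.conn > 0)
        if adj.any():
            c = self.conn[adj]
            deg = self.S[adj].sum(axis=1)
            w_int_new = self.w_int + c
            w_ext_new = w_ext - c + (deg - c)
            denom = w_int_new + w_ext_new + self.alpha * (size + 1)
            add_cs[adj] = np.where(denom > 0, w_int_new / denom, 0.0)

        rem_cs = np.full(self.n, -np.inf)
        mem = self.in_group.copy()
        mem[self.seed_idx] = False
        if size > 1 and mem.any():
            c = self.conn[mem]
            deg = self.S[mem].sum(axis=1)
            w_int_new = self.w_int - c
            w_ext_new = w_ext - (deg - c) + c
            denom = w_int_new + w_ext_new + self.alpha * (size - 1)
            rem_cs[mem] = np.where(denom > 0, w_int_new / denom, 0.0)
        return add_cs, rem_cs

    def add(self, v: int) -> None:
        self.w_int += self.conn[v]
        self.in_group[v] = True
        self.conn += self.S[v]

    def remove(self, v: int) -> None:
        self.conn -= self.S[v]
        self.in_group[v] = False
        self.w_int -= self.conn[v]

    def members(self) -> frozenset[str]:
        return frozenset(self.M.ids[i] for i in np.flatnonzero(self.in_group))


def grow_group(seed: str, M: CollaborationMatrix, params: GroupingParams,
               side: str = "mirna") -> Group:
    """Grow a cohesive group from a seed vertex to a cohesiveness local maximum.

    Each step applies the single admissible move (add an adjacent external
    vertex, or remove a non-seed member) with the largest strict increase in
    cohesiveness. On ties, additions beat removals and the lexicographically
    smallest ID wins. The stored cohesiveness is recomputed from scratch at
    the end, never carried over from incremental state.
    """
    if seed not in M.ids:
        raise MembershipError(f"seed {seed!r} not in collaboration matrix")
    state = _GrowState(M, M.index_of(seed), params.alpha)
    ids = np.array(M.ids)
    while True:
        current = state.cohesiveness()
        add_cs, rem_cs = state.candidate_scores()
        best_add = float(add_cs.max()) if add_cs.size else -np.inf
        best_rem = float(rem_cs.max()) if rem_cs.size else -np.inf
        best = max(best_add, best_rem)
        if best <= current:
            break
        if best_add >= best_rem:        # additions preferred on ties
            cand = np.flatnonzero(add_cs == best_add)
            v = cand[np.argsort(ids[cand])[0]]
            state.add(int(v))
        else:
            cand = np.flatnonzero(rem_cs == best_rem)
            v = cand[np.argsort(ids[cand])[0]]
            state.remove(int(v))
    members = state.members()
    return Group(member_ids=members,
                 cohesiveness=cohesiveness(members, M, params.alpha),
                 side=side)


def _density(g: Group, M: CollaborationMatrix) -> float:
    if len(g) < 2:
        return 0.0
    idx = [M.index_of(m) for m in g.sorted_members()]
    w_int = M.scores[np.ix_(idx, idx)].sum() / 2.0
    return 2.0 * w_int / (len(g) * (len(g) - 1))


def _merge_to_fixpoint(groups: list[Group], M: CollaborationMatrix,
                       params: GroupingParams, side: str) -> list[Group]:
    groups = list(groups)
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if overlap_score(groups[i].member_ids, groups[j].member_ids) \
                        >= params.merge_overlap:
                    union = groups[i].member_ids | groups[j].member_ids
                    g = Group(union, cohesiveness(union, M, params.alpha), side)
                    groups = [g] + [x for k, x in enumerate(groups) if k not in (i, j)]
                    merged = True
                    break
            if merged:
                break
    return groups


def discover_groups(M: CollaborationMatrix, params: GroupingParams,
                    side: str = "mirna") -> list[Group]:
    """Discover cohesive overlapping groups from a collaboration matrix.

    Seeds are all vertices, taken in descending total-collaboration order,
    skipping vertices already covered by a previously grown group (covered
    status accrues even when the grown group later fails a size filter).
    Grown groups failing min/max size are discarded; redundant groups
    (overlap score >= merge_overlap) are merged until no pair qualifies;
    merging can only grow a group, so only max_size is re-checked after it.
    Output is sorted by cohesiveness descending, ties by lexicographically
    smallest member.
    """
    covered: set[str] = set()
    grown: list[Group] = []
    for seed, _total in total_collaboration_ranking(M):
        if seed in covered:
            continue
        g = grow_group(seed, M, params, side)
        covered |= g.member_ids
        grown.append(g)

    kept = [g for g in grown if params.min_size <= len(g) <= params.max_size]
    if params.min_density is not None:
        kept = [g for g in kept if _density(g, M) >= params.min_density]
    merged = _merge_to_fixpoint(kept, M, params, side)
    final = []
    for g in merged:
        if len(g) > params.max_size:
            logger.info("discarding merged %s group of size %d > max_size %s",
                        side, len(g), params.max_size)
            continue
        final.append(g)
    final.sort(key=lambda g: (-g.cohesiveness, min(g.member_ids)))
    return final


def groups_to_json(groups: list[Group]) -> list[dict]:
    return [
        {"side": g.side, "members": g.sorted_members(), "cohesiveness": g.cohesiveness}
        for g in groups
    ]


def groups_to_gmt(groups: list[Group], prefix: str = "group") -> str:
    """GMT-style serialization: group_id, cohesiveness, tab-separated members."""
    lines = []
    for i, g in enumerate(groups, start=1):
        fields = [f"{prefix}{i}", f"{g.cohesiveness:.6f}", *g.sorted_members()]
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")
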