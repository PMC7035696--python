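"""Maximal biclique enumeration by depth-first branch and bound.

Two variants of the same search are provided.  The basic algorithm
(MBEA) grows a biclique one right vertex at a time: the recursion frame
carries the common left neighbourhood ``L`` of the current right set
``R``, the ordered candidate right vertices ``P`` that can still extend
``R``, and the right vertices ``Q`` already processed at ancestor
branches.  Branching on a candidate ``x`` shrinks ``L`` to
``L' = L ∩ N(x)``; a scan of ``Q`` detects non-maximal branches (some
earlier vertex is adjacent to all of ``L'``) and prunes them, a scan of
``P`` absorbs every candidate adjacent to all of ``L'`` directly into
``R'`` (the closure step) and keeps the rest as ``P'``.

The improved variant (iMBEA) adds the two classic refinements: the
candidate list is kept sorted by non-decreasing common-neighbourhood
size so that tight, early-terminating branches are explored first, and
an absorbed candidate whose whole neighbourhood lies inside ``L'``
is retired (moved to ``Q``) after the branch — every maximal biclique
containing it has already been emitted, so its own subtree is skipped.

Vertex sets on the left side are integer bitmasks, which makes each
neighbourhood intersection a single bignum AND; the recursion is run on
an explicit stack so graphs with tens of thousands of right vertices
cannot overflow the interpreter call stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from .errors import ValidationError
from .graph import BipartiteGraph, mask_to_indices

__all__ = [
    "Algorithm",
    "EnumerationParams",
    "Biclique",
    "BicliqueCollection",
    "enumerate_maximal_bicliques",
    "iter_maximal_bicliques",
    "search_masks",
    "is_biclique",
    "is_maximal_biclique",
]


class Algorithm(str, Enum):
    """Which search variant to run."""

    MBEA = "mbea"
    IMBEA = "imbea"


@dataclass(frozen=True)
class EnumerationParams:
    """Reporting thresholds and algorithm choice.

    ``left_least`` / ``right_least`` are the minimum number of vertices a
    maximal biclique must have on each side to be *reported*; they never
    alter the search itself, so a small biclique nested inside a reported
    one is not reported unless it is maximal in its own right.  Defaults
    report every maximal biclique with at least one edge, via iMBEA.
    """

    left_least: int = 1
    right_least: int = 1
    algorithm: Algorithm = Algorithm.IMBEA

    def __post_init__(self) -> None:
        if self.left_least < 1 or self.right_least < 1:
            raise ValidationError("size thresholds must be >= 1")
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))


@dataclass(frozen=True)
class Biclique:
    """A complete bipartite subgraph K_{p,q}, both sides non-empty.

    ``left`` and ``right`` hold 0-based vertex indices into the host
    graph's label sequences; ``p = |left|``, ``q = |right|``.
    """

    left: frozenset[int]
    right: frozenset[int]

    @property
    def p(self) -> int:
        return len(self.left)

    @property
    def q(self) -> int:
        return len(self.right)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.p, self.q)

    @property
    def n_vertices(self) -> int:
        return self.p + self.q

    @property
    def n_edges(self) -> int:
        return self.p * self.q


@dataclass(frozen=True)
class BicliqueCollection:
    """The ordered result of one enumeration run over one host graph."""

    bicliques: tuple[Biclique, ...]
    graph: BipartiteGraph
    params: EnumerationParams = field(default_factory=EnumerationParams)

    def __len__(self) -> int:
        return len(self.bicliques)

    def __iter__(self) -> Iterator[Biclique]:
        return iter(self.bicliques)

    def __getitem__(self, i):
        return self.bicliques[i]

    def labels(self, b: Biclique) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """The biclique's vertex labels, each side in input order."""
        return (
            tuple(self.graph.left_labels[i] for i in sorted(b.left)),
            tuple(self.graph.right_labels[j] for j in sorted(b.right)),
        )

    def as_set(self) -> frozenset[tuple[frozenset[int], frozenset[int]]]:
        """Order-free view used to compare runs of different algorithms."""
        return frozenset((b.left, b.right) for b in self.bicliques)

    def sorted(self) -> "BicliqueCollection":
        """Deterministically sorted copy: by shape, then labels (for diffing)."""
        key = lambda b: (b.shape, self.labels(b))
        return BicliqueCollection(
            tuple(sorted(self.bicliques, key=key)), self.graph, self.params
        )


def search_masks(
    adj: Sequence[int],
    n_left: int,
    *,
    left_least: int = 1,
    right_least: int = 1,
    improved: bool = True,
) -> Iterator[tuple[int, tuple[int, ...]]]:
    """Core branch-and-bound search over bitmask adjacency.

    ``adj[j]`` is the bitmask of left neighbours of right vertex ``j``.
    Yields each maximal biclique exactly once as ``(left_mask,
    right_indices)``; bicliques below the reporting thresholds are
    silently suppressed (the search still traverses them).  The traversal
    order is deterministic for a fixed adjacency sequence.
    """
    cand = [j for j in range(len(adj)) if adj[j]]
    if not cand:
        return
    if improved:
        # non-decreasing degree; Python sort is stable, ties stay in input order
        cand.sort(key=lambda j: adj[j].bit_count())
    full = (1 << n_left) - 1
    # frame: [L mask, R tuple, P list (ordered candidates), Q list]
    stack: list[list] = [[full, (), cand, []]]
    while stack:
        frame = stack[-1]
        P = frame[2]
        if not P:
            stack.pop()
            continue
        x = P.pop(0)
        L, R, Q = frame[0], frame[1], frame[3]
        Lp = L & adj[x]
        maximal = True
        Qp = []
        for q in Q:
            common = adj[q] & Lp
            if common == Lp:
                maximal = False
                break
            if common:
                Qp.append(q)
        retired: list[int] = []
        if maximal:
            Rp = list(R)
            Rp.append(x)
            Pp: list[tuple[int, int]] = []
            for p in P:
                common = adj[p] & Lp
                if common == Lp:
                    Rp.append(p)
                    # neighbourhood confined to L': no new maximal biclique
                    # can arise from branching on p later — retire it
                    if improved and (adj[p] & L) == Lp:
                        retired.append(p)
                elif common:
                    Pp.append((common.bit_count(), p))
            if Lp.bit_count() >= left_least and len(Rp) >= right_least:
                yield Lp, tuple(Rp)
            if Pp:
                if improved:
                    Pp.sort()
                stack.append([Lp, tuple(Rp), [p for _, p in Pp], Qp])
        Q.append(x)
        if retired:
            drop = set(retired)
            frame[2] = [p for p in P if p not in drop]
            Q.extend(retired)


def iter_maximal_bicliques(
    graph: BipartiteGraph,
    params: EnumerationParams | None = None,
    *,
    branch_side: str = "right",
) -> Iterator[Biclique]:
    """Stream the maximal bicliques of *graph* in traversal order.

    ``branch_side`` selects which partite set supplies the branching
    candidates: ``"right"`` (default, fixed semantics), ``"left"``, or
    ``"auto"`` — a performance heuristic that branches on the smaller
    side so the bitmask side (the common neighbourhood) is the larger.
    The emitted *set* of bicliques is identical either way.
    """
    params = params or EnumerationParams()
    if branch_side == "auto":
        branch_side = "right" if graph.n_right <= graph.n_left else "left"
    if branch_side not in ("left", "right"):
        raise ValidationError(f"unknown branch_side {branch_side!r}")
    improved = params.algorithm is Algorithm.IMBEA
    if branch_side == "right":
        adj = graph.right_neighbor_masks()
        for lmask, rtuple in search_masks(
            adj,
            graph.n_left,
            left_least=params.left_least,
            right_least=params.right_least,
            improved=improved,
        ):
            yield Biclique(frozenset(mask_to_indices(lmask)), frozenset(rtuple))
    else:
        adj = graph.left_neighbor_masks()
        for rmask, ltuple in search_masks(
            adj,
            graph.n_right,
            left_least=params.right_least,
            right_least=params.left_least,
            improved=improved,
        ):
            yield Biclique(frozenset(ltuple), frozenset(mask_to_indices(rmask)))


def enumerate_maximal_bicliques(
    graph: BipartiteGraph,
    params: EnumerationParams | None = None,
    *,
    branch_side: str = "right",
) -> BicliqueCollection:
    """Enumerate every maximal biclique of *graph* meeting the thresholds.

    Returns each qualifying maximal biclique exactly once, in a
    deterministic order for a fixed input.  An empty result is valid
    (e.g. an edgeless graph).
    """
    params = params or EnumerationParams()
    found = tuple(iter_maximal_bicliques(graph, params, branch_side=branch_side))
    return BicliqueCollection(found, graph, params)


def is_biclique(graph: BipartiteGraph, left: frozenset[int], right: frozenset[int]) -> bool:
    """True iff both sides are non-empty and every cross pair is an edge."""
    if not left or not right:
        return False
    edge_set = graph.edge_set
    return all((l, r) in edge_set for l in left for r in right)


def is_maximal_biclique(
    graph: BipartiteGraph, left: frozenset[int], right: frozenset[int]
) -> bool:
    """True iff (left, right) is a biclique and no vertex can be added."""
    if not is_biclique(graph, left, right):
        return False
    edge_set = graph.edge_set
    for l in range(graph.n_left):
        if l not in left and all((l, r) in edge_set for r in right):
            return False
    for r in range(graph.n_right):
        if r not in right and all((l, r) in edge_set for l in left):
            return False
    return True
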