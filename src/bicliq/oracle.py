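"""Brute-force maximal biclique enumeration by subset closure.

Maximal bicliques of a bipartite graph correspond one-to-one with closed
pairs: take any non-empty subset ``S`` of one side, form the common
neighbourhood ``C`` of ``S`` on the other side, then the common
neighbourhood ``T`` of ``C`` back on the first side; ``(T, C)`` is a
maximal biclique whenever both parts are non-empty, and every maximal
biclique arises this way.  Enumerating all subsets of the *smaller* side
therefore finds them all in ``O(2^min(|U|,|V|))`` — exponential, but
trivially auditable, which is exactly what an independent test oracle
should be.  This module shares no code path with the branch-and-bound
search.
"""

from __future__ import annotations

from .enumerate import Biclique, BicliqueCollection, EnumerationParams
from .errors import CapacityError
from .graph import BipartiteGraph, mask_to_indices

__all__ = ["brute_force_enumerate", "closed_pairs_masks", "ORACLE_SIDE_LIMIT"]

ORACLE_SIDE_LIMIT = 20


def closed_pairs_masks(adj: list[int], n_enum: int) -> set[tuple[int, int]]:
    """All closed pairs ``(other_side_mask, enumerated_side_mask)``.

    ``adj[i]`` is the bitmask of neighbours (on the *other* side) of
    vertex ``i`` on the enumerated side; subsets of the enumerated side
    are scanned exhaustively.  Pairs with an empty part are dropped.
    """
    full_other = 0
    for m in adj:
        full_other |= m
    pairs: set[tuple[int, int]] = set()
    for subset in range(1, 1 << n_enum):
        common = full_other
        s = subset
        while s:
            low = s & -s
            common &= adj[low.bit_length() - 1]
            s ^= low
        if not common:
            continue
        # close back: every enumerated-side vertex adjacent to all of `common`
        closed = 0
        for i in range(n_enum):
            if adj[i] & common == common:
                closed |= 1 << i
        pairs.add((common, closed))
    return pairs


def brute_force_enumerate(
    graph: BipartiteGraph, params: EnumerationParams | None = None
) -> BicliqueCollection:
    """Enumerate maximal bicliques by exhaustive subset closure.

    Guarded: requires ``min(n_left, n_right) <= 20`` so the ``2^k``
    subset scan stays tractable; larger graphs must use
    :func:`~bicliq.enumerate.enumerate_maximal_bicliques`.
    """
    params = params or EnumerationParams()
    k = min(graph.n_left, graph.n_right)
    if k > ORACLE_SIDE_LIMIT:
        raise CapacityError(
            f"smaller side has {k} vertices (limit {ORACLE_SIDE_LIMIT}); "
            "the brute-force oracle would scan 2^k subsets — use "
            "enumerate_maximal_bicliques instead"
        )
    if graph.n_left <= graph.n_right:
        # enumerate subsets of the left side; adj maps left -> right mask
        pairs = closed_pairs_masks(graph.left_neighbor_masks(), graph.n_left)
        raw = [(left, right) for right, left in pairs]
    else:
        pairs = closed_pairs_masks(graph.right_neighbor_masks(), graph.n_right)
        raw = list(pairs)
    found = []
    for lmask, rmask in sorted(raw):
        b = Biclique(frozenset(mask_to_indices(lmask)), frozenset(mask_to_indices(rmask)))
        if b.p >= params.left_least and b.q >= params.right_least:
            found.append(b)
    return BicliqueCollection(tuple(found), graph, params)
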