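"""Bipartite graph data model.

A bipartite graph is stored as two ordered label sequences — the *left*
and *right* partite sets — plus a duplicate-free sequence of cross edges
given as ``(left_index, right_index)`` pairs.  Bipartiteness is
structural: an edge can only join a left vertex to a right vertex, so no
2-colouring check is ever needed.  The same label may occur on both
sides; the two occurrences are distinct vertices.

Vertex subsets are manipulated internally as integer bitmasks (bit ``i``
set means vertex ``i`` is in the subset), which keeps the set algebra of
the enumeration algorithms to single machine operations per step.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ValidationError

__all__ = ["BipartiteGraph", "degrees", "mask_to_indices"]


def _check_labels(labels: Sequence[str], side: str) -> tuple[str, ...]:
    out = tuple(str(x) for x in labels)
    seen: set[str] = set()
    for lab in out:
        if not lab:
            raise ValidationError(f"empty {side} vertex label")
        if "\t" in lab or "\n" in lab or "\r" in lab:
            raise ValidationError(f"{side} label {lab!r} contains a tab or newline")
        if lab in seen:
            raise ValidationError(f"duplicate {side} label {lab!r}")
        seen.add(lab)
    return out


def mask_to_indices(mask: int) -> Iterator[int]:
    """Yield the set bit positions of *mask* in ascending order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class BipartiteGraph:
    """A finite, simple, unweighted, undirected bipartite graph.

    Parameters
    ----------
    left_labels, right_labels:
        Ordered vertex labels; each label is unique within its side.
    edges:
        Iterable of ``(left_index, right_index)`` pairs, 0-based.
        Duplicates are collapsed; the first-appearance order of edges is
        preserved (it is what the edge-list writer emits).
    """

    __slots__ = ("left_labels", "right_labels", "edges", "_edge_set")

    def __init__(
        self,
        left_labels: Sequence[str],
        right_labels: Sequence[str],
        edges: Iterable[tuple[int, int]],
    ):
        self.left_labels = _check_labels(left_labels, "left")
        self.right_labels = _check_labels(right_labels, "right")
        nl, nr = len(self.left_labels), len(self.right_labels)
        ordered: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for e in edges:
            l, r = int(e[0]), int(e[1])
            if not (0 <= l < nl) or not (0 <= r < nr):
                raise ValidationError(f"edge ({l}, {r}) out of range for {nl}x{nr} graph")
            if (l, r) not in seen:
                seen.add((l, r))
                ordered.append((l, r))
        self.edges: tuple[tuple[int, int], ...] = tuple(ordered)
        self._edge_set: frozenset[tuple[int, int]] = frozenset(seen)

    # -- basic accessors -------------------------------------------------
    @property
    def n_left(self) -> int:
        return len(self.left_labels)

    @property
    def n_right(self) -> int:
        return len(self.right_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        return self._edge_set

    def has_edge(self, left: int, right: int) -> bool:
        return (left, right) in self._edge_set

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return (
            self.left_labels == other.left_labels
            and self.right_labels == other.right_labels
            and self._edge_set == other._edge_set
        )

    def __hash__(self) -> int:
        return hash((self.left_labels, self.right_labels, self._edge_set))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BipartiteGraph({self.n_left}x{self.n_right}, {self.n_edges} edges)"

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_label_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BipartiteGraph":
        """Build a graph from labelled edges, sides ordered by first appearance."""
        left_order: dict[str, int] = {}
        right_order: dict[str, int] = {}
        edges: list[tuple[int, int]] = []
        for l_lab, r_lab in pairs:
            li = left_order.setdefault(l_lab, len(left_order))
            ri = right_order.setdefault(r_lab, len(right_order))
            edges.append((li, ri))
        return cls(tuple(left_order), tuple(right_order), edges)

    def transpose(self) -> "BipartiteGraph":
        """Swap the two partite sets."""
        return BipartiteGraph(
            self.right_labels, self.left_labels, [(r, l) for l, r in self.edges]
        )

    # -- adjacency as bitmasks -------------------------------------------
    def right_neighbor_masks(self) -> list[int]:
        """For each right vertex, the bitmask of its left neighbours."""
        masks = [0] * self.n_right
        for l, r in self.edges:
            masks[r] |= 1 << l
        return masks

    def left_neighbor_masks(self) -> list[int]:
        """For each left vertex, the bitmask of its right neighbours."""
        masks = [0] * self.n_left
        for l, r in self.edges:
            masks[l] |= 1 << r
        return masks

    # -- degrees ----------------------------------------------------------
    def degrees(self) -> tuple[dict[str, int], dict[str, int]]:
        """Per-side ``label -> degree`` mappings, in input label order."""
        left = dict.fromkeys(self.left_labels, 0)
        right = dict.fromkeys(self.right_labels, 0)
        for l, r in self.edges:
            left[self.left_labels[l]] += 1
            right[self.right_labels[r]] += 1
        return left, right

    def isolated_vertices(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Labels of degree-0 vertices on each side."""
        left_deg, right_deg = self.degrees()
        return (
            tuple(lab for lab, d in left_deg.items() if d == 0),
            tuple(lab for lab, d in right_deg.items() if d == 0),
        )


def degrees(graph: BipartiteGraph) -> tuple[Mapping[str, int], Mapping[str, int]]:
    """Degree of every vertex, as ``(left_mapping, right_mapping)``.

    The sum of left degrees equals the sum of right degrees equals the
    number of edges.
    """
    return graph.degrees()
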