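"""Readers and writers for the two bipartite-graph file dialects.

Edge-list dialect
    Line 1: ``n_left<TAB>n_right<TAB>n_edges``.  Every further non-blank
    line: ``left_label<TAB>right_label``.  Labels are arbitrary non-empty
    text without tabs; vertices are ordered by first appearance.  The
    format cannot express isolated vertices.

Binary-matrix dialect
    Line 1: tab-separated right-vertex labels.  Every further line: a
    left-vertex label followed by one ``0``/``1`` entry per right label.
    Isolated vertices are representable (all-zero row or column).

Fields are separated by exactly one tab; surrounding spaces inside a
field are stripped; blank lines are ignored.  Writers emit LF line
endings and no trailing blank line.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, TextIO

from .errors import FormatError, ValidationError
from .graph import BipartiteGraph

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_binary_matrix",
    "write_binary_matrix",
    "format_edge_list",
    "degree_report_lines",
    "write_degree_report",
]

logger = logging.getLogger(__name__)

PathLike = str | os.PathLike


def _split(line: str) -> list[str]:
    return [tok.strip() for tok in line.rstrip("\n").rstrip("\r").split("\t")]


def _iter_content_lines(handle: TextIO):
    """Yield (1-based line number, raw line) for non-blank lines."""
    for no, raw in enumerate(handle, start=1):
        if raw.strip():
            yield no, raw


def read_edge_list(path: PathLike, *, strict: bool = True) -> BipartiteGraph:
    """Parse a headered edge-list file into a :class:`BipartiteGraph`.

    Parameters
    ----------
    path:
        File to read.
    strict:
        When true (the default) the declared header counts must match the
        observed numbers of distinct left labels, right labels and edges;
        a mismatch raises :class:`ValidationError`.  When false the
        header is read but only the observed content is trusted — useful
        for salvaging files with a corrupt header.

    Duplicate edge lines collapse to a single edge with a logged warning.
    """
    with open(path, "r", encoding="utf-8") as handle:
        lines = list(_iter_content_lines(handle))
    if not lines:
        raise FormatError("empty file: missing header line", path=path, line=1)
    header_no, header = lines[0]
    tokens = _split(header)
    if len(tokens) != 3:
        raise FormatError(
            f"header must have three tab-separated integers, got {len(tokens)} fields",
            path=path,
            line=header_no,
        )
    try:
        n_left, n_right, n_edges = (int(t) for t in tokens)
    except ValueError:
        raise FormatError(
            f"header fields must be integers, got {tokens!r}", path=path, line=header_no
        ) from None
    if min(n_left, n_right, n_edges) < 0:
        raise FormatError("header counts must be non-negative", path=path, line=header_no)

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for no, raw in lines[1:]:
        toks = _split(raw)
        if len(toks) != 2 or not toks[0] or not toks[1]:
            raise FormatError(
                f"edge line must have exactly two tab-separated labels, got {toks!r}",
                path=path,
                line=no,
            )
        pair = (toks[0], toks[1])
        if pair in seen:
            logger.warning("%s: line %d: duplicate edge %s-%s collapsed", path, no, *pair)
            continue
        seen.add(pair)
        pairs.append(pair)

    graph = BipartiteGraph.from_label_pairs(pairs)
    if strict:
        observed = (graph.n_left, graph.n_right, graph.n_edges)
        declared = (n_left, n_right, n_edges)
        if observed != declared:
            raise ValidationError(
                f"{path}: header declares {declared[0]} left / {declared[1]} right / "
                f"{declared[2]} edges but content has {observed[0]} / {observed[1]} / "
                f"{observed[2]}"
            )
    return graph


def write_edge_list(
    graph: BipartiteGraph, path: PathLike, *, drop_isolated: bool = False
) -> None:
    """Write *graph* in the headered edge-list dialect.

    The dialect cannot name isolated vertices; if the graph has any, a
    :class:`ValidationError` is raised unless ``drop_isolated`` is set,
    in which case they are silently omitted and the header counts only
    the vertices that carry edges.
    """
    iso_left, iso_right = graph.isolated_vertices()
    if (iso_left or iso_right) and not drop_isolated:
        raise ValidationError(
            "edge-list format cannot represent isolated vertices "
            f"(left: {list(iso_left)}, right: {list(iso_right)}); "
            "use the binary-matrix writer or drop_isolated=True"
        )
    n_left = graph.n_left - len(iso_left)
    n_right = graph.n_right - len(iso_right)
    out = [f"{n_left}\t{n_right}\t{graph.n_edges}"]
    for l, r in graph.edges:
        out.append(f"{graph.left_labels[l]}\t{graph.right_labels[r]}")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(out) + "\n")


def read_binary_matrix(path: PathLike) -> BipartiteGraph:
    """Parse a tab-separated binary adjacency matrix.

    The first line holds the right-vertex labels; every subsequent line a
    left-vertex label followed by one 0/1 entry per right vertex.
    """
    with open(path, "r", encoding="utf-8") as handle:
        lines = list(_iter_content_lines(handle))
    if not lines:
        raise FormatError("empty file: missing column-label line", path=path, line=1)
    header_no, header = lines[0]
    right_labels = _split(header)
    if any(not lab for lab in right_labels):
        raise FormatError("empty column label", path=path, line=header_no)
    left_labels: list[str] = []
    edges: list[tuple[int, int]] = []
    for row_index, (no, raw) in enumerate(lines[1:]):
        toks = _split(raw)
        if len(toks) != len(right_labels) + 1:
            raise FormatError(
                f"row has {len(toks) - 1} entries, expected {len(right_labels)}",
                path=path,
                line=no,
            )
        left_labels.append(toks[0])
        for col, tok in enumerate(toks[1:]):
            if tok == "1":
                edges.append((row_index, col))
            elif tok != "0":
                raise FormatError(
                    f"matrix entry must be 0 or 1, got {tok!r}", path=path, line=no
                )
    return BipartiteGraph(left_labels, right_labels, edges)


def write_binary_matrix(graph: BipartiteGraph, path: PathLike) -> None:
    """Write *graph* as a tab-separated 0/1 matrix (isolated vertices kept)."""
    row_masks = graph.left_neighbor_masks()
    out = ["\t".join(graph.right_labels)]
    for i, lab in enumerate(graph.left_labels):
        bits = "\t".join(
            "1" if row_masks[i] >> j & 1 else "0" for j in range(graph.n_right)
        )
        out.append(f"{lab}\t{bits}" if graph.n_right else lab)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(out) + "\n")


def format_edge_list(raw_path: PathLike, out_path: PathLike) -> BipartiteGraph:
    """Prepend the count header a headerless edge file is missing.

    Reads a file of bare ``left<TAB>right`` edge lines, removes duplicate
    lines, counts distinct left labels, right labels and edges, and
    writes a headered edge list accepted by :func:`read_edge_list`.
    Returns the parsed graph for convenience.
    """
    with open(raw_path, "r", encoding="utf-8") as handle:
        lines = list(_iter_content_lines(handle))
    if not lines:
        raise FormatError("empty input: no edges to declare", path=raw_path, line=1)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for no, raw in lines:
        toks = _split(raw)
        if len(toks) != 2 or not toks[0] or not toks[1]:
            raise FormatError(
                f"edge line must have exactly two tab-separated labels, got {toks!r}",
                path=raw_path,
                line=no,
            )
        pair = (toks[0], toks[1])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    graph = BipartiteGraph.from_label_pairs(pairs)
    write_edge_list(graph, out_path)
    return graph


def degree_report_lines(graph: BipartiteGraph) -> list[str]:
    """``label<TAB>degree`` lines, left side first, each in input order."""
    left, right = graph.degrees()
    return [f"{lab}\t{deg}" for lab, deg in left.items()] + [
        f"{lab}\t{deg}" for lab, deg in right.items()
    ]


def write_degree_report(graph: BipartiteGraph, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(degree_report_lines(graph)) + "\n")
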