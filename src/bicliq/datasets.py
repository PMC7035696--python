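"""Bundled and classic example graphs.

``worked_example`` is the 5×4, 10-edge bipartite graph used throughout
the documentation; it ships as a plain edge-list file so it can also be
fed to the command-line interface.  ``davis_southern_women`` rebuilds
the classic Davis Southern Women affiliation network (18 women × 14
social events, 89 attendance edges) from the generator in networkx, with
women on the left side.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .graph import BipartiteGraph
from .io import read_edge_list

__all__ = ["worked_example", "worked_example_path", "davis_southern_women"]


def worked_example_path() -> Path:
    """Filesystem path of the bundled 5×4 example edge list."""
    return Path(str(resources.files("bicliq").joinpath("data/example.el")))


def worked_example() -> BipartiteGraph:
    """The bundled 5×4 example graph (u1..u5 left, v1..v4 right, 10 edges)."""
    return read_edge_list(worked_example_path())


def davis_southern_women() -> BipartiteGraph:
    """Davis Southern Women affiliation graph: 18 women, 14 events, 89 edges.

    Vertex and edge order are made deterministic by sorting edges by
    (woman index, event index) in the generator's node order.
    """
    import networkx as nx

    g = nx.davis_southern_women_graph()
    women = [n for n, d in g.nodes(data=True) if d["bipartite"] == 0]
    events = [n for n, d in g.nodes(data=True) if d["bipartite"] == 1]
    w_index = {w: i for i, w in enumerate(women)}
    e_index = {e: j for j, e in enumerate(events)}
    edges = sorted(
        (w_index[a], e_index[b]) if a in w_index else (w_index[b], e_index[a])
        for a, b in g.edges()
    )
    return BipartiteGraph(tuple(women), tuple(events), edges)
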