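"""Size-distribution and extremal summaries over an enumerated collection.

The shape of a biclique is the pair ``(p, q)`` — left-side and
right-side vertex counts of ``K_{p,q}``.  The distribution maps shapes
to counts; the vertex-maximum biclique maximises ``p + q`` and the
edge-maximum biclique maximises ``p × q``.  Both extremes are maximal
bicliques, so scanning the enumerated collection finds them exactly.
"""

from __future__ import annotations

import os
from typing import TextIO

from .enumerate import Biclique, BicliqueCollection
from .errors import FormatError

__all__ = [
    "size_distribution",
    "vertex_maximum",
    "edge_maximum",
    "histogram_text",
    "summary_lines",
    "write_bicliques",
    "biclique_lines",
    "read_biclique_shapes",
]

HISTOGRAM_WIDTH = 50


def size_distribution(collection: BicliqueCollection) -> dict[tuple[int, int], int]:
    """Count of maximal bicliques per shape ``(p, q)``."""
    dist: dict[tuple[int, int], int] = {}
    for b in collection:
        dist[b.shape] = dist.get(b.shape, 0) + 1
    return dist


def _extreme(collection: BicliqueCollection, score) -> tuple[tuple[int, int], Biclique] | None:
    """Best biclique under *score*; ties go to larger p, then smallest left labels."""
    if len(collection) == 0:
        return None
    best = min(
        collection,
        key=lambda b: (-score(b), -b.p, collection.labels(b)[0]),
    )
    return best.shape, best


def vertex_maximum(collection) -> tuple[tuple[int, int], Biclique] | None:
    """Shape and witness of the biclique maximising p + q (None if empty)."""
    return _extreme(collection, lambda b: b.n_vertices)


def edge_maximum(collection) -> tuple[tuple[int, int], Biclique] | None:
    """Shape and witness of the biclique maximising p × q (None if empty)."""
    return _extreme(collection, lambda b: b.n_edges)


def histogram_text(dist: dict[tuple[int, int], int]) -> list[str]:
    """Text histogram of a size distribution, one line per shape.

    Shapes appear in ascending ``(p, q)`` order; bars of ``#`` marks are
    scaled linearly so the most common shape spans the full width.
    """
    lines = ["biclique size distribution"]
    if not dist:
        lines.append("no bicliques")
        return lines
    top = max(dist.values())
    for (p, q) in sorted(dist):
        count = dist[(p, q)]
        bar = "#" * max(1, round(count * HISTOGRAM_WIDTH / top))
        lines.append(f"{f'K{p},{q}':<10}{count:>8}  {bar}")
    return lines


def summary_lines(collection: BicliqueCollection) -> list[str]:
    """The stable summary block: count, distribution, extremal shapes."""
    lines = [f"bicliques: {len(collection)}"]
    if len(collection) == 0:
        return lines
    dist = size_distribution(collection)
    for (p, q) in sorted(dist):
        lines.append(f"{p} x {q} : {dist[(p, q)]}")
    (vp, vq), _ = vertex_maximum(collection)
    (ep, eq), _ = edge_maximum(collection)
    lines.append(f"vertex-max: K{vp},{vq}")
    lines.append(f"edge-max: K{ep},{eq}")
    return lines


def biclique_lines(
    collection: BicliqueCollection, *, style: str = "block", sort: bool = False
) -> list[str]:
    """Serialise a collection.

    ``block`` style: per biclique, a line of tab-separated left labels, a
    line of right labels, then a blank line.  ``line`` style: one
    biclique per line as ``left labels<TAB>... ; right labels``.
    ``sort`` orders bicliques by shape then labels for diff-stable output;
    by default traversal order is kept.
    """
    col = collection.sorted() if sort else collection
    out: list[str] = []
    for b in col:
        left, right = col.labels(b)
        if style == "block":
            out.append("\t".join(left))
            out.append("\t".join(right))
            out.append("")
        elif style == "line":
            out.append("\t".join(left) + " ; " + "\t".join(right))
        else:
            raise ValueError(f"unknown style {style!r}")
    return out


def write_bicliques(
    collection: BicliqueCollection,
    path: str | os.PathLike | TextIO,
    *,
    style: str = "block",
    sort: bool = False,
) -> None:
    lines = biclique_lines(collection, style=style, sort=sort)
    text = "\n".join(lines) + "\n" if lines else ""
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(text)


def read_biclique_shapes(path: str | os.PathLike) -> dict[tuple[int, int], int]:
    """Recover a size distribution from a serialised biclique file.

    Accepts either output style of :func:`write_bicliques`; the style is
    detected from the first non-blank line (``line`` style contains the
    `` ; `` separator).
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = handle.read().split("\n")
    content = [ln for ln in raw if ln.strip()]
    if not content:
        return {}
    dist: dict[tuple[int, int], int] = {}
    if " ; " in content[0]:
        for no, ln in enumerate(content, start=1):
            if " ; " not in ln:
                raise FormatError("missing ' ; ' separator", path=path, line=no)
            left, right = ln.split(" ; ", 1)
            shape = (len(left.split("\t")), len(right.split("\t")))
            dist[shape] = dist.get(shape, 0) + 1
    else:
        if len(content) % 2:
            raise FormatError(
                "block-style file must pair left/right label lines", path=path
            )
        for i in range(0, len(content), 2):
            shape = (len(content[i].split("\t")), len(content[i + 1].split("\t")))
            dist[shape] = dist.get(shape, 0) + 1
    return dist
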