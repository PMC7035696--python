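"""Seeded synthetic bipartite graph generators.

Two families: Erdős–Rényi-style random bipartite graphs (each of the
``n_left × n_right`` possible cross edges present independently with a
fixed probability) and planted-biclique graphs (the same background with
a complete ``a × b`` block forced present at seeded random positions).
A :class:`GeneratorSpec`, seed included, maps to exactly one graph, so
every generated fixture is replayable from its parameters alone; the
edge-list dialect has no comment syntax, so the spec is echoed in
:meth:`GeneratorSpec.tag` for use in filenames and logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .graph import BipartiteGraph

__all__ = ["GeneratorSpec", "random_bipartite", "planted_biclique", "planted_indices"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic graph; a pure function of its fields."""

    n_left: int
    n_right: int
    edge_probability: float
    seed: int
    planted: tuple[int, int] | None = None  # (a, b) block shape, optional

    def __post_init__(self) -> None:
        if self.n_left < 1 or self.n_right < 1:
            raise ValidationError("side sizes must be positive")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValidationError("edge_probability must lie in [0, 1]")
        if self.planted is not None:
            a, b = self.planted
            if not (1 <= a <= self.n_left and 1 <= b <= self.n_right):
                raise ValidationError(
                    f"planted shape {self.planted} exceeds {self.n_left}x{self.n_right}"
                )

    def tag(self) -> str:
        """Filename-safe echo of the spec, e.g. ``rand_L5_R4_p0.2_s7``."""
        base = f"L{self.n_left}_R{self.n_right}_p{self.edge_probability:g}_s{self.seed}"
        if self.planted is not None:
            return f"plant{self.planted[0]}x{self.planted[1]}_{base}"
        return f"rand_{base}"


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


def _edges_from_matrix(mat: np.ndarray) -> list[tuple[int, int]]:
    return [(int(i), int(j)) for i, j in np.argwhere(mat)]


def random_bipartite(spec: GeneratorSpec) -> BipartiteGraph:
    """Seeded random bipartite graph with labels ``u1.. / v1..``.

    Isolated vertices are kept (their labels exist even with no edges);
    the edge-list writer refuses such graphs unless told to drop them.
    """
    rng = np.random.default_rng(spec.seed)
    mat = rng.random((spec.n_left, spec.n_right)) < spec.edge_probability
    return BipartiteGraph(
        _labels("u", spec.n_left), _labels("v", spec.n_right), _edges_from_matrix(mat)
    )


def _planted_positions(spec: GeneratorSpec, rng: np.random.Generator):
    a, b = spec.planted
    rows = np.sort(rng.choice(spec.n_left, size=a, replace=False))
    cols = np.sort(rng.choice(spec.n_right, size=b, replace=False))
    return rows, cols


def planted_biclique(spec: GeneratorSpec) -> BipartiteGraph:
    """Random background graph with a complete ``a × b`` block forced in.

    The planted pair is a biclique by construction; it may extend to a
    larger maximal biclique once background edges are added, so the only
    guarantee is containment.  The block position is drawn from the same
    seeded stream before the background, so :func:`planted_indices`
    recovers it from the spec alone.
    """
    if spec.planted is None:
        raise ValidationError("spec.planted must be set for planted_biclique")
    rng = np.random.default_rng(spec.seed)
    rows, cols = _planted_positions(spec, rng)
    mat = rng.random((spec.n_left, spec.n_right)) < spec.edge_probability
    mat[np.ix_(rows, cols)] = True
    return BipartiteGraph(
        _labels("u", spec.n_left), _labels("v", spec.n_right), _edges_from_matrix(mat)
    )


def planted_indices(spec: GeneratorSpec) -> tuple[frozenset[int], frozenset[int]]:
    """The (left, right) index sets of the block :func:`planted_biclique` planted."""
    if spec.planted is None:
        raise ValidationError("spec.planted must be set")
    rng = np.random.default_rng(spec.seed)
    rows, cols = _planted_positions(spec, rng)
    return frozenset(int(i) for i in rows), frozenset(int(j) for j in cols)
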