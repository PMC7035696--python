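# Methods

## Problem

A bipartite graph G = (U ∪ V, E) has all edges between the two partite
sets U ("left") and V ("right").  A *biclique* K_p,q is a complete
bipartite subgraph with p left and q right vertices; it is *maximal* if
no vertex of G can be added without breaking completeness.  `bicliq`
enumerates every maximal biclique with both sides non-empty.  The count
can be exponential — a graph on n vertices can hold up to 2^(n/2)
maximal bicliques, and the crown graphs K_n,n minus a perfect matching
realise 2^n − 2 — so enumeration, not optimisation, is the task: the
vertex-maximum (max p+q) and edge-maximum (max p·q) bicliques are found
afterwards by scanning the enumerated set, never by a dedicated solver.

## The branch-and-bound search (MBEA / iMBEA)

The search grows a biclique one right vertex at a time.  A frame carries
four sets:

- **R** — right vertices of the current partial biclique;
- **L** — all left vertices adjacent to every member of R (so (L, R) is
  always a biclique with L as large as possible);
- **P** — ordered right candidates that still have a neighbour in L;
- **Q** — right vertices already handled at ancestor branches, kept for
  maximality testing.

Branching on a candidate x sets L′ = L ∩ N(x) and R′ = R ∪ {x}.  The
frame is then refined in two scans:

1. **Maximality check (prune):** if any q ∈ Q is adjacent to all of L′,
   every biclique below this branch could be enlarged by q, so the whole
   subtree is pruned.  Otherwise only the q with at least one neighbour
   in L′ are kept in Q′.
2. **Closure (expand):** every remaining candidate p ∈ P adjacent to all
   of L′ is absorbed into R′ immediately — (L′, R′) is then the unique
   maximal biclique with left side L′.  Candidates with some but not all
   neighbours in L′ form P′; the rest are dropped.

(L′, R′) is emitted if it passes the reporting thresholds, the search
recurses on (L′, R′, P′, Q′) while P′ is non-empty, and x moves from P
to Q.  Every maximal biclique is emitted exactly once.

iMBEA adds two refinements to the same skeleton:

- **Candidate ordering:** P is kept sorted by non-decreasing common
  neighbourhood size with L (ties in input order), so tight branches
  that fail fast are explored first;
- **Subtree skipping:** an absorbed candidate whose entire neighbourhood
  lies inside L′ (N(p) ∩ (L \ L′) = ∅) can produce no further maximal
  biclique of its own and is retired directly to Q after the branch.

MBEA processes P strictly in input (file-appearance) order, making both
variants deterministic for a fixed input file; they always emit the same
*set*, in possibly different orders.  A `--sort` option (shape, then
labels) gives diff-stable output.

### Numerical / implementation choices

- Left-side vertex subsets are arbitrary-precision integer bitmasks, so
  each neighbourhood intersection is a single bignum AND and each size a
  `bit_count()`.  Right-side sets stay as index lists.
- The recursion runs on an explicit stack, so a right side with tens of
  thousands of vertices cannot overflow the interpreter call stack.
- Thresholds (`left_least`, `right_least`, both default 1, i.e. "every
  maximal biclique with at least one edge") filter **reporting only**;
  the traversal itself is unchanged, so results at thresholds (a, b)
  always equal the (1, 1) results filtered by size.  The default
  algorithm is iMBEA.
- `branch_side` selects which side supplies candidates: `"right"`
  (default, fixed semantics), `"left"`, or `"auto"`, a heuristic that
  branches on the smaller side so the bitmask side is the larger.  The
  emitted set is identical in all cases (tested).
- Degenerate inputs: an edgeless graph yields an empty collection;
  degree-0 vertices are never candidates and never appear in results.

## The closure oracle

Maximal bicliques correspond one-to-one with closed pairs: for any
non-empty S ⊆ U, let C be the common neighbourhood of S in V and T the
common neighbourhood of C back in U; (T, C) is maximal whenever both are
non-empty, and all maximal bicliques arise this way.  The test oracle
enumerates all 2^k subsets of the smaller side (guarded at k ≤ 20),
closes each, and deduplicates on canonical mask pairs.  It shares no
code path with the branch-and-bound search.  The two are compared
exhaustively on **all** bipartite graphs with ≤ 4 vertices per side
(65,536 adjacency matrices) and on hundreds of seeded random graphs; a
third, fully external check maps maximal bicliques to maximal cliques of
the side-completed graph via networkx.

## Synthetic data

`random_bipartite` draws each of the n_left × n_right possible edges
independently with probability `edge_probability` from a seeded
generator (numpy `default_rng`); `planted_biclique` adds a complete
a × b block at seeded random positions on the same background.  A
`GeneratorSpec` (seed included) maps to exactly one graph.  Defaults in
the test suite use side sizes of roughly 8–30 vertices and edge
densities 0.05–0.5 — the regime where maximal-biclique structure is
rich but the closure oracle stays instant.  These generators emulate
only unstructured background noise plus one planted block: they have
none of the heavy-tailed degree distributions or community structure of
real affiliation networks, so passing tests certify algorithmic
correctness, not performance on real data.  The one real network
exercised is the Davis Southern Women affiliation graph (18 women × 14
events, 89 edges), whose full census — 63 maximal bicliques, vertex-max
K_14,1, edge-max K_5,4 — is asserted.  A planted block may merge with
background edges into a larger maximal biclique, so the planted tests
assert containment, not exact recovery.

## File dialects

The edge-list dialect is tab-separated: a header line declaring left
vertex, right vertex and edge counts, then one `left<TAB>right` labelled
edge per line.  Header validation is strict (declared must equal
observed) with a `strict=False` escape hatch that trusts content only.
Duplicate edge lines collapse with a logged warning — affiliation
exports routinely contain them and enumeration is set-based.  The format
cannot express isolated vertices; the binary-matrix dialect (first line:
column labels; each row: a row label plus 0/1 entries) can.  The matrix
layout — rows = left vertices — is this package's fixed choice.  Writers
emit LF endings and no trailing blank line, and writer output is
bit-stable for fixed input.

## Known limitations

- Output-bound by nature: on large dense graphs the number of maximal
  bicliques itself is the bottleneck (stream with
  `iter_maximal_bicliques` rather than collecting).
- Unweighted, undirected, simple graphs only; no quasi-bicliques or
  one-sided relaxations.
- The pure-Python core trades raw speed for auditability; graphs with
  tens of thousands of vertices enumerate, but not at C speeds.
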