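# bicliq

Maximal biclique enumeration in bipartite graphs.

Bipartite graphs model relations between two heterogeneous vertex types
— genes × conditions, patients × exposures, authors × papers, actors ×
events.  A **biclique** K_p,q is a complete bipartite subgraph (every
one of the p left vertices adjacent to every one of the q right
vertices); a **maximal** biclique is one no vertex can be added to.
Maximal bicliques are the all-ones submatrices of the biadjacency
matrix, which makes their enumeration the combinatorial core of
biclustering, of affiliation-network analysis and of closed-itemset
mining.  `bicliq` enumerates all of them with two depth-first
branch-and-bound algorithms — **MBEA** and its improved variant
**iMBEA** (candidate ordering plus subtree skipping) — and reports
per-side size thresholds, degree tables, size-distribution histograms
and the extremal shapes: the vertex-maximum biclique (max p+q) and the
edge-maximum biclique (max p·q).

Everything is exact and deterministic; an independent brute-force
closure oracle ships with the package so every enumeration claim is
checkable (see `docs/methods.md` for the algorithm and its validation).

## Worked example

The 5×4 graph bundled as `bicliq.datasets.worked_example()` (left
vertices u1–u5, right vertices v1–v4, 10 edges):

```python
import bicliq as bq

graph = bq.read_edge_list("src/bicliq/data/example.el")
col = bq.enumerate_maximal_bicliques(graph)   # defaults: thresholds 1/1, iMBEA
for b in col:
    print(col.labels(b))
print(*bq.summary_lines(col), sep="\n")
```

prints

```
(('u3',), ('v4', 'v3'))
(('u1', 'u2'), ('v1', 'v2', 'v4'))
(('u1', 'u2', 'u3', 'u4', 'u5'), ('v4',))
bicliques: 3
1 x 2 : 1
2 x 3 : 1
5 x 1 : 1
vertex-max: K5,1
edge-max: K2,3
```

The graph holds exactly three maximal bicliques.  The star of v4 (all
five left vertices, one right vertex) is the vertex-maximum, K5,1 with
6 vertices; {u1,u2} × {v1,v2,v4} is the edge-maximum, K2,3 with 6
edges.  Raising the thresholds reports only the bicliques with at least
that many vertices per side:

```python
len(bq.enumerate_maximal_bicliques(graph, bq.EnumerationParams(2, 2)))  # -> 1
```

The same runs from the shell:

```sh
bicliq enumerate src/bicliq/data/example.el          # bicliques + summary
bicliq enumerate graph.el --left-least 2 --right-least 2 --algorithm mbea
bicliq degree src/bicliq/data/example.el             # "v4<TAB>5" etc.
bicliq format raw_edges.txt graph.el                 # prepend the count header
bicliq histogram src/bicliq/data/example.el          # '#'-bar size histogram
bicliq generate fx.el --n-left 30 --n-right 30 --probability 0.2 --seed 7
```

Edge-list input is tab-separated with a `n_left n_right n_edges` header
line; a tab-separated 0/1 matrix dialect (`--input-format matrix`) is
also read and can express isolated vertices.

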