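# netdim

A complexity ("network dimension") measure for binary and weighted
networks, with exact maximum-k-clique search, box-covering dimensions
(MEMB and compact box burning), validation-model generators, and a
command line.

## The measure

For a connected graph `G`, let `mu` be the mean shortest-path distance
over all node pairs and `k = floor(mu)`. A *maximum k-clique* is a
largest vertex set whose members lie pairwise within distance `k`
(equivalently, a maximum clique of the k-th graph power). With `cl` its
cardinality,

```
Ndim(G) = log cl / log(k + 1)
```

`Ndim` behaves like a dimension: it is 1 on paths, approaches 2 on
growing 2-D grids, equals `log2(n)` on the complete graph `K_n`, and
agrees with the box-covering dimension on fractal graphs — while
remaining well defined on small-world graphs, where box covering has no
linear scaling regime. Because it is read at the single natural scale
`k = floor(mu)`, it needs one clique computation rather than a covering
curve.

Weighted networks (e.g. |correlation| matrices, where larger weight
means *closer*) are handled three ways: hard thresholding, Monte-Carlo
ensembles of binary realisations with edge marginals equal to the
normalised weights, and a functional-distance method that converts
weights to integer path lengths and applies the generalised formula
`log cl / log((k + m_min)/m_min)`. See `docs/methods.md` for the full
description, assumptions, and limitations.

## Worked example

Generate a 30×30 grid lattice and measure it:

```
$ netdim simulate lattice --dims 30,30 -o grid30.tsv
wrote grid30.tsv

$ netdim -v ndim grid30.tsv
mu=20.0000 k=20 |clique|=221
Ndim = 1.77307
```

The mean distance on the grid is exactly 20, so `k = 20`; the maximum
20-clique is the 221-node L1 ball of radius 10, and
`Ndim = log(221)/log(21) = 1.77307` — close to the topological
dimension 2, from below, as expected for a finite grid. The
box-covering dimension of the same graph agrees:

```
$ netdim boxdim grid30.tsv --algorithm memb --sizes 1,2,3,4,5,6
d_B = 1.703   R^2 = 0.999
```

The same computations from Python:

```python
>>> from netdim.models import lattice_graph
>>> from netdim.ndim import ndim_binary
>>> r = ndim_binary(lattice_graph([30, 30]))
>>> r.mu, r.k, r.clique_cardinality, r.value
(20.0, 20, 221, 1.773073712524284)
```

A weighted example — the functional-distance method on a 3-node chain
with weights 0.5 and 0.25 (distances 2 and 4, scaled to integer lengths
100 and 200):

```python
>>> import numpy as np
>>> from netdim import WeightedGraph
>>> from netdim.weighted import ndim_functional, ScalingSpec
>>> W = np.zeros((3, 3)); W[0, 1] = W[1, 0] = 0.5; W[1, 2] = W[2, 1] = 0.25
>>> r = ndim_functional(WeightedGraph(W), ScalingSpec(kappa=100))
>>> r.m_min, r.k, r.value
(100.0, 200, 0.6309297535714574)
```

`0.63093 = log 2 / log 3`: the weighted chain carries the dimension of
a 2-point set at scale 3, and the result is invariant under any
rescaling `W -> lambda * W`.

## Command line

* `netdim ndim FILE [--method binary|threshold|montecarlo|functional]`
  — Ndim of a graph file (edge-list TSV, matrix CSV, or GraphML).
* `netdim boxdim FILE --algorithm memb|cbb|wcbb --sizes 1,2,4,...`
  — box-covering dimension with per-size best-of-`--repeats` covers.
* `netdim compare A.txt B.txt` — Brunner–Munzel test between two
  one-value-per-line Ndim sample files.
* `netdim simulate lattice|fractal-model|correlation-matrix -o FILE`
  — validation-graph generators with a JSON metadata sidecar.

Exit codes: 0 success, 2 input/parameter error, 3 infeasible
computation (e.g. clique-enumeration cap exceeded). `-v` prints `mu`,
`k`, the clique cardinality, and CPU seconds.

## Layout

```
src/netdim/graph_core.py   graphs, shortest paths, cost/efficiency
src/netdim/clique.py       exact max-clique / max-k-clique search
src/netdim/ndim.py         the dimension measure (binary graphs)
src/netdim/weighted.py     thresholding, Monte-Carlo, functional distances
src/netdim/boxcover.py     MEMB, CBB, weighted CBB, log-log fits
src/netdim/models.py       lattices, hub-repulsion model, noise, synthetic matrices
src/netdim/stats.py        Brunner-Munzel test, core-node analysis
src/netdim/io_cli.py       file formats, result serialisation, CLI
docs/methods.md            models, assumptions, parameters, limitations
tests/                     unit, property, and acceptance tests
scripts/acceptance.py      standalone recomputation of numeric targets
```
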