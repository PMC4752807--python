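# Methods

This document describes the models and algorithms implemented in
`netdim`, the assumptions behind them, the meaning of every tunable
parameter, and the known limitations.

## 1. The network dimension Ndim

### Definition

For a connected undirected binary graph `G` with `n` nodes, let
`d(i, j)` be the chemical (hop) distance and

```
mu = mean over all distinct pairs of d(i, j)      (characteristic path length)
k  = floor(mu)
```

A *k-clique* is a vertex set whose members lie pairwise within distance
`k` in `G`; equivalently, a clique of the k-th graph power `G^k`. With
`cl(G, k)` the cardinality of a maximum k-clique,

```
Ndim(G) = log cl(G, k) / log(k + 1)
```

The generalised form used by the functional-distance pipeline replaces
unit edge lengths with positive integer lengths `m(i, j)`; with
`m_min = min m(i, j)` and `k = floor(mu)` computed on the weighted
shortest-path distances,

```
Ndim(G) = log cl(G, k) / log((k + m_min) / m_min)
```

which reduces to the binary formula when every length is 1.

### Rationale

`Ndim` is a covering-type dimension read off at a single natural scale:
`k = floor(mu)` is the scale at which the graph "looks like" its own
typical neighbourhood. On a complete graph `K_n` the value is
`log2(n)`; on paths it is 1; on 2-D grids it approaches 2 from below as
the grid grows. It agrees with the box-covering dimension on fractal
graphs while remaining defined (and cheap to interpret) on small-world
graphs where box covering has no linear scaling regime.

### k-mode

Two choices of `k` are implemented (`k_mode`):

* `floor_mu` (default): `k = floor(mu)`, the standard definition;
* `half_diameter`: `k = floor(diameter / 2)`, a variant that anchors
  the scale to the graph's extent rather than its mean distance.

### Disconnected graphs

`Ndim` requires a connected graph. `ndim_components_weighted` analyses
each connected component of at least `min_component_size` nodes
(default 5) and returns the node-count-weighted mean of the per-component
values; components below the cutoff are dropped because `mu` and the
clique scale are not meaningful on a handful of nodes.

## 2. Maximum k-clique search

Finding a maximum clique is NP-hard; `netdim` uses an exact
branch-and-bound of the Tomita style:

* vertices of the candidate set are greedily coloured; the colour count
  bounds the clique extension, so whole branches are pruned;
* a greedy clique (and, on the power graph, the best distance-`k` ball)
  seeds the incumbent, which tightens pruning from the first node;
* two engines share the algorithm: a pure-Python bitset reference used
  on small graphs and in tests, and a twin-contracted engine compiled
  with numba. The contraction merges vertices with identical closed
  neighbourhoods into weighted classes — any maximum clique is a union
  of whole classes — turning the problem into a smaller max-weight
  clique search with a cumulative per-colour weight bound. When numba
  is unavailable the reference engine handles everything.

### Special cases used as exact shortcuts

* On a tree, a set of vertices is pairwise within distance `k` exactly
  when it is contained in a ball: radius `k//2` around a node for even
  `k`, or around an edge for odd `k`. The maximum k-clique of a tree is
  therefore the heaviest such ball, found in `O(n^2)` without search.
* In any graph every distance-`k//2` ball is a valid k-clique, so the
  best ball is always used to warm-start the branch and bound.

### Lower-bound constraint on growing models

For a sequence of growing graphs `G_3, G_4, ...` whose Ndim is
nondecreasing (true for the hub-repulsion model), the previous stage
yields a certified clique lower bound
`ndim_lower_bound(prev_value, k) = ceil(exp(prev_value * log(k + 1)))`
which is fed to the solver as a hard floor. If the assumption fails the
stage is recomputed without the seed, so results are always exact.

### Node-budget truncation

`node_budget` caps the number of branch expansions. When the cap is
reached the search stops and returns the incumbent with
`exhausted=False`: a *certified lower bound* on the maximum clique,
bit-for-bit reproducible across machines because the cap counts nodes,
not wall time. This matters on dense power graphs (see Limitations).

## 3. Weighted pipelines

Weights follow communication-network semantics: larger weight = closer.
Three routes reduce a `WeightedGraph` to the binary machinery:

* **Thresholding** (`ndim_thresholded`): keep edges with weight above
  (or below) `tau`, then run the binary pipeline. Simple but
  discontinuous in `tau`.
* **Monte-Carlo ensembles** (`mc_ndim_distribution`): normalise weights
  by `joint_max` and draw binary graphs whose independent edge
  marginals equal the normalised weights; the result is a distribution
  of Ndim values rather than a single number, with every draw
  reproducible from `(seed, draw_index)`. Distributions from two
  conditions are compared with the Brunner–Munzel test.
* **Functional distances** (`ndim_functional`): transform weights to
  distances `w~ = 1/w`, rescale to positive integers
  `m(i, j) = round(c * w~(i, j))` with `c = kappa / (max w~ - min w~)`
  (or `kappa / min w~` when all `w~` are equal is rejected as
  degenerate), and apply the generalised formula. The construction is
  invariant under `W -> lambda W` because only ratios of `w~` enter.
  `kappa` controls integer resolution; too small a `kappa` collapses
  distinct distances (a warning is logged) or rounds short edges to
  zero (an error).

## 4. Box-covering dimensions

`d_B` is the negative slope of `log N_B` against `log l_B` for minimum
box covers of increasing linear size. Exact minimisation is NP-hard;
two randomised greedy algorithms are provided, with the per-size
minimum over `repeats` seeded runs (default 10) as the estimate:

* **MEMB** (maximum excluded mass burning) selects box centres by
  excluded mass within radius `r_B` and assigns nodes to their nearest
  centre; box nominal size is `2 r_B + 1`.
* **CBB** (compact box burning) grows boxes of pairwise diameter
  `< l_B` from random seeds; a weighted variant accepts real path
  lengths and a real threshold `l_w`.

The regression abscissa is the *measured* mean box size (box diameter
in host-graph distance, plus 1) rather than the nominal size, which
markedly improves log-log linearity. `R^2` of the fit is the fractality
check; below roughly 0.98 the graph has no reliable box-scaling regime.
`box_dimension` grows the size grid automatically (linear or dyadic
spacing) until covers collapse to fewer than `min_boxes` boxes.

## 5. Validation models

* `lattice_graph`: 1-D paths and 2-D four-neighbour grids — known
  topological dimensions 1 and 2.
* `fractal_model` f(g, n, m, e): inverse-renormalisation growth. Each
  generation multiplies the node count by `n` and node degrees by `m`;
  every inherited edge is subdivided into a path of `m` unit edges with
  probability `1 - e` (hub repulsion) or kept direct with probability
  `e` (hub attraction). At `e = 0` the graph is a tree-like fractal
  with limiting dimension `ln n / ln m`; at `e = 1` it is a small
  world. Leaf offspring are added or removed at random to hit the exact
  size `n^g`; way-point nodes are never touched, preserving the
  distance scaling. The published model family leaves the offspring
  bookkeeping underdetermined; this implementation's rule is one
  consistent choice, and validation tolerances on model targets are set
  accordingly.
* `add_random_edges`: uniform noise edges (`round(fraction * E)` new
  edges without replacement), driving the fractal-to-small-world
  transition.
* `synthetic_correlation_matrix`: block-structured stand-in for an
  fMRI |correlation| matrix (within/between-block weights plus clipped
  symmetric Gaussian noise). Purely synthetic; used to exercise the
  weighted pipelines without imaging data.

## 6. Statistics

* **Brunner–Munzel test** (`brunner_munzel`): rank-based test for a
  stochastic shift between two Ndim samples, assuming neither normality
  nor equal variances. Implemented from midranks with the Satterthwaite
  degrees-of-freedom approximation; direction conventions match the
  common library implementations ("less" means the first sample lies
  stochastically below the second). Accuracy is unreliable below ~10
  observations per sample (a warning is issued).
* **Core nodes** (`core_nodes`, `core_node_probabilities`): the
  intersection of *all* maximum k-cliques; across a Monte-Carlo
  ensemble each node gets a probability of being core, localising the
  hubs that drive complexity. Clique enumeration is capped
  (`CliqueEnumerationCap`) to keep worst cases bounded.

## 7. Limitations

* **Exact clique search on dense power graphs.** Adding even 1% random
  edges to a generation-6 hub-repulsion model collapses its diameter;
  the resulting power graph at `k = floor(mu)` has ~0.5 edge density on
  4096 nodes with maximum cliques of 1000+ vertices. Exact maximum
  clique at that size/density is beyond any known solver at desk scale.
  `netdim` handles this honestly via `node_budget`: results are flagged
  `exhausted=False` and are certified lower bounds on `cl`, hence lower
  bounds on Ndim. Percent-increase experiments on noisy graphs are
  therefore conservative: more search can only raise the reported
  increase.
* **Randomised box covers.** MEMB/CBB approximate an NP-hard minimum;
  `d_B` estimates carry the min-over-repeats heuristic and a seed
  dependence, though with fixed seeds all outputs are bit-reproducible.
* **Single natural scale.** Ndim reads the dimension at `k = floor(mu)`
  only; it does not characterise multi-scale structure the way a full
  box-covering curve does. The two are complementary and agree on
  fractal graphs.
* **Finite graphs only.** The infinite-graph limit of the dimension is
  not computable here; convergence is demonstrated empirically on
  growing model families.
* **Analyses not reproduced at desk scale.** Published applications of
  this family of measures to clinical resting-state fMRI cohorts and
  dual-task experiments, and benchmark tables over third-party network
  collections, require restricted or external data and specific
  hardware, and are not reproduced in this repository. The pipelines
  they exercise (thresholding, Monte-Carlo ensembles, functional
  distances, core-node probabilities, Brunner–Munzel comparison) are
  instead validated end-to-end on synthetic correlation matrices with
  known block structure. CPU-time figures are likewise
  hardware-specific and are not validation targets.

## 8. Determinism

Every stochastic routine takes an explicit seed and uses a counter-based
generator; per-draw and per-repeat streams are derived from
`(seed, index)` so that individual draws can be recomputed in
isolation. Identical inputs and seeds give identical outputs across
platforms.
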