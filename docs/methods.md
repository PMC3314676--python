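# Methods

## The hierarchy measure

A flow hierarchy exists when influence in a directed network runs
predominantly from a few top nodes to many bottom nodes. We quantify a
node's position by its **local reaching centrality** — for an unweighted
digraph, the number of nodes at finite positive directed distance from it,
divided by `N − 1` — and the network's overall hierarchy by the **global
reaching centrality (GRC)**, the mean deviation of all nodes from the
best-reaching node:

```
GRC = Σ_i (C_R^max − C_R(i)) / (N − 1)
```

The normalization makes GRC = 1 exactly for the out-star (one node with
nonzero reach) and GRC = 0 whenever all reaches are equal (cycles, complete
digraphs, edgeless graphs). A directed chain of N nodes has
GRC = N / (2(N − 1)) → 1/2. The measure has no free parameters; a node never
counts as reaching itself, which also makes self-loops inert (they are
dropped at load).

Assumptions worth keeping in mind: reachability is purely topological (an
arbitrarily long path counts as much as a direct edge in the unweighted
variant), and the measure captures *flow* hierarchy only — order or nested
hierarchies must be converted to a directed network first.

### Weighted variant

Each reachable `j` contributes the *average edge weight* of a shortest
(fewest-hop) path `i → j`; among equally short paths, the heaviest (maximum
total weight) is used. We compute it by dynamic programming over the
BFS-layered shortest-path DAG: processing nodes in order of increasing hop
distance, the best total weight to `v` is `max over predecessors u of
best(u) + w(u, v)`. Ties in total weight are broken arbitrarily — tied paths
contribute identically. With all weights equal to 1 the unweighted variant
is recovered exactly (asserted in the tests). Weights above 1 can push
individual values, and hence the GRC, outside [0, 1]; the formula is applied
as written and the range documented rather than clamped.

### Undirected variant

The directional term is dropped: the value is the harmonic sum
`Σ_j 1/d(i, j)` over `i`'s connected component divided by `N − 1` —
equivalent to harmonic (disconnected-graph) closeness up to the
normalization. Partially directed or undirected inputs to the *directed*
variant are first expanded to their bidirected equivalent, which makes
mutually connected pairs equivalent in the hierarchy.

### Degenerate cases

`N = 1` returns GRC = 0 by convention (and logs a warning at the node
level); `N = 2` is handled by the general formula.

## Computation

The directed all-node profile is computed on the condensation: strongly
connected components are found with scipy's C implementation, the component
DAG is topologically sorted, and descendant sets propagate bottom-up as
Python-integer bitsets. This is orders of magnitude faster than one BFS per
node on the ensemble workloads and is cross-checked in the tests against an
independent Boolean matrix-powering oracle (and the per-node BFS route).
Undirected distances come from scipy's BFS (`csgraph.dijkstra` with
`unweighted=True`).

## Generators

All generators are deterministic given a seed (numpy `default_rng`); the
edge-count knob is the average degree `k`, with exactly `round(k·N)` edges
placed.

* **ER digraph** — `round(k·N)` distinct ordered non-self pairs, uniform.
* **SF digraph** — static model: endpoint `i` (rank `i+1`) is drawn with
  probability ∝ `rank^(−α)`, `α = 1/(γ−1)`, independently for source and
  target, rejecting self-loops and duplicates. Default `γ = 3.0`,
  configurable; the static model was chosen because it gives an exact edge
  count and an adjustable exponent without growth dynamics.
* **Random arborescence** — breadth-first growth; each expanded node draws a
  child count uniformly from `{1, …, b_max}` (default `b_max = 5`),
  truncated at `N`. Levels: deepest nodes have ℓ = 1 and every edge steps
  down one level, so the root's level equals the number of levels.
* **AH model** — arborescence backbone plus
  `round(k·N) − (N − 1)` extra edges. Each extra edge is decided *once* to be
  a "down" edge (probability `p`) or fully random, then the pair is
  rejection-sampled: down edges require strictly decreasing level
  (same-level edges count as unconstrained noise) and must not duplicate an
  existing edge in that direction; the opposite orientation of an existing
  edge is allowed. Rejection is capped at `100 × (extra edges)` attempts;
  exhaustion (possible only near complete density) raises an error rather
  than silently relaxing the constraints.

At `N = 500`, `k = 3`, `b_max = 5`, sweeping `p` over {0, 0.25, 0.5, 0.75,
1} moves the ensemble-mean GRC monotonically from ≈ 0.11 to ≈ 0.97; at fixed
`p` the GRC falls with density, vanishing for dense ER/SF graphs.

## Null model and classification

Randomized counterparts preserve every node's in- and out-degree exactly:
a configuration-model stub matching (self-loops and duplicate edges repaired
by re-pairing the offending stubs together with one random good pair per
round, bounded at 1000 rounds) followed by `round(10 × E)` *accepted*
degree-preserving double edge swaps. Counting accepted rather than attempted
swaps is the stricter reading of "rewired edge pairs"; rigid graphs that
admit no legal swap (e.g. a lone 3-cycle) simply return their forced
realization. The per-replicate streams are spawned from a single seed
sequence, so replicates are independent but jointly reproducible.

Classification is a two-sided empirical-quantile test (type-1 / inverse-CDF
quantiles, strict inequalities): with confidence 0.98 and 100 replicates the
thresholds are the 1st and 99th percentiles of the randomized GRC sample.
A degenerate null distribution — e.g. an out-star, whose degree sequence
admits exactly one simple realization — necessarily yields "indistinct":
the network is not *more* hierarchical than its degree sequence demands.

## Controllability

Driver nodes under linear node dynamics: `N_D = max(N − M, 1)` where `M` is
the maximum matching of the bipartite out-copy/in-copy representation of the
edge set, computed exactly with Hopcroft–Karp (deterministic node order; the
count, not the matching, is the contract — verified against an exhaustive
recursive matching oracle on small digraphs). Edge-based (switchboard)
dynamics is not implemented; externally computed driver fractions can be fed
to the correlation routine instead.

## Layout

Nodes are sorted by the graded quantity (local reaching centrality by
default; ties broken by node id) and greedily grouped: a node joins the
current level while the level's *population* standard deviation stays within
`z` times the graph-wide population standard deviation. Default
`z = 1e−6` — effectively "exact value" grouping for the discrete unweighted
C_R while tolerating floating-point jitter; `z = 0` demands exact equality.
All-equal quantities give a single level. Level means are strictly
increasing by construction, so inter-level gaps are positive.

Vertical placement: gaps are first set proportional to consecutive level-
mean differences with the smallest gap equal to the unit horizontal spacing,
then log-compressed as `1 + log(Δ/Δ_min)` and uniformly rescaled so the
total height matches the pre-compression height. This realization preserves
the ordering of gap sizes and the stated height conservation. Within a
level, nodes sit at unit-spaced x positions with zero mean.

Ensemble overlays rescale each layout affinely into the unit square
(degenerate axes centred at 0.5 — idempotent for layouts already spanning
the square), bin node positions on a `G × G` grid (default `G = 64`) and
accumulate counts, so the grid total equals the combined node count. The raw
grid is always exported; the bundled heat-map rendering colors
`log10(ρ/ρ̄)` with empty bins masked, and any other transform can be applied
downstream.

## Synthetic data and what the tests show

All tests run on generated graphs: canonical graphs with closed-form GRC
(stars, chains, cycles), small random digraphs checked against brute-force
oracles, and model ensembles. Ensemble sizes were chosen to give stable
means on a single CPU: 100 seeds per parameter point at `N = 500` (AH sweep)
or `N = 1000` (ER/SF density sweep), 20 seeds × 100 replicates for the
null-model classification rates. The generators emulate the degree structure
and tunable hierarchy of real networks but not their weights, motif content
or community structure, so passing tests establish the correctness and
qualitative behaviour of the measure — not claims about any particular
empirical network. Real networks can be analyzed through the edge-list /
GraphML loaders (with a direction-reversal flag for datasets whose arrow
convention points up the hierarchy), but no external datasets are bundled.

## Known limitations

* The weighted variant's GRC is not confined to [0, 1] when weights exceed 1.
* The configuration-model repair loop can fail on adversarial degree
  sequences (it errors out rather than biasing the sample).
* No multigraphs, no edge attributes beyond one positive weight, no
  crossing-minimization in the layout (levels are readable for large graphs;
  edge routing is not the goal).
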