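"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different computational route from the
library code: reachability by Boolean matrix powering (vs BFS / condensation
bitsets), the weighted reach by exhaustive shortest-path enumeration with
networkx (vs layered dynamic programming), the undirected reach by explicit
all-pairs BFS, and the maximum matching by exhaustive recursion (vs
Hopcroft–Karp).
"""

from __future__ import annotations

import numpy as np

from hiernet.graph_core import Network


def reachability_matrix(net: Network) -> np.ndarray:
    """Transitive closure by Boolean matrix powering: R = A + A^2 + ... + A^N."""
    index = {n: i for i, n in enumerate(net.nodes)}
    n = net.N
    a = np.zeros((n, n), dtype=bool)
    for u, v in net.edges:
        a[index[u], index[v]] = True
        if not net.directed:
            a[index[v], index[u]] = True
    closure = a.copy()
    power = a.copy()
    for _ in range(n - 1):
        power = power @ a
        closure |= power
    return closure


def local_reach_directed_oracle(net: Network, i: str) -> float:
    closure = reachability_matrix(net)
    idx = {n: k for k, n in enumerate(net.nodes)}[i]
    row = closure[idx].copy()
    row[idx] = False  # a node never counts as reaching itself
    return row.sum() / (net.N - 1)


def local_reach_weighted_oracle(net: Network, i: str) -> float:
    """Exhaustive enumeration of all shortest paths, keeping the heaviest."""
    import networkx as nx

    g = net.to_networkx()
    total = 0.0
    for j in net.nodes:
        if j == i:
            continue
        try:
            paths = list(nx.all_shortest_paths(g, i, j))  # unweighted (hop) shortest
        except nx.NetworkXNoPath:
            continue
        best = max(
            sum(g[u][v]["weight"] for u, v in zip(path, path[1:])) for path in paths
        )
        total += best / (len(paths[0]) - 1)
    return total / (net.N - 1)


def local_reach_undirected_oracle(net: Network, i: str) -> float:
    """All-pairs BFS harmonic sum over the connected component of ``i``."""
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for u, v in net.edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {i: 0}
    frontier = [i]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return sum(1.0 / d for n, d in dist.items() if n != i) / (net.N - 1)


def grc_oracle(net: Network) -> float:
    vals = [local_reach_directed_oracle(net, i) for i in net.nodes]
    c_max = max(vals)
    return sum(c_max - v for v in vals) / (net.N - 1)


def max_matching_oracle(net: Network) -> int:
    """Maximum bipartite matching of the directed edge set, by exhaustive search."""
    edges = list(net.edges)

    def best(k: int, used_out: frozenset, used_in: frozenset) -> int:
        if k == len(edges):
            return 0
        u, v = edges[k]
        skip = best(k + 1, used_out, used_in)
        if u not in used_out and v not in used_in:
            take = 1 + best(k + 1, used_out | {u}, used_in | {v})
            return max(skip, take)
        return skip

    return best(0, frozenset(), frozenset())


def random_digraph(rng: np.random.Generator, n_max: int = 8) -> Network:
    """Small random digraph for oracle suites (may be disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.05, 0.6)
    labels = [f"v{i}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                edges[(labels[i], labels[j])] = 1.0
    return Network(nodes=tuple(labels), edges=edges, directed=True)


def random_weighted_digraph(rng: np.random.Generator, n_max: int = 8) -> Network:
    net = random_digraph(rng, n_max)
    edges = {e: float(rng.uniform(0.1, 2.0)) for e in net.edges}
    return Network(nodes=net.nodes, edges=edges, directed=True)


def random_undirected_graph(rng: np.random.Generator, n_max: int = 8) -> Network:
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.05, 0.6)
    labels = [f"v{i}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(labels[i], labels[j])] = 1.0
    return Network(nodes=tuple(labels), edges=edges, directed=False)
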