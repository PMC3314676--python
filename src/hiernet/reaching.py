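"""Local reaching centralities and the global reaching centrality (GRC).

The local reaching centrality ``C_R(i)`` of a node in a directed graph is the
fraction of all other nodes that can be reached from ``i`` along directed
paths.  It generalizes the m-reach centrality to ``m = N`` and grades nodes by
their impact on the rest of the network.  The global reaching centrality

    GRC = sum_i (C_R^max - C_R(i)) / (N - 1)

measures the heterogeneity of that impact: 0 for an egalitarian graph (every
node reaches the same share, e.g. a directed cycle) and 1 for the maximally
hierarchical out-star, where a single node reaches everything and nobody else
reaches anything.

Three variants of ``C_R`` are provided:

``directed``
    Unweighted reach fraction (the default used for model and real networks).
``weighted``
    For each reachable node ``j`` take, among the shortest directed paths
    ``i -> j``, the one with maximum total weight and contribute its average
    edge weight (total weight divided by hop count).  With all weights equal
    to 1 this reduces exactly to the unweighted variant.  With weights above
    1 individual values may exceed 1; the GRC formula is applied as-is.
``undirected``
    Harmonic (reciprocal-distance) sum over the node's connected component,
    normalized by ``N - 1`` — the closeness generalization that remains well
    defined on disconnected graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from collections import deque

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import LookupNodeError, UsageError
from .graph_core import Network, to_bidirected

logger = logging.getLogger(__name__)

__all__ = [
    "ReachProfile",
    "VARIANTS",
    "local_reach_directed",
    "local_reach_weighted",
    "local_reach_undirected",
    "reach_profile",
    "grc",
    "reach_distribution",
]

VARIANTS = ("directed", "weighted", "undirected")


@dataclass(frozen=True)
class ReachProfile:
    """Per-node local reaching centralities plus the derived GRC."""

    values: dict[str, float]
    variant: str
    c_max: float
    grc: float

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


def _adjacency(net: Network) -> tuple[sp.csr_array, dict[str, int]]:
    """Unweighted adjacency in CSR form plus the node -> row index map."""
    index = {n: i for i, n in enumerate(net.nodes)}
    n = net.N
    rows = np.fromiter((index[u] for u, _ in net.edges), dtype=np.int64, count=net.E)
    cols = np.fromiter((index[v] for _, v in net.edges), dtype=np.int64, count=net.E)
    data = np.ones(net.E, dtype=np.int8)
    return sp.csr_array((data, (rows, cols)), shape=(n, n)), index


def _hop_distances(net: Network, *, directed: bool) -> np.ndarray:
    """All-pairs hop distances (BFS); ``inf`` marks unreachable pairs."""
    adj, _ = _adjacency(net)
    return dijkstra(adj, directed=directed, unweighted=True)


def _reach_counts(net: Network) -> np.ndarray:
    """Number of nodes reachable from each node (excluding itself).

    Works on the condensation: strongly connected components are collapsed
    (scipy, C speed), the component DAG is topologically sorted, and the
    descendant sets are propagated bottom-up as bitsets, so the cost is
    O(C * E_c / 64) instead of one BFS per node.
    """
    adj, _ = _adjacency(net)
    nc, labels = connected_components(adj, connection="strong", directed=True)
    sizes = np.bincount(labels, minlength=nc)
    coo = adj.tocoo()
    dag: dict[int, set[int]] = {}
    indeg = np.zeros(nc, dtype=np.int64)
    for cu, cv in zip(labels[coo.row].tolist(), labels[coo.col].tolist()):
        if cu != cv:
            succ = dag.setdefault(cu, set())
            if cv not in succ:
                succ.add(cv)
                indeg[cv] += 1
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    order: list[int] = []
    while queue:
        c = queue.popleft()
        order.append(c)
        for w in dag.get(c, ()):
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    reach: list[int] = [0] * nc
    for c in reversed(order):
        bits = 1 << c
        for w in dag.get(c, ()):
            bits |= reach[w]
        reach[c] = bits
    reach_size = np.zeros(nc, dtype=np.int64)
    for c in range(nc):
        bits = reach[c]
        total = 0
        while bits:
            low = bits & -bits
            total += sizes[low.bit_length() - 1]
            bits ^= low
        reach_size[c] = total
    return reach_size[labels] - 1


def _require_node(net: Network, i: str) -> None:
    if i not in net:
        raise LookupNodeError(f"node {i!r} not in network")


def _as_directed(net: Network) -> Network:
    return net if net.directed else to_bidirected(net)


# ---------------------------------------------------------------------------
# Local reaching centralities
# ---------------------------------------------------------------------------

def local_reach_directed(net: Network, i: str) -> float:
    """Fraction of other nodes reachable from ``i`` via outgoing edges."""
    _require_node(net, i)
    if net.N == 1:
        logger.warning("single-node network: local reaching centrality is 0 by convention")
        return 0.0
    net = _as_directed(net)
    # single-source BFS over the successor lists
    succ: dict[str, list[str]] = {}
    for u, v in net.edges:
        succ.setdefault(u, []).append(v)
    seen = {i}
    frontier = [i]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in succ.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return (len(seen) - 1) / (net.N - 1)


def local_reach_weighted(net: Network, i: str) -> float:
    """Average-weight reach of ``i`` in a weighted directed graph.

    Each reachable ``j`` contributes the average edge weight of a maximum-
    weight shortest path ``i -> j``.  The maximum-weight path is found by
    dynamic programming over the BFS shortest-path DAG: processing nodes in
    order of increasing hop distance, the best total weight to ``v`` is the
    maximum over shortest-path predecessors ``u`` of ``best(u) + w(u, v)``.
    Ties in total weight give identical contributions, so tie-breaking is
    immaterial.
    """
    _require_node(net, i)
    if not net.directed:
        raise UsageError("weighted variant requires a directed network")
    if net.N == 1:
        logger.warning("single-node network: local reaching centrality is 0 by convention")
        return 0.0
    succ: dict[str, list[tuple[str, float]]] = {}
    for (u, v), w in net.edges.items():
        succ.setdefault(u, []).append((v, w))
    dist = {i: 0}
    best = {i: 0.0}
    frontier = [i]
    d = 0
    total = 0.0
    while frontier:
        d += 1
        nxt: dict[str, float] = {}
        for u in frontier:
            bu = best[u]
            for v, w in succ.get(u, ()):
                if v in dist and dist[v] < d:
                    continue  # not on a shortest path to v
                cand = bu + w
                if v not in nxt or cand > nxt[v]:
                    nxt[v] = cand
        for v, bw in nxt.items():
            dist[v] = d
            best[v] = bw
            total += bw / d
        frontier = list(nxt)
    return total / (net.N - 1)


def local_reach_undirected(net: Network, i: str) -> float:
    """Harmonic closeness of ``i`` normalized by ``N - 1``.

    Nodes outside ``i``'s connected component contribute 0, so the value is
    well defined on disconnected graphs.
    """
    _require_node(net, i)
    if net.directed:
        raise UsageError("undirected variant requires an undirected network")
    if net.N == 1:
        logger.warning("single-node network: local reaching centrality is 0 by convention")
        return 0.0
    adjac: dict[str, list[str]] = {}
    for u, v in net.edges:
        adjac.setdefault(u, []).append(v)
        adjac.setdefault(v, []).append(u)
    seen = {i}
    frontier = [i]
    d = 0
    total = 0.0
    while frontier:
        d += 1
        nxt: list[str] = []
        for u in frontier:
            for v in adjac.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        total += len(nxt) / d
        frontier = nxt
    return total / (net.N - 1)


# ---------------------------------------------------------------------------
# Profiles and the GRC
# ---------------------------------------------------------------------------

def reach_profile(net: Network, variant: str = "directed") -> ReachProfile:
    """Compute local reaching centralities for every node, plus the GRC.

    The directed variants accept an undirected input by first expanding it to
    its bidirected equivalent, which treats mutual influence symmetrically;
    the ``weighted`` variant insists on a genuinely directed network, and the
    ``undirected`` variant on an undirected one.
    """
    if variant not in VARIANTS:
        raise UsageError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant == "weighted" and not net.directed:
        raise UsageError("weighted variant requires a directed network")
    if variant == "undirected" and net.directed:
        raise UsageError("undirected variant requires an undirected network")

    if net.N == 1:
        values = {net.nodes[0]: 0.0}
        return ReachProfile(values=values, variant=variant, c_max=0.0, grc=0.0)

    n = net.N
    if variant == "directed":
        dnet = _as_directed(net)
        vals = _reach_counts(dnet) / (n - 1)
    elif variant == "undirected":
        dist = _hop_distances(net, directed=False)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
        vals = inv.sum(axis=1) / (n - 1)
    else:  # weighted
        vals = np.array([local_reach_weighted(net, i) for i in net.nodes])

    values = {node: float(v) for node, v in zip(net.nodes, vals)}
    c_max = float(vals.max())
    g = float((c_max - vals).sum() / (n - 1))
    return ReachProfile(values=values, variant=variant, c_max=c_max, grc=g)


def grc(net: Network, variant: str = "directed") -> float:
    """Convenience wrapper returning only the global reaching centrality."""
    return reach_profile(net, variant).grc


def reach_distribution(
    profile: ReachProfile, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Relative-frequency histogram of the local reaching centralities.

    Fixed-width bins on [0, 1] with a right-closed last bin; values above 1
    (possible for the weighted variant with weights above 1) are counted in
    the last bin.  Returns ``(bin_centers, relative_frequencies)`` with the
    frequencies summing to 1.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    vals = np.clip(np.fromiter(profile.values.values(), dtype=float), 0.0, 1.0)
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / counts.sum()
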