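"""Seeded random-graph generators, including the adjustable-hierarchy model.

Four families are provided, all directed and all deterministic given a seed:

* :func:`er_digraph` — Erdős–Rényi digraphs with an exact edge count
  ``round(k * N)``, so the user-facing knob is the average degree ``k``.
* :func:`sf_digraph` — scale-free digraphs built with the static model: node
  ``i`` (rank ``i + 1``) is chosen as an endpoint with probability
  proportional to ``rank ** (-alpha)``, ``alpha = 1 / (gamma - 1)``,
  independently for sources and targets, which yields degree exponent
  ``gamma`` for large N.
* :func:`random_arborescence` — spanning directed trees grown breadth-first
  with a per-node branching number drawn uniformly from ``{1, ..., b_max}``;
  all edges point from the root towards the leaves.
* :func:`ah_network` — the adjustable-hierarchy (AH) model: an arborescence
  backbone plus extra random edges, a fraction ``p`` of which are constrained
  to point strictly downwards in the backbone's level structure and therefore
  leave the hierarchy intact.  ``p`` tunes the graph continuously from
  ER-like (p = 0) to strongly hierarchical (p = 1).

Levels are counted from the bottom: the deepest nodes have level 1 and the
root's level equals the number of levels, so every backbone edge goes from
some level ``l`` to level ``l - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, RandomizationError
from .graph_core import Network

__all__ = ["AHGraph", "random_arborescence", "er_digraph", "sf_digraph", "ah_network"]


@dataclass(frozen=True)
class AHGraph:
    """A network together with the backbone arborescence that defines it.

    Attributes
    ----------
    net
        The full directed network (backbone plus extra edges).
    levels
        Node -> integer hierarchy level; leaves of the deepest branch are at
        level 1 and the root at the top.
    p
        Fraction of extra edges constrained to point down the hierarchy.
    backbone
        The arborescence edge subset (``N - 1`` edges spanning all nodes).
    """

    net: Network
    levels: dict[str, int]
    p: float
    backbone: frozenset[tuple[str, str]]


def _node_labels(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


def random_arborescence(N: int, b_max: int = 5, seed: int | None = None) -> AHGraph:
    """Spanning arborescence with random branching numbers.

    Nodes are expanded breadth-first from the root; each expanded node
    receives a child count drawn uniformly from ``{1, ..., b_max}``, truncated
    once ``N`` nodes exist.  Because every node keeps producing at least one
    child, the tree always reaches ``N`` nodes.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    if b_max < 1:
        raise ParameterError("b_max must be >= 1")
    rng = np.random.default_rng(seed)
    labels = _node_labels(N)
    edges: dict[tuple[str, str], float] = {}
    depth = {labels[0]: 0}
    queue = [labels[0]]
    next_id = 1
    qi = 0
    while next_id < N:
        parent = queue[qi]
        qi += 1
        b = int(rng.integers(1, b_max + 1))
        for _ in range(b):
            if next_id >= N:
                break
            child = labels[next_id]
            next_id += 1
            edges[(parent, child)] = 1.0
            depth[child] = depth[parent] + 1
            queue.append(child)
    net = Network(nodes=labels, edges=edges, directed=True)
    max_depth = max(depth.values())
    levels = {n: max_depth - d + 1 for n, d in depth.items()}
    return AHGraph(net=net, levels=levels, p=1.0, backbone=frozenset(edges))


def _distinct_random_pairs(
    N: int,
    m: int,
    rng: np.random.Generator,
    *,
    endpoint_p: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Sample ``m`` distinct ordered non-self pairs from ``{0..N-1}^2``.

    With ``endpoint_p`` given, sources and targets are drawn independently
    from that distribution (rejecting collisions); otherwise uniformly.
    """
    if m > N * (N - 1):
        raise ParameterError(f"requested {m} edges but only {N * (N - 1)} distinct pairs exist")
    chosen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    # batched draws keep the rejection loop vectorized
    while len(out) < m:
        batch = max(2 * (m - len(out)), 64)
        if endpoint_p is None:
            us = rng.integers(0, N, size=batch)
            vs = rng.integers(0, N, size=batch)
        else:
            us = rng.choice(N, size=batch, p=endpoint_p)
            vs = rng.choice(N, size=batch, p=endpoint_p)
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v:
                continue
            pair = (u, v)
            if pair in chosen:
                continue
            chosen.add(pair)
            out.append(pair)
            if len(out) == m:
                break
    return out


def er_digraph(N: int, k: float, seed: int | None = None) -> Network:
    """Erdős–Rényi digraph with exactly ``round(k * N)`` directed edges."""
    if N < 2:
        raise ParameterError("N must be >= 2")
    if not (0 <= k <= N - 1):
        raise ParameterError("mean degree k must satisfy 0 <= k <= N - 1")
    rng = np.random.default_rng(seed)
    m = round(k * N)
    labels = _node_labels(N)
    pairs = _distinct_random_pairs(N, m, rng)
    edges = {(labels[u], labels[v]): 1.0 for u, v in pairs}
    return Network(nodes=labels, edges=edges, directed=True)


def sf_digraph(N: int, k: float, gamma: float = 3.0, seed: int | None = None) -> Network:
    """Scale-free digraph (static model) with ``round(k * N)`` edges.

    As ``gamma -> inf`` the endpoint distribution flattens and the model
    approaches :func:`er_digraph`.
    """
    if N < 2:
        raise ParameterError("N must be >= 2")
    if gamma <= 2:
        raise ParameterError("degree exponent gamma must be > 2")
    if not (0 < k <= N - 1):
        raise ParameterError("mean degree k must satisfy 0 < k <= N - 1")
    rng = np.random.default_rng(seed)
    m = round(k * N)
    alpha = 1.0 / (gamma - 1.0)
    weights = np.arange(1, N + 1, dtype=float) ** (-alpha)
    weights /= weights.sum()
    labels = _node_labels(N)
    pairs = _distinct_random_pairs(N, m, rng, endpoint_p=weights)
    edges = {(labels[u], labels[v]): 1.0 for u, v in pairs}
    return Network(nodes=labels, edges=edges, directed=True)


def ah_network(
    N: int,
    k: float,
    p: float,
    b_max: int = 5,
    seed: int | None = None,
) -> AHGraph:
    """Adjustable-hierarchy network: arborescence backbone plus random edges.

    ``round(k * N) - (N - 1)`` extra edges are added to the backbone.  Each
    extra edge is, with probability ``p``, a "down" edge — a uniformly chosen
    pair with a strictly higher source level, skipped if that pair is already
    connected in that direction — and otherwise a fully random non-self pair,
    again avoiding exact duplicates.  Down edges never disturb the backbone's
    level structure, so ``p`` directly controls how much of the added noise
    respects the hierarchy.
    """
    if not (0 <= p <= 1):
        raise ParameterError("p must lie in [0, 1]")
    m_total = round(k * N)
    n_extra = m_total - (N - 1)
    if n_extra < 0:
        raise ParameterError(
            f"mean degree k={k} too small: backbone alone needs {N - 1} edges "
            f"but round(k*N)={m_total}"
        )
    rng = np.random.default_rng(seed)
    backbone = random_arborescence(N, b_max=b_max, seed=rng)
    labels = backbone.net.nodes
    levels = backbone.levels
    level_arr = np.array([levels[n] for n in labels])
    edges = dict(backbone.net.edges)

    # the down/random decision is made once per edge so that the realized
    # down fraction is binomial(p); only the pair draw is rejection-sampled
    max_attempts = max(100 * n_extra, 1000)
    attempts = 0
    for _ in range(n_extra):
        down = bool(rng.random() < p)
        while True:
            if attempts >= max_attempts:
                raise RandomizationError(
                    f"could not place {n_extra} extra edges after {attempts} attempts; "
                    "the graph is too dense for the requested parameters"
                )
            attempts += 1
            u, v = rng.integers(0, N, size=2)
            if u == v:
                continue
            if down and level_arr[u] <= level_arr[v]:
                continue
            key = (labels[u], labels[v])
            if key in edges:
                continue
            edges[key] = 1.0
            break

    net = Network(nodes=labels, edges=edges, directed=True)
    return AHGraph(net=net, levels=levels, p=float(p), backbone=backbone.backbone)
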