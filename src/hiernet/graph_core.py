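"""Graph data model and plain-text / GraphML I/O.

The single in-memory representation used throughout the package is
:class:`Network`: an ordered node set plus a mapping from ordered node pairs
to positive edge weights, with a graph-level ``directed`` flag.  Node
identifiers are opaque strings; all algorithms are independent of any
internal indexing.

The canonical on-disk format is a UTF-8 edge list::

    # comment
    #node<TAB>lonely_id        (declares an isolated node)
    source<TAB>target[<TAB>weight]

Fields may be separated by any run of whitespace.  Self-loops are dropped at
load (they are inert for reaching centrality, which never counts a node as
reaching itself) and duplicate ``(source, target)`` records are collapsed
keeping the maximum weight, so that edge counts and the average degree
``<k> = E / N`` stay meaningful.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import EdgeListParseError, UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "to_bidirected",
]


@dataclass(frozen=True)
class Network:
    """An immutable directed or undirected graph with positive edge weights.

    Parameters
    ----------
    nodes
        Node identifiers in a fixed, deterministic order.
    edges
        Mapping ``(source, target) -> weight``.  For undirected networks each
        edge is stored once under an arbitrary but fixed orientation.
    directed
        Whether edge direction is meaningful.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    directed: bool = True
    _node_set: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        node_set = frozenset(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        if not self.nodes:
            raise ValidationError("a network must have at least one node")
        seen: set[tuple[str, str]] = set()
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u!r}, {v!r}) uses unknown node")
            if not (w > 0) or math.isinf(w):
                raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")
            key = (u, v) if self.directed else (min(u, v), max(u, v))
            if key in seen:
                raise ValidationError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
        object.__setattr__(self, "_node_set", node_set)

    # -- basic accessors ---------------------------------------------------
    @property
    def N(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def E(self) -> int:
        """Number of edges (directed-edge count for directed networks)."""
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        """Average degree ``<k> = E / N``."""
        return self.E / self.N

    def __contains__(self, node: str) -> bool:
        return node in self._node_set

    def has_edge(self, u: str, v: str) -> bool:
        if self.directed:
            return (u, v) in self.edges
        return (u, v) in self.edges or (v, u) in self.edges

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> "nx.DiGraph | nx.Graph":
        """Export to a :mod:`networkx` graph with ``weight`` edge attributes."""
        g: nx.DiGraph | nx.Graph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g

    @classmethod
    def from_networkx(cls, g: "nx.DiGraph | nx.Graph") -> "Network":
        directed = g.is_directed()
        nodes = tuple(str(n) for n in g.nodes)
        edges: dict[tuple[str, str], float] = {}
        for u, v, data in g.edges(data=True):
            if str(u) == str(v):
                continue
            edges[(str(u), str(v))] = float(data.get("weight", 1.0))
        return cls(nodes=nodes, edges=edges, directed=directed)

    @classmethod
    def from_edges(
        cls,
        edge_iter: Iterable[tuple[str, str] | tuple[str, str, float]],
        *,
        directed: bool = True,
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from an iterable of ``(u, v[, w])`` tuples.

        Self-loops are dropped and duplicates collapsed keeping the maximum
        weight, mirroring the file reader's behaviour.
        """
        nodes: list[str] = []
        seen: set[str] = set()
        edges: dict[tuple[str, str], float] = {}

        def add_node(n: str) -> None:
            if n not in seen:
                seen.add(n)
                nodes.append(n)

        n_loops = 0
        for rec in edge_iter:
            u, v = str(rec[0]), str(rec[1])
            w = float(rec[2]) if len(rec) == 3 else 1.0
            add_node(u)
            add_node(v)
            if u == v:
                n_loops += 1
                continue
            key = (u, v) if directed else (min(u, v), max(u, v))
            edges[key] = max(w, edges.get(key, 0.0))
        for n in extra_nodes:
            add_node(str(n))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        return cls(nodes=tuple(nodes), edges=edges, directed=directed)


# ---------------------------------------------------------------------------
# Edge-list format
# ---------------------------------------------------------------------------

def read_edge_list(
    source: str | io.TextIOBase,
    *,
    directed: bool = True,
    weighted: bool = False,
    reverse: bool = False,
) -> Network:
    """Parse an edge list into a :class:`Network`.

    Parameters
    ----------
    source
        Text content, or an open text stream.
    directed
        Interpret records as ordered pairs.
    weighted
        Expect a third positive-real weight column.
    reverse
        Flip every edge at load.  Useful when a dataset's arrow convention is
        the opposite of "the source influences the target", which is the
        orientation reaching centrality assumes.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    records: list[tuple[str, str, float]] = []
    isolated: list[str] = []
    n_loops = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#node"):
            fields = line.split(None, 1)
            if len(fields) != 2 or not fields[1].strip():
                raise EdgeListParseError(lineno, "#node record without an identifier")
            isolated.append(fields[1].strip())
            continue
        if line.startswith("#"):
            continue
        fields = line.split()
        want = 3 if weighted else 2
        if len(fields) != want:
            raise EdgeListParseError(
                lineno, f"expected {want} fields, got {len(fields)}: {line!r}"
            )
        u, v = fields[0], fields[1]
        if weighted:
            try:
                w = float(fields[2])
            except ValueError:
                raise EdgeListParseError(lineno, f"weight {fields[2]!r} is not a number") from None
            if not (w > 0) or math.isinf(w) or math.isnan(w):
                raise ValidationError(f"line {lineno}: non-positive weight {fields[2]}")
        else:
            w = 1.0
        if reverse:
            u, v = v, u
        if u == v:
            n_loops += 1
            # still register the node
            records.append((u, u, w))
            continue
        records.append((u, v, w))
    net = Network.from_edges(records, directed=directed, extra_nodes=isolated)
    return net


def write_edge_list(net: Network) -> str:
    """Serialize a network; inverse of :func:`read_edge_list` up to ordering.

    Isolated nodes are written as ``#node<TAB>id`` records so the round trip
    preserves the node count.
    """
    touched = {n for edge in net.edges for n in edge}
    out: list[str] = []
    for (u, v), w in net.edges.items():
        if w == 1.0:
            out.append(f"{u}\t{v}")
        else:
            out.append(f"{u}\t{v}\t{w!r}")
    for n in net.nodes:
        if n not in touched:
            out.append(f"#node\t{n}")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# GraphML interchange
# ---------------------------------------------------------------------------

def read_graphml(path: str, *, reverse: bool = False) -> Network:
    """Load a network from GraphML; edge ``weight`` attributes are honoured."""
    g = nx.read_graphml(path)
    if isinstance(g, (nx.MultiDiGraph, nx.MultiGraph)):
        flat: nx.DiGraph | nx.Graph = nx.DiGraph() if g.is_directed() else nx.Graph()
        flat.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            if flat.has_edge(u, v):
                flat[u][v]["weight"] = max(flat[u][v]["weight"], w)
            else:
                flat.add_edge(u, v, weight=w)
        g = flat
    if reverse and g.is_directed():
        g = g.reverse()
    return Network.from_networkx(g)


def write_graphml(net: Network, path: str) -> None:
    nx.write_graphml(net.to_networkx(), path)


# ---------------------------------------------------------------------------
# Direction handling
# ---------------------------------------------------------------------------

def to_bidirected(net: Network) -> Network:
    """Expand an undirected network into its bidirected directed equivalent.

    Every undirected edge ``{i, j}`` becomes the pair ``i->j`` and ``j->i``
    with the same weight, which makes mutually connected nodes equivalent in
    the flow hierarchy.
    """
    if net.directed:
        raise UsageError("to_bidirected expects an undirected network")
    edges: dict[tuple[str, str], float] = {}
    for (u, v), w in net.edges.items():
        edges[(u, v)] = w
        edges[(v, u)] = w
    return Network(nodes=net.nodes, edges=edges, directed=True)
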