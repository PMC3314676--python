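"""Structural controllability: driver-node counting and its relation to GRC.

Under linear node dynamics, the minimum number of driver nodes ``N_D`` — the
nodes that must receive independent external signals for the network to be
fully controllable — equals ``N`` minus the size of a maximum matching of the
directed edge set viewed as a bipartite graph (an "out" copy of every node on
one side, an "in" copy on the other, one bipartite edge per directed edge),
with a floor of one driver even for perfectly matched networks.

Comparing ``n_D = N_D / N`` with the global reaching centrality across a set
of networks probes whether more hierarchical networks are harder or easier to
control under these dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
from scipy import stats

from .errors import ParameterError, UsageError
from .graph_core import Network
from .reaching import reach_profile

__all__ = ["ControllabilityResult", "driver_nodes", "grc_driver_correlation"]


@dataclass(frozen=True)
class ControllabilityResult:
    """Minimum driver-node count for linear node dynamics."""

    n_driver: int
    fraction: float
    matching_size: int


def driver_nodes(net: Network) -> ControllabilityResult:
    """Minimum driver nodes via maximum bipartite matching.

    The matching is computed exactly with Hopcroft–Karp on the out-copy /
    in-copy bipartite representation; the driver count, not the particular
    matching, is the meaningful output.
    """
    if not net.directed:
        raise UsageError("driver_nodes requires a directed network")
    bip = nx.Graph()
    top = [("out", u) for u in net.nodes]
    bip.add_nodes_from(top, bipartite=0)
    bip.add_nodes_from((("in", v) for v in net.nodes), bipartite=1)
    bip.add_edges_from((("out", u), ("in", v)) for u, v in net.edges)
    matching = nx.bipartite.hopcroft_karp_matching(bip, top_nodes=top)
    m = len(matching) // 2
    n_d = max(net.N - m, 1)
    return ControllabilityResult(n_driver=n_d, fraction=n_d / net.N, matching_size=m)


def grc_driver_correlation(
    nets: Sequence[Network],
    driver_fractions: Sequence[float] | None = None,
) -> float:
    """Pearson correlation between GRC and the driver-node fraction.

    Parameters
    ----------
    nets
        At least three directed networks.
    driver_fractions
        Optional externally computed ``n_D`` values (e.g. from an alternative
        controllability framework such as switchboard dynamics); when omitted
        they are derived from :func:`driver_nodes`.
    """
    if len(nets) < 3:
        raise ParameterError("need at least 3 networks for a correlation")
    grcs = [reach_profile(n, "directed").grc for n in nets]
    if driver_fractions is None:
        fracs = [driver_nodes(n).fraction for n in nets]
    else:
        if len(driver_fractions) != len(nets):
            raise ParameterError("driver_fractions length must match nets")
        fracs = [float(f) for f in driver_fractions]
    if len(set(grcs)) == 1 or len(set(fracs)) == 1:
        raise ParameterError("correlation undefined: zero variance in GRC or n_D")
    r, _ = stats.pearsonr(grcs, fracs)
    return float(r)
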