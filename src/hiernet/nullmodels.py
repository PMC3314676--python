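"""Degree-preserving randomization and the null-model hierarchy test.

To decide whether an observed global reaching centrality is a genuine
structural feature rather than a by-product of the degree sequence, the
original network is compared against an ensemble of randomized networks with
exactly the same node-wise in- and out-degrees.  Each replicate is built by
(1) a directed configuration-model stub matching (with self-loops and
duplicate edges repaired by re-pairing the offending stubs) and (2) a long
run of degree-preserving double-edge swaps — by default ten times as many
accepted swaps as there are edges — which washes out any residual correlation
from the stub matching.

The classification is a two-sided empirical-quantile test: with confidence
``c`` the original network is *hierarchical* when its GRC exceeds the upper
``(1 + c) / 2`` quantile of the randomized sample, *egalitarian* when it
falls below the lower ``(1 - c) / 2`` quantile, and *indistinct* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .errors import ParameterError, RandomizationError, UsageError
from .graph_core import Network
from .reaching import reach_profile

__all__ = ["SignificanceResult", "configuration_randomize", "grc_significance"]

#: accepted-swap multiplier: swaps performed = round(swap_factor * E)
DEFAULT_SWAP_FACTOR = 10.0


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of comparing a network's GRC against its degree-preserving null."""

    grc_original: float
    grc_random: tuple[float, ...]
    confidence: float
    classification: str  # "hierarchical" | "egalitarian" | "indistinct"

    @property
    def grc_random_mean(self) -> float:
        return float(np.mean(self.grc_random))


def _empirical_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Type-1 (inverse-CDF) empirical quantile of a pre-sorted sample."""
    n = len(sorted_vals)
    idx = max(ceil(q * n), 1) - 1
    return float(sorted_vals[min(idx, n - 1)])


def _stub_matching(
    out_stubs: list[int], in_stubs: list[int], rng: np.random.Generator, max_repair: int = 1000
) -> set[tuple[int, int]]:
    """Random pairing of out- and in-stubs avoiding self-loops and duplicates.

    Offending pairs are re-paired among themselves (plus a random good pair to
    break parity deadlocks); if the repair loop stalls, raise.
    """
    out_arr = np.array(out_stubs)
    in_arr = np.array(in_stubs)
    perm = rng.permutation(len(in_arr))
    pairs = list(zip(out_arr.tolist(), in_arr[perm].tolist()))

    for _ in range(max_repair):
        seen: set[tuple[int, int]] = set()
        bad_idx: list[int] = []
        for idx, (u, v) in enumerate(pairs):
            if u == v or (u, v) in seen:
                bad_idx.append(idx)
            else:
                seen.add((u, v))
        if not bad_idx:
            return seen
        # re-pair the bad stubs together with one random good pair
        extra = int(rng.integers(0, len(pairs)))
        pool = sorted(set(bad_idx) | {extra})
        outs = [pairs[i][0] for i in pool]
        ins = [pairs[i][1] for i in pool]
        shuffled = rng.permutation(len(ins))
        for slot, i in enumerate(pool):
            pairs[i] = (outs[slot], ins[shuffled[slot]])
    raise RandomizationError(
        "configuration-model stub matching failed to remove self-loops/duplicates"
    )


def _double_edge_swaps(
    edges: set[tuple[int, int]],
    n_swaps: int,
    rng: np.random.Generator,
    max_attempts: int,
) -> tuple[set[tuple[int, int]], int]:
    """Perform up to ``n_swaps`` accepted degree-preserving swaps.

    A swap picks two edges (a, b), (c, d) and rewires them to (a, d), (c, b);
    it is rejected when it would create a self-loop or a duplicate edge.
    Returns the edge set and the number of accepted swaps (which may fall
    short of ``n_swaps`` only for rigid graphs that admit no legal swap,
    e.g. a lone directed cycle).
    """
    edge_list = list(edges)
    edge_set = set(edges)
    accepted = 0
    attempts = 0
    m = len(edge_list)
    if m < 2:
        return edge_set, 0
    # draw candidate edge-pair indices in blocks; per-call RNG overhead would
    # otherwise dominate the whole randomization
    block: list[int] = []
    bi = 0
    while accepted < n_swaps and attempts < max_attempts:
        if bi >= len(block):
            block = rng.integers(0, m, size=8192).tolist()
            bi = 0
        i = block[bi]
        j = block[bi + 1]
        bi += 2
        attempts += 1
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if a == d or c == b:
            continue  # would create a self-loop
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i], edge_list[j] = e1, e2
        accepted += 1
    return edge_set, accepted


def configuration_randomize(
    net: Network,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int | np.random.Generator | None = None,
    *,
    full_output: bool = False,
) -> Network | tuple[Network, dict]:
    """Randomize a directed network preserving every node's in/out degree.

    Parameters
    ----------
    net
        Directed network; weights are ignored (the null model is unweighted).
    swap_factor
        Number of accepted double-edge swaps as a multiple of the edge count.
    seed
        Seed or generator for reproducibility.
    full_output
        Also return a dict with the accepted-swap count.
    """
    if not net.directed:
        raise UsageError("configuration_randomize requires a directed network")
    if net.E < 2:
        raise ParameterError("randomization needs at least 2 edges")
    rng = np.random.default_rng(seed)
    index = {n: i for i, n in enumerate(net.nodes)}
    out_stubs: list[int] = []
    in_stubs: list[int] = []
    for u, v in net.edges:
        out_stubs.append(index[u])
        in_stubs.append(index[v])
    edge_set = _stub_matching(out_stubs, in_stubs, rng)
    n_swaps = round(swap_factor * net.E)
    edge_set, accepted = _double_edge_swaps(
        edge_set, n_swaps, rng, max_attempts=max(100 * n_swaps, 1000)
    )
    labels = net.nodes
    edges = {(labels[u], labels[v]): 1.0 for u, v in edge_set}
    result = Network(nodes=labels, edges=edges, directed=True)
    if full_output:
        return result, {"accepted_swaps": accepted, "requested_swaps": n_swaps}
    return result


def grc_significance(
    net: Network,
    replicates: int = 100,
    confidence: float = 0.98,
    seed: int | None = None,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
) -> SignificanceResult:
    """Classify a network as hierarchical / egalitarian / indistinct.

    The GRC of ``net`` is compared against ``replicates`` degree-preserving
    randomizations, each generated from an independently spawned random
    stream, using a two-sided empirical-quantile test at the given
    confidence level.
    """
    if replicates < 2:
        raise ParameterError("need at least 2 replicates")
    if not (0 < confidence < 1):
        raise ParameterError("confidence must lie strictly between 0 and 1")
    grc_orig = reach_profile(net, "directed").grc
    streams = np.random.SeedSequence(seed).spawn(replicates)
    sample = []
    for ss in streams:
        rand_net = configuration_randomize(net, swap_factor=swap_factor, seed=np.random.default_rng(ss))
        sample.append(reach_profile(rand_net, "directed").grc)
    arr = np.sort(np.array(sample))
    lo = _empirical_quantile(arr, (1 - confidence) / 2)
    hi = _empirical_quantile(arr, (1 + confidence) / 2)
    if grc_orig > hi:
        classification = "hierarchical"
    elif grc_orig < lo:
        classification = "egalitarian"
    else:
        classification = "indistinct"
    return SignificanceResult(
        grc_original=grc_orig,
        grc_random=tuple(sample),
        confidence=confidence,
        classification=classification,
    )
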