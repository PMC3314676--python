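"""Hierarchy-based layered layout and ensemble-overlay density maps.

A graded local quantity — by default the local reaching centrality — induces
a layered drawing of the graph: nodes are sorted by the quantity and greedily
grouped into levels whose internal spread stays below a fraction ``z`` of the
graph-wide spread, levels are stacked bottom-to-top in order of increasing
mean, horizontally centred, and separated vertically by log-compressed gaps
proportional to the differences of consecutive level means (total height is
preserved).  Egalitarian graphs collapse into one or two nearby layers;
strongly hierarchical graphs spread into many well-separated layers with a
lone node at the top.

To compare graph *models* rather than single realizations, many single-graph
layouts are rescaled into the unit square, overlaid, and binned into a node
density grid (:func:`ensemble_density`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .graph_core import Network
from .reaching import reach_profile

__all__ = [
    "HierarchyLayout",
    "EnsembleDensity",
    "assign_levels",
    "hierarchy_layout",
    "ensemble_density",
]

#: level-grouping threshold used for the effectively discrete reaching
#: centrality: small enough that only near-identical values share a level,
#: while remaining robust to floating-point jitter (z = 0 would demand exact
#: equality)
DEFAULT_Z = 1e-6


@dataclass(frozen=True)
class HierarchyLayout:
    """Layered 2-D embedding of a graph driven by a local quantity."""

    levels: tuple[tuple[str, ...], ...]  # bottom -> top
    coords: dict[str, tuple[float, float]]
    z: float
    quantity: dict[str, float]


@dataclass(frozen=True)
class EnsembleDensity:
    """Node-count grid over the unit square from overlaid layouts."""

    grid: np.ndarray  # (G, G), grid[row, col]; row 0 is the bottom stripe
    n_graphs: int

    @property
    def mean_density(self) -> float:
        g = self.grid.shape[0]
        return float(self.grid.sum() / (g * g))


def _pstd(vals: list[float]) -> float:
    """Population standard deviation."""
    n = len(vals)
    mean = sum(vals) / n
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / n)


def assign_levels(quantity: dict[str, float], z: float) -> list[list[str]]:
    """Greedy bottom-up grouping of nodes into levels.

    Nodes are visited in increasing order of their quantity (ties broken by
    node id for determinism) and appended to the current level as long as the
    level's population standard deviation stays within ``z`` times the
    graph-wide standard deviation; the first violation closes the level.
    With ``z = 0`` only exactly equal values share a level.  A graph-wide
    standard deviation of zero (all values equal) yields a single level.
    """
    if z < 0:
        raise ParameterError("z must be >= 0")
    if not quantity:
        raise ParameterError("need at least one node")
    ordered = sorted(quantity, key=lambda n: (quantity[n], n))
    sigma_graph = _pstd([quantity[n] for n in ordered])
    if sigma_graph == 0.0:
        return [ordered]
    limit = z * sigma_graph
    levels: list[list[str]] = []
    current: list[str] = []
    current_vals: list[float] = []
    for node in ordered:
        trial = current_vals + [quantity[node]]
        if current and _pstd(trial) > limit:
            levels.append(current)
            current = [node]
            current_vals = [quantity[node]]
        else:
            current = current + [node]
            current_vals = trial
    levels.append(current)
    return levels


def hierarchy_layout(
    net: Network, variant: str = "directed", z: float = DEFAULT_Z
) -> HierarchyLayout:
    """Layered layout of ``net`` graded by a reaching-centrality variant.

    Within a level, nodes are placed on unit-spaced x positions with zero
    mean; all nodes of a level share a y coordinate.  The vertical gaps are
    first set proportional to the differences between consecutive level means
    (smallest gap = 1, the horizontal unit), then log-compressed as
    ``1 + log(gap / gap_min)`` and uniformly rescaled so the total height of
    the drawing is unchanged by the compression.
    """
    profile = reach_profile(net, variant)
    levels = assign_levels(profile.values, z)
    means = [sum(profile.values[n] for n in lev) / len(lev) for lev in levels]

    ys = [0.0]
    if len(levels) > 1:
        deltas = [means[i + 1] - means[i] for i in range(len(levels) - 1)]
        d_min = min(deltas)
        prop = [d / d_min for d in deltas]  # smallest gap -> unit spacing
        logged = [1.0 + math.log(pr) for pr in prop]
        scale = sum(prop) / sum(logged)  # keep the pre-log total height
        for g in logged:
            ys.append(ys[-1] + g * scale)

    coords: dict[str, tuple[float, float]] = {}
    for lev, y in zip(levels, ys):
        n = len(lev)
        for idx, node in enumerate(lev):
            coords[node] = (idx - (n - 1) / 2.0, y)
    return HierarchyLayout(
        levels=tuple(tuple(lev) for lev in levels),
        coords=coords,
        z=z,
        quantity=profile.values,
    )


def _rescale_unit_square(xy: np.ndarray) -> np.ndarray:
    """Affinely map positions into the unit square, centering flat axes."""
    out = np.empty_like(xy, dtype=float)
    for dim in range(2):
        lo, hi = xy[:, dim].min(), xy[:, dim].max()
        if hi > lo:
            out[:, dim] = (xy[:, dim] - lo) / (hi - lo)
        else:
            out[:, dim] = 0.5
    return out


def ensemble_density(
    layouts: list[HierarchyLayout] | tuple[HierarchyLayout, ...],
    grid_size: int = 64,
) -> EnsembleDensity:
    """Overlay layouts in the unit square and bin node positions.

    Each layout is rescaled to unit width and height (degenerate axes are
    centred at 0.5) and its node positions are accumulated on a
    ``grid_size x grid_size`` grid, so the grid total equals the combined
    node count of all layouts.
    """
    if not layouts:
        raise ParameterError("need at least one layout")
    if grid_size < 2:
        raise ParameterError("grid_size must be >= 2")
    grid = np.zeros((grid_size, grid_size), dtype=float)
    for lay in layouts:
        xy = np.array([lay.coords[n] for n in sorted(lay.coords)], dtype=float)
        unit = _rescale_unit_square(xy)
        cols = np.minimum((unit[:, 0] * grid_size).astype(int), grid_size - 1)
        rows = np.minimum((unit[:, 1] * grid_size).astype(int), grid_size - 1)
        np.add.at(grid, (rows, cols), 1.0)
    return EnsembleDensity(grid=grid, n_graphs=len(layouts))
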