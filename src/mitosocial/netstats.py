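"""Summary statistics of encounter networks.

Five statistics characterise each network's potential for exchange
through the mitochondrial population:

* **mean degree** — immediate neighbours per node, averaged over the
  number of nodes (isolated nodes included).
* **efficiency** — global network efficiency
  E(G) = 1/(n(n−1)) · Σ_{i≠j} 1/d(i, j), with d in unweighted hops and
  1/d = 0 for disconnected pairs; 1 iff the graph is complete.
* **diameter** — longest shortest path (in edges) between connected
  nodes; on disconnected graphs the largest connected component's
  diameter is reported, with the component count alongside so nothing
  is hidden.
* **mean betweenness** — mean over nodes of betweenness centrality
  (shortest paths between *other* node pairs passing through the node,
  endpoints excluded, tied shortest paths credited fractionally).  The
  raw (unnormalized) mean is the headline value; the
  (n−1)(n−2)/2-normalized mean is emitted alongside.
* **component count** — number of connected components; isolated nodes
  count as components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import networkx as nx
import numpy as np

from .network import EncounterNetwork

GraphLike = Union[EncounterNetwork, nx.Graph]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this graph (too few nodes/edges)."""


def _as_graph(g: GraphLike) -> nx.Graph:
    return g.graph if isinstance(g, EncounterNetwork) else g


@dataclass
class NetworkSummary:
    """The five network statistics plus size bookkeeping for one window."""

    mean_degree: float
    efficiency: float
    diameter: float
    mean_betweenness: float
    mean_betweenness_normalized: float
    n_components: int
    n_nodes: int
    n_edges: int
    window_end_frame: int = -1


def mean_degree(g: GraphLike, include_isolated: bool = True) -> float:
    """Mean node degree, 2·E/N.

    ``include_isolated=False`` restricts the average to nodes with at
    least one encounter, for comparison with pipelines that drop
    never-encountering tracks.
    """
    graph = _as_graph(g)
    degrees = [d for _, d in graph.degree]
    if not include_isolated:
        degrees = [d for d in degrees if d > 0]
    if not degrees:
        raise UndefinedStatisticError("mean degree undefined on an empty graph")
    return float(np.mean(degrees))


def efficiency(g: GraphLike) -> float:
    """Global efficiency E(G) in [0, 1]; disconnected pairs contribute 0."""
    graph = _as_graph(g)
    if graph.number_of_nodes() < 2:
        raise UndefinedStatisticError("efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(graph))


def diameter(g: GraphLike) -> int:
    """Largest-component diameter in edges.

    Undefined (raises) on edgeless graphs, where no two nodes are
    connected at all.
    """
    graph = _as_graph(g)
    if graph.number_of_nodes() < 2 or graph.number_of_edges() == 0:
        raise UndefinedStatisticError("diameter needs at least one edge")
    largest = max(nx.connected_components(graph), key=len)
    return int(nx.diameter(graph.subgraph(largest)))


def betweenness(g: GraphLike, normalized: bool = False) -> dict[int, float]:
    """Per-node betweenness centrality (endpoints excluded, ties fractional)."""
    return nx.betweenness_centrality(_as_graph(g), normalized=normalized)


def mean_betweenness(g: GraphLike, normalized: bool = False) -> float:
    """Mean betweenness centrality over nodes; 0 for graphs with < 3 nodes."""
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        raise UndefinedStatisticError("betweenness undefined on an empty graph")
    if graph.number_of_nodes() < 3:
        return 0.0
    return float(np.mean(list(betweenness(graph, normalized).values())))


def n_components(g: GraphLike) -> int:
    """Number of connected components (0 for the empty graph)."""
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        return 0
    return int(nx.number_connected_components(graph))


def summarize_network(net: EncounterNetwork, include_isolated: bool = True) -> NetworkSummary:
    """All five statistics for one network; undefined ones become NaN."""
    graph = net.graph

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedStatisticError:
            return float("nan")

    return NetworkSummary(
        mean_degree=_try(mean_degree, graph, include_isolated),
        efficiency=_try(efficiency, graph),
        diameter=_try(diameter, graph),
        mean_betweenness=_try(mean_betweenness, graph, False),
        mean_betweenness_normalized=_try(mean_betweenness, graph, True),
        n_components=n_components(graph),
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        window_end_frame=net.window[1],
    )


def summarize_series(series: Sequence[EncounterNetwork]) -> list[NetworkSummary]:
    """One :class:`NetworkSummary` per checkpoint network."""
    return [summarize_network(net) for net in series]
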