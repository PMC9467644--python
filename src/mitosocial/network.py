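"""Time-accumulating encounter ("social") networks.

Nodes are mitochondrial trajectories; an edge joins two trajectories
that were ever within a threshold distance (default 1.6 µm, just over
one mitochondrion's length) of each other in the same frame of the
observation window.  Networks only accumulate: extending the window or
raising the threshold can add edges but never remove them.

Edges are binary for the network statistics; the number of
co-localized frames is kept as an edge ``weight`` annotation only.  A
single sustained contact of k frames is one edge of weight k.  A single
contact frame suffices for an edge — no minimum contact duration is
imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from .config import DEFAULT_ENCOUNTER_THRESHOLD_UM
from .io import TrajectorySet
from .physical import coloc_time


@dataclass
class EncounterNetwork:
    """An encounter network for one cell and one observation window.

    ``graph`` is an undirected networkx graph whose nodes are track ids
    and whose edges carry a ``weight`` attribute (number of encounter
    frames).  Nodes include every track with at least one spot in the
    window, so tracks that never encounter anyone appear as isolated
    nodes.
    """

    graph: nx.Graph
    window: tuple[int, int]
    threshold_um: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)


def build_network(
    ts: TrajectorySet,
    threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM,
    window: Optional[tuple[int, int]] = None,
) -> EncounterNetwork:
    """Build the encounter network for ``window`` (whole video by default).

    The edge (i, j) is present iff tracks i and j are simultaneously
    present and within ``threshold_um`` in at least one frame of the
    window; its weight is the number of such frames.  This is exactly
    the positive-pair table of
    :func:`mitosocial.physical.coloc_time` at the same threshold and
    window.
    """
    if window is None:
        window = (0, max(ts.n_frames - 1, 0))
    lo, hi = window
    if lo < 0 or hi >= ts.n_frames:
        raise ValueError(f"window {window} outside observed frames [0, {ts.n_frames - 1}]")
    sub = ts.restrict_frames(lo, hi)
    g = nx.Graph()
    g.add_nodes_from(int(t) for t in sub.track_ids)
    table = coloc_time(ts, threshold_um, window=window)
    for row in table.itertuples(index=False):
        g.add_edge(int(row.track_i), int(row.track_j), weight=int(row.frames))
    return EncounterNetwork(graph=g, window=(lo, hi), threshold_um=threshold_um)


def network_series(
    ts: TrajectorySet,
    threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM,
    checkpoints: Optional[Sequence[int]] = None,
) -> list[EncounterNetwork]:
    """Networks for the nested windows [0, c] at each checkpoint frame c.

    Checkpoints must be ascending; by default the quarter, half,
    three-quarter and full window ends are used.  The returned edge
    sets are nested (networks accumulate).
    """
    if checkpoints is None:
        last = ts.n_frames - 1
        checkpoints = sorted({last // 4, last // 2, 3 * last // 4, last})
    cps = list(checkpoints)
    if any(b <= a for a, b in zip(cps, cps[1:])):
        raise ValueError("checkpoints must be strictly ascending")
    return [build_network(ts, threshold_um, window=(0, int(c))) for c in cps]


def write_edge_list(net: EncounterNetwork, path: str | Path) -> None:
    """Write a plain-text edge list: ``node_i<TAB>node_j<TAB>weight``."""
    lines = [
        f"{min(u, v)}\t{max(u, v)}\t{d['weight']}"
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: EncounterNetwork, path: str | Path) -> None:
    """Write the network as GraphML for interoperability."""
    nx.write_graphml(net.graph, str(path))
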