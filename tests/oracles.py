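"""Independent brute-force oracles for graph and trajectory statistics.

These deliberately avoid networkx and the package's own code paths:
graph quantities come from numpy Floyd–Warshall all-pairs distances and
adjacency-matrix-power shortest-path counting (a walk of minimal length
is necessarily a shortest path), and trajectory quantities from plain
pair-by-pair, frame-by-frame Python loops.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# graph oracles (nodes are 0..n-1, edges a list of (i, j) pairs)


def adjacency(n: int, edges) -> np.ndarray:
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def oracle_mean_degree(n: int, edges) -> float:
    return adjacency(n, edges).sum() / n


def oracle_efficiency(n: int, edges) -> float:
    d = floyd_warshall(adjacency(n, edges))
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return float((1.0 / d[finite]).sum() / (n * (n - 1)))


def oracle_components(n: int, edges) -> list[set[int]]:
    d = floyd_warshall(adjacency(n, edges))
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = set(np.flatnonzero(np.isfinite(d[i])).tolist())
        comps.append(comp)
        seen |= comp
    return comps


def oracle_n_components(n: int, edges) -> int:
    return len(oracle_components(n, edges))


def oracle_diameter_largest_component(n: int, edges) -> float:
    comps = oracle_components(n, edges)
    largest = sorted(max(comps, key=len))
    if len(largest) < 2:
        return float("nan")
    d = floyd_warshall(adjacency(n, edges))[np.ix_(largest, largest)]
    return float(d.max())


def shortest_path_counts(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[i, j] = number of shortest i-j paths, via matrix powers.

    (A^k)[i, j] counts walks of length k; for k = d(i, j) every minimal
    walk is a simple shortest path, so the count is exact.
    """
    n = len(a)
    finite = d[np.isfinite(d)]
    kmax = int(finite.max()) if len(finite) else 0
    powers = [np.eye(n)]
    for _ in range(kmax):
        powers.append(powers[-1] @ a)
    sigma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if np.isfinite(d[i, j]):
                sigma[i, j] = powers[int(d[i, j])][i, j]
    return sigma


def oracle_betweenness(n: int, edges) -> np.ndarray:
    """Unnormalized betweenness per node, endpoints excluded, unordered pairs."""
    a = adjacency(n, edges)
    d = floyd_warshall(a)
    sigma = shortest_path_counts(a, d)
    bc = np.zeros(n)
    idx = np.arange(n)
    for v in range(n):
        on_path = (
            np.isfinite(d)
            & np.isfinite(d[:, v])[:, None]
            & np.isfinite(d[v, :])[None, :]
            & (d[:, v][:, None] + d[v, :][None, :] == d)
        )
        on_path[v, :] = on_path[:, v] = False  # endpoints excluded
        on_path[idx, idx] = False
        contrib = np.outer(sigma[:, v], sigma[v, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(on_path, contrib / np.where(sigma > 0, sigma, 1.0), 0.0)
        bc[v] = frac.sum()
    return bc / 2.0  # ordered pairs counted twice


def random_graph(rng: np.random.Generator, max_nodes: int = 50):
    """A random Erdős–Rényi-style graph, sometimes sparse enough to disconnect."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.5))
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return n, edges


# ---------------------------------------------------------------------------
# trajectory oracles (operate on a TrajectorySet without using the package's
# vectorised statistics)


def _track_points(ts) -> dict[int, list[tuple[int, float, float]]]:
    out: dict[int, list[tuple[int, float, float]]] = {}
    for row in ts.spots.itertuples(index=False):
        out.setdefault(int(row.track_id), []).append((int(row.frame), row.x, row.y))
    for pts in out.values():
        pts.sort()
    return out


def oracle_track_speeds(ts) -> dict[int, float]:
    speeds = {}
    for tid, pts in _track_points(ts).items():
        steps = []
        for (f0, x0, y0), (f1, x1, y1) in zip(pts, pts[1:]):
            steps.append(math.hypot(x1 - x0, y1 - y0) / (f1 - f0))
        if steps:
            speeds[tid] = sum(steps) / len(steps)
    return speeds


def oracle_inter_mito_distance(ts) -> float:
    by_frame: dict[int, list[tuple[float, float]]] = {}
    for row in ts.spots.itertuples(index=False):
        by_frame.setdefault(int(row.frame), []).append((row.x, row.y))
    frame_means = []
    for pts in by_frame.values():
        if len(pts) < 2:
            continue
        nns = []
        for i, (xi, yi) in enumerate(pts):
            best = min(
                math.hypot(xi - xj, yi - yj)
                for j, (xj, yj) in enumerate(pts)
                if j != i
            )
            nns.append(best)
        frame_means.append(sum(nns) / len(nns))
    return sum(frame_means) / len(frame_means) if frame_means else float("nan")


def oracle_coloc_counts(ts, threshold: float, window=None) -> dict[tuple[int, int], int]:
    tracks = _track_points(ts)
    ids = sorted(tracks)
    counts: dict[tuple[int, int], int] = {}
    for a_i, i in enumerate(ids):
        pos_i = {f: (x, y) for f, x, y in tracks[i]}
        for j in ids[a_i + 1 :]:
            pos_j = {f: (x, y) for f, x, y in tracks[j]}
            c = 0
            for f, (xi, yi) in pos_i.items():
                if window is not None and not (window[0] <= f <= window[1]):
                    continue
                if f in pos_j:
                    xj, yj = pos_j[f]
                    if math.hypot(xi - xj, yi - yj) <= threshold:
                        c += 1
            if c > 0:
                counts[(i, j)] = c
    return counts
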