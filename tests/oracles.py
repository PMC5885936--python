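"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (DFS path
enumeration, hand-rolled BFS, layered shortest-path counting, dense
eigen-decomposition, exhaustive threshold scans) and shares no code with
the package's fast paths.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> dict[int, int]:
    """Plain BFS distance map from ``source`` over reachable nodes."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(adj[u]):
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_oracle(adj: np.ndarray) -> np.ndarray:
    """Component-rescaled closeness from raw BFS distances."""
    p = adj.shape[0]
    out = np.zeros(p)
    if p == 1:
        return out
    for v in range(p):
        dist = bfs_distances(adj, v)
        r = len(dist)
        if r == 1:
            continue
        s = sum(dist.values())
        out[v] = ((r - 1) / (p - 1)) * ((r - 1) / s)
    return out


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest simple path s..t, by exhaustive DFS (tiny graphs only)."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    target_len = dist[t]
    paths: list[tuple[int, ...]] = []
    stack = [(s, (s,))]
    while stack:
        u, path = stack.pop()
        if len(path) - 1 > target_len:
            continue
        if u == t:
            if len(path) - 1 == target_len:
                paths.append(path)
            continue
        for v in np.flatnonzero(adj[u]):
            v = int(v)
            if v not in path:
                stack.append((v, path + (v,)))
    return paths


def betweenness_enumeration_oracle(adj: np.ndarray) -> np.ndarray:
    """Betweenness by literally enumerating all shortest paths (<= ~8 nodes)."""
    p = adj.shape[0]
    out = np.zeros(p)
    for s, t in combinations(range(p), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def betweenness_counting_oracle(adj: np.ndarray) -> np.ndarray:
    """Betweenness via layered shortest-path counts (independent of Brandes'
    accumulation): sigma[s][v] summed over predecessors in BFS order, then
    pair-by-pair combination sigma_sv * sigma_vt / sigma_st."""
    p = adj.shape[0]
    dist = np.full((p, p), np.inf)
    sigma = np.zeros((p, p))
    for s in range(p):
        dmap = bfs_distances(adj, s)
        for v, d in dmap.items():
            dist[s, v] = d
        order = sorted(dmap, key=dmap.get)
        sigma[s, s] = 1.0
        for v in order:
            if v == s:
                continue
            for u in np.flatnonzero(adj[v]):
                u = int(u)
                if dist[s, u] == dist[s, v] - 1:
                    sigma[s, v] += sigma[s, u]
    out = np.zeros(p)
    for s, t in combinations(range(p), 2):
        if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(p):
            if v in (s, t):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                out[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return out


def eigenvector_oracle(adj: np.ndarray) -> np.ndarray:
    """Principal eigenvector via general (non-symmetric-path) decomposition."""
    if not adj.any():
        return np.zeros(adj.shape[0])
    w, v = np.linalg.eig(adj.astype(float))
    vec = np.abs(np.real(v[:, np.argmax(np.real(w))]))
    return vec / np.linalg.norm(vec)


def minimum_edges_scan_oracle(values: np.ndarray) -> int:
    """Smallest E such that the top-E positive-edge graph is connected,
    found by scanning E = 1..#positive edges with a BFS connectivity check."""
    p = values.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = values[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    order = np.argsort(-vals, kind="stable")
    iu, ju = iu[order], ju[order]
    for e in range(1, len(iu) + 1):
        adj = np.zeros((p, p), dtype=int)
        adj[iu[:e], ju[:e]] = 1
        adj[ju[:e], iu[:e]] = 1
        if len(bfs_distances(adj, 0)) == p:
            return e
    raise ValueError("not connectable")


def partial_corr_pair_oracle(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> float:
    """Partial correlation of x and y given covariates, via explicit
    normal-equation OLS residuals and the Pearson formula."""
    n = len(x)
    design = np.column_stack([np.ones(n), covariates])
    beta_x = np.linalg.solve(design.T @ design, design.T @ x)
    beta_y = np.linalg.solve(design.T @ design, design.T @ y)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    return float(
        (rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum())
    )
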