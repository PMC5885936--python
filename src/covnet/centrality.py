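"""Four node-centrality measures on binary undirected networks.

Conventions (fixed so that disconnected nodes behave like the published
brain-network tables, where a degree-0 node prints 0.000 for every measure):

- degree: number of incident edges.
- betweenness: unnormalized fractional shortest-path counts over unordered
  node pairs (Brandes semantics); unreachable pairs contribute 0.
- closeness: Wasserman–Faust component-rescaled form.  With ``r`` the size
  of the node's connected component, ``S`` the sum of shortest-path lengths
  to its reachable nodes, and ``p`` the node count:
  ``closeness = ((r - 1) / (p - 1)) * ((r - 1) / S)``; an isolated node has
  closeness 0; on a connected graph this reduces to ``(p - 1) / S``.
- eigenvector: entrywise non-negative principal eigenvector of the full
  (possibly disconnected) adjacency, unit Euclidean norm; a graph with no
  edges yields all zeros.  Mass concentrates on the component with the
  largest spectral radius, so nodes outside it (including isolated nodes)
  get ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from covnet.network import BinaryNetwork

MEASURES = ("degree", "betweenness", "closeness", "eigenvector")


@dataclass(frozen=True)
class CentralityTable:
    """Per-node values of the four centrality measures for one network."""

    labels: tuple[str, ...]
    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray

    def measure(self, name: str) -> np.ndarray:
        if name not in MEASURES:
            raise KeyError(name)
        return getattr(self, name)

    def as_matrix(self) -> np.ndarray:
        """4 × p array in the fixed measure order."""
        return np.vstack([self.degree, self.betweenness,
                          self.closeness, self.eigenvector])


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net)


def degree_values(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(float)


def betweenness_values(adj: np.ndarray) -> np.ndarray:
    ii, jj = np.nonzero(np.triu(adj, k=1))
    g = ig.Graph(n=adj.shape[0], edges=list(zip(ii.tolist(), jj.tolist())))
    return np.asarray(g.betweenness(directed=False), dtype=float)


def closeness_values(adj: np.ndarray) -> np.ndarray:
    p = adj.shape[0]
    if p == 1:
        return np.zeros(1)
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    finite = np.isfinite(dist)
    r = finite.sum(axis=1).astype(float)  # includes self
    s = np.where(finite, dist, 0.0).sum(axis=1)
    out = np.zeros(p)
    reach = r > 1
    out[reach] = ((r[reach] - 1) / (p - 1)) * ((r[reach] - 1) / s[reach])
    return out


def eigenvector_values(adj: np.ndarray) -> np.ndarray:
    if not adj.any():
        return np.zeros(adj.shape[0])
    _, vecs = np.linalg.eigh(adj.astype(float))
    vec = np.abs(vecs[:, -1])
    return vec / np.linalg.norm(vec)


def degree_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Per-node edge counts."""
    return degree_values(_adj(net))


def betweenness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized fractional shortest-path betweenness."""
    return betweenness_values(_adj(net))


def closeness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Component-rescaled closeness in [0, 1]."""
    return closeness_values(_adj(net))


def eigenvector_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Non-negative unit-norm principal eigenvector of the adjacency."""
    return eigenvector_values(_adj(net))


def centrality_matrix(adj: np.ndarray) -> np.ndarray:
    """All four measures as a 4 × p array (degree, betweenness, closeness,
    eigenvector) — the fast path used by the resampling loops."""
    return np.vstack([
        degree_values(adj),
        betweenness_values(adj),
        closeness_values(adj),
        eigenvector_values(adj),
    ])


def centrality_profile(net: BinaryNetwork) -> CentralityTable:
    """All four measures computed consistently on one network."""
    mat = centrality_matrix(net.adjacency)
    return CentralityTable(net.labels, mat[0], mat[1], mat[2], mat[3])
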