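"""Partial-correlation matrices and wiring-cost-matched binary networks.

A group's structural covariance network is built in three steps:

1. residualize each region's thickness on the covariates (with intercept),
2. Pearson-correlate the residual columns pairwise (the standard estimator
   of partial correlation given a set of controls),
3. binarize by keeping the ``E`` largest strictly positive partial
   correlations, where ``E`` is matched across groups.

Matching uses the connectivity (percolation) threshold: for each group the
minimum number of edges ``E_min`` — adding positive correlations in
descending order — at which the graph first spans all nodes in one
component; the largest ``E_min`` across groups becomes the common edge
count, so all groups have exactly equal wiring cost ``E / (p(p-1)/2)``.
Negative and zero partial correlations are never eligible as edges.

Ties at the binarization cutoff are broken by lexicographic node-pair order,
which makes every network bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    """Covariate-adjusted correlation matrix for one group."""

    values: np.ndarray  # p x p, symmetric, unit diagonal
    n_subjects: int
    k_covariates: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = v.shape[0]
        if v.shape != (p, p) or p != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.abs(v) > 1 + 1e-10):
            raise ValueError("correlation outside [-1, 1]")
        if self.residual_df < 1:
            raise ValueError("residual degrees of freedom < 1")
        object.__setattr__(self, "values", v)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def residual_df(self) -> int:
        return self.n_subjects - self.k_covariates - 2


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted region graph at a fixed edge count."""

    adjacency: np.ndarray  # p x p symmetric 0/1, zero diagonal
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def wiring_cost(self) -> float:
        return wiring_cost_of(self)


def residualize(data: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Remove the least-squares fit on [intercept, covariates] from each column.

    With no covariates this is plain column-mean centering.  Output columns
    are orthogonal to the intercept and to every covariate column.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if covariates is None or covariates.size == 0:
        return data - data.mean(axis=0)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    design = np.column_stack([np.ones(n), cov])
    if n <= design.shape[1]:
        raise ValueError("need n > k + 1 subjects to residualize")
    q, r = np.linalg.qr(design)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(r))):
        raise ValueError("rank-deficient covariate design")
    return data - q @ (q.T @ data)


def partial_corr_values(
    thickness: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """p × p partial-correlation matrix as a plain array (fast path)."""
    resid = residualize(thickness, covariates)
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance residual column {j}")
    values = np.corrcoef(resid, rowvar=False)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return values


def partial_correlation_matrix(
    thickness: np.ndarray,
    covariates: np.ndarray | None,
    labels: Sequence[str],
) -> PartialCorrelationMatrix:
    """Covariate-adjusted partial correlations for one group's subjects."""
    thickness = np.asarray(thickness, dtype=float)
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).reshape(
        thickness.shape[0], -1
    ).shape[1]
    if thickness.shape[0] < k + 3:
        raise ValueError(f"need n >= k + 3 subjects (n={thickness.shape[0]}, k={k})")
    return PartialCorrelationMatrix(
        partial_corr_values(thickness, covariates),
        n_subjects=thickness.shape[0],
        k_covariates=k,
        labels=tuple(labels),
    )


def ranked_positive_edges(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle strictly positive entries, strongest first.

    Ties are broken by lexicographic (i, j) node-pair order.  Returns the
    (i, j) index arrays in rank order.
    """
    p = values.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = values[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


class _UnionFind:
    __slots__ = ("parent", "count")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.count = n

    def find(self, a: int) -> int:
        parent = self.parent
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            self.count -= 1


def minimum_edge_count(pcm: PartialCorrelationMatrix | np.ndarray) -> tuple[int, float]:
    """Connectivity threshold: edges needed for one spanning component.

    Adds strictly positive correlations in descending order and returns
    ``(E_min, cost)`` at the first point where the graph connects all p
    nodes.  Raises if the positive edges cannot connect the graph.
    """
    values = pcm.values if isinstance(pcm, PartialCorrelationMatrix) else np.asarray(pcm)
    p = values.shape[0]
    if p < 2:
        raise ValueError("need at least two regions")
    ii, jj = ranked_positive_edges(values)
    uf = _UnionFind(p)
    for e, (i, j) in enumerate(zip(ii, jj), start=1):
        uf.union(int(i), int(j))
        if uf.count == 1:
            return e, e / (p * (p - 1) / 2)
    raise ValueError(
        "not connectable: positive partial correlations do not span all regions"
    )


def matched_edge_count(pcms: Sequence[PartialCorrelationMatrix | np.ndarray]) -> int:
    """Common edge count: the largest per-group connectivity threshold."""
    if not pcms:
        raise ValueError("no matrices given")
    return max(minimum_edge_count(pcm)[0] for pcm in pcms)


def binarize_top_edges(
    pcm: PartialCorrelationMatrix | np.ndarray,
    e_target: int,
    labels: Sequence[str] | None = None,
) -> BinaryNetwork:
    """Keep exactly the ``e_target`` largest strictly positive correlations."""
    if isinstance(pcm, PartialCorrelationMatrix):
        values = pcm.values
        labels = pcm.labels if labels is None else tuple(labels)
    else:
        values = np.asarray(pcm)
        if labels is None:
            labels = tuple(f"n{i}" for i in range(values.shape[0]))
    adj = binarize_top_edges_values(values, e_target)
    return BinaryNetwork(adj, tuple(labels))


def binarize_top_edges_values(values: np.ndarray, e_target: int) -> np.ndarray:
    """Adjacency-only fast path for :func:`binarize_top_edges`."""
    ii, jj = ranked_positive_edges(values)
    if len(ii) < e_target:
        raise ValueError(
            f"insufficient positive edges: {len(ii)} available, {e_target} requested"
        )
    p = values.shape[0]
    adj = np.zeros((p, p), dtype=np.int8)
    ii, jj = ii[:e_target], jj[:e_target]
    adj[ii, jj] = 1
    adj[jj, ii] = 1
    return adj


def wiring_cost_of(network: BinaryNetwork) -> float:
    """Fraction of realized edges: E / (p(p-1)/2)."""
    p = network.p
    return network.edge_count / (p * (p - 1) / 2)
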