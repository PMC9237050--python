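"""Connectome preprocessing and structural graph measures.

Thresholding removes the weakest streamline counts (<= 3 by default); the
homeostatic normalization divides every row of the count matrix by its sum so
each node's total incoming weight is 1.  Graph measures (average degree,
Louvain modularity, global efficiency, structural entropy) are computed on
the binary undirected adjacency of the thresholded matrix.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from neurocrit.synthetic import Parcellation

__all__ = [
    "RawConnectome",
    "NormalizedConnectome",
    "GraphMetrics",
    "threshold_connectome",
    "homeostatic_normalize",
    "graph_metrics",
    "structural_entropy",
    "recovery_index",
]


@dataclass
class RawConnectome:
    """Symmetric nonnegative streamline-count matrix plus metadata."""

    W: np.ndarray
    parcellation: Parcellation
    subject_id: str = "unknown"
    timepoint: str = "t1"

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.array_equal(W, W.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("connectome matrix must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("streamline counts must be nonnegative")
        self.W = W

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class NormalizedConnectome:
    """Row-normalized weights W~ plus the undirected binary adjacency."""

    W_tilde: np.ndarray
    adjacency: np.ndarray            # bool, symmetric
    isolated_nodes: np.ndarray       # int indices with zero row sum
    parcellation: Parcellation
    subject_id: str = "unknown"
    timepoint: str = "t1"

    @property
    def n_nodes(self) -> int:
        return self.W_tilde.shape[0]


@dataclass
class GraphMetrics:
    K: float          # average binary degree
    Q: float          # Newman modularity (NaN when undefined)
    E_global: float   # global efficiency, disconnected pairs contribute 0
    H_SC: float       # connectivity disorder (normalized entropy)


def threshold_connectome(raw: RawConnectome, min_streamlines: int = 3) -> RawConnectome:
    """Zero out the weakest connections (entries <= min_streamlines)."""
    W = raw.W.copy()
    W[W <= min_streamlines] = 0
    if not np.any(W):
        warnings.warn(
            f"thresholding at <= {min_streamlines} left a fully disconnected "
            f"matrix for subject {raw.subject_id}",
            stacklevel=2,
        )
    return dataclasses.replace(raw, W=W)


def homeostatic_normalize(raw: RawConnectome) -> NormalizedConnectome:
    """Divide each row by its sum; zero rows stay zero and are flagged isolated."""
    W = raw.W.astype(float)
    row_sums = W.sum(axis=1)
    isolated = np.flatnonzero(row_sums == 0)
    safe = np.where(row_sums == 0, 1.0, row_sums)
    W_tilde = W / safe[:, None]
    adjacency = raw.W > 0
    return NormalizedConnectome(
        W_tilde=W_tilde,
        adjacency=adjacency,
        isolated_nodes=isolated,
        parcellation=raw.parcellation,
        subject_id=raw.subject_id,
        timepoint=raw.timepoint,
    )


def structural_entropy(W_tilde: np.ndarray, bins: int = 100) -> float:
    """Normalized Shannon entropy of all N^2 entries of W~, binned on [0, 1]."""
    counts, _ = np.histogram(W_tilde, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(bins))


def _global_efficiency(adjacency: np.ndarray) -> float:
    n = adjacency.shape[0]
    if n < 2 or not adjacency.any():
        return 0.0
    d = shortest_path(csr_array(adjacency.astype(np.int8)), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0     # disconnected pairs and the diagonal
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _louvain_modularity(
    adjacency: np.ndarray, seed: int, n_restarts: int
) -> float:
    G = nx.from_numpy_array(adjacency.astype(int))
    best = -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        parts = nx.community.louvain_communities(
            G, weight=None, seed=int(rng.integers(2**31))
        )
        q = nx.community.modularity(G, parts, weight=None)
        best = max(best, q)
    return float(best)


def graph_metrics(
    norm: NormalizedConnectome,
    bins: int = 100,
    louvain_seed: int = 0,
    n_restarts: int = 20,
) -> GraphMetrics:
    """Average degree, Louvain modularity, global efficiency and entropy.

    Modularity keeps the best of ``n_restarts`` Louvain partitions (the
    algorithm is stochastic).  An empty adjacency yields K = E = H = 0 and
    Q = NaN.
    """
    A = norm.adjacency
    n = norm.n_nodes
    K = float(A.sum() / n)
    H_SC = structural_entropy(norm.W_tilde, bins=bins)
    if not A.any():
        return GraphMetrics(K=0.0, Q=float("nan"), E_global=0.0, H_SC=H_SC)
    E = _global_efficiency(A)
    Q = _louvain_modularity(A, louvain_seed, n_restarts)
    return GraphMetrics(K=K, Q=Q, E_global=E, H_SC=H_SC)


def recovery_index(metric_t2: float, metric_t1: float) -> float:
    """Longitudinal recovery index: value at t2 minus value at t1."""
    if not (np.isfinite(metric_t2) and np.isfinite(metric_t1)):
        raise ValueError("recovery_index requires finite inputs")
    return float(metric_t2) - float(metric_t1)
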