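"""Brute-force reference implementations used by oracle tests."""

import numpy as np


def brute_modularity(A, communities):
    """Direct double-sum evaluation of Newman modularity for a partition."""
    m = A.sum() / 2
    k = A.sum(axis=1)
    label = {}
    for ci, nodes in enumerate(communities):
        for v in nodes:
            label[v] = ci
    q = 0.0
    n = A.shape[0]
    for v in range(n):
        for w in range(n):
            if label[v] == label[w]:
                q += A[v, w] - k[v] * k[w] / (2 * m)
    return q / (2 * m)


def brute_efficiency(A):
    """All-pairs BFS global efficiency; disconnected pairs contribute zero."""
    n = A.shape[0]
    total = 0.0
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(A[u]):
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        total += sum(1.0 / dd for v, dd in dist.items() if v != src)
    return total / (n * (n - 1))
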