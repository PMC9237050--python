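"""Numba kernel for the 3-state excitable network simulation.

States are encoded 0 = inactive (I), 1 = active (A), 2 = refractory (R).
Propagation reads the previous step's states for every node (synchronous
update).  Incoming input to node i is the sum of row-normalized weights
W~[i, j] over active neighbours j; the kernel receives the CSR structure of
W~ transposed so that active nodes can push their outgoing (column) weights,
which is cheap when activity is sparse.  Cluster statistics use a union-find
over the undirected structural edge list restricted to simultaneously active
endpoints.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    tindptr,
    tindices,
    tdata,
    edge_u,
    edge_v,
    n,
    T,
    r1,
    r2,
    t_s,
    burn_in,
    seed,
    collect_hist,
):
    """Simulate one replicate; return (mean_A, sd_A, mean_S1, mean_S2, hist).

    ``hist[c]`` counts, over recorded steps, active clusters of size ``c``
    (only populated when ``collect_hist`` is true).
    """
    np.random.seed(seed)
    s = np.empty(n, np.int8)
    for i in range(n):
        s[i] = np.random.randint(0, 3)

    acc = np.zeros(n, np.float64)
    parent = np.empty(n, np.int64)
    size = np.empty(n, np.int64)
    hist = np.zeros(n + 1, np.int64)

    sum_a = 0.0
    sum_a2 = 0.0
    sum_s1 = 0.0
    sum_s2 = 0.0
    recorded = 0

    for t in range(t_s):
        # Input from the previous step's active nodes.
        for i in range(n):
            acc[i] = 0.0
        for j in range(n):
            if s[j] == 1:
                for k in range(tindptr[j], tindptr[j + 1]):
                    acc[tindices[k]] += tdata[k]

        for i in range(n):
            st = s[i]
            if st == 1:                      # A -> R with probability 1
                s[i] = 2
            elif st == 2:                    # R -> I with probability r2
                if np.random.random() < r2:
                    s[i] = 0
            else:                            # I -> A: threshold, else r1
                if acc[i] > T:
                    s[i] = 1
                elif np.random.random() < r1:
                    s[i] = 1

        if t < burn_in:
            continue

        a = 0
        for i in range(n):
            if s[i] == 1:
                a += 1
        sum_a += a
        sum_a2 += float(a) * a

        s1 = 0
        s2 = 0
        if a > 0:
            for i in range(n):
                parent[i] = i
                size[i] = 1
            for e in range(edge_u.size):
                u = edge_u[e]
                if s[u] != 1:
                    continue
                v = edge_v[e]
                if s[v] != 1:
                    continue
                ru = u
                while parent[ru] != ru:
                    parent[ru] = parent[parent[ru]]
                    ru = parent[ru]
                rv = v
                while parent[rv] != rv:
                    parent[rv] = parent[parent[rv]]
                    rv = parent[rv]
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
            for i in range(n):
                if s[i] == 1 and parent[i] == i:
                    c = size[i]
                    if collect_hist:
                        hist[c] += 1
                    if c > s1:
                        s2 = s1
                        s1 = c
                    elif c > s2:
                        s2 = c
        sum_s1 += s1
        sum_s2 += s2
        recorded += 1

    mean_a = sum_a / recorded
    var_a = sum_a2 / recorded - mean_a * mean_a
    sd_a = np.sqrt(var_a) if var_a > 0.0 else 0.0
    return mean_a, sd_a, sum_s1 / recorded, sum_s2 / recorded, hist
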