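"""Numba kernels for the small-worldness null ensembles.

These exist because sigma requires thousands of degree-preserving rewired
null graphs per experiment; the pure-Python equivalents (networkx) are the
test oracles. All kernels are deterministic given their integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rewire_edges(edges, n_nodes, n_attempts, seed):
    """Maslov–Sneppen double edge swap on an undirected simple graph.

    ``edges`` is an (E, 2) int64 array; modified in place. Each attempt
    picks two distinct edges and one of the two cross-pairings at random,
    rejecting swaps that would create self-loops or multi-edges. The degree
    sequence is preserved exactly. Returns the number of successful swaps.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for k in range(n_edges):
        adj[edges[k, 0], edges[k, 1]] = True
        adj[edges[k, 1], edges[k, 0]] = True
    successes = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose a-c, b-d
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, c] = adj[c, a] = True
        adj[b, d] = adj[d, b] = True
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        successes += 1
    return successes


@njit(cache=True)
def transitivity_from_edges(edges, n_nodes):
    """Global transitivity 3*triangles/triples; 0.0 if there are no triples."""
    n_edges = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    deg = np.zeros(n_nodes, dtype=np.int64)
    for k in range(n_edges):
        i, j = edges[k, 0], edges[k, 1]
        adj[i, j] = adj[j, i] = True
        deg[i] += 1
        deg[j] += 1
    closed = 0  # = 3 * number of triangles (each triangle has 3 edges)
    for k in range(n_edges):
        i, j = edges[k, 0], edges[k, 1]
        for v in range(n_nodes):
            if adj[i, v] and adj[j, v]:
                closed += 1
    triples = 0
    for i in range(n_nodes):
        triples += deg[i] * (deg[i] - 1) // 2
    if triples == 0:
        return 0.0, 0
    # each triangle is counted once per incident edge, so closed == 3*T
    return closed / triples, triples


@njit(cache=True)
def bfs_path_stats(indptr, indices, n_nodes):
    """All-pairs BFS. Returns (sum of distances, reached, unreached) over
    ordered pairs of distinct nodes."""
    total = 0
    reached = 0
    dist = np.empty(n_nodes, dtype=np.int64)
    queue = np.empty(n_nodes, dtype=np.int64)
    for src in range(n_nodes):
        dist[:] = -1
        dist[src] = 0
        queue[0] = src
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue[tail] = v
                    tail += 1
        for v in range(n_nodes):
            if v != src and dist[v] > 0:
                total += dist[v]
                reached += 1
    unreached = n_nodes * (n_nodes - 1) - reached
    return total, reached, unreached


@njit(cache=True)
def _csr_from_adj(adj, n_nodes, n_edges):
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    indices = np.empty(2 * n_edges, dtype=np.int64)
    pos = 0
    for i in range(n_nodes):
        for j in range(n_nodes):
            if adj[i, j]:
                indices[pos] = j
                pos += 1
        indptr[i + 1] = pos
    return indptr, indices


@njit(cache=True)
def _c_and_l(edges, adj, deg, n_nodes):
    """(transitivity, mean shortest path over reachable pairs) from the
    adjacency/degree scratch arrays."""
    closed = 0
    for k in range(edges.shape[0]):
        i, j = edges[k, 0], edges[k, 1]
        for v in range(n_nodes):
            if adj[i, v] and adj[j, v]:
                closed += 1
    triples = 0
    for i in range(n_nodes):
        triples += deg[i] * (deg[i] - 1) // 2
    c = closed / triples if triples > 0 else 0.0

    indptr, indices = _csr_from_adj(adj, n_nodes, edges.shape[0])
    total = 0
    reached = 0
    dist = np.empty(n_nodes, dtype=np.int64)
    queue = np.empty(n_nodes, dtype=np.int64)
    for src in range(n_nodes):
        dist[:] = -1
        dist[src] = 0
        queue[0] = src
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue[tail] = v
                    tail += 1
        for v in range(n_nodes):
            if v != src and dist[v] > 0:
                total += dist[v]
                reached += 1
    l = total / reached if reached > 0 else np.nan
    return c, l


@njit(cache=True)
def sigma_ensemble(edges, n_nodes, n_null, n_attempts, seed):
    """(C_g, L_g, C_rand, L_rand) for a graph and its rewired null ensemble.

    Runs the full Maslov–Sneppen ensemble in one compiled call; the target
    graph's edges are not modified.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    deg = np.zeros(n_nodes, dtype=np.int64)
    for k in range(n_edges):
        i, j = edges[k, 0], edges[k, 1]
        adj[i, j] = adj[j, i] = True
        deg[i] += 1
        deg[j] += 1
    c_g, l_g = _c_and_l(edges, adj, deg, n_nodes)

    c_sum = 0.0
    l_sum = 0.0
    work = np.empty_like(edges)
    for _ in range(n_null):
        work[:] = edges
        wadj = adj.copy()
        for _ in range(n_attempts):
            e1 = np.random.randint(n_edges)
            e2 = np.random.randint(n_edges)
            if e1 == e2:
                continue
            a, b = work[e1, 0], work[e1, 1]
            c, d = work[e2, 0], work[e2, 1]
            if np.random.randint(2) == 1:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if wadj[a, c] or wadj[b, d]:
                continue
            wadj[a, b] = wadj[b, a] = False
            wadj[c, d] = wadj[d, c] = False
            wadj[a, c] = wadj[c, a] = True
            wadj[b, d] = wadj[d, b] = True
            work[e1, 0], work[e1, 1] = a, c
            work[e2, 0], work[e2, 1] = b, d
        c_k, l_k = _c_and_l(work, wadj, deg, n_nodes)
        c_sum += c_k
        l_sum += l_k
    return c_g, l_g, c_sum / n_null, l_sum / n_null


def edges_to_csr(edges: np.ndarray, n_nodes: int):
    """Symmetric CSR (indptr, indices) from an (E, 2) edge array."""
    if edges.size == 0:
        return np.zeros(n_nodes + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    und = np.concatenate([edges, edges[:, ::-1]])
    order = np.lexsort((und[:, 1], und[:, 0]))
    und = und[order]
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.add.at(indptr, und[:, 0] + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, np.ascontiguousarray(und[:, 1])
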