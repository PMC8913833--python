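"""Numba kernels for binary-graph metrics and degree-preserving rewiring.

These are the hot loops: a single analysis evaluates efficiencies on
10^5-10^6 small graphs (null ensembles inside permutation tests), so the
kernels work on plain uint8 adjacency matrices, reuse preallocated
workspace buffers, and avoid any per-call object construction.  All public
wrappers live in :mod:`metabnet.metrics`.

Randomness: the swap loop is RNG-bound, so kernels use an inline
xorshift64* generator (state seeded from the caller's 31-bit seed via
splitmix64).  This is deterministic, platform-independent, and an order of
magnitude cheaper than the Mersenne Twister behind np.random.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK31 = 0x7FFFFFFF
_U64 = np.uint64


@njit(cache=True)
def _seed_state(seed):
    """splitmix64 step: turns a small integer seed into a full 64-bit
    xorshift state (never zero)."""
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def hop_matrix(adj):
    """All-pairs hop counts by BFS; np.inf for unreachable pairs."""
    m = adj.shape[0]
    dist = np.full((m, m), np.inf)
    queue = np.empty(m, np.int64)
    for s in range(m):
        dist[s, s] = 0.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(m):
                if adj[u, v] != 0 and np.isinf(dist[s, v]):
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def _geff_ws(adj, m, dist, queue):
    """Global efficiency of adj[:m, :m] using int64 workspace buffers."""
    if m < 2:
        return 0.0
    total = 0.0
    for s in range(m):
        for v in range(m):
            dist[v] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for v in range(m):
                if adj[u, v] != 0 and dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for v in range(m):
            if v != s and dist[v] > 0:
                total += 1.0 / dist[v]
    return total / (m * (m - 1))


@njit(cache=True)
def _leff_ws(adj, m, nbr, sub, dist, queue, out):
    """Per-node local efficiency into ``out``; returns the node mean."""
    total = 0.0
    for i in range(m):
        k = 0
        for j in range(m):
            if adj[i, j] != 0:
                nbr[k] = j
                k += 1
        if k < 2:
            out[i] = 0.0
            continue
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nbr[a], nbr[b]]
        e = _geff_ws(sub, k, dist, queue)
        out[i] = e
        total += e
    return total / m


@njit(cache=True)
def global_eff(adj):
    """Mean inverse hop distance over ordered pairs (1/inf := 0)."""
    m = adj.shape[0]
    dist = np.empty(m, np.int64)
    queue = np.empty(m, np.int64)
    return _geff_ws(adj, m, dist, queue)


@njit(cache=True)
def local_eff(adj):
    """Per-node local efficiency: global efficiency of the subgraph induced
    by each node's neighbours (the node itself excluded); 0 for degree < 2."""
    m = adj.shape[0]
    out = np.zeros(m)
    nbr = np.empty(m, np.int64)
    sub = np.empty((m, m), np.uint8)
    dist = np.empty(m, np.int64)
    queue = np.empty(m, np.int64)
    _leff_ws(adj, m, nbr, sub, dist, queue, out)
    return out


@njit(cache=True)
def _rewire_inplace(edges, n_edges, adj, n_target, budget, state):
    """Maslov-Sneppen double-edge swaps on (edges[:n_edges], adj), both
    updated in place.  Swaps that would create a self-loop or multi-edge
    are rejected.  Returns (successful swaps, new RNG state)."""
    swaps = 0
    attempts = 0
    n64 = _U64(n_edges)
    while swaps < n_target and attempts < budget:
        attempts += 1
        # one xorshift64* draw supplies both edge indices and the flip bit
        state ^= state >> _U64(12)
        state ^= state << _U64(25)
        state ^= state >> _U64(27)
        x = state * _U64(2685821657736338717)
        e1 = int(((x >> _U64(32)) * n64) >> _U64(32))
        e2 = int(((x & _U64(0xFFFFFFFF)) * n64) >> _U64(32))
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if x & _U64(1):
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(b,c)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] != 0 or adj[b, c] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[b, c] = 1
        adj[c, b] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = b
        edges[e2, 1] = c
        swaps += 1
    return swaps, state


@njit(cache=True)
def edge_list(adj):
    """Upper-triangle edge list (E, 2) of a symmetric adjacency matrix."""
    m = adj.shape[0]
    n_edges = 0
    for i in range(m):
        for j in range(i + 1, m):
            if adj[i, j] != 0:
                n_edges += 1
    edges = np.empty((n_edges, 2), np.int64)
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            if adj[i, j] != 0:
                edges[k, 0] = i
                edges[k, 1] = j
                k += 1
    return edges


@njit(cache=True)
def rewire(adj0, n_swap_per_edge, seed):
    """One degree-preserving randomization of adj0.

    Returns (new adjacency, successful swaps, target swaps).
    """
    state = _seed_state(seed & _MASK31)
    adj = adj0.copy()
    edges = edge_list(adj)
    n_edges = edges.shape[0]
    if n_edges < 2:
        return adj, 0, 0
    target = n_swap_per_edge * n_edges
    swaps, state = _rewire_inplace(edges, n_edges, adj, target, 100 * target,
                                   state)
    return adj, swaps, target


@njit(cache=True)
def _ensemble_means_ws(adj0, n_random, n_swap_per_edge,
                       base_edges, n_edges, work_edges, adj,
                       nbr, sub, dist, queue, el_out, state):
    """Ensemble means with caller-provided workspace and RNG state; caller
    guarantees n_edges >= 2.  Returns (mean E_glob, mean E_loc, state)."""
    m = adj0.shape[0]
    target = n_swap_per_edge * n_edges
    budget = 100 * target
    sum_eg = 0.0
    sum_el = 0.0
    for _ in range(n_random):
        for i in range(m):
            for j in range(m):
                adj[i, j] = adj0[i, j]
        for e in range(n_edges):
            work_edges[e, 0] = base_edges[e, 0]
            work_edges[e, 1] = base_edges[e, 1]
        _, state = _rewire_inplace(work_edges, n_edges, adj, target, budget,
                                   state)
        sum_eg += _geff_ws(adj, m, dist, queue)
        sum_el += _leff_ws(adj, m, nbr, sub, dist, queue, el_out)
    return sum_eg / n_random, sum_el / n_random, state


@njit(cache=True)
def ensemble_means(adj0, n_random, n_swap_per_edge, seed):
    """Mean global efficiency and mean (node-averaged) local efficiency over
    n_random independent degree-preserving rewirings of adj0."""
    state = _seed_state(seed & _MASK31)
    m = adj0.shape[0]
    base_edges = edge_list(adj0)
    n_edges = base_edges.shape[0]
    nbr = np.empty(m, np.int64)
    sub = np.empty((m, m), np.uint8)
    dist = np.empty(m, np.int64)
    queue = np.empty(m, np.int64)
    el_out = np.empty(m)
    if n_edges < 2:
        # no legal swap exists: the ensemble is the graph itself
        eg = _geff_ws(adj0, m, dist, queue)
        el = _leff_ws(adj0, m, nbr, sub, dist, queue, el_out)
        return eg, el
    work_edges = np.empty_like(base_edges)
    adj = np.empty_like(adj0)
    eg, el, state = _ensemble_means_ws(adj0, n_random, n_swap_per_edge,
                                       base_edges, n_edges, work_edges, adj,
                                       nbr, sub, dist, queue, el_out, state)
    return eg, el


@njit(cache=True)
def sigma_sweep(absrho, thresholds, n_random, n_swap_per_edge, seed):
    """Small-worldness sigma at each threshold of a sweep, in one call.

    For each threshold: binarize (strictly above), compute real efficiencies
    and the degree-matched ensemble means, and return
    sigma = (E_loc/E_loc_rand) / (E_glob/E_glob_rand).  NaN marks an
    undefined sigma (edgeless network or degenerate ensemble); with < 2
    edges no legal swap exists and the ensemble equals the graph itself.
    """
    state = _seed_state(seed & _MASK31)
    m = absrho.shape[0]
    n_t = thresholds.shape[0]
    out = np.empty(n_t)
    max_e = m * (m - 1) // 2
    base_edges = np.empty((max_e, 2), np.int64)
    work_edges = np.empty((max_e, 2), np.int64)
    adj0 = np.empty((m, m), np.uint8)
    adj = np.empty((m, m), np.uint8)
    nbr = np.empty(m, np.int64)
    sub = np.empty((m, m), np.uint8)
    dist = np.empty(m, np.int64)
    queue = np.empty(m, np.int64)
    el_out = np.empty(m)
    for ti in range(n_t):
        t = thresholds[ti]
        n_edges = 0
        for i in range(m):
            adj0[i, i] = 0
            for j in range(i + 1, m):
                if absrho[i, j] > t:
                    adj0[i, j] = 1
                    adj0[j, i] = 1
                    base_edges[n_edges, 0] = i
                    base_edges[n_edges, 1] = j
                    n_edges += 1
                else:
                    adj0[i, j] = 0
                    adj0[j, i] = 0
        if n_edges < 1:
            out[ti] = np.nan
            continue
        real_eg = _geff_ws(adj0, m, dist, queue)
        real_el = _leff_ws(adj0, m, nbr, sub, dist, queue, el_out)
        if n_edges < 2:
            rand_eg, rand_el = real_eg, real_el
        else:
            rand_eg, rand_el, state = _ensemble_means_ws(
                adj0, n_random, n_swap_per_edge, base_edges, n_edges,
                work_edges, adj, nbr, sub, dist, queue, el_out, state)
        if rand_eg == 0.0 or rand_el == 0.0:
            out[ti] = np.nan
            continue
        out[ti] = (real_el / rand_el) / (real_eg / rand_eg)
    return out
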