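"""Numba kernels for the two expensive inner loops.

The optimizer evaluates the attack-robustness objective tens of thousands of
times and the game objective thousands of times per run, so both simulations
are compiled: graphs are passed as CSR arrays (see
:func:`robustcoop.graph_core.graph_arrays`).  Component sizes along a removal
sequence are obtained by replaying the sequence backwards with a union-find,
which makes one full attack curve O((N+M) α) after the O(N²) (or O(M²))
greedy target-selection pass.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:  # path compression
        parent[x], x = root, parent[x]
    return root


@njit(cache=True)
def largest_component_size(n, edges):
    """Size of the largest connected component (union-find over the edges)."""
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    max_size = 1 if n > 0 else 0
    for e in range(edges.shape[0]):
        ru = _find(parent, edges[e, 0])
        rv = _find(parent, edges[e, 1])
        if ru != rv:
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            if size[ru] > max_size:
                max_size = size[ru]
    return max_size


@njit(cache=True)
def node_attack(indptr, indices, tie_random, seed):
    """Sequential highest-degree node removal with degree recalculation.

    Returns (order, curve): the removal order and the fractions s(Q) of the
    largest connected component after Q = 1..N removals (curve[Q-1] = s(Q)).
    Ties broken by lowest node id, or uniformly at random when ``tie_random``.
    """
    n = indptr.size - 1
    if tie_random:
        np.random.seed(seed)
    deg = np.empty(n, dtype=np.int64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]
    alive = np.ones(n, dtype=np.bool_)
    order = np.empty(n, dtype=np.int64)
    for step in range(n):
        best = -1
        best_deg = -1
        n_ties = 0
        for i in range(n):
            if alive[i]:
                if deg[i] > best_deg:
                    best_deg = deg[i]
                    best = i
                    n_ties = 1
                elif deg[i] == best_deg:
                    n_ties += 1
        if tie_random and n_ties > 1:
            pick = np.random.randint(0, n_ties)
            seen = 0
            for i in range(n):
                if alive[i] and deg[i] == best_deg:
                    if seen == pick:
                        best = i
                        break
                    seen += 1
        order[step] = best
        alive[best] = False
        for ptr in range(indptr[best], indptr[best + 1]):
            nbr = indices[ptr]
            if alive[nbr]:
                deg[nbr] -= 1
    # replay backwards: nodes order[Q:] survive after Q removals
    parent = np.empty(n, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.bool_)
    curve = np.zeros(n, dtype=np.float64)
    max_size = 0
    for q in range(n - 1, 0, -1):
        v = order[q]
        parent[v] = v
        size[v] = 1
        active[v] = True
        if size[v] > max_size:
            max_size = size[v]
        for ptr in range(indptr[v], indptr[v + 1]):
            u = indices[ptr]
            if active[u]:
                ru = _find(parent, u)
                rv = _find(parent, v)
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
                    if size[ru] > max_size:
                        max_size = size[ru]
        curve[q - 1] = max_size / n
    return order, curve


@njit(cache=True)
def edge_attack(indptr, indices, edges, use_sum):
    """Sequential highest link-degree edge removal with recalculation.

    Link-degree of edge (u, v) is k_u·k_v (or k_u+k_v when ``use_sum``),
    recomputed from the current degrees before every removal.  Returns
    (order, curve) with curve[P-1] = s(P), the largest-component fraction
    after removing P edges; nodes are never removed so s(M) = 1/N.
    """
    n = indptr.size - 1
    m = edges.shape[0]
    deg = np.empty(n, dtype=np.int64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]
    alive = np.ones(m, dtype=np.bool_)
    order = np.empty(m, dtype=np.int64)
    for step in range(m):
        best = -1
        best_score = np.int64(-1)
        for e in range(m):
            if alive[e]:
                u, v = edges[e, 0], edges[e, 1]
                score = deg[u] + deg[v] if use_sum else deg[u] * deg[v]
                if score > best_score:
                    best_score = score
                    best = e
        order[step] = best
        alive[best] = False
        deg[edges[best, 0]] -= 1
        deg[edges[best, 1]] -= 1
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    curve = np.empty(m, dtype=np.float64)
    max_size = 1
    curve[m - 1] = 1.0 / n
    for p in range(m - 1, 0, -1):
        e = order[p]
        ru = _find(parent, edges[e, 0])
        rv = _find(parent, edges[e, 1])
        if ru != rv:
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            if size[ru] > max_size:
                max_size = size[ru]
        curve[p - 1] = max_size / n
    return order, curve


@njit(cache=True)
def game_run(
    indptr,
    indices,
    t_pay,
    r_pay,
    p_pay,
    s_pay,
    w_denom,
    init_coop_fraction,
    transient,
    sample,
    seed,
):
    """One realization of the networked PD under synchronous imitation.

    Strategies are 1 (cooperate) / 0 (defect).  Every sweep recomputes all
    payoffs from scratch, then every node compares with one uniformly random
    neighbour and, if poorer, copies that neighbour's strategy with
    probability (P_j - P_i) / (w_denom · max(k_i, k_j)) clipped to [0, 1].
    Returns the cooperator fraction averaged over ``sample`` post-transient
    sweeps; all-C / all-D states exit early at their absorbing value.
    """
    np.random.seed(seed)
    n = indptr.size - 1
    deg = np.empty(n, dtype=np.int64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]
    strat = np.zeros(n, dtype=np.int8)
    n_coop = int(np.ceil(init_coop_fraction * n))
    perm = np.arange(n)
    np.random.shuffle(perm)
    for i in range(n_coop):
        strat[perm[i]] = 1
    payoff = np.empty(n, dtype=np.float64)
    new_strat = np.empty(n, dtype=np.int8)
    acc = 0.0
    for sweep in range(transient + sample):
        total_c = 0
        for i in range(n):
            total_c += strat[i]
        if total_c == 0 or total_c == n:
            frac = total_c / n
            if sweep >= transient:
                acc += frac * (transient + sample - sweep)
            else:
                acc = frac * sample
            return acc / sample
        for i in range(n):
            p = 0.0
            si = strat[i]
            for ptr in range(indptr[i], indptr[i + 1]):
                sj = strat[indices[ptr]]
                if si == 1:
                    p += r_pay if sj == 1 else s_pay
                else:
                    p += t_pay if sj == 1 else p_pay
            payoff[i] = p
        for i in range(n):
            new_strat[i] = strat[i]
            if deg[i] == 0:
                continue
            j = indices[indptr[i] + np.random.randint(0, deg[i])]
            if payoff[i] < payoff[j]:
                kmax = deg[i] if deg[i] > deg[j] else deg[j]
                w = (payoff[j] - payoff[i]) / (w_denom * kmax)
                if w > 1.0:
                    w = 1.0
                if np.random.random() < w:
                    new_strat[i] = strat[j]
        for i in range(n):
            strat[i] = new_strat[i]
        if sweep >= transient:
            total_c = 0
            for i in range(n):
                total_c += strat[i]
            acc += total_c / n
    return acc / sample
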