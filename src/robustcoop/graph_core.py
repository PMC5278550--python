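"""Graph container, generators, structural measures and edge-list I/O.

Networks are plain :class:`networkx.Graph` objects restricted to simple,
undirected graphs whose nodes are the contiguous integers ``0..N-1``.  All
construction and rewiring operations in this package preserve both the node
count ``N`` and the link count ``M``; :func:`validate_network` enforces the
representation invariants at the boundaries.

Two structural measures drive the optimizer:

* **heterogeneity** ``H`` — a Gini-type index of degree inequality,
  ``H = sum_ij |k_i - k_j| / (2 N^2 <k>)``, which is 0 exactly on regular
  graphs and approaches 1 for extremely unequal degree sequences;
* **assortativity** ``r`` — the Pearson correlation of the degrees found at
  the two ends of an edge (Newman's degree mixing coefficient), positive when
  hubs attach to hubs ("onion-like"), negative when hubs attach to leaves
  ("star-like").
"""

from __future__ import annotations

import dataclasses
from pathlib import Path


import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "StructuralSummary",
    "GraphError",
    "EdgeListError",
    "UndefinedMeasureError",
    "validate_network",
    "generate_er",
    "generate_ba",
    "generate_ws",
    "scale_free_reference",
    "heterogeneity",
    "heterogeneity_from_degrees",
    "assortativity",
    "structural_summary",
    "read_edge_list",
    "write_edge_list",
    "write_gml",
    "graph_arrays",
]

#: Alias documenting that the package's network chromosome is a networkx graph.
Network = nx.Graph


class GraphError(ValueError):
    """An operation received a graph violating the package invariants."""


class EdgeListError(GraphError):
    """Malformed edge-list input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class UndefinedMeasureError(GraphError):
    """A structural measure is undefined on the given graph."""


@dataclasses.dataclass(frozen=True)
class StructuralSummary:
    """Bundle of the structural quantities reported for one network."""

    heterogeneity: float
    assortativity: float | None  # None when the edge-degree variance is zero
    mean_degree: float
    degree_sequence: tuple[int, ...]


def validate_network(g: Network) -> None:
    """Raise :class:`GraphError` unless ``g`` is a valid network chromosome.

    Valid means: undirected simple graph, nodes labelled ``0..N-1``.
    """
    if g.is_directed() or g.is_multigraph():
        raise GraphError("network must be an undirected simple graph")
    n = g.number_of_nodes()
    if set(g.nodes) != set(range(n)):
        raise GraphError("node ids must be the contiguous integers 0..N-1")
    if any(u == v for u, v in g.edges):
        raise GraphError("self-loops are not allowed")


def _connected_resample(build, seed: int, max_tries: int = 200) -> Network:
    """Call ``build(s)`` with seeds derived from ``seed`` until connected."""
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_tries):
        g = build(int(child.generate_state(1)[0] % (2**31)))
        if nx.is_connected(g):
            return g
    raise GraphError(f"no connected sample after {max_tries} tries")


def generate_er(n: int, m: int, seed: int) -> Network:
    """Connected Erdős–Rényi G(n, m) graph; resamples until connected.

    ``m`` must allow connectivity (``m >= n-1``) and simplicity
    (``m <= n(n-1)/2``).  Deterministic given ``seed``.
    """
    if m < n - 1:
        raise GraphError(f"m={m} is below the n-1={n - 1} edges needed for connectivity")
    if m > n * (n - 1) // 2:
        raise GraphError(f"m={m} exceeds the simple-graph maximum n(n-1)/2")
    return _connected_resample(lambda s: nx.gnm_random_graph(n, m, seed=s), seed)


def generate_ba(n: int, m_attach: int, seed: int) -> Network:
    """Barabási–Albert preferential-attachment graph, mean degree ≈ 2·m_attach."""
    if m_attach < 1 or n <= m_attach:
        raise GraphError("require 1 <= m_attach < n")
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    return nx.barabasi_albert_graph(n, m_attach, seed=rng_seed)


def generate_ws(n: int, k_ring: int, p_rewire: float, seed: int) -> Network:
    """Connected Watts–Strogatz small-world graph with exactly n·k_ring/2 edges."""
    if k_ring % 2 != 0:
        raise GraphError("k_ring must be even (ring lattice neighbours per side)")
    if not 0.0 <= p_rewire <= 1.0:
        raise GraphError("p_rewire must lie in [0, 1]")
    return _connected_resample(
        lambda s: nx.watts_strogatz_graph(n, k_ring, p_rewire, seed=s), seed
    )


def scale_free_reference(n: int, m: int, seed: int) -> Network:
    """Connected preferential-attachment graph with exactly n nodes, m edges.

    A Barabási–Albert graph with ``m_attach = round(m / n)`` is padded (or
    trimmed) to exactly ``m`` edges: padding attaches additional edges from
    uniformly random nodes to degree-proportionally sampled partners, so the
    extra edges follow the same rich-get-richer statistics; trimming removes
    random edges whose loss keeps the graph connected.
    """
    m_attach = max(1, int(round(m / n)))
    if not n - 1 <= m <= n * (n - 1) // 2:
        raise GraphError(f"cannot build a connected simple graph with n={n}, m={m}")
    rng = np.random.default_rng(seed)
    g = generate_ba(n, m_attach, int(rng.integers(0, 2**31)))
    while g.number_of_edges() > m:
        edges = list(g.edges)
        u, v = edges[rng.integers(0, len(edges))]
        g.remove_edge(u, v)
        if not nx.is_connected(g):
            g.add_edge(u, v)
    degrees = np.array([g.degree(i) for i in range(n)], dtype=float)
    while g.number_of_edges() < m:
        a = int(rng.integers(0, n))
        weights = degrees.copy()
        weights[a] = 0.0
        weights[[b for b in g.neighbors(a)]] = 0.0
        total = weights.sum()
        if total == 0:
            raise GraphError("no room left for padding edges")
        b = int(rng.choice(n, p=weights / total))
        g.add_edge(a, b)
        degrees[a] += 1
        degrees[b] += 1
    return g


def heterogeneity_from_degrees(degrees: np.ndarray) -> float:
    """Gini-type degree-inequality index computed from a degree sequence."""
    k = np.sort(np.asarray(degrees, dtype=np.float64))
    n = k.size
    total = k.sum()
    if n == 0 or total == 0:
        raise UndefinedMeasureError("heterogeneity is undefined without edges")
    # sum_ij |k_i - k_j| = 2 * sum_i (2i - n + 1) * k_(i)  for ascending k
    weights = 2.0 * np.arange(n) - n + 1.0
    abs_diff_sum = 2.0 * float(weights @ k)
    mean_k = total / n
    return abs_diff_sum / (2.0 * n * n * mean_k)


def heterogeneity(g: Network) -> float:
    """Degree-heterogeneity index H ∈ [0, 1]; exactly 0 on regular graphs."""
    return heterogeneity_from_degrees(np.array([d for _, d in g.degree()]))


def assortativity(g: Network) -> float:
    """Degree assortativity r: Pearson correlation over edge endpoint degrees.

    Raises :class:`UndefinedMeasureError` when every edge joins nodes of the
    same degree-pair pattern (zero variance, e.g. regular or star-free
    complete graphs where the correlation is 0/0).
    """
    m = g.number_of_edges()
    if m < 2:
        raise UndefinedMeasureError("assortativity needs at least two edges")
    deg = dict(g.degree())
    us, vs = np.empty(2 * m), np.empty(2 * m)
    for idx, (u, v) in enumerate(g.edges):
        us[2 * idx], vs[2 * idx] = deg[u], deg[v]
        us[2 * idx + 1], vs[2 * idx + 1] = deg[v], deg[u]
    if np.var(us) == 0.0:
        raise UndefinedMeasureError("edge-degree variance is zero; r undefined")
    return float(np.corrcoef(us, vs)[0, 1])


def structural_summary(g: Network) -> StructuralSummary:
    """H, r (None when undefined), mean degree and degree sequence of ``g``."""
    degrees = tuple(d for _, d in g.degree())
    try:
        r: float | None = assortativity(g)
    except UndefinedMeasureError:
        r = None
    return StructuralSummary(
        heterogeneity=heterogeneity(g),
        assortativity=r,
        mean_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        degree_sequence=degrees,
    )


def read_edge_list(path: str | Path) -> Network:
    """Parse a whitespace-separated, 0-based integer edge list.

    One edge per line; ``#`` starts a comment line.  Self-loops and duplicate
    edges are rejected with the offending line number.  The node count is
    ``max id + 1``.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListError(f"expected two ids, got {len(parts)}", lineno)
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListError(f"non-integer node id in {parts!r}", lineno) from None
            if u < 0 or v < 0:
                raise EdgeListError("node ids must be non-negative", lineno)
            if u == v:
                raise EdgeListError(f"self-loop on node {u}", lineno)
            e = (min(u, v), max(u, v))
            if e in seen:
                raise EdgeListError(f"duplicate edge {e}", lineno)
            seen.add(e)
            edges.append(e)
    if not edges:
        raise EdgeListError("edge list contains no edges")
    g = nx.Graph()
    g.add_nodes_from(range(max(max(e) for e in edges) + 1))
    g.add_edges_from(edges)
    validate_network(g)
    return g


def write_edge_list(g: Network, path: str | Path) -> None:
    """Write one ``u v`` pair per line, each edge once with u < v."""
    validate_network(g)
    with open(path, "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges):
            fh.write(f"{u} {v}\n")


def write_gml(g: Network, path: str | Path) -> None:
    """GML export for interoperability with external network tools."""
    nx.write_gml(g, path)


def graph_arrays(g: Network) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CSR adjacency (indptr, indices) plus an (M, 2) edge array.

    Nodes must already be labelled 0..N-1.  Used to hand graphs to the
    compiled attack/game kernels.
    """
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty((0, 2), dtype=np.int64)
    raw = np.fromiter((x for e in g.edges for x in e), dtype=np.int64, count=2 * g.number_of_edges())
    edges = np.sort(raw.reshape(-1, 2), axis=1)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]  # canonical tie-break order
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    degrees = np.bincount(src, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(degrees, out=indptr[1:])
    return indptr, indices, edges
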