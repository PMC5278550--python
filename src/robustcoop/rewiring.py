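"""Edge-rewiring moves and greedy hill climbing on structural objectives.

Two move types are the search operators of the whole package:

* **relink** — detach one endpoint of a random edge (a, b) and reattach it
  to a random non-neighbour c of a.  Keeps N and M fixed but shifts one unit
  of degree from b to c, so relinks reshape the degree distribution (and
  hence heterogeneity H and robustness R).
* **swap** — replace two independent edges (a, b), (c, d) by (a, c), (b, d)
  or (a, d), (b, c).  Every node keeps its degree, so H is exactly invariant
  while the degree-degree correlation r moves; choosing the pairing with the
  larger (smaller) sum of endpoint-degree products steers r up (down), as in
  Xulvi-Brunet–Sokolov rewiring.

:func:`hill_climb` greedily accepts strictly improving moves and stops after
``patience`` consecutive non-improving proposals.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Literal

import numpy as np

from . import _kernels
from .graph_core import (
    Network,
    UndefinedMeasureError,
    graph_arrays,
    heterogeneity_from_degrees,
)

__all__ = [
    "RewireMove",
    "MoveError",
    "propose_relink",
    "propose_swap",
    "apply_move",
    "revert_move",
    "hill_climb",
    "robustness_directed_moves",
    "cooperation_directed_moves",
]

Direction = Literal["max", "min"]


class MoveError(RuntimeError):
    """No legal rewiring move could be found."""


@dataclasses.dataclass(frozen=True)
class RewireMove:
    """A reversible edge replacement preserving N and M."""

    kind: Literal["relink", "swap"]
    removed: tuple[tuple[int, int], ...]
    added: tuple[tuple[int, int], ...]


def apply_move(g: Network, move: RewireMove) -> None:
    g.remove_edges_from(move.removed)
    g.add_edges_from(move.added)


def revert_move(g: Network, move: RewireMove) -> None:
    g.remove_edges_from(move.added)
    g.add_edges_from(move.removed)


def _edge_list(g: Network) -> list[tuple[int, int]]:
    return list(g.edges)


def propose_relink(
    g: Network,
    rng: np.random.Generator,
    max_tries: int = 100,
    hub_biased: bool = False,
) -> RewireMove:
    """Random single-endpoint relink: remove (a, b), add (a, c).

    By default the kept endpoint a is chosen at random from the edge and c
    is a uniformly random node outside {a, b} not already adjacent to a.
    With ``hub_biased`` the move grows hub-and-spoke structure instead: the
    poorer endpoint of the edge is kept and reattached to the highest-degree
    node among a small random sample (tournament preferential attachment),
    draining the richer endpoint.  Raises :class:`MoveError` when no legal
    relink exists (e.g. complete graph).
    """
    n = g.number_of_nodes()
    edges = _edge_list(g)
    for _ in range(max_tries):
        a, b = edges[rng.integers(0, len(edges))]
        if hub_biased:
            if g.degree(a) > g.degree(b):
                a, b = b, a
        elif rng.random() < 0.5:
            a, b = b, a
        if g.degree(a) >= n - 1:
            continue
        if hub_biased:
            sample = [int(v) for v in rng.integers(0, n, size=3)]
            sample = [v for v in sample if v not in (a, b) and not g.has_edge(a, v)]
            if not sample:
                continue
            c = max(sample, key=g.degree)
        else:
            c = int(rng.integers(0, n))
            if c == a or c == b or g.has_edge(a, c):
                continue
        return RewireMove("relink", ((min(a, b), max(a, b)),), ((min(a, c), max(a, c)),))
    raise MoveError(f"no legal relink found in {max_tries} tries")


def propose_swap(
    g: Network,
    rng: np.random.Generator,
    direction: Literal["increase_r", "decrease_r", None] = None,
    max_tries: int = 200,
) -> RewireMove:
    """Degree-preserving two-edge swap, optionally steered in r.

    With a direction, the replacement pairing is the one whose sum of
    endpoint-degree products strictly increases (decreases) relative to the
    removed pair — the sign of that change is the sign of the change in the
    assortativity numerator, all else being degree-invariant.
    """
    edges = _edge_list(g)
    m = len(edges)
    if m < 2:
        raise MoveError("swap needs at least two edges")
    deg = dict(g.degree())
    for _ in range(max_tries):
        i, j = rng.integers(0, m), rng.integers(0, m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        options = []
        for (p1, q1), (p2, q2) in (((a, c), (b, d)), ((a, d), (b, c))):
            if g.has_edge(p1, q1) or g.has_edge(p2, q2):
                continue
            delta = (
                deg[p1] * deg[q1] + deg[p2] * deg[q2] - deg[a] * deg[b] - deg[c] * deg[d]
            )
            options.append((delta, (p1, q1), (p2, q2)))
        if not options:
            continue
        if direction == "increase_r":
            options = [o for o in options if o[0] > 0]
        elif direction == "decrease_r":
            options = [o for o in options if o[0] < 0]
        if not options:
            continue
        _, e1, e2 = options[int(rng.integers(0, len(options)))]
        return RewireMove(
            "swap",
            ((min(a, b), max(a, b)), (min(c, d), max(c, d))),
            ((min(*e1), max(*e1)), (min(*e2), max(*e2))),
        )
    raise MoveError(f"no legal swap found in {max_tries} tries")


def _assortativity_from_arrays(edges: np.ndarray, deg: np.ndarray) -> float:
    du = deg[edges[:, 0]].astype(np.float64)
    dv = deg[edges[:, 1]].astype(np.float64)
    x = np.concatenate([du, dv])
    y = np.concatenate([dv, du])
    if np.var(x) == 0.0:
        raise UndefinedMeasureError("edge-degree variance is zero; r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _measure(name: str, indptr: np.ndarray, indices: np.ndarray, edges: np.ndarray) -> float:
    deg = np.diff(indptr)
    if name == "H":
        return heterogeneity_from_degrees(deg)
    if name == "r":
        return _assortativity_from_arrays(edges, deg)
    if name == "R":
        _, curve = _kernels.node_attack(indptr, indices, False, 0)
        return float(curve.mean())
    raise ValueError(f"unknown objective {name!r}; expected 'R', 'H' or 'r'")


def hill_climb(
    net: Network,
    objective: str | Callable[[Network], float],
    direction: Direction = "max",
    patience: int = 1000,
    connectivity_required: bool = True,
    rng: np.random.Generator | int | None = None,
    max_accepts: int | None = None,
    max_evaluations: int | None = None,
    move_kind: Literal["relink", "swap", "auto"] = "auto",
    stop_at: float | None = None,
) -> tuple[Network, float, list[float]]:
    """Greedy strict-improvement rewiring search.

    Proposes moves (relink for the degree-sensitive objectives R and H, swap
    for r, unless ``move_kind`` overrides), accepts a move only when the
    objective strictly improves in ``direction`` and, when
    ``connectivity_required``, the graph stays connected.  Stops after
    ``patience`` consecutive rejected proposals, after ``max_accepts``
    accepted moves, after ``max_evaluations`` proposals in total, or as soon
    as the objective reaches ``stop_at`` (in the climb direction).

    Returns ``(graph, objective_value, trajectory)``; the input graph is not
    modified, and the trajectory lists the objective after each acceptance
    (strictly monotone by construction).
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = net.copy()
    named = isinstance(objective, str)
    if named and objective not in ("R", "H", "r"):
        raise ValueError(f"unknown objective {objective!r}")
    if move_kind == "auto":
        move_kind = "swap" if objective == "r" else "relink"
    swap_dir = None
    if move_kind == "swap" and named and objective == "r":
        swap_dir = "increase_r" if direction == "max" else "decrease_r"

    def evaluate(graph: Network) -> tuple[float, np.ndarray]:
        indptr, indices, edges = graph_arrays(graph)
        if named:
            return _measure(objective, indptr, indices, edges), edges
        return float(objective(graph)), edges

    sign = 1.0 if direction == "max" else -1.0
    current, edges_arr = evaluate(g)
    n = g.number_of_nodes()
    trajectory: list[float] = []
    stall = 0
    accepts = 0
    evaluations = 0
    while stall < patience:
        if stop_at is not None and sign * (current - stop_at) >= 0:
            break
        if max_accepts is not None and accepts >= max_accepts:
            break
        if max_evaluations is not None and evaluations >= max_evaluations:
            break
        try:
            if move_kind == "swap":
                move = propose_swap(g, rng, direction=swap_dir)
            else:
                move = propose_relink(g, rng)
        except MoveError:
            break
        apply_move(g, move)
        evaluations += 1
        try:
            value, edges_arr = evaluate(g)
        except UndefinedMeasureError:
            revert_move(g, move)
            stall += 1
            continue
        improved = sign * (value - current) > 0
        if improved and connectivity_required:
            improved = _kernels.largest_component_size(n, edges_arr) == n
        if improved:
            current = value
            trajectory.append(value)
            accepts += 1
            stall = 0
        else:
            revert_move(g, move)
            stall += 1
    return g, current, trajectory


def cooperation_directed_moves(
    net: Network,
    steps: int,
    patience: int,
    rng: np.random.Generator,
    connectivity_required: bool = True,
    relink_mix: float = 0.0,
) -> Network:
    """Cooperation-directed variation: disassortative degree-preserving swaps.

    Applies up to ``steps`` accepted assortativity-lowering swaps
    (disassortative mixing shelters cooperators behind hubs).  Cooperation
    is far too expensive to evaluate per move, so moves are accepted
    whenever they keep the graph simple and (optionally) connected;
    selection on the offspring's evaluated f(c) provides the actual
    objective pressure.  ``relink_mix`` > 0 additionally mixes in hub-biased
    relinks (reattach the poorer end of a random edge to the hub of a small
    tournament), an experimental degree-changing variant that can grow
    hub-and-spoke structure but tends to thin the mid-hub tier of already
    well-organised members; it is off by default.
    """
    g = net.copy()
    n = g.number_of_nodes()
    accepted = 0
    stall = 0
    while accepted < steps and stall < patience:
        use_relink = rng.random() < relink_mix
        try:
            if use_relink:
                move = propose_relink(g, rng, hub_biased=True)
            else:
                move = propose_swap(g, rng, direction="decrease_r")
        except MoveError:
            stall += 1
            continue
        apply_move(g, move)
        if connectivity_required:
            _, _, edges = graph_arrays(g)
            if _kernels.largest_component_size(n, edges) != n:
                revert_move(g, move)
                stall += 1
                continue
        accepted += 1
        stall = 0
    return g


def robustness_directed_moves(
    net: Network,
    steps: int,
    patience: int,
    rng: np.random.Generator,
    connectivity_required: bool = True,
    swap_mix: float = 0.5,
) -> Network:
    """Robustness-directed variation: relink ascent plus onionizing drift.

    Applies up to ``steps`` accepted moves of two kinds, chosen with
    probability ``swap_mix``:

    * a relink accepted only when R strictly increases (greedy ascent that
      reshapes the degree distribution towards attack-tolerant homogeneity);
    * an assortativity-raising degree-preserving swap accepted whenever R
      does **not decrease** — a neutral-or-better drift along R plateaus
      that progressively links nodes of similar degree.

    Pure strict relink ascent stalls in robust but weakly assortative local
    optima; allowing R-neutral assortative swaps lets the search walk those
    plateaus towards the onion-like organisation (homogeneous degrees,
    assortative shells) characteristic of attack-robust networks, and in
    practice also unlocks further strict R gains.  Gives up after
    ``patience`` consecutive rejections.
    """
    g = net.copy()
    n = g.number_of_nodes()
    indptr, indices, edges = graph_arrays(g)
    _, curve = _kernels.node_attack(indptr, indices, False, 0)
    current = float(curve.mean())
    accepted = 0
    stall = 0
    while accepted < steps and stall < patience:
        use_swap = rng.random() < swap_mix
        try:
            if use_swap:
                move = propose_swap(g, rng, direction="increase_r")
            else:
                move = propose_relink(g, rng)
        except MoveError:
            break
        apply_move(g, move)
        indptr, indices, edges = graph_arrays(g)
        _, curve = _kernels.node_attack(indptr, indices, False, 0)
        value = float(curve.mean())
        ok = value >= current if use_swap else value > current
        if ok and connectivity_required:
            ok = _kernels.largest_component_size(n, edges) == n
        if ok:
            current = value
            accepted += 1
            stall = 0
        else:
            revert_move(g, move)
            stall += 1
    return g
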