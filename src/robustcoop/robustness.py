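"""Malicious-attack simulation and the scalar robustness measure R.

The attack model is the strongest standard reading of a targeted attack:
remove the node (or edge) with the highest current degree (link-degree),
recomputing degrees after every removal.  The robustness of a network is

    R = (1/N) · sum_{Q=1..N} s(Q)

where s(Q) is the fraction of nodes in the largest connected component after
Q removals (Schneider's measure).  The 1/N normalization makes R comparable
across sizes; connected graphs satisfy 0 < R <= (N-1)/(2N), with the complete
graph attaining the bound.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from . import _kernels
from .graph_core import GraphError, Network, graph_arrays

__all__ = [
    "AttackCurve",
    "node_attack_order",
    "node_attack_curve",
    "robustness_R",
    "edge_attack_curve",
]

TieBreak = Literal["lowest_id", "random"]
LinkDegree = Literal["product", "sum"]


@dataclasses.dataclass(frozen=True)
class AttackCurve:
    """Largest-component fractions along a removal sequence.

    ``fractions[i]`` is the fraction after i+1 removals; non-increasing, and
    in node mode the final entry is exactly 0.
    """

    fractions: np.ndarray
    mode: Literal["node", "edge"]
    order: np.ndarray

    @property
    def area(self) -> float:
        """Mean of the curve — equals R in node mode."""
        return float(self.fractions.mean())


def _tie_args(tie_break: TieBreak, rng: np.random.Generator | None) -> tuple[bool, int]:
    if tie_break == "lowest_id":
        return False, 0
    if tie_break == "random":
        rng = np.random.default_rng() if rng is None else rng
        return True, int(rng.integers(0, 2**31))
    raise ValueError(f"unknown tie_break {tie_break!r}")


def node_attack_curve(
    net: Network,
    tie_break: TieBreak = "lowest_id",
    rng: np.random.Generator | None = None,
    recalculate: bool = True,
) -> AttackCurve:
    """Disintegration curve s(Q) under the recalculated highest-degree attack.

    With ``recalculate=False`` the removal order is fixed by the initial
    degrees instead (non-adaptive attack).
    """
    if net.number_of_nodes() == 0:
        raise GraphError("attack on an empty network")
    indptr, indices, _ = graph_arrays(net)
    if recalculate:
        tie_random, seed = _tie_args(tie_break, rng)
        order, curve = _kernels.node_attack(indptr, indices, tie_random, seed)
    else:
        deg = np.diff(indptr)
        order = np.lexsort((np.arange(deg.size), -deg)).astype(np.int64)
        curve = _curve_for_order(indptr, indices, order)
    return AttackCurve(fractions=curve, mode="node", order=order)


def _curve_for_order(indptr, indices, order) -> np.ndarray:
    """Largest-component fractions for an externally supplied removal order."""
    n = indptr.size - 1
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    active = np.zeros(n, dtype=bool)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    curve = np.zeros(n)
    max_size = 0
    for q in range(n - 1, 0, -1):
        v = int(order[q])
        active[v] = True
        max_size = max(max_size, 1)
        for u in indices[indptr[v] : indptr[v + 1]]:
            if active[u]:
                ru, rv = find(int(u)), find(v)
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
                    max_size = max(max_size, int(size[ru]))
        curve[q - 1] = max_size / n
    return curve


def node_attack_order(
    net: Network,
    tie_break: TieBreak = "lowest_id",
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Removal order of the recalculated highest-degree node attack."""
    return [int(v) for v in node_attack_curve(net, tie_break, rng).order]


def robustness_R(net: Network) -> float:
    """Schneider robustness R = (1/N)·Σ_Q s(Q) under the default attack."""
    return node_attack_curve(net).area


def edge_attack_curve(net: Network, link_degree: LinkDegree = "product") -> AttackCurve:
    """Disintegration curve s(P) under the highest link-degree edge attack.

    The link-degree of edge (u, v) is k_u·k_v by default (``"sum"`` selects
    k_u + k_v); degrees are recomputed after every removal.
    """
    if net.number_of_edges() < 1:
        raise GraphError("edge attack needs at least one edge")
    indptr, indices, edges = graph_arrays(net)
    order, curve = _kernels.edge_attack(indptr, indices, edges, link_degree == "sum")
    return AttackCurve(fractions=curve, mode="edge", order=order)
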