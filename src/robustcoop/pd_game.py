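"""Evolutionary prisoner's dilemma on a network.

Every node plays one of two pure strategies, cooperate (1) or defect (0),
against all of its neighbours.  Pairwise payoffs follow the PD matrix with
temptation T, reward R, punishment P and sucker's payoff S, ordered
T > R > P >= S (the weak dilemma T=2, R=1, P=S=0 allows P = S).  Payoffs are
accumulated from scratch each round.  The population then updates
synchronously: every node i compares with one uniformly random neighbour j
and, if P_i < P_j, imitates j's strategy with probability

    W = (P_j - P_i) / ((T - S) · max(k_i, k_j))

— the payoff-difference rule normalized by the larger degree, so better-off,
well-connected neighbours are imitated but never with probability above 1.
The order parameter is f(c), the stationary fraction of cooperators averaged
over post-transient sweeps and over independent realizations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

from . import _kernels
from .graph_core import Network, graph_arrays

__all__ = [
    "PayoffParams",
    "WEAK_PD",
    "accumulate_payoffs",
    "imitation_update",
    "run_game",
    "estimate_fc",
]


@dataclasses.dataclass(frozen=True)
class PayoffParams:
    """PD payoff quadruple with the ordering constraint T > R > P >= S."""

    T: float = 2.0
    R: float = 1.0
    P: float = 0.0
    S: float = 0.0
    #: imitation-probability denominator: (T - S) (default) or T alone.
    w_normalization: Literal["T-S", "T"] = "T-S"

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P >= self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P >= S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )

    @property
    def w_denom(self) -> float:
        return self.T - self.S if self.w_normalization == "T-S" else self.T


#: The weak dilemma used throughout the experiments: T=2, R=1, P=S=0.
WEAK_PD = PayoffParams()


def accumulate_payoffs(
    net: Network, strategies: np.ndarray, params: PayoffParams = WEAK_PD
) -> np.ndarray:
    """Per-node payoff against all neighbours; isolated nodes get 0."""
    s = np.asarray(strategies)
    indptr, indices, _ = graph_arrays(net)
    coop_nbrs = np.zeros(s.size, dtype=np.float64)
    nbr_strats = s[indices].astype(np.float64)
    for i in range(s.size):  # small graphs only; hot path uses the kernel
        coop_nbrs[i] = nbr_strats[indptr[i] : indptr[i + 1]].sum()
    deg = np.diff(indptr).astype(np.float64)
    defect_nbrs = deg - coop_nbrs
    coop_pay = params.R * coop_nbrs + params.S * defect_nbrs
    defect_pay = params.T * coop_nbrs + params.P * defect_nbrs
    return np.where(s == 1, coop_pay, defect_pay)


def imitation_update(
    net: Network,
    strategies: np.ndarray,
    params: PayoffParams,
    rng: np.random.Generator,
    payoffs: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous imitation sweep; returns the new strategy vector.

    All nodes sample their neighbour and decide from the pre-sweep strategies
    and payoffs; adoptions are applied simultaneously.  Reference (pure
    NumPy) implementation used for small graphs and as the oracle for the
    compiled game kernel.
    """
    s = np.asarray(strategies).copy()
    if payoffs is None:
        payoffs = accumulate_payoffs(net, s, params)
    indptr, indices, _ = graph_arrays(net)
    deg = np.diff(indptr)
    new_s = s.copy()
    for i in range(s.size):
        if deg[i] == 0:
            continue
        j = int(indices[indptr[i] + rng.integers(0, deg[i])])
        if payoffs[i] < payoffs[j]:
            w = (payoffs[j] - payoffs[i]) / (params.w_denom * max(deg[i], deg[j]))
            if rng.random() < min(w, 1.0):
                new_s[i] = s[j]
    return new_s


def run_game(
    net: Network,
    params: PayoffParams = WEAK_PD,
    init_coop_fraction: float = 0.5,
    transient_sweeps: int = 1000,
    sample_sweeps: int = 100,
    rng: np.random.Generator | int | None = None,
    engine: Literal["compiled", "python"] = "compiled",
) -> float:
    """One realization: random initialization, transient, then sampling.

    ``ceil(init_coop_fraction · N)`` cooperators are placed uniformly at
    random; after ``transient_sweeps`` synchronous sweeps the cooperator
    fraction is averaged over the next ``sample_sweeps`` sweeps.  All-C and
    all-D are absorbing and exit early at their exact value.
    """
    if not 0.0 <= init_coop_fraction <= 1.0:
        raise ValueError("init_coop_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    indptr, indices, _ = graph_arrays(net)
    if engine == "compiled":
        seed = int(rng.integers(0, 2**31))
        return float(
            _kernels.game_run(
                indptr,
                indices,
                params.T,
                params.R,
                params.P,
                params.S,
                params.w_denom,
                init_coop_fraction,
                transient_sweeps,
                sample_sweeps,
                seed,
            )
        )
    # pure-python path (oracle / debugging)
    n = net.number_of_nodes()
    strategies = np.zeros(n, dtype=np.int8)
    strategies[rng.permutation(n)[: math.ceil(init_coop_fraction * n)]] = 1
    acc = 0.0
    for sweep in range(transient_sweeps + sample_sweeps):
        total = int(strategies.sum())
        if total in (0, n):
            if sweep >= transient_sweeps:  # fill the remaining samples
                acc += (total / n) * (transient_sweeps + sample_sweeps - sweep)
                return acc / sample_sweeps
            return total / n
        strategies = imitation_update(net, strategies, params, rng)
        if sweep >= transient_sweeps:
            acc += strategies.sum() / n
    return acc / sample_sweeps


def estimate_fc(
    net: Network,
    params: PayoffParams = WEAK_PD,
    n_realizations: int = 50,
    rng: np.random.Generator | int | None = None,
    **run_kwargs,
) -> float:
    """The cooperation objective f(c): mean of run_game over realizations."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return float(
        np.mean([run_game(net, params, rng=rng, **run_kwargs) for _ in range(n_realizations)])
    )
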