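"""Diffusion heuristic turning a distal target into attainable subgoal preferences.

A graph Laplacian is built from the agent's posterior belief that each cell is
open, with an off-diagonal rate into cell ``i`` from any cell that can reach it
in one action.  Its matrix exponential spreads occupancy probability for one
time step; the log of the mass diffusing *from the target* becomes a
log-preference over location outcomes, with an additional flat penalty on
cells that receive (numerically) no mass diffusing from the agent's current
location, i.e. are out of reach.  Recomputed every trial, the maximum of the
preference within the short policy horizon acts as a subgoal en route to the
target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import DegeneratePreferenceError, InvalidArgumentError
from .model_core import PROB_FLOOR, TransitionSet

__all__ = [
    "DiffusionGraph",
    "PreferenceVector",
    "build_graph_laplacian",
    "preference_vector",
    "COST_CAP",
    "REACH_THRESHOLD",
]

#: Flat penalty added to cells out of diffusion reach of the current location.
COST_CAP = 16.0
#: Occupancy mass below which a cell counts as out of reach.
REACH_THRESHOLD = float(np.exp(-3.0))


@dataclass
class DiffusionGraph:
    """Zero-column-sum generator of open-weighted diffusion on the maze graph."""

    L: np.ndarray  # [n_states, n_states]
    p_open: np.ndarray  # [n_states]


@dataclass
class PreferenceVector:
    """Log-preference over location outcomes (shift-invariant by contract)."""

    ln_p_where: np.ndarray
    cost_cap: float = COST_CAP
    reach_threshold: float = REACH_THRESHOLD


def build_graph_laplacian(p_open: np.ndarray, transitions: TransitionSet) -> DiffusionGraph:
    """Laplacian with rate ``p_open[i]`` into ``i`` from every one-action neighbour.

    Columns sum to zero, so ``expm(L)`` is column-stochastic.
    """
    p_open = np.asarray(p_open, dtype=float)
    if ((p_open < 0) | (p_open > 1)).any():
        raise InvalidArgumentError("p_open entries must lie in [0, 1]")
    n = transitions.n_states
    if p_open.shape != (n,):
        raise InvalidArgumentError("p_open must have one entry per state")
    reachable = transitions.B.sum(axis=0) > 0  # [to, from], includes self-loops
    np.fill_diagonal(reachable, False)
    L = np.where(reachable, p_open[:, None], 0.0)
    np.fill_diagonal(L, 0.0)
    np.fill_diagonal(L, -L.sum(axis=0))
    return DiffusionGraph(L=L, p_open=p_open)


def preference_vector(
    graph: DiffusionGraph,
    current: int,
    target: int,
    cost_cap: float = COST_CAP,
    reach_threshold: float = REACH_THRESHOLD,
    variant: str = "one-sum",
) -> PreferenceVector:
    """Log-preferences over location outcomes for one trial.

    cost = cost_cap * [occupancy from ``current`` < reach_threshold]
           - ln(occupancy from ``target``)

    and the returned log-preference is ``-cost``.  The default ``"one-sum"``
    generator has columns summing to one (identity added to the zero-sum
    Laplacian), so its exponential is ``e`` times the column-stochastic kernel
    of the ``"zero-sum"`` variant.  The scale is an additive constant after
    the log -- irrelevant to policy selection -- but it *does* matter to the
    absolute reach threshold: with the zero-sum kernel, cells two moves away
    already dip below ``e**-3`` and get spuriously capped, which stalls
    navigation at the policy horizon.
    """
    n = graph.L.shape[0]
    if not (0 <= current < n and 0 <= target < n):
        raise InvalidArgumentError("current/target outside the state space")
    if variant == "one-sum":
        gen = graph.L + np.eye(n)
    elif variant == "zero-sum":
        gen = graph.L
    else:
        raise InvalidArgumentError(f"unknown variant {variant!r}")
    kernel = expm(gen)
    occ_current = kernel[:, current]
    occ_target = kernel[:, target]
    if occ_target.max() <= PROB_FLOOR:
        raise DegeneratePreferenceError("target diffuses no mass anywhere")
    cost = cost_cap * (occ_current < reach_threshold).astype(float)
    cost -= np.log(np.maximum(occ_target, PROB_FLOOR))
    return PreferenceVector(
        ln_p_where=-cost, cost_cap=cost_cap, reach_threshold=reach_threshold
    )
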