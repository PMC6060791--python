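"""Generative model of the grid-maze task.

The world is a rectangular grid of open/closed cells.  The agent's generative
model has a single hidden-state factor (its location, one state per cell) and
two outcome modalities:

* ``what`` -- whether the current cell is open or closed.  The mapping from
  location to this outcome is parameterised by a matrix of Dirichlet
  concentration parameters (``a_what``), so it can be *learned*.
* ``where`` -- the location itself, reported veridically (identity mapping).

Actions are single steps ``up/down/left/right`` plus ``stay``; each action has
a deterministic, column-stochastic transition matrix in which moves that would
leave the grid map a state to itself.  Policies are all action sequences of a
fixed (short) horizon.

Coordinates are row-major and 0-based with the origin at the top-left, so the
flat state index of cell ``(r, c)`` is ``r * n_cols + c`` and "the lower-left
entrance" is the last row, first column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import digamma

from .errors import InvalidArgumentError

__all__ = [
    "OPEN",
    "CLOSED",
    "PROB_FLOOR",
    "Action",
    "ACTION_ORDER",
    "MazeGrid",
    "LikelihoodModel",
    "TransitionSet",
    "PolicySet",
    "PreferenceModel",
    "AgentConfig",
    "GenerativeModel",
    "enumerate_policies",
    "build_transitions",
    "build_model",
    "expected_log_likelihood",
]

#: Outcome indices of the ``what`` modality (also used as cell codes).
OPEN, CLOSED = 0, 1

#: Floor applied to any probability before a logarithm is taken.
PROB_FLOOR = 1e-16


class Action(IntEnum):
    """Primitive moves, in the fixed order used for enumeration/tie-breaks."""

    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3
    STAY = 4


ACTION_ORDER: tuple[Action, ...] = (
    Action.UP,
    Action.DOWN,
    Action.LEFT,
    Action.RIGHT,
    Action.STAY,
)

_DELTAS = {
    Action.UP: (-1, 0),
    Action.DOWN: (1, 0),
    Action.LEFT: (0, -1),
    Action.RIGHT: (0, 1),
    Action.STAY: (0, 0),
}

_ASCII_CODES = {".": OPEN, "#": CLOSED, "S": OPEN, "T": OPEN}


@dataclass(frozen=True)
class MazeGrid:
    """Ground-truth maze: open/closed cells plus start and target locations.

    ``cells`` holds ``OPEN``/``CLOSED`` codes; ``start`` and ``target`` are
    flat state indices and must sit on open cells.
    """

    cells: np.ndarray
    start: int
    target: int

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        if cells.ndim != 2 or cells.size == 0:
            raise InvalidArgumentError("maze cells must form a non-empty 2-D grid")
        if not np.isin(cells, (OPEN, CLOSED)).all():
            raise InvalidArgumentError("maze cells must be OPEN or CLOSED")
        object.__setattr__(self, "cells", cells)
        n = cells.size
        for name in ("start", "target"):
            idx = getattr(self, name)
            if not (0 <= idx < n):
                raise InvalidArgumentError(f"{name} index {idx} outside the grid")
            if cells.flat[idx] != OPEN:
                raise InvalidArgumentError(f"{name} cell must be OPEN")

    # -- geometry ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def n_states(self) -> int:
        return self.cells.size

    def index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def coords(self, state: int) -> tuple[int, int]:
        return divmod(state, self.n_cols)

    def is_open(self, state: int) -> bool:
        return bool(self.cells.flat[state] == OPEN)

    #: Open-probability of every cell (1.0 open / 0.0 closed), flat order.
    @property
    def open_map(self) -> np.ndarray:
        return (self.cells.reshape(-1) == OPEN).astype(float)

    # -- ASCII round trip --------------------------------------------------
    @classmethod
    def from_ascii(cls, text: str) -> "MazeGrid":
        """Parse the maze format: ``#`` closed, ``.`` open, ``S`` start, ``T`` target."""
        rows = [line for line in text.splitlines() if line.strip()]
        if not rows:
            raise InvalidArgumentError("empty maze text")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise InvalidArgumentError("maze rows must all have the same length")
        cells = np.empty((len(rows), width), dtype=np.int8)
        start = target = None
        for r, line in enumerate(rows):
            for c, ch in enumerate(line):
                if ch not in _ASCII_CODES:
                    raise InvalidArgumentError(f"unknown maze character {ch!r}")
                cells[r, c] = _ASCII_CODES[ch]
                if ch == "S":
                    start = r * width + c
                elif ch == "T":
                    target = r * width + c
        if start is None or target is None:
            raise InvalidArgumentError("maze must mark exactly one S and one T")
        return cls(cells=cells, start=start, target=target)

    def to_ascii(self) -> str:
        chars = np.where(self.cells == OPEN, ".", "#").astype(object)
        sr, sc = self.coords(self.start)
        tr, tc = self.coords(self.target)
        chars[sr, sc] = "S"
        chars[tr, tc] = "T"
        return "\n".join("".join(row) for row in chars)


@dataclass
class LikelihoodModel:
    """Likelihood mappings: learnable ``what`` concentrations + identity ``where``."""

    a_what: np.ndarray  # [2, n_states] Dirichlet concentrations per column
    A_where: np.ndarray  # [n_states, n_states] identity

    def __post_init__(self) -> None:
        self.a_what = np.asarray(self.a_what, dtype=float)
        self.A_where = np.asarray(self.A_where, dtype=float)
        if self.a_what.ndim != 2 or self.a_what.shape[0] != 2:
            raise InvalidArgumentError("a_what must be [2, n_states]")
        if (self.a_what <= 0).any():
            raise InvalidArgumentError("concentrations must be positive")
        n = self.a_what.shape[1]
        if self.A_where.shape != (n, n):
            raise InvalidArgumentError("A_where must be square [n_states, n_states]")

    @property
    def n_states(self) -> int:
        return self.a_what.shape[1]


@dataclass(frozen=True)
class TransitionSet:
    """One deterministic column-stochastic matrix per action."""

    B: np.ndarray  # [n_actions, n_states, n_states]

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "B", B)
        if B.ndim != 3 or B.shape[1] != B.shape[2]:
            raise InvalidArgumentError("B must be [n_actions, n, n]")

    @property
    def n_actions(self) -> int:
        return self.B.shape[0]

    @property
    def n_states(self) -> int:
        return self.B.shape[1]

    def __getitem__(self, action: int) -> np.ndarray:
        return self.B[action]


@dataclass(frozen=True)
class PolicySet:
    """All action sequences of a fixed horizon, in lexicographic order."""

    horizon: int
    actions: tuple[int, ...]
    policies: np.ndarray  # [n_policies, horizon]

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]


@dataclass
class PreferenceModel:
    """Log-preferences over outcomes; behaviour is invariant to additive shifts."""

    c_what: np.ndarray  # [2]
    c_where: np.ndarray  # [n_states]

    def __post_init__(self) -> None:
        self.c_what = np.asarray(self.c_what, dtype=float)
        self.c_where = np.asarray(self.c_where, dtype=float)
        if not (np.isfinite(self.c_what).all() and np.isfinite(self.c_where).all()):
            raise InvalidArgumentError("preferences must be finite")


@dataclass
class AgentConfig:
    """Run-time constants of the belief-updating scheme.

    ``outcome_period_ms`` is the sampling interval of outcomes (one epoch);
    each epoch is resolved in ``iterations_per_epoch`` gradient iterations, so
    a trace bin lasts ``outcome_period_ms / iterations_per_epoch``.
    """

    horizon: int = 2
    outcome_period_ms: float = 256.0
    iterations_per_epoch: int = 16
    beta0: float = 1.0
    eta: float = 1.0
    decay: float = 0.0
    novelty_on: bool = True
    step_size: float = 0.25
    f_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1 or self.iterations_per_epoch < 1:
            raise InvalidArgumentError("horizon and iterations must be positive")
        if self.outcome_period_ms <= 0 or self.beta0 <= 0:
            raise InvalidArgumentError("durations and beta0 must be positive")

    @property
    def epochs_per_trial(self) -> int:
        return self.horizon + 1

    @property
    def bin_ms(self) -> float:
        return self.outcome_period_ms / self.iterations_per_epoch


@dataclass
class GenerativeModel:
    """Bundle of likelihood, transitions, preferences, initial prior and policies."""

    likelihood: LikelihoodModel
    transitions: TransitionSet
    preferences: PreferenceModel
    d: np.ndarray  # initial-state prior
    policy_set: PolicySet
    shape: tuple[int, int]

    @property
    def n_states(self) -> int:
        return self.likelihood.n_states


def enumerate_policies(
    actions: Sequence[int] = ACTION_ORDER, horizon: int = 2
) -> PolicySet:
    """Enumerate all ``|actions| ** horizon`` action sequences.

    Order is lexicographic in the given action order, which makes every
    downstream tie-break deterministic.
    """
    actions = tuple(int(a) for a in actions)
    if horizon < 1:
        raise InvalidArgumentError("horizon must be >= 1")
    if not actions:
        raise InvalidArgumentError("need at least one action")
    policies = np.array(
        list(itertools.product(actions, repeat=horizon)), dtype=np.int64
    )
    return PolicySet(horizon=horizon, actions=actions, policies=policies)


def build_transitions(n_rows: int, n_cols: int) -> TransitionSet:
    """Deterministic moves on the grid; boundary transgressions map to self."""
    n = n_rows * n_cols
    B = np.zeros((len(ACTION_ORDER), n, n))
    for a in ACTION_ORDER:
        dr, dc = _DELTAS[a]
        for s in range(n):
            r, c = divmod(s, n_cols)
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < n_rows and 0 <= c2 < n_cols):
                r2, c2 = r, c
            B[a, r2 * n_cols + c2, s] = 1.0
    return TransitionSet(B=B)


#: Concentration used for an unexplored cell (both outcomes equally plausible).
NOVEL_CONCENTRATION = 1.0 / 8.0
#: Concentration placed on the true outcome of a thoroughly learned cell.
FAMILIAR_CONCENTRATION = 128.0


def build_model(
    maze: MazeGrid,
    familiarity: Union[str, np.ndarray] = "novel",
    horizon: int = 2,
) -> GenerativeModel:
    """Construct the generative model for ``maze``.

    ``familiarity`` is ``"novel"`` (all ``what`` concentrations 1/8),
    ``"familiar"`` (128 on the true outcome of each cell, floored at 1/8 on
    the other) or an explicit ``[2, n_states]`` concentration matrix.
    """
    n = maze.n_states
    if isinstance(familiarity, str):
        if familiarity == "novel":
            a_what = np.full((2, n), NOVEL_CONCENTRATION)
        elif familiarity == "familiar":
            a_what = np.full((2, n), NOVEL_CONCENTRATION)
            truth = maze.cells.reshape(-1)
            a_what[truth, np.arange(n)] = FAMILIAR_CONCENTRATION
        else:
            raise InvalidArgumentError(f"unknown familiarity {familiarity!r}")
    else:
        a_what = np.asarray(familiarity, dtype=float)
        if a_what.shape != (2, n):
            raise InvalidArgumentError("concentration matrix must be [2, n_states]")
        if (a_what <= 0).any():
            raise InvalidArgumentError("concentrations must be positive")
        a_what = a_what.copy()

    likelihood = LikelihoodModel(a_what=a_what, A_where=np.eye(n))
    transitions = build_transitions(maze.n_rows, maze.n_cols)
    preferences = PreferenceModel(c_what=np.zeros(2), c_where=np.zeros(n))
    d = np.zeros(n)
    d[maze.start] = 1.0
    policy_set = enumerate_policies(ACTION_ORDER, horizon)
    return GenerativeModel(
        likelihood=likelihood,
        transitions=transitions,
        preferences=preferences,
        d=d,
        policy_set=policy_set,
        shape=(maze.n_rows, maze.n_cols),
    )


def expected_log_likelihood(
    a: np.ndarray, method: str = "digamma"
) -> tuple[np.ndarray, np.ndarray]:
    """Expectation ``Abar`` and expected log ``lnAbar`` of a Dirichlet likelihood.

    Columns of ``a`` are independent Dirichlet parameters.  ``lnAbar`` is the
    variational expectation ``digamma(a) - digamma(colsum(a))``; pass
    ``method="mean"`` for the plain log-of-mean ablation.
    """
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise InvalidArgumentError("concentrations must be positive")
    colsum = a.sum(axis=0, keepdims=True)
    abar = a / colsum
    if method == "digamma":
        ln_abar = digamma(a) - digamma(colsum)
    elif method == "mean":
        ln_abar = np.log(np.maximum(abar, PROB_FLOOR))
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return abar, ln_abar
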