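"""Ground-truth maze world: stepping, observation, synthesis and a BFS oracle.

Closed cells are physically enterable -- walls live in the agent's preferences,
not in the physics -- so "mistakes" (entries into closed cells) are possible
and countable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .model_core import ACTION_ORDER, CLOSED, OPEN, Action, MazeGrid, _DELTAS

__all__ = [
    "AgentState",
    "step",
    "observe",
    "generate_maze",
    "shortest_path",
    "is_solvable",
]


@dataclass
class AgentState:
    """Where the agent is and where it has been."""

    location: int
    move_count: int = 0
    visited: list[int] = field(default_factory=list)

    def record(self, new_location: int) -> None:
        self.location = new_location
        self.move_count += 1
        self.visited.append(new_location)


def step(maze: MazeGrid, location: int, action: int) -> int:
    """Apply one action; ``stay`` or a boundary transgression leaves it unchanged."""
    if not 0 <= location < maze.n_states:
        raise InvalidArgumentError(f"location {location} outside the grid")
    dr, dc = _DELTAS[Action(action)]
    r, c = maze.coords(location)
    r2, c2 = r + dr, c + dc
    if not (0 <= r2 < maze.n_rows and 0 <= c2 < maze.n_cols):
        return location
    return maze.index(r2, c2)


def observe(maze: MazeGrid, location: int) -> tuple[int, int]:
    """Return (what, where): the true cell state and the veridical location."""
    if not 0 <= location < maze.n_states:
        raise InvalidArgumentError(f"location {location} outside the grid")
    return int(maze.cells.flat[location]), location


def _open_neighbours(maze: MazeGrid, state: int):
    # Neighbour order follows the fixed action order -> deterministic ties.
    for action in ACTION_ORDER[:4]:
        nxt = step(maze, state, action)
        if nxt != state and maze.is_open(nxt):
            yield nxt


def shortest_path(maze: MazeGrid, a: int, b: int) -> list[int] | None:
    """Breadth-first shortest open path ``a -> b`` (inclusive), or None.

    Only OPEN cells are traversable; ties are broken by the fixed action order.
    """
    if not (maze.is_open(a) and maze.is_open(b)):
        return None
    prev: dict[int, int] = {a: a}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        if cur == b:
            path = [cur]
            while path[-1] != a:
                path.append(prev[path[-1]])
            return path[::-1]
        for nxt in _open_neighbours(maze, cur):
            if nxt not in prev:
                prev[nxt] = cur
                queue.append(nxt)
    return None


def is_solvable(maze: MazeGrid) -> bool:
    return shortest_path(maze, maze.start, maze.target) is not None


def _carve_path(
    maze_open: np.ndarray, n_rows: int, n_cols: int, start: int, target: int, rng
) -> list[int] | None:
    """Random self-avoiding walk start->target via randomised depth-first search."""
    stack = [start]
    seen = {start}
    while stack:
        cur = stack[-1]
        if cur == target:
            return list(stack)
        r, c = divmod(cur, n_cols)
        options = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                nxt = r2 * n_cols + c2
                if nxt not in seen:
                    options.append(nxt)
        if options:
            nxt = options[rng.integers(len(options))]
            seen.add(nxt)
            stack.append(nxt)
        else:
            stack.pop()
    return None


def generate_maze(
    n_rows: int = 8,
    n_cols: int = 8,
    wall_density: float = 0.35,
    seed: int = 0,
    max_attempts: int = 100,
) -> MazeGrid:
    """Synthesise a solvable maze, deterministically per seed.

    A random self-avoiding open path is carved from a bottom-left start to an
    interior target; the remaining cells are closed with probability
    ``wall_density``.  Regenerates until the BFS oracle confirms solvability.
    """
    if not 0.0 <= wall_density <= 1.0:
        raise InvalidArgumentError("wall_density must lie in [0, 1]")
    if n_rows < 2 or n_cols < 2:
        raise InvalidArgumentError("maze must be at least 2x2")
    rng = np.random.default_rng(seed)
    start = (n_rows - 1) * n_cols  # lower-left entrance
    for _ in range(max_attempts):
        # target deep within the maze: upper half, away from the side walls
        t_row = int(rng.integers(0, max(1, n_rows // 2)))
        t_col = int(rng.integers(1, n_cols - 1))
        target = t_row * n_cols + t_col
        if target == start:
            continue
        path = _carve_path(None, n_rows, n_cols, start, target, rng)
        if path is None:
            continue
        cells = np.where(
            rng.random((n_rows, n_cols)) < wall_density, CLOSED, OPEN
        ).astype(np.int8)
        for s in path:
            cells.flat[s] = OPEN
        maze = MazeGrid(cells=cells, start=start, target=target)
        if is_solvable(maze):
            return maze
    raise InvalidArgumentError("could not generate a solvable maze")
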