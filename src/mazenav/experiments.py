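"""End-to-end sessions: exploration, navigation, goal-directed search, sweep.

All randomness enters through the maze generator seed; given a maze and a
configuration every session is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import is_solvable, shortest_path
from .errors import InvalidArgumentError
from .inference import TrialResult, run_trial
from .model_core import AgentConfig, GenerativeModel, MazeGrid, build_model
from .neural import SessionTrace, performance_metrics
from .subgoals import build_graph_laplacian, preference_vector

__all__ = [
    "SessionConfig",
    "ExplorationResult",
    "NavigationResult",
    "SearchResult",
    "run_exploration",
    "run_navigation",
    "run_goal_exploration",
    "run_familiarity_sweep",
]


@dataclass
class SessionConfig:
    """Top-level run configuration for the CLI modes."""

    mode: str = "explore"
    maze_path: str | None = None
    n_rows: int = 8
    n_cols: int = 8
    wall_density: float = 0.35
    seed: int = 0
    trials: int = 32
    searches: int = 4
    familiarity: str = "novel"
    out_dir: str | None = None
    agent: AgentConfig = field(default_factory=AgentConfig)

    def __post_init__(self) -> None:
        if self.trials < 1 or self.searches < 1:
            raise InvalidArgumentError("trials and searches must be positive")

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "agent"}
        d["agent"] = self.agent.__dict__
        return json.dumps(d, indent=2)


def _new_trace(model: GenerativeModel, config: AgentConfig) -> SessionTrace:
    return SessionTrace(
        n_states=model.n_states,
        n_epochs=config.epochs_per_trial,
        bin_ms=config.bin_ms,
    )


def _refresh_preferences(model: GenerativeModel, location: int, target: int) -> None:
    from .model_core import expected_log_likelihood

    abar, _ = expected_log_likelihood(model.likelihood.a_what)
    graph = build_graph_laplacian(abar[0], model.transitions)
    prefs = preference_vector(graph, location, target)
    model.preferences.c_where = prefs.ln_p_where


@dataclass
class ExplorationResult:
    model: GenerativeModel
    trace: SessionTrace
    path: list[int]
    trials: list[TrialResult]
    snapshots: dict[int, np.ndarray]  # move count -> copy of a_what


def run_exploration(
    maze: MazeGrid,
    n_trials: int = 32,
    config: AgentConfig | None = None,
    snapshot_every_moves: int | None = None,
    record_trace: bool = True,
) -> ExplorationResult:
    """Pure epistemic foraging of a novel maze with flat preferences."""
    if not is_solvable(maze):
        raise InvalidArgumentError("maze is not solvable")
    config = config or AgentConfig()
    model = build_model(maze, "novel", horizon=config.horizon)
    trace = _new_trace(model, config) if record_trace else None
    location = maze.start
    path = [location]
    trials = []
    snapshots: dict[int, np.ndarray] = {}
    moves = 0
    for t in range(n_trials):
        res = run_trial(model, maze, location, config, trace=trace, trial_index=t)
        trials.append(res)
        path.extend(res.path[1:])
        location = res.path[-1]
        moves += len(res.actions)
        if snapshot_every_moves and moves % snapshot_every_moves == 0:
            snapshots[moves] = model.likelihood.a_what.copy()
    snapshots[moves] = model.likelihood.a_what.copy()
    return ExplorationResult(
        model=model, trace=trace, path=path, trials=trials, snapshots=snapshots
    )


@dataclass
class NavigationResult:
    trace: SessionTrace
    path: list[int]
    latency: int | None
    mistakes: int
    shortest_len: int | None
    trials: list[TrialResult]


def run_navigation(
    maze: MazeGrid,
    model: GenerativeModel | None = None,
    config: AgentConfig | None = None,
    max_trials: int = 16,
    learn: bool = True,
    start: int | None = None,
    record_trace: bool = True,
) -> NavigationResult:
    """Goal-directed navigation start -> target under subgoal preferences.

    Preferences are refreshed from the current beliefs before every trial; the
    session ends as soon as the target is occupied (or the trial budget runs
    out).  With a familiar model the traversed path matches the BFS shortest
    path with zero mistakes.
    """
    config = config or AgentConfig()
    model = model if model is not None else build_model(maze, "familiar", config.horizon)
    trace = _new_trace(model, config) if record_trace else None
    location = maze.start if start is None else start
    path = [location]
    trials = []
    reached = location == maze.target
    for t in range(max_trials):
        if reached:
            break
        _refresh_preferences(model, location, maze.target)
        res = run_trial(model, maze, location, config, trace=trace, trial_index=t, learn=learn)
        trials.append(res)
        path.extend(res.path[1:])
        location = res.path[-1]
        if maze.target in res.path:
            reached = True
    latency, mistakes = performance_metrics(path, maze) if path[0] == maze.start else (None, 0)
    sp = shortest_path(maze, maze.start, maze.target)
    return NavigationResult(
        trace=trace,
        path=path,
        latency=latency,
        mistakes=mistakes,
        shortest_len=None if sp is None else len(sp) - 1,
        trials=trials,
    )


@dataclass
class SearchResult:
    search: int
    path: list[int]
    latency: int | None
    mistakes: int
    trace: SessionTrace
    a_what: np.ndarray


def run_goal_exploration(
    maze: MazeGrid,
    searches: int = 4,
    trials_per_search: int = 8,
    config: AgentConfig | None = None,
    record_trace: bool = True,
) -> list[SearchResult]:
    """Repeated goal-directed searches of a novel maze.

    The agent starts each search at the maze start; likelihood concentrations
    persist across searches while beliefs reset every trial.  Every search
    comprises the full trial budget; latency and mistakes are scored en route
    (up to the first arrival at the target).
    """
    if not is_solvable(maze):
        raise InvalidArgumentError("maze is not solvable")
    config = config or AgentConfig()
    model = build_model(maze, "novel", horizon=config.horizon)
    results = []
    for search in range(searches):
        trace = _new_trace(model, config) if record_trace else None
        location = maze.start
        path = [location]
        for t in range(trials_per_search):
            _refresh_preferences(model, location, maze.target)
            res = run_trial(model, maze, location, config, trace=trace, trial_index=t)
            path.extend(res.path[1:])
            location = res.path[-1]
        latency, mistakes = performance_metrics(path, maze)
        results.append(
            SearchResult(
                search=search,
                path=path,
                latency=latency,
                mistakes=mistakes,
                trace=trace,
                a_what=model.likelihood.a_what.copy(),
            )
        )
    return results


def run_familiarity_sweep(
    maze: MazeGrid,
    durations_s: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16),
    config: AgentConfig | None = None,
    max_trials: int = 16,
) -> pd.DataFrame:
    """Exposure-duration -> navigation-performance curve.

    The maze is explored once; likelihood concentrations are snapshotted at
    each requested duration of simulated time (moves x outcome period), then
    frozen and used for a goal-directed navigation whose latency and mistakes
    are recorded.
    """
    config = config or AgentConfig()
    move_s = config.outcome_period_ms / 1000.0
    moves_per_trial = config.horizon
    wanted_moves = []
    for d in durations_s:
        m = int(round(d / move_s / moves_per_trial)) * moves_per_trial
        wanted_moves.append(max(m, moves_per_trial))
    n_trials = max(wanted_moves) // moves_per_trial
    expl = run_exploration(
        maze,
        n_trials=n_trials,
        config=config,
        snapshot_every_moves=moves_per_trial,
        record_trace=False,
    )
    rows = []
    for d, m in zip(durations_s, wanted_moves):
        snap_moves = max(k for k in expl.snapshots if k <= m)
        model = build_model(maze, expl.snapshots[snap_moves], horizon=config.horizon)
        nav = run_navigation(
            maze, model, config, max_trials=max_trials, learn=False, record_trace=False
        )
        rows.append(
            {
                "duration_s": d,
                "moves_explored": snap_moves,
                "latency": nav.latency,
                "mistakes": nav.mistakes,
                "shortest_len": nav.shortest_len,
            }
        )
    return pd.DataFrame(rows)


def save_path_log(path: list[int], maze: MazeGrid, out: str | Path) -> None:
    """CSV log: (move_index, row, col, what_observed, mistake_flag)."""
    rows = []
    for i, loc in enumerate(path):
        r, c = maze.coords(loc)
        closed = maze.cells.flat[loc] != 0
        mistake = bool(closed and i > 0 and path[i - 1] != loc)
        rows.append(
            {
                "move_index": i,
                "row": r,
                "col": c,
                "what_observed": "closed" if closed else "open",
                "mistake_flag": int(mistake),
            }
        )
    pd.DataFrame(rows).to_csv(out, index=False)
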