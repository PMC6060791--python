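# mazenav

An active-inference agent that forages for information and navigates to goals
in grid mazes. The agent holds a discrete generative model of an 8×8 maze
(location as the hidden state; `what` = open/closed and `where` = veridical
position as outcome modalities), updates beliefs by relaxing log expectations
toward exact per-policy posteriors, scores its 25 two-move policies by
expected free energy (risk + ambiguity − novelty), and learns the maze by
accumulating Dirichlet concentration counts. A graph-Laplacian diffusion
heuristic converts a distal target into attainable subgoal preferences, and a
synthetic neural readout turns the session trace into rasters, LFPs,
time–frequency maps, dopamine (precision) signals and place/path-cell
classifications.

## Layout

| module | contents |
| --- | --- |
| `mazenav.model_core` | maze grids (ASCII I/O), likelihood/transition/policy/preference types, model constructors |
| `mazenav.inference` | state inference, expected free energy, policy posterior, precision, action selection, learning, the trial loop |
| `mazenav.subgoals` | graph Laplacian, diffusion kernel, subgoal preference vectors |
| `mazenav.environment` | stepping, observation, seeded maze synthesis, BFS shortest-path oracle |
| `mazenav.neural` | session traces, rasters, LFP/spectrogram, dopamine, unit classification, latency/mistake metrics |
| `mazenav.experiments` / `mazenav.cli` | end-to-end sessions (explore, navigate, goal-explore, familiarity sweep) and the CLI |

## CLI

```sh
mazenav explore --gen 8x8 --seed 3 --trials 32 --out out/explore
mazenav navigate --gen 8x8 --seed 3 --known --out out/nav
mazenav goal-explore --gen 8x8 --seed 3 --searches 4 --trials 8 --out out/goal
mazenav sweep --gen 8x8 --seed 3 --out out/sweep
mazenav analyze-units --gen 8x8 --seed 3 --out out/units
```

Mazes can also be given as ASCII files (`--maze path`): `#` closed, `.` open,
`S` start, `T` target, one line per row. Every run writes a config echo, the
maze, per-move CSV logs, metrics JSON and CSV trace matrices.

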