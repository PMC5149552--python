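"""Deterministic grid-maze environments for spatial-navigation experiments.

A maze is a rectangular grid of discrete cells. The agent occupies one cell,
knows nothing but its own location, and moves with four compass actions.
Bumping into a wall (or the arena boundary) leaves the agent in place and
costs ``wall_penalty``; stepping onto the goal pays ``goal_reward`` and ends
the trial (the experiment driver relocates the agent to the start cell).

Cells are 0-based ``(row, col)`` pairs; internally states are flat indices
``row * cols + col``. Actions are indexed ``0..3`` in the fixed order
up, down, left, right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "ACTIONS",
    "UP",
    "DOWN",
    "LEFT",
    "RIGHT",
    "GridMaze",
    "Experience",
    "step",
    "make_open_arena",
    "scale_arena",
    "make_adaptation_maze",
    "make_four_goal_arena",
    "FOUR_GOAL_SITES",
    "read_maze",
    "write_maze",
    "maze_by_name",
]

UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
ACTIONS = ("up", "down", "left", "right")
#: (drow, dcol) for each action index.
DELTAS = ((-1, 0), (1, 0), (0, -1), (0, 1))


class MazeFormatError(ValueError):
    """Raised for malformed ASCII maze text."""


@dataclass(frozen=True)
class Experience:
    """One observed transition ``<s, a, s', r>`` (flat state indices)."""

    state: int
    action: int
    next_state: int
    reward: float


@dataclass(frozen=True)
class GridMaze:
    """Discrete rectangular arena with walls, a start cell and a goal cell."""

    rows: int
    cols: int
    walls: frozenset = field(default_factory=frozenset)
    start: tuple = (0, 0)
    goal: tuple = (0, 1)
    goal_reward: float = 100.0
    wall_penalty: float = -1.0
    step_cap: int = 5000
    name: str = "maze"

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError("maze dimensions must be at least 2x2")
        for label, cell in (("start", self.start), ("goal", self.goal)):
            if not self.in_bounds(cell):
                raise ValueError(f"{label} cell {cell} out of bounds")
            if cell in self.walls:
                raise ValueError(f"{label} cell {cell} is a wall")
        if self.start == self.goal:
            raise ValueError("start and goal must differ")

    # -- geometry -----------------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.rows * self.cols

    @property
    def n_free(self) -> int:
        return self.n_states - len(self.walls)

    def in_bounds(self, cell) -> bool:
        r, c = cell
        return 0 <= r < self.rows and 0 <= c < self.cols

    def index(self, cell) -> int:
        return cell[0] * self.cols + cell[1]

    def cell(self, state: int) -> tuple:
        return divmod(state, self.cols)

    @property
    def start_state(self) -> int:
        return self.index(self.start)

    @property
    def goal_state(self) -> int:
        return self.index(self.goal)

    def neighbor(self, state: int, action: int):
        """Flat index of the in-bounds grid neighbor, or None at the edge.

        Pure geometry: walls are cells too, and the agent cannot sense them.
        """
        r, c = divmod(state, self.cols)
        dr, dc = DELTAS[action]
        r, c = r + dr, c + dc
        if 0 <= r < self.rows and 0 <= c < self.cols:
            return r * self.cols + c
        return None

    def transition(self, state: int, action: int):
        """Fast flat-index transition: ``(next_state, reward, goal_reached)``."""
        nxt = self.neighbor(state, action)
        if nxt is None or self.cell(nxt) in self.walls:
            return state, self.wall_penalty, False
        if nxt == self.goal_state:
            return nxt, self.goal_reward, True
        return nxt, 0.0, False


def step(maze: GridMaze, state, action):
    """Advance one step from ``state`` (a ``(row, col)`` cell) along ``action``.

    Returns ``(next_cell, reward, goal_reached)``. Moving into a wall or off
    the grid keeps the agent in place with ``wall_penalty``; entering the goal
    pays ``goal_reward`` and sets the flag (the caller relocates the agent).
    """
    if isinstance(action, str):
        action = ACTIONS.index(action)
    if not maze.in_bounds(state) or tuple(state) in maze.walls:
        raise ValueError(f"invalid state {state}: out of bounds or inside a wall")
    s = maze.index(state)
    nxt, reward, done = maze.transition(s, action)
    return maze.cell(nxt), reward, done


# -- builders ---------------------------------------------------------------

def _default_placement(rows: int, cols: int):
    """Start mid-height near the left end, goal mid-height near the right
    (clamped inward so tiny arenas stay valid)."""
    start_col = min(2, cols - 2)
    goal_col = max(cols - 3, start_col + 1)
    return (rows // 2, start_col), (rows // 2, goal_col)


def make_open_arena(rows: int, cols: int, start=None, goal=None, **kw) -> GridMaze:
    """Wall-free rectangular arena (the 'open field' task geometry)."""
    d_start, d_goal = _default_placement(rows, cols)
    return GridMaze(
        rows,
        cols,
        frozenset(),
        start if start is not None else d_start,
        goal if goal is not None else d_goal,
        name=kw.pop("name", f"open{rows}x{cols}"),
        **kw,
    )


def scale_arena(base_rows: int = 16, base_cols: int = 48, factor: float = 1,
                **kw) -> GridMaze:
    """Open arena scaled by ``factor``; start/goal rescale proportionally.

    The per-trial step cap scales with the factor as well, since the base cap
    is defined for the 16x48 arena.
    """
    rows, cols = base_rows * factor, base_cols * factor
    if rows != int(rows) or cols != int(cols):
        raise ValueError(f"factor {factor} does not give integer dimensions")
    rows, cols = int(rows), int(cols)
    b_start, b_goal = _default_placement(base_rows, base_cols)
    start = (int(b_start[0] * factor), int(b_start[1] * factor))
    goal = (int(b_goal[0] * factor), int(b_goal[1] * factor))
    cap = kw.pop("step_cap", None)
    if cap is None:
        cap = int(round(5000 * factor))
    return make_open_arena(rows, cols, start, goal, step_cap=cap,
                           name=f"scaled{factor}", **kw)


def _wall_run(r0, r1, c0, c1) -> Iterable:
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            yield (r, c)


#: Internal-boundary layouts added to the 16x48 arena after the tenth trial.
#: Each is a list of inclusive (row0, row1, col0, col1) wall runs drawn so
#: that the previously learned straight route is cut and a detour is forced.
_ADAPTATION_WALLS = {
    "A": [(0, 11, 24, 24)],                         # wall from the top, gap below
    "B": [(4, 15, 24, 24)],                         # wall from the bottom, gap above
    "C": [(0, 11, 16, 16), (4, 15, 32, 32)],        # zig-zag through two walls
    "D": [(0, 11, 12, 12), (4, 15, 24, 24), (0, 11, 36, 36)],  # serpentine
    "E": [(2, 13, 40, 40), (2, 2, 40, 46), (13, 13, 40, 46)],  # pocket round the goal
}


def make_adaptation_maze(variant: str, **kw) -> GridMaze:
    """16x48 arena plus the internal boundaries of panel ``variant`` (A..E)."""
    variant = variant.upper()
    if variant not in _ADAPTATION_WALLS:
        raise ValueError(f"unknown adaptation variant {variant!r} (use A..E)")
    walls = frozenset(
        cell for run in _ADAPTATION_WALLS[variant] for cell in _wall_run(*run)
    )
    start, goal = _default_placement(16, 48)
    return GridMaze(16, 48, walls, start, goal, name=f"adapt{variant}", **kw)


#: Reward sites of the probabilistic-reward task, in a 7x7 arena whose start
#: is the centre of the bottom row. One site is armed per trial.
FOUR_GOAL_SITES = ((0, 0), (0, 6), (3, 3), (6, 6))


def make_four_goal_arena(site_index: int = 0, **kw) -> GridMaze:
    """7x7 arena for the four-goal context task; ``site_index`` arms one site."""
    goal = FOUR_GOAL_SITES[site_index]
    return GridMaze(7, 7, frozenset(), (6, 3), goal, step_cap=500,
                    name=f"fourgoal7x7[{site_index}]", **kw)


# -- ASCII I/O --------------------------------------------------------------

def write_maze(maze: GridMaze) -> str:
    """Render a maze as text: '#' wall, '.' free, 'S' start, 'G' goal."""
    lines = []
    for r in range(maze.rows):
        row = []
        for c in range(maze.cols):
            if (r, c) == maze.start:
                row.append("S")
            elif (r, c) == maze.goal:
                row.append("G")
            elif (r, c) in maze.walls:
                row.append("#")
            else:
                row.append(".")
        lines.append("".join(row))
    return "\n".join(lines) + "\n"


def read_maze(text: str, **kw) -> GridMaze:
    """Parse the ASCII format produced by :func:`write_maze`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MazeFormatError("empty maze text")
    cols = len(lines[0])
    if any(len(ln) != cols for ln in lines):
        raise MazeFormatError("ragged rows in maze text")
    walls, start, goal = set(), None, None
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln):
            if ch == "#":
                walls.add((r, c))
            elif ch == "S":
                if start is not None:
                    raise MazeFormatError("duplicate start cell 'S'")
                start = (r, c)
            elif ch == "G":
                if goal is not None:
                    raise MazeFormatError("duplicate goal cell 'G'")
                goal = (r, c)
            elif ch != ".":
                raise MazeFormatError(f"unknown character {ch!r}")
    if start is None or goal is None:
        raise MazeFormatError("maze text must contain exactly one 'S' and one 'G'")
    return GridMaze(len(lines), cols, frozenset(walls), start, goal, **kw)


def maze_by_name(name: str) -> GridMaze:
    """Resolve CLI maze names: open16x48, adaptA..E, fourgoal7x7, scaled:<f>."""
    if name == "open16x48":
        return make_open_arena(16, 48)
    if name.startswith("adapt") and len(name) == 6:
        return make_adaptation_maze(name[5])
    if name == "fourgoal7x7":
        return make_four_goal_arena()
    if name.startswith("scaled:"):
        f = float(name.split(":", 1)[1])
        return scale_arena(factor=int(f) if f.is_integer() else f)
    raise ValueError(f"unknown maze name {name!r}")
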