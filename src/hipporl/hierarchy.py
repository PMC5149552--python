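"""Hierarchical spatial abstraction and the planning agent.

Space is represented at multiple resolutions, coarsening the grid the way
place-field size grows along the hippocampal septotemporal axis: level 0 is
the raw maze grid and each higher level aggregates 2x2 blocks of the level
below (groups of four along the long axis once one dimension collapses to
1), until a single macro-state remains. One tabular world model and one
prioritized-sweeping value table run per level, with discount factors
decreasing with abstraction so that no level dominates goal setting.

Acting combines three pieces:

* goal selection — the maximum action value across all levels nominates a
  (macro-)state, the one where the best action is expected to lead;
* successive refinement — A* forward sweeps plan a route to the goal region
  at the level below the goal, then each lower level re-plans the first leg
  at finer resolution, down to a concrete base-level move;
* an epsilon-greedy policy — the planned action executes with probability
  ``epsilon`` (here 0.8), otherwise a uniformly random action.

A single-level agent has no higher level to set goals and degenerates to
conventional tabular MBRL: it acts epsilon-greedily on its local action
values. ``ConventionalAgent`` builds exactly that configuration.
"""

from __future__ import annotations

import heapq

import numpy as np

from .gridworld import Experience, GridMaze
from .planner_rl import N_ACTIONS, PrioritizedSweeper, q_learning_update  # noqa: F401
from .world_model import WorldModel, grid_candidates

__all__ = ["LevelGeometry", "Level", "build_hierarchy",
           "HierarchicalAgent", "ConventionalAgent", "level_shapes"]

_NEG_INF = float("-inf")


class LevelGeometry:
    """Rectangular grid of macro-states at one abstraction level."""

    __slots__ = ("rows", "cols", "n_states")

    def __init__(self, rows: int, cols: int):
        self.rows = rows
        self.cols = cols
        self.n_states = rows * cols

    def neighbor(self, s: int, a: int):
        r, c = divmod(s, self.cols)
        if a == 0:
            r -= 1
        elif a == 1:
            r += 1
        elif a == 2:
            c -= 1
        else:
            c += 1
        if 0 <= r < self.rows and 0 <= c < self.cols:
            return r * self.cols + c
        return None

    def direction(self, s: int, s2: int):
        """Compass action from s to adjacent macro-state s2, else None."""
        r, c = divmod(s, self.cols)
        r2, c2 = divmod(s2, self.cols)
        dr, dc = r2 - r, c2 - c
        if (dr, dc) == (-1, 0):
            return 0
        if (dr, dc) == (1, 0):
            return 1
        if (dr, dc) == (0, -1):
            return 2
        if (dr, dc) == (0, 1):
            return 3
        return None


def level_shapes(rows: int, cols: int):
    """Shapes of every abstraction level, finest to coarsest (ends at 1x1)."""
    shapes = [(rows, cols)]
    while shapes[-1][0] * shapes[-1][1] > 1:
        r, c = shapes[-1]
        if r == 1:
            r2, c2 = 1, (c + 3) // 4
        elif c == 1:
            r2, c2 = (r + 3) // 4, 1
        else:
            r2, c2 = (r + 1) // 2, (c + 1) // 2
        shapes.append((r2, c2))
    return shapes


def _parent_map(child: LevelGeometry, parent: LevelGeometry) -> np.ndarray:
    """child state id -> parent macro id (total, single valued)."""
    m = np.empty(child.n_states, dtype=np.int64)
    for s in range(child.n_states):
        r, c = divmod(s, child.cols)
        if child.rows == 1 and parent.rows == 1 and parent.cols < (child.cols + 1) // 2:
            pr, pc = 0, c // 4
        elif child.cols == 1 and parent.cols == 1 and parent.rows < (child.rows + 1) // 2:
            pr, pc = r // 4, 0
        else:
            pr, pc = min(r // 2, parent.rows - 1), min(c // 2, parent.cols - 1)
        m[s] = pr * parent.cols + pc
    return m


class Level:
    """One abstraction level: geometry, world model, planner, accumulator."""

    def __init__(self, index: int, geometry: LevelGeometry, gamma: float,
                 budget: int, optimism: float, priority_threshold: float,
                 track_distribution: bool = False):
        self.index = index
        self.geometry = geometry
        self.budget = budget
        self.model = WorldModel(grid_candidates(geometry.neighbor),
                                track_distribution=track_distribution)
        self.sweeper = PrioritizedSweeper(
            self.model, geometry.n_states, gamma=gamma, optimism=optimism,
            priority_threshold=priority_threshold,
            neighbor_fn=geometry.neighbor)
        # max base-level reward seen during the current macro-state occupancy
        self.reward_accumulator = _NEG_INF

    @property
    def q(self) -> np.ndarray:
        return self.sweeper.qtable.q

    @property
    def gamma(self) -> float:
        return self.sweeper.qtable.gamma


def discount_schedule(n_levels: int, low: float = 0.5, high: float = 0.9):
    """Linear per-level discounts from ``high`` (base) down to ``low`` (top)."""
    if n_levels == 1:
        return [high]
    return [high - (high - low) * i / (n_levels - 1) for i in range(n_levels)]


def build_hierarchy(maze: GridMaze, n_levels=None, budget_per_level: int = 20,
                    discounts=None, optimism=None, priority_threshold=1e-4,
                    track_distribution=False):
    """Create the stack of levels for ``maze`` (all levels by default)."""
    shapes = level_shapes(maze.rows, maze.cols)
    if n_levels is not None:
        shapes = shapes[:n_levels]
    geoms = [LevelGeometry(r, c) for r, c in shapes]
    if discounts is None:
        discounts = discount_schedule(len(geoms))
    if optimism is None:
        optimism = abs(maze.goal_reward)
    levels = []
    for i, g in enumerate(geoms):
        levels.append(Level(i, g, discounts[i], budget_per_level, optimism,
                            priority_threshold,
                            track_distribution=(track_distribution and i == 0)))
    return levels


class HierarchicalAgent:
    """Multi-resolution model-based RL agent with forward-sweep planning."""

    def __init__(self, maze: GridMaze, n_levels=None, budget_per_level=20,
                 epsilon: float = 0.8, discounts=None, optimism=None,
                 priority_threshold: float = 1e-4, rng=None,
                 track_distribution: bool = False):
        if not 0.0 <= epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        self.maze = maze
        self.epsilon = epsilon
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.levels = build_hierarchy(
            maze, n_levels=n_levels, budget_per_level=budget_per_level,
            discounts=discounts, optimism=optimism,
            priority_threshold=priority_threshold,
            track_distribution=track_distribution)
        # base cell -> macro id, per level (level 0 is the identity)
        self.base_parent = [np.arange(self.levels[0].geometry.n_states)]
        # level-(k) macro id -> array of level-(k-1) children
        self.children = [None]
        for k in range(1, len(self.levels)):
            pm = _parent_map(self.levels[k - 1].geometry, self.levels[k].geometry)
            self.base_parent.append(pm[self.base_parent[k - 1]])
            kids = [[] for _ in range(self.levels[k].geometry.n_states)]
            for child, par in enumerate(pm):
                kids[par].append(child)
            self.children.append([tuple(c) for c in kids])
        self.plan_accesses = 0

    # -- bookkeeping --------------------------------------------------------
    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def accesses(self) -> int:
        """Cumulative model accesses: backups plus planning expansions."""
        return self.plan_accesses + sum(l.sweeper.accesses for l in self.levels)

    def end_trial(self) -> None:
        for lev in self.levels:
            lev.reward_accumulator = _NEG_INF

    # -- learning -----------------------------------------------------------
    def on_step(self, e: Experience, goal_reached: bool = False) -> None:
        """Absorb one base experience into every level, then sweep."""
        lev0 = self.levels[0]
        lev0.model.observe(e)
        lev0.sweeper.notify(e)
        for k in range(1, self.n_levels):
            lev = self.levels[k]
            lev.reward_accumulator = max(lev.reward_accumulator, e.reward)
            m = int(self.base_parent[k][e.state])
            m2 = int(self.base_parent[k][e.next_state])
            if m2 != m or goal_reached:
                a = e.action if m2 == m else lev.geometry.direction(m, m2)
                # A goal entry ends the episode: the transition is absorbing
                # at abstract levels, else a rewarded macro self-loop would
                # bootstrap its own value without bound.
                if goal_reached and a is not None:
                    lev.sweeper.mark_absorbing(m, a, m2)
                if a is not None:
                    me = Experience(m, a, m2, lev.reward_accumulator)
                    lev.model.observe(me)
                    if m2 == m:
                        # a goal entry inside one macro-state is not a bounce
                        lev.model._blocked.discard((m, a))
                    lev.sweeper.notify(me)
                lev.reward_accumulator = _NEG_INF
        for lev in self.levels:
            lev.sweeper.sweep(lev.budget)

    # -- goal selection -----------------------------------------------------
    def select_goal(self):
        """Best action value anywhere: (level, source, action, goal state).

        The goal state is where the best action is expected to lead under
        that level's T table. Exact value ties resolve toward the finest
        level: before any reward is known the table maximum is the shared
        optimistic constant, and consuming untried pairs in finest-level
        index order makes exploration an efficient near-deterministic
        raster instead of a scatter of cross-arena macro errands. Returns
        None when no action value is positive (the caller explores at
        random).
        """
        best = None
        best_v = 0.0
        for k in range(self.n_levels):
            q = self.levels[k].q
            self.plan_accesses += 1
            flat = int(np.argmax(q))
            v = float(q.flat[flat])
            if v > best_v:
                best_v = v
                best = (k, flat // N_ACTIONS, flat % N_ACTIONS)
        if best is None:
            return None
        k, s, a = best
        return k, s, a, self.levels[k].model.predicted_successor(s, a)

    # -- A* forward sweep ---------------------------------------------------
    def plan_route(self, level: int, source: int, targets, domain=None):
        """A* through the level's transition web from ``source`` to any of
        ``targets``; untried moves are optimistically assumed passable, and
        value estimates break expansion ties. Returns the state sequence or
        None."""
        lev = self.levels[level]
        geom, model, v = lev.geometry, lev.model, lev.sweeper._v
        targets = set(targets)
        if source in targets:
            return [source]
        cols = geom.cols
        tcells = [divmod(t, cols) for t in targets]

        def h(s):
            r, c = divmod(s, cols)
            return min(abs(r - tr) + abs(c - tc) for tr, tc in tcells)

        g_cost = {source: 0}
        came = {}
        seq = 0
        open_heap = [(h(source), -float(v[source]), 0, source)]
        closed = set()
        while open_heap:
            f, _, seq_, s = heapq.heappop(open_heap)
            if s in closed:
                continue
            closed.add(s)
            self.plan_accesses += 1
            if s in targets:
                path = [s]
                while s in came:
                    s = came[s]
                    path.append(s)
                path.reverse()
                return path
            g = g_cost[s]
            for a in range(N_ACTIONS):
                if model.blocked(s, a):
                    continue
                nxt = geom.neighbor(s, a)
                if nxt is None or nxt in closed:
                    continue
                if domain is not None and nxt not in domain and nxt not in targets:
                    continue
                ng = g + 1
                if ng < g_cost.get(nxt, 1 << 30):
                    g_cost[nxt] = ng
                    came[nxt] = s
                    seq += 1
                    heapq.heappush(open_heap,
                                   (ng + h(nxt), -float(v[nxt]), seq, nxt))
        return None

    # -- acting -------------------------------------------------------------
    def _random_action(self) -> int:
        return int(self.rng.integers(N_ACTIONS))

    def _epsilon_greedy(self, planned: int) -> int:
        if self.rng.random() < self.epsilon:
            return planned
        return self._random_action()

    def _local_greedy_action(self, state: int) -> int:
        """Conventional MBRL action: argmax over the local Q row, random ties."""
        row = self.levels[0].q[state]
        self.plan_accesses += 1
        best = np.flatnonzero(row == row.max())
        if len(best) == 1:
            return int(best[0])
        return int(self.rng.choice(best))

    def refine_and_act(self, state: int) -> int:
        """Select a goal and refine a route to it down to one base action."""
        goal = self.select_goal()
        if goal is None:
            return self._random_action()
        glevel, gsource, gaction, gstate = goal
        if glevel == 0:
            # route to the valued pair's source cell and execute its action
            # there; the pair's expected successor is the goal state proper
            if state == gsource:
                return self._epsilon_greedy(gaction)
            plan = self.plan_route(0, state, (gsource,))
            if plan is None:
                return self._random_action()
            if len(plan) < 2:
                return self._epsilon_greedy(self._local_greedy_action(state))
            planned = self.levels[0].geometry.direction(plan[0], plan[1])
            return self._epsilon_greedy(planned)
        waypoint = gstate
        for k in range(glevel - 1, -1, -1):
            src = int(self.base_parent[k][state])
            targets = self.children[k + 1][waypoint]
            if k == glevel - 1:
                domain = None
            else:
                cur_above = int(self.base_parent[k + 1][state])
                domain = set(self.children[k + 1][cur_above])
                domain.update(targets)
            plan = self.plan_route(k, src, targets, domain)
            if plan is None and domain is not None:
                plan = self.plan_route(k, src, targets, None)
            if plan is None:
                return self._random_action()
            waypoint = plan[1] if len(plan) > 1 else plan[0]
        if waypoint == state:
            # inside the goal region at every resolution: the plan cannot
            # name a move, so follow the local value gradient instead
            return self._epsilon_greedy(self._local_greedy_action(state))
        planned = self.levels[0].geometry.direction(state, waypoint)
        if planned is None:
            return self._random_action()
        return self._epsilon_greedy(planned)

    def act(self, state: int) -> int:
        """Choose the next base-level action from ``state``."""
        if self.n_levels == 1:
            return self._epsilon_greedy(self._local_greedy_action(state))
        return self.refine_and_act(state)


def ConventionalAgent(maze: GridMaze, budget: int = 120, epsilon: float = 0.8,
                      gamma: float = 0.9, rng=None, **kw) -> HierarchicalAgent:
    """Non-hierarchical tabular MBRL baseline: a single-level agent that
    sweeps with the full update budget and acts greedily on its local Q."""
    return HierarchicalAgent(maze, n_levels=1, budget_per_level=budget,
                             epsilon=epsilon, discounts=[gamma], rng=rng, **kw)
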