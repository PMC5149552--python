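"""Simulated hippocampal lesions.

A ventral (vH) lesion removes the coarse upper levels of the spatial
hierarchy, leaving only the finest level — the agent degenerates to
conventional single-level MBRL and must learn without abstract goal
setting. A dorsal (dH) lesion removes the fine levels instead: the highest
informative level survives as a model-based goal-setter, while base-level
action selection falls back on a slow model-free Q-learner, so the agent
can reach the general goal region but must rediscover the exact goal cell
by near-random motion every time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridworld import Experience
from .hierarchy import HierarchicalAgent, N_ACTIONS
from .planner_rl import QTable, q_learning_update

__all__ = ["LesionSpec", "apply_lesion", "DHLesionedAgent"]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class LesionSpec:
    kind: str = "none"

    def __post_init__(self):
        if self.kind not in ("none", "vH", "dH"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")


class DHLesionedAgent:
    """Dorsal-lesioned agent: top-level model-based goal-setting plus a
    base-level model-free learner.

    The surviving macro level is the highest one with more than one state
    (the literal topmost level is a single macro-state and cannot express a
    goal). Once its world model associates reward with a macro-state, a
    compass policy steers the agent to the nearest cell of that region;
    inside it, the epsilon-greedy model-free values (random tie-breaks)
    take over, so the agent reaches the general goal region quickly but
    must rediscover the exact goal cell by near-random motion until the
    model-free table converges. Before any reward has been seen the agent
    relies on random motion.
    """

    def __init__(self, intact: HierarchicalAgent, alpha: float = 0.1,
                 gamma: float = 0.9, budget: int = 120):
        keep = max((k for k, lev in enumerate(intact.levels)
                    if lev.geometry.n_states > 1), default=0)
        self.level = intact.levels[keep]
        self.level.budget = budget
        self.base_parent = intact.base_parent[keep]
        self.maze = intact.maze
        self.epsilon = intact.epsilon
        self.rng = intact.rng
        self.alpha = alpha
        n_base = intact.levels[0].geometry.n_states
        self.qfree = QTable(n_base, gamma=gamma, init=0.0)
        self.reward_seen = False
        self.plan_accesses = 0

    @property
    def accesses(self) -> int:
        return self.plan_accesses + self.level.sweeper.accesses

    def end_trial(self) -> None:
        self.level.reward_accumulator = _NEG_INF

    def on_step(self, e: Experience, goal_reached: bool = False) -> None:
        if e.reward > 0:
            self.reward_seen = True
        if goal_reached:
            self.qfree.mark_terminal(e.next_state)
        q_learning_update(self.qfree, e, self.alpha)
        lev = self.level
        lev.reward_accumulator = max(lev.reward_accumulator, e.reward)
        m = int(self.base_parent[e.state])
        m2 = int(self.base_parent[e.next_state])
        if m2 != m or goal_reached:
            a = e.action if m2 == m else lev.geometry.direction(m, m2)
            if goal_reached and a is not None:
                lev.sweeper.mark_absorbing(m, a, m2)
            if a is not None:
                me = Experience(m, a, m2, lev.reward_accumulator)
                lev.model.observe(me)
                if m2 == m:
                    lev.model._blocked.discard((m, a))
                lev.sweeper.notify(me)
            lev.reward_accumulator = _NEG_INF
        lev.sweeper.sweep(lev.budget)

    def _macro_box(self, macro: int):
        if not hasattr(self, "_boxes"):
            cols = self.maze.cols
            n = self.level.geometry.n_states
            pts = [[] for _ in range(n)]
            for cell, m in enumerate(self.base_parent):
                pts[m].append(divmod(cell, cols))
            self._boxes = [(min(p[0] for p in ps), max(p[0] for p in ps),
                            min(p[1] for p in ps), max(p[1] for p in ps))
                           for ps in pts]
        return self._boxes[macro]

    def _compass(self, state: int, macro: int):
        """Base action toward the nearest cell of the region ``macro``
        (None when already inside its bounding box). Entering at the
        nearest edge leaves motion inside the region unconstrained, so no
        restoring force pins the agent to the region's centre."""
        r, c = divmod(state, self.maze.cols)
        rmin, rmax, cmin, cmax = self._macro_box(macro)
        dr = rmin - r if r < rmin else (rmax - r if r > rmax else 0)
        dc = cmin - c if c < cmin else (cmax - c if c > cmax else 0)
        if abs(dr) >= abs(dc) and dr != 0:
            return 0 if dr < 0 else 1
        if dc != 0:
            return 2 if dc < 0 else 3
        return None

    def act(self, state: int) -> int:
        """Top-level goal-setting steers between regions; model-free values
        (with random tie-breaks) take over inside the goal region."""
        self.plan_accesses += 1
        lev = self.level
        planned = None
        here = int(self.base_parent[state])
        goal_macros = [m for m in range(lev.geometry.n_states)
                       if lev.model.expects_reward_at(m)]
        if goal_macros:
            # reward association names the goal region directly; the entry
            # probability itself is tiny (one goal entry among many ordinary
            # crossings), so Q magnitudes cannot be trusted for this
            gm = goal_macros[0]
            if here != gm:
                planned = self._compass(state, gm)
            # inside the goal region the model-free values take over
        # before any reward has been seen there is no goal region to set:
        # the dorsal-lesioned agent relies on random motion
        if planned is None:
            row = self.qfree.q[state]
            best = np.flatnonzero(row == row.max())
            planned = int(best[0]) if len(best) == 1 else int(self.rng.choice(best))
        if self.rng.random() < self.epsilon:
            return planned
        return int(self.rng.integers(N_ACTIONS))


def apply_lesion(agent: HierarchicalAgent, spec, total_budget: int = 120):
    """Return the lesioned variant of a freshly built intact agent.

    ``none`` returns the agent unchanged. ``vH`` truncates the hierarchy to
    level 0 (conventional MBRL) and concentrates the full update budget
    there. ``dH`` wraps the highest informative level with a model-free base
    learner. The vH variant mutates and returns the given agent; dH returns
    a wrapper sharing the surviving level.
    """
    if isinstance(spec, str):
        spec = LesionSpec(spec)
    if spec.kind == "none":
        return agent
    if spec.kind == "vH":
        agent.levels = agent.levels[:1]
        agent.base_parent = agent.base_parent[:1]
        agent.children = agent.children[:1]
        agent.levels[0].budget = total_budget
        return agent
    return DHLesionedAgent(agent, budget=total_budget)
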