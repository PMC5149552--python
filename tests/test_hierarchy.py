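"""Hierarchy construction, macro learning, goal selection, A* refinement
and the epsilon-greedy policy."""

import collections

import numpy as np
import pytest

from hipporl.experiments import run_trial
from hipporl.gridworld import Experience, make_open_arena
from hipporl.hierarchy import (ConventionalAgent, HierarchicalAgent,
                               build_hierarchy, level_shapes)


def bfs_path_length(maze, start, goal):
    """Unit-cost shortest path length in states (BFS oracle)."""
    frontier = collections.deque([(start, 1)])
    seen = {start}
    while frontier:
        s, n = frontier.popleft()
        if s == goal:
            return n
        for a in range(4):
            nxt, _, _ = maze.transition(s, a)
            if nxt != s and nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, n + 1))
    return None


class TestBuildHierarchy:
    def test_16x48_arena_has_six_levels(self):
        shapes = level_shapes(16, 48)
        assert len(shapes) == 6
        assert [r * c for r, c in shapes] == [768, 192, 48, 12, 3, 1]

    def test_2x2_maze_has_two_levels(self):
        assert [r * c for r, c in level_shapes(2, 2)] == [4, 1]

    @pytest.mark.parametrize("rows,cols", [(16, 48), (7, 7), (5, 9)])
    def test_parent_maps_partition_every_level(self, rows, cols):
        agent = HierarchicalAgent(make_open_arena(rows, cols))
        n_base = rows * cols
        for k in range(1, agent.n_levels):
            parents = agent.base_parent[k]
            assert len(parents) == n_base
            seen = collections.defaultdict(set)
            for child in range(n_base):
                seen[int(parents[child])].add(child)
            # children partition the base grid
            assert sum(len(v) for v in seen.values()) == n_base
            assert set(seen) == set(range(agent.levels[k].geometry.n_states))

    def test_discounts_strictly_decrease_with_level(self):
        agent = HierarchicalAgent(make_open_arena(16, 48))
        gammas = [lev.gamma for lev in agent.levels]
        assert gammas[0] == pytest.approx(0.9)
        assert gammas[-1] == pytest.approx(0.5)
        assert all(a > b for a, b in zip(gammas, gammas[1:]))


class TestMacroLearning:
    def test_macro_reward_is_max_within_occupancy(self):
        """Rewards [-1, -1, 100] inside one macro-state then an exit record
        a macro transition carrying r = 100."""
        maze = make_open_arena(4, 4, start=(0, 0), goal=(3, 3))
        agent = HierarchicalAgent(maze)
        lev1 = agent.levels[1]
        # three steps inside macro 0 (cells (0,0),(0,1),(1,0),(1,1))
        agent.on_step(Experience(maze.index((0, 0)), 3, maze.index((0, 0)), -1.0))
        agent.on_step(Experience(maze.index((0, 0)), 3, maze.index((0, 1)), -1.0))
        agent.on_step(Experience(maze.index((0, 1)), 1, maze.index((1, 1)), 100.0))
        # exit to macro 1 via (1,2)
        agent.on_step(Experience(maze.index((1, 1)), 3, maze.index((1, 2)), 0.0))
        assert lev1.model.count(0, 3, 1) == 1
        assert lev1.model.mean_rewards(0, 3)[0] == pytest.approx(100.0)

    def test_within_macro_movement_records_no_macro_transition(self):
        maze = make_open_arena(4, 4, start=(0, 0), goal=(3, 3))
        agent = HierarchicalAgent(maze)
        agent.on_step(Experience(maze.index((0, 0)), 3, maze.index((0, 1)), 0.0))
        assert not agent.levels[1].model._cnt

    def test_macro_trajectory_contiguous(self):
        """Any base trajectory induces a well-defined macro trajectory whose
        consecutive macro-states are equal or grid-adjacent."""
        maze = make_open_arena(8, 12)
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(3))
        state = maze.start_state
        segments = [[state]]
        for _ in range(400):
            a = agent.act(state)
            nxt, r, done = maze.transition(state, a)
            agent.on_step(Experience(state, a, nxt, r), goal_reached=done)
            segments[-1].append(nxt)
            if done:  # trial-boundary teleport starts a new trajectory
                state = maze.start_state
                segments.append([state])
            else:
                state = nxt
        for k in range(1, agent.n_levels):
            geom = agent.levels[k].geometry
            for seg in segments:
                macros = [int(agent.base_parent[k][s]) for s in seg]
                for m1, m2 in zip(macros, macros[1:]):
                    assert m1 == m2 or geom.direction(m1, m2) is not None


class TestGoalSelection:
    def test_untrained_agent_has_no_reward_goal(self):
        maze = make_open_arena(4, 4)
        agent = HierarchicalAgent(maze, optimism=0.0)
        assert agent.select_goal() is None

    def test_goal_contains_reward_cell_after_discovery(self):
        maze = make_open_arena(4, 6, start=(0, 0), goal=(2, 4))
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(0))
        # walk the agent to the goal once
        run_trial(agent, maze)
        k, s, a, gstate = agent.select_goal()
        assert int(agent.base_parent[k][maze.goal_state]) == gstate

    def test_goal_values_exceed_optimism_only_after_reward(self):
        maze = make_open_arena(4, 6)
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(0))
        assert float(agent.levels[0].q.max()) == pytest.approx(100.0)
        run_trial(agent, maze)
        assert float(agent.levels[0].q.max()) > 100.0


class TestPlanning:
    def test_planned_path_length_matches_bfs(self):
        maze = make_open_arena(6, 10)
        agent = HierarchicalAgent(maze)
        src, dst = maze.index((0, 0)), maze.index((5, 9))
        plan = agent.plan_route(0, src, {dst})
        assert len(plan) == bfs_path_length(maze, src, dst)

    def test_source_in_targets_gives_single_element_plan(self):
        agent = HierarchicalAgent(make_open_arena(4, 4))
        assert agent.plan_route(0, 7, {7, 9}) == [7]

    def test_walled_off_target_fails(self):
        agent = HierarchicalAgent(make_open_arena(4, 4))
        model = agent.levels[0].model
        # observe every edge into cell (0,0) as blocked
        for s, a in (((0, 1), 2), ((1, 0), 0)):
            src = agent.maze.index(s)
            model.observe(Experience(src, a, src, -1.0))
        assert agent.plan_route(0, agent.maze.index((2, 2)),
                                {agent.maze.index((0, 0))}) is None

    def test_route_near_optimal_on_learned_arena(self):
        """After learning, the greedy route is between the BFS optimum and
        1.5x it (hierarchical solutions are marginally sub-optimal); the
        noisy epsilon=0.8 route can only be at least the optimum."""
        maze = make_open_arena(8, 24)
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(1))
        for _ in range(4):
            steps, reached = run_trial(agent, maze)
        assert reached
        optimum = bfs_path_length(maze, maze.start_state, maze.goal_state) - 1
        assert steps >= optimum
        agent.epsilon = 1.0
        steps, reached = run_trial(agent, maze)
        assert reached and optimum <= steps <= 1.5 * optimum


class TestPolicy:
    def test_planned_action_frequency_near_085(self):
        """With epsilon=0.8 the planned action executes with frequency
        0.8 + 0.2/4 (the random draw can coincide with the plan)."""
        maze = make_open_arena(4, 4)
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(7))
        hits = sum(agent._epsilon_greedy(2) == 2 for _ in range(20000))
        assert hits / 20000 == pytest.approx(0.85, abs=0.01)

    def test_epsilon_zero_is_uniform(self):
        maze = make_open_arena(4, 4)
        agent = HierarchicalAgent(maze, epsilon=0.0,
                                  rng=np.random.default_rng(7))
        counts = collections.Counter(agent._epsilon_greedy(2)
                                     for _ in range(20000))
        for a in range(4):
            assert counts[a] / 20000 == pytest.approx(0.25, abs=0.02)

    def test_epsilon_one_reaches_goal_greedily(self):
        maze = make_open_arena(6, 12)
        agent = HierarchicalAgent(maze, rng=np.random.default_rng(5))
        run_trial(agent, maze)  # discover the goal
        agent.epsilon = 1.0
        steps, reached = run_trial(agent, maze)
        assert reached
        optimum = bfs_path_length(maze, maze.start_state, maze.goal_state) - 1
        assert steps <= 1.5 * optimum


class TestConventionalEquivalence:
    def test_single_level_agent_equals_conventional_trajectory(self):
        """A 1-level hierarchical agent and ConventionalAgent produce the
        identical trajectory under a shared seed."""
        maze = make_open_arena(6, 10)
        a1 = HierarchicalAgent(maze, n_levels=1, budget_per_level=120,
                               discounts=[0.9], rng=np.random.default_rng(11))
        a2 = ConventionalAgent(maze, budget=120, rng=np.random.default_rng(11))
        s1 = s2 = maze.start_state
        for _ in range(600):
            act1, act2 = a1.act(s1), a2.act(s2)
            assert act1 == act2
            n1, r1, d1 = maze.transition(s1, act1)
            a1.on_step(Experience(s1, act1, n1, r1), goal_reached=d1)
            a2.on_step(Experience(s2, act2, n1, r1), goal_reached=d1)
            s1 = s2 = maze.start_state if d1 else n1
            if d1:
                a1.end_trial()
                a2.end_trial()

    def test_conventional_is_single_level(self):
        agent = ConventionalAgent(make_open_arena(4, 4))
        assert agent.n_levels == 1
        assert agent.levels[0].budget == 120

    def test_build_hierarchy_respects_n_levels(self):
        maze = make_open_arena(16, 48)
        assert len(build_hierarchy(maze, n_levels=3)) == 3
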