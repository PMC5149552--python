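"""Experiment drivers: lesion comparison, boundary adaptation, probabilistic
reward contexts, and scaling, plus summary statistics.

Every driver returns a tidy :class:`pandas.DataFrame` with one row per
(repetition, agent, trial): steps to goal (capped), whether the goal was
reached, cumulative model accesses, and — for the context task — the size
of the context bank. A single master seed determines every record
bit-for-bit: repetitions and agent groups draw from independent child
streams of ``numpy.random.SeedSequence(master_seed)``.

Budget parity: the conventional agent's per-step update budget always
equals the hierarchical agent's total (20 updates per level), e.g. 120 on
the 16x48 arena with its six levels.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from scipy import stats

from .context import ContextBank
from .gridworld import (Experience, GridMaze, make_adaptation_maze,
                        make_four_goal_arena, make_open_arena, scale_arena,
                        FOUR_GOAL_SITES)
from .hierarchy import ConventionalAgent, HierarchicalAgent, level_shapes
from .lesions import apply_lesion

__all__ = ["run_trial", "run_lesion", "run_adaptation", "run_context",
           "run_scaling", "summarize", "rank_sum_p",
           "BUDGET_PER_LEVEL", "conventional_budget"]

BUDGET_PER_LEVEL = 20


def conventional_budget(maze: GridMaze) -> int:
    """Total per-step update budget matching the hierarchy on this maze."""
    return BUDGET_PER_LEVEL * len(level_shapes(maze.rows, maze.cols))


def run_trial(agent, maze: GridMaze):
    """Run one trial (start to goal or step cap); returns (steps, reached)."""
    state = maze.start_state
    steps = 0
    reached = False
    while steps < maze.step_cap:
        a = agent.act(state)
        ns, r, done = maze.transition(state, a)
        steps += 1
        agent.on_step(Experience(state, a, ns, r), goal_reached=done)
        state = ns
        if done:
            reached = True
            break
    agent.end_trial()
    return steps, reached


def _row(rep, agent_name, maze, trial, steps, reached, accesses, seed,
         n_contexts=None, variant=None):
    return {"rep": rep, "agent": agent_name, "maze": maze.name, "trial": trial,
            "steps": steps, "reached": reached, "accesses": accesses,
            "n_contexts": n_contexts, "variant": variant, "seed": seed}


# -- lesion study -----------------------------------------------------------

def run_lesion(n_reps: int = 20, n_trials: int = 30, seed: int = 0,
               rows: int = 16, cols: int = 48,
               agent_kwargs=None) -> pd.DataFrame:
    """Intact vs vH- vs dH-lesioned agents on the open-arena task."""
    rows_out = []
    kw = dict(budget_per_level=BUDGET_PER_LEVEL, **(agent_kwargs or {}))
    ss = np.random.SeedSequence(seed)
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        for name, child in zip(("intact", "vH", "dH"), rep_ss.spawn(3)):
            rng = np.random.default_rng(child)
            maze = make_open_arena(rows, cols)
            agent = HierarchicalAgent(maze, rng=rng, **kw)
            if name != "intact":
                agent = apply_lesion(agent, name,
                                     total_budget=conventional_budget(maze))
            for t in range(n_trials):
                steps, reached = run_trial(agent, maze)
                rows_out.append(_row(rep, name, maze, t, steps, reached,
                                     agent.accesses, seed))
    return pd.DataFrame(rows_out)


# -- boundary adaptation ----------------------------------------------------

def run_adaptation(variants, n_reps: int = 20, pre_trials: int = 10,
                   post_trials: int = 10, seed: int = 0,
                   agent_kwargs=None) -> pd.DataFrame:
    """Open-arena training then sudden internal boundaries (variants A..E).

    ``variants`` may be one variant name or a list; with several variants
    each repetition trains once in the open arena and every variant branches
    from a snapshot of that trained agent (a within-repetition crossover),
    which leaves the per-variant statistics unchanged while avoiding
    retraining.
    """
    if isinstance(variants, str):
        variants = [variants]
    arena = make_open_arena(16, 48)
    mazes = {v: make_adaptation_maze(v) for v in variants}
    rows_out = []
    agent_kwargs = agent_kwargs or {}
    ss = np.random.SeedSequence(seed)
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        for name, child in zip(("hierarchical", "conventional"), rep_ss.spawn(2)):
            rng = np.random.default_rng(child)
            if name == "hierarchical":
                agent = HierarchicalAgent(arena,
                                          budget_per_level=BUDGET_PER_LEVEL,
                                          rng=rng, **agent_kwargs)
            else:
                agent = ConventionalAgent(arena,
                                          budget=conventional_budget(arena),
                                          rng=rng, **agent_kwargs)
            pre_rows = []
            for t in range(pre_trials):
                steps, reached = run_trial(agent, arena)
                pre_rows.append((t, steps, reached, agent.accesses))
            for i, v in enumerate(variants):
                branch = agent if i == len(variants) - 1 else copy.deepcopy(agent)
                for t, steps, reached, acc in pre_rows:
                    rows_out.append(_row(rep, name, arena, t, steps, reached,
                                         acc, seed, variant=v))
                for t in range(pre_trials, pre_trials + post_trials):
                    steps, reached = run_trial(branch, mazes[v])
                    rows_out.append(_row(rep, name, mazes[v], t, steps,
                                         reached, branch.accesses, seed,
                                         variant=v))
    return pd.DataFrame(rows_out)


# -- probabilistic-reward contexts ------------------------------------------

def run_context(n_reps: int = 20, n_trials: int = 40, seed: int = 0,
                m: int = 10, temperature: float = 1.0,
                agent_kwargs=None) -> pd.DataFrame:
    """Four randomly armed reward sites in a 7x7 arena, 500-step cap.

    Compares the context-switching hierarchical framework against a single
    conventional agent. Both see the same per-trial site sequence.
    """
    rows_out = []
    ss = np.random.SeedSequence(seed)
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        site_rng, hier_ss, conv_ss, bank_ss = rep_ss.spawn(4)
        sites = np.random.default_rng(site_rng).integers(
            0, len(FOUR_GOAL_SITES), n_trials)
        base = make_four_goal_arena(0)

        def factory(child_ss=hier_ss):
            # SeedSequence.spawn is stateful: each call yields a fresh stream
            return HierarchicalAgent(
                base, budget_per_level=BUDGET_PER_LEVEL,
                rng=np.random.default_rng(child_ss.spawn(1)[0]),
                track_distribution=True, **(agent_kwargs or {}))

        bank = ContextBank(factory, m=m, temperature=temperature,
                           rng=np.random.default_rng(bank_ss))
        conv = ConventionalAgent(base, budget=conventional_budget(base),
                                 rng=np.random.default_rng(conv_ss),
                                 **(agent_kwargs or {}))
        for t in range(n_trials):
            maze = make_four_goal_arena(int(sites[t]))
            steps, reached = run_trial(bank, maze)
            rows_out.append(_row(rep, "hierarchical+context", maze, t, steps,
                                 reached, bank.accesses, seed,
                                 n_contexts=bank.n_contexts))
            steps, reached = run_trial(conv, maze)
            rows_out.append(_row(rep, "conventional", maze, t, steps, reached,
                                 conv.accesses, seed))
    return pd.DataFrame(rows_out)


# -- scaling ----------------------------------------------------------------

def run_scaling(factor, n_reps: int = 5, n_trials: int = 3,
                seed: int = 0, agent_kwargs=None) -> pd.DataFrame:
    """Both agents on the open arena scaled by ``factor``, equal budgets."""
    maze = scale_arena(factor=factor)
    rows_out = []
    agent_kwargs = agent_kwargs or {}
    ss = np.random.SeedSequence(seed)
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        for name, child in zip(("hierarchical", "conventional"), rep_ss.spawn(2)):
            rng = np.random.default_rng(child)
            if name == "hierarchical":
                agent = HierarchicalAgent(maze,
                                          budget_per_level=BUDGET_PER_LEVEL,
                                          rng=rng, **agent_kwargs)
            else:
                agent = ConventionalAgent(maze, budget=conventional_budget(maze),
                                          rng=rng, **agent_kwargs)
            for t in range(n_trials):
                steps, reached = run_trial(agent, maze)
                rows_out.append(_row(rep, name, maze, t, steps, reached,
                                     agent.accesses, seed))
    return pd.DataFrame(rows_out)


def scaling_failed(records: pd.DataFrame, agent: str) -> pd.Series:
    """Per-rep flag: goal never reached in any trial of the run."""
    sub = records[records.agent == agent]
    return ~sub.groupby("rep")["reached"].any()


# -- summaries --------------------------------------------------------------

def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per (agent, trial) mean and 2.5/97.5 percentile band of the step and
    access counts across repetitions."""
    if len(records) == 0:
        raise ValueError("no records to summarize")

    def agg(g):
        return pd.Series({
            "steps_mean": g.steps.mean(),
            "steps_p2.5": np.percentile(g.steps, 2.5),
            "steps_p97.5": np.percentile(g.steps, 97.5),
            "accesses_mean": g.accesses.mean(),
            "accesses_p2.5": np.percentile(g.accesses, 2.5),
            "accesses_p97.5": np.percentile(g.accesses, 97.5),
            "n": len(g),
        })

    out = (records.groupby(["agent", "trial"])
           .apply(agg, include_groups=False).reset_index())
    return out


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples."""
    return float(stats.ranksums(np.asarray(x), np.asarray(y)).pvalue)
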