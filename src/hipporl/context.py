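"""Likelihood-based context detection and global remapping.

A bank of stored agents — one per learned context — watches a ring buffer
of the ``m`` most recent experiences. The lowest-level world model of each
stored context assigns the history a likelihood

    P(H) = prod_i P(e_i),   P(e_i) = P(s'|s,a) * P(r|s,a,s'),

compared on the scale-free geometric mean g = P(H)^(1/m). When the active
context stops being the best explanation, a different stored context is
selected through a softmax over log-likelihoods.

A *surprise* — arriving where the active model predicts reward and finding
none — rules every context that predicts reward at that location out for
the remainder of the trial. The bank then falls through its remaining
candidates by likelihood until one of them is rewarded, which is what makes
the agent visit learned reward sites systematically instead of
perseverating on the first one; when a surprise leaves no candidate at all,
a brand-new context is created — the computational analogue of hippocampal
global remapping. Unexpected rewards are credited to the context that
predicts reward at that location (switching before the experience is
absorbed), so stored contexts stay single-site experts, and contexts that
never acquire any reward association are pruned at trial boundaries.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

from .gridworld import Experience

__all__ = ["History", "ContextBank", "history_likelihood", "surprise_check",
           "evaluate_contexts"]


class History:
    """Ring buffer of the m most recent experiences, oldest first."""

    def __init__(self, m: int = 10):
        self.m = m
        self._buf = deque(maxlen=m)

    def append(self, e: Experience) -> None:
        self._buf.append(e)

    def __len__(self):
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)

    @property
    def full(self) -> bool:
        return len(self._buf) == self.m

    def clear(self) -> None:
        self._buf.clear()


def history_likelihood(model, history) -> float:
    """P(H) under one world model; 1 for an empty history."""
    p = 1.0
    for e in history:
        p *= model.experience_prob(e)
    return p


def _log_likelihood(model, history) -> float:
    ll = 0.0
    for e in history:
        ll += math.log(max(model.experience_prob(e), 1e-300))
    return ll


def surprise_check(model, e: Experience) -> bool:
    """True when the model expected positive reward on e's transition but
    the obtained reward was not positive."""
    return e.reward <= 0 and model.expects_reward(e.state, e.action, e.next_state)


class ContextBank:
    """Stored full agents, an experience history, and switching machinery."""

    def __init__(self, agent_factory, m: int = 10, temperature: float = 1.0,
                 new_context_threshold: float = 0.5, rng=None):
        self.agent_factory = agent_factory
        self.contexts = [agent_factory()]
        self.active = 0
        self.history = History(m)
        self.temperature = temperature
        self.new_context_threshold = new_context_threshold
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._excluded = set()   # context indices ruled out this trial
        self._rewarded_this_trial = False
        self.switches = 0

    # -- agent-like surface -------------------------------------------------
    @property
    def active_agent(self):
        return self.contexts[self.active]

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    @property
    def accesses(self) -> int:
        return sum(a.accesses for a in self.contexts)

    def act(self, state: int) -> int:
        return self.active_agent.act(state)

    def end_trial(self) -> None:
        self.active_agent.end_trial()
        self._excluded.clear()
        self._prune()
        self._rewarded_this_trial = False

    def _prune(self) -> None:
        """Drop contexts that encode no reward policy at a trial boundary.

        A context that never acquired a reward association holds only
        geometric knowledge every other context shares; keeping it would
        let a goal-less model win the likelihood race on its own wanderings
        and monopolise behaviour."""
        if len(self.contexts) <= 1:
            return
        keep = [k for k, a in enumerate(self.contexts)
                if a.levels[0].model.has_reward_association()]
        if not keep:
            keep = [self.active]
        if len(keep) == len(self.contexts):
            return
        old_active = self.active
        self.contexts = [self.contexts[k] for k in keep]
        if old_active in keep:
            self.active = keep.index(old_active)
        else:
            lls = [_log_likelihood(a.levels[0].model, self.history)
                   for a in self.contexts]
            self.active = int(np.argmax(lls))
            self.switches += 1

    def _credit_reward(self, e: Experience) -> None:
        """Route an unexpected reward to the context that predicts reward at
        that location, so stored contexts stay single-site experts instead of
        blending; a fresh context is created when the active one is already
        committed to a different reward site and no stored expert fits."""
        model = self.active_agent.levels[0].model
        if model.expects_reward_at(e.next_state):
            return  # the active context predicted this: nothing to reroute
        experts = [k for k, agent in enumerate(self.contexts)
                   if k != self.active
                   and agent.levels[0].model.expects_reward_at(e.next_state)]
        if experts:
            best = max(experts, key=lambda k: _log_likelihood(
                self.contexts[k].levels[0].model, self.history))
            self.active = best
            self.switches += 1
        elif model._reward_into and any(model._reward_into.values()):
            self._spawn()  # active is another site's expert: global remap

    def on_step(self, e: Experience, goal_reached: bool = False) -> None:
        """Re-evaluate the bank against the experience, then feed whichever
        context ends up active."""
        model = self.active_agent.levels[0].model
        surprise = surprise_check(model, e)
        if e.reward > 0:
            self._credit_reward(e)
            self.active_agent.on_step(e, goal_reached)
            self.history.append(e)
            self._excluded.clear()
            self._rewarded_this_trial = True
            return
        self.active_agent.on_step(e, goal_reached)
        self.history.append(e)
        if surprise:
            for k, agent in enumerate(self.contexts):
                if agent.levels[0].model.expects_reward_at(e.next_state):
                    self._excluded.add(k)
            self.evaluate(surprise=True)
        elif self.history.full:
            self.evaluate(surprise=False)

    # -- switching ----------------------------------------------------------
    def _geometric_means(self, candidates):
        n = max(len(self.history), 1)
        out = {}
        for k in candidates:
            ll = _log_likelihood(self.contexts[k].levels[0].model, self.history)
            out[k] = (math.exp(ll / n), ll)
        return out

    def _spawn(self) -> None:
        self.contexts.append(self.agent_factory())
        self.active = len(self.contexts) - 1
        self.switches += 1

    def evaluate(self, surprise: bool = False) -> None:
        """Re-select the active context (or create one) from the history.

        Stored contexts excluded this trial are not candidates. A new
        context is created when no candidate explains the history — i.e.
        every candidate's geometric-mean likelihood falls strictly below
        the threshold — or when a surprise leaves no candidate at all.
        """
        candidates = [k for k in range(len(self.contexts))
                      if k not in self._excluded]
        if not candidates:
            self._spawn()
            return
        scores = self._geometric_means(candidates)
        gmax = max(g for g, _ in scores.values())
        g_active = scores.get(self.active, (-1.0, 0.0))[0]
        if not surprise and g_active >= gmax:
            return  # current context remains the best explanation
        # softmax over log-likelihoods (temperature-scaled)
        keys = list(scores)
        lls = np.array([scores[k][1] for k in keys]) / self.temperature
        lls -= lls.max()
        w = np.exp(lls)
        pick = keys[int(self.rng.choice(len(keys), p=w / w.sum()))]
        if pick != self.active:
            self.switches += 1
            self.active = pick


def evaluate_contexts(bank: ContextBank, history: History = None,
                      surprise: bool = False) -> ContextBank:
    """Functional surface over :meth:`ContextBank.evaluate`."""
    if history is not None:
        bank.history = history
    bank.evaluate(surprise=surprise)
    return bank


def save_context_models(bank: ContextBank, directory) -> None:
    """Persist the bank's base-level world models: one portable key-value
    file per context plus a small JSON manifest (active index, buffer
    length, temperature). Value tables are not stored — they are derived
    state, recomputable by sweeping a loaded model."""
    import json
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, agent in enumerate(bank.contexts):
        (directory / f"context{k}.model.tsv").write_text(
            agent.levels[0].model.to_text())
    manifest = {"n_contexts": bank.n_contexts, "active": bank.active,
                "m": bank.history.m, "temperature": bank.temperature}
    (directory / "bank.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_context_models(directory, candidates_fn):
    """Load the per-context world models written by
    :func:`save_context_models`; returns (models, manifest)."""
    import json
    import pathlib

    from .world_model import WorldModel

    directory = pathlib.Path(directory)
    manifest = json.loads((directory / "bank.json").read_text())
    models = [WorldModel.from_text(
        (directory / f"context{k}.model.tsv").read_text(), candidates_fn,
        track_distribution=True) for k in range(manifest["n_contexts"])]
    return models, manifest
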