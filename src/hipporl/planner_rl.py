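"""Value computation: model-based backups scheduled by prioritized sweeping,
and a one-step model-free Q-learner.

The model-based backup is the expectation over the learned model,

    Q(s,a) = sum_s' P(s'|s,a) (R(s,a,s') + gamma * max_a' Q(s',a')),

evaluated over the candidate-successor set of the world model. Updates are
scheduled Moore–Atkeson style: states whose value estimate is stale by more
than ``priority_threshold`` wait in a priority queue keyed by the magnitude
of the pending change, and each environment step may pop at most ``budget``
states. When nothing new has been learned the queue is empty and no work is
done.

Exploration follows the optimistic flavour of prioritized sweeping: every
untried state-action pair holds an optimistic initial value (``optimism``,
by default the goal-reward magnitude) and keeps it until the pair is first
tried. Unexplored terrain therefore glows with promise, and the value
surface pulls the agent through systematic coverage of the environment;
once a real reward is discovered, bootstrapping through the (still
optimistic) successor lifts the discovered goal's value above the optimism
constant, and behaviour flips from exploration to exploitation.

Every backup computed and every A* node expansion elsewhere increments a
shared access counter, the framework's proxy for cognitive load.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["QTable", "SweepQueue", "PrioritizedSweeper",
           "backup", "prioritized_sweep", "q_learning_update"]

#: opposite compass action, used to enumerate grid predecessors
_OPP = (1, 0, 3, 2)
N_ACTIONS = 4


class QTable:
    """Dense action-value table with a discount and optional terminal states."""

    def __init__(self, n_states: int, gamma: float = 0.9, init: float = 0.0):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        self.q = np.full((n_states, N_ACTIONS), float(init))
        self.gamma = gamma
        self.terminal = set()

    @property
    def n_states(self) -> int:
        return self.q.shape[0]

    def value(self, s: int) -> float:
        return 0.0 if s in self.terminal else float(self.q[s].max())

    def mark_terminal(self, s: int) -> None:
        self.terminal.add(s)
        self.q[s, :] = 0.0


class SweepQueue:
    """Max-priority queue of states with lazy invalidation."""

    def __init__(self, priority_threshold: float = 1e-4):
        self.priority_threshold = priority_threshold
        self._heap = []
        self._pending = {}
        self._seq = 0

    def __len__(self) -> int:
        return len(self._pending)

    def push(self, s: int, priority: float) -> None:
        if priority <= self.priority_threshold:
            return
        cur = self._pending.get(s)
        if cur is not None and cur >= priority:
            return
        self._pending[s] = priority
        self._seq += 1
        heapq.heappush(self._heap, (-priority, self._seq, s))

    def pop(self):
        while self._heap:
            negp, _, s = heapq.heappop(self._heap)
            if self._pending.get(s) == -negp:
                del self._pending[s]
                return s
        return None


class PrioritizedSweeper:
    """Couples a world model, a Q-table and a sweep queue for one level."""

    def __init__(self, model, n_states: int, gamma: float = 0.9,
                 optimism: float = 0.0, priority_threshold: float = 1e-4,
                 neighbor_fn=None):
        self.model = model
        self.qtable = QTable(n_states, gamma, init=optimism)
        self.queue = SweepQueue(priority_threshold)
        self.optimism = optimism
        self.neighbor_fn = neighbor_fn
        self.accesses = 0
        # transitions that end the episode: their successor value reads 0
        self.absorbing = set()
        if optimism and neighbor_fn is not None:
            # Optimism is a promise about where an action might lead; actions
            # with no geometric successor (off the grid) promise nothing.
            # Without this mask, untriable pairs (e.g. the single-state top
            # level's actions) would pin the cross-level argmax forever.
            q = self.qtable.q
            for s in range(n_states):
                for a in range(N_ACTIONS):
                    if neighbor_fn(s, a) is None:
                        q[s, a] = 0.0
        self._v = self.qtable.q.max(axis=1).copy()

    # -- core backup --------------------------------------------------------
    def state_value(self, s: int) -> float:
        if s in self.qtable.terminal:
            return 0.0
        return float(self._v[s])

    def backup(self, s: int, a: int) -> float:
        """Expected one-step return of (s, a) under the current model."""
        self.accesses += 1
        model = self.model
        key = (s, a)
        cands = model._cands.get(key)
        if cands is None:
            cands = tuple(model.candidates(s, a))
            model._cands[key] = cands
        gamma = self.qtable.gamma
        cnt = model._cnt.get(key)
        c = model.c
        terminal = self.qtable.terminal
        v_arr = self._v
        if cnt is None:
            total = 0.0
            for s2 in cands:
                if s2 not in terminal:
                    total += gamma * v_arr[s2]
            return total / len(cands)
        rew = model._rew[key]
        num = 0.0
        den = 0.0
        absorbing = self.absorbing
        for i, s2 in enumerate(cands):
            w = cnt[i] + c
            if s2 in terminal or (absorbing and (s, a, s2) in absorbing):
                v = 0.0
            else:
                v = v_arr[s2]
            num += w * (rew[i] + gamma * v)
            den += w
        return num / den

    # -- prioritized sweeping ----------------------------------------------
    def notify(self, e) -> None:
        """Seed the queue after the model absorbed experience ``e``."""
        s, a = e.state, e.action
        if s in self.qtable.terminal:
            return
        pr = abs(self.backup(s, a) - float(self.qtable.q[s, a]))
        self.queue.push(s, pr)

    def _refresh(self, s: int) -> float:
        """Recompute every tried action of ``s``; return |value change|."""
        q = self.qtable.q
        old = self.state_value(s)
        for a in range(N_ACTIONS):
            if self.model.tried(s, a):
                q[s, a] = self.backup(s, a)
        self._v[s] = q[s].max()
        return abs(self.state_value(s) - old)

    def sweep(self, budget) -> int:
        """Pop up to ``budget`` states in priority order; returns pops done."""
        n = 0
        model = self.model
        queue = self.queue
        while (budget is None or n < budget):
            s = queue.pop()
            if s is None:
                break
            n += 1
            if s in self.qtable.terminal:
                continue
            delta = self._refresh(s)
            if delta <= queue.priority_threshold or self.neighbor_fn is None:
                continue
            # predecessors found through T: grid neighbors that have been
            # observed to move into s (direct table access; the first
            # candidate slot is the geometric successor by convention)
            cnt_tab = model._cnt
            c = model.c
            terminal = self.qtable.terminal
            for a in range(N_ACTIONS):
                sp = self.neighbor_fn(s, _OPP[a])
                if sp is None or sp == s or sp in terminal:
                    continue
                cnt = cnt_tab.get((sp, a))
                if cnt is not None and cnt[0] > 0:
                    p = (cnt[0] + c) / (sum(cnt) + c * len(cnt))
                    queue.push(sp, p * delta)
            # a state is its own predecessor through bounce self-loops
            for a in range(N_ACTIONS):
                cnt = cnt_tab.get((s, a))
                if cnt is None:
                    continue
                i = len(cnt) - 1  # the stay slot is last by convention
                if cnt[i] > 0:
                    p = (cnt[i] + c) / (sum(cnt) + c * len(cnt))
                    queue.push(s, p * delta)
                    break
        return n

    def mark_terminal(self, s: int) -> None:
        self.qtable.mark_terminal(s)
        self._v[s] = 0.0

    def mark_absorbing(self, s: int, a: int, s2: int) -> None:
        """Declare the (s, a, s2) transition episode-ending: backups of
        (s, a) treat this successor's value as 0."""
        self.absorbing.add((s, a, s2))


# -- spec-level functional surface -----------------------------------------

def backup(model, qtable: QTable, s: int, a: int,
           sweeper: PrioritizedSweeper = None) -> float:
    """One model-based backup of (s, a); see :class:`PrioritizedSweeper`."""
    if sweeper is None:
        sweeper = PrioritizedSweeper(model, qtable.n_states, qtable.gamma)
        sweeper.qtable = qtable
        sweeper._v = qtable.q.max(axis=1)
    return sweeper.backup(s, a)


def prioritized_sweep(model, qtable: QTable, queue: SweepQueue, budget,
                      sweeper: PrioritizedSweeper = None, neighbor_fn=None):
    """Run up to ``budget`` prioritized value updates; returns the Q-table."""
    if sweeper is None:
        sweeper = PrioritizedSweeper(model, qtable.n_states, qtable.gamma,
                                     neighbor_fn=neighbor_fn)
        sweeper.qtable = qtable
        sweeper.queue = queue
        sweeper._v = qtable.q.max(axis=1)
        for s in qtable.terminal:
            sweeper._v[s] = 0.0
    sweeper.sweep(budget)
    return qtable


def q_learning_update(qfree: QTable, e, alpha: float) -> QTable:
    """One-step temporal-difference update of a model-free Q-table."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    q = qfree.q
    target = e.reward + qfree.gamma * qfree.value(e.next_state)
    q[e.state, e.action] += alpha * (target - q[e.state, e.action])
    return qfree
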