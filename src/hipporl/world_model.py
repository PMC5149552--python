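"""Tabular world model: transition counts, running-average rewards, and an
optional per-transition reward distribution.

The model keeps a lazily grown count table ``T[s, a, s']`` and reward table
``R[s, a, s']``. Transition probabilities are Laplace-smoothed over a small
candidate-successor set with prior count ``c`` (default 1):

    P(s' | s, a) = (T[s,a,s'] + c) / sum_k (T[s,a,k] + c)

and ``R`` is updated as an exact running mean,
``R <- R + (r - R) / T``. When ``track_distribution`` is on, a per-transition
histogram of observed rewards supports ``P(r | s, a, s')`` estimates used by
context-likelihood scoring.

The candidate-successor set of each ``(s, a)`` is supplied by a callable; on
a grid it is the geometric neighbor plus the state itself (a move either
succeeds or bounces). The first candidate is, by convention, the geometric
successor when one exists.
"""

from __future__ import annotations

from typing import Callable, Optional

__all__ = ["WorldModel", "grid_candidates"]


def grid_candidates(neighbor_fn: Callable[[int, int], Optional[int]]):
    """Candidate set for grid motion: (geometric successor, stay), or (stay,)."""

    def candidates(s: int, a: int):
        nxt = neighbor_fn(s, a)
        if nxt is None:
            return (s,)
        return (nxt, s)

    return candidates


class WorldModel:
    """Count/reward tables over a fixed candidate-successor structure."""

    def __init__(self, candidates_fn: Callable[[int, int], tuple],
                 prior_count: float = 1.0, track_distribution: bool = False):
        self.candidates = candidates_fn
        self.c = prior_count
        self.track_distribution = track_distribution
        self._cands = {}   # (s,a) -> tuple of candidate successors
        self._cnt = {}     # (s,a) -> list[int] counts per candidate
        self._rew = {}     # (s,a) -> list[float] running-mean reward
        self._rdist = {}   # (s,a) -> list[dict] reward-value histogram
        self._blocked = set()   # (s,a) whose most recent attempt bounced
        self.reward_values = set()  # every reward value seen anywhere
        self._reward_into = {}  # s2 -> set of (s,a) with positive mean reward

    # -- updates ------------------------------------------------------------
    def _slots(self, s: int, a: int):
        key = (s, a)
        cands = self._cands.get(key)
        if cands is None:
            cands = tuple(self.candidates(s, a))
            self._cands[key] = cands
        return key, cands

    def observe(self, e) -> None:
        """Fold one experience into T, R (and the reward histogram)."""
        key, cands = self._slots(e.state, e.action)
        try:
            i = cands.index(e.next_state)
        except ValueError:
            raise ValueError(
                f"successor {e.next_state} not a candidate of {key}") from None
        cnt = self._cnt.get(key)
        if cnt is None:
            cnt = [0] * len(cands)
            self._cnt[key] = cnt
            self._rew[key] = [0.0] * len(cands)
            if self.track_distribution:
                self._rdist[key] = [dict() for _ in cands]
        cnt[i] += 1
        rew = self._rew[key]
        rew[i] += (e.reward - rew[i]) / cnt[i]
        sources = self._reward_into.setdefault(e.next_state, set())
        if rew[i] > 0:
            sources.add(key)
        else:
            sources.discard(key)
        if self.track_distribution:
            hist = self._rdist[key][i]
            hist[e.reward] = hist.get(e.reward, 0) + 1
            self.reward_values.add(e.reward)
        # Recency bit used by the planner's passability test: a move that
        # bounced is considered blocked until it is next seen to succeed.
        if len(cands) > 1:
            if e.next_state == e.state:
                self._blocked.add(key)
            else:
                self._blocked.discard(key)

    # -- queries ------------------------------------------------------------
    def count(self, s: int, a: int, s2: Optional[int] = None):
        """Total visit count of (s, a), or of the (s, a, s2) triple."""
        cnt = self._cnt.get((s, a))
        if cnt is None:
            return 0
        if s2 is None:
            return sum(cnt)
        cands = self._cands[(s, a)]
        return cnt[cands.index(s2)] if s2 in cands else 0

    def tried(self, s: int, a: int) -> bool:
        return (s, a) in self._cnt

    def blocked(self, s: int, a: int) -> bool:
        """True when the most recent attempt of (s, a) bounced off a wall."""
        return (s, a) in self._blocked

    def transition_probs(self, s: int, a: int):
        """``(candidates, probabilities)`` over the candidate set (sums to 1)."""
        key, cands = self._slots(s, a)
        cnt = self._cnt.get(key)
        c = self.c
        if cnt is None:
            p = 1.0 / len(cands)
            return cands, [p] * len(cands)
        tot = sum(cnt) + c * len(cands)
        return cands, [(n + c) / tot for n in cnt]

    def transition_prob(self, s: int, a: int, s2: int) -> float:
        """Smoothed P(s2 | s, a); 0 for a successor outside the candidate set."""
        cands, probs = self.transition_probs(s, a)
        if s2 not in cands:
            return 0.0
        return probs[cands.index(s2)]

    def mean_rewards(self, s: int, a: int):
        rew = self._rew.get((s, a))
        if rew is None:
            return None
        return rew

    def reward_prob(self, s: int, a: int, s2: int, r: float) -> float:
        """Empirical P(r | s, a, s2) with add-one smoothing over the set of
        reward values seen anywhere in the model.

        A never-observed transition carries no reward evidence and scores 1,
        so that the experience likelihood reduces to the transition prior.
        """
        if not self.track_distribution:
            raise RuntimeError("reward distribution tracking is disabled")
        key = (s, a)
        hists = self._rdist.get(key)
        if hists is None:
            return 1.0
        cands = self._cands[key]
        if s2 not in cands:
            return 1.0
        hist = hists[cands.index(s2)]
        total = sum(hist.values())
        if total == 0:
            return 1.0
        k = max(1, len(self.reward_values))
        return (hist.get(r, 0) + 1) / (total + k)

    def experience_prob(self, e) -> float:
        """P(e) = P(s'|s,a) * P(r|s,a,s') (distribution variant)."""
        return (self.transition_prob(e.state, e.action, e.next_state)
                * self.reward_prob(e.state, e.action, e.next_state, e.reward))

    def predicted_successor(self, s: int, a: int) -> int:
        """argmax_s' T[s,a,s']; ties break to the lower state index; with no
        observations, the geometric successor (first candidate)."""
        key, cands = self._slots(s, a)
        cnt = self._cnt.get(key)
        if cnt is None or not any(cnt):
            return cands[0]
        best = max(range(len(cands)), key=lambda i: (cnt[i], -cands[i]))
        return cands[best]

    def expects_reward(self, s: int, a: int, s2: int) -> bool:
        """True when the learned mean reward of the observed triple is > 0."""
        key = (s, a)
        cnt = self._cnt.get(key)
        if cnt is None:
            return False
        cands = self._cands[key]
        if s2 not in cands:
            return False
        i = cands.index(s2)
        return cnt[i] > 0 and self._rew[key][i] > 0

    def expects_reward_at(self, s2: int) -> bool:
        """True when any observed transition into ``s2`` has mean reward > 0."""
        return bool(self._reward_into.get(s2))

    def has_reward_association(self) -> bool:
        """True when the model predicts positive reward anywhere at all."""
        return any(self._reward_into.values())

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        """Portable key-value dump: one line per (s, a, s') with data."""
        lines = ["# s\ta\ts'\tcount\tmean_reward\thistogram"]
        for (s, a), cnt in sorted(self._cnt.items()):
            cands = self._cands[(s, a)]
            for i, n in enumerate(cnt):
                if n == 0:
                    continue
                hist = ""
                if self.track_distribution:
                    h = self._rdist[(s, a)][i]
                    hist = ",".join(f"{v}:{k}" for v, k in sorted(h.items()))
                lines.append(
                    f"{s}\t{a}\t{cands[i]}\t{n}\t{self._rew[(s, a)][i]!r}\t{hist}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, candidates_fn, **kw) -> "WorldModel":
        from .gridworld import Experience

        model = cls(candidates_fn, **kw)
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            s, a, s2, n, rmean, hist = line.split("\t")
            s, a, s2, n = int(s), int(a), int(s2), int(n)
            if model.track_distribution and hist:
                for item in hist.split(","):
                    v, k = item.split(":")
                    for _ in range(int(k)):
                        model.observe(Experience(s, a, s2, float(v)))
            else:
                rmean = float(rmean)
                for _ in range(n):
                    model.observe(Experience(s, a, s2, rmean))
        return model
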