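# Methods

## Environment

A maze is a rectangular grid of discrete cells with four compass actions.
Moving into a wall cell or off the grid leaves the agent in place and costs
−1; entering the goal cell pays +100 and ends the trial (the driver
relocates the agent to the start cell without recording a transition).
Trials are capped at 5000 steps on the 16×48 reference arena; for arenas
scaled by a factor *f* the cap scales to 5000·*f*, since a fixed cap would
make every large maze unsolvable within a trial regardless of algorithm.
The agent senses only its own location — walls and rewards are discovered
by bumping into them and stepping on them.

Default geometry places the start at mid-height two columns from the left
end and the goal at mid-height three columns from the right end, which
scales cleanly with the arena. The five boundary-adaptation layouts are
approximations with the same character as the originals: long walls that
cut the straight learned route and force detours (single walls with a gap
at one end, a zig-zag, a three-wall serpentine, and a pocket around the
goal). Their exact geometry is a free choice; every comparison made with
them is between agents on the *same* maze, never across layouts.

## World model

Per level, a count table `T[s,a,s']` and reward table `R[s,a,s']` are
stored lazily (absent entries read zero). The candidate-successor set of a
grid action is the geometric neighbor plus the state itself — the two
outcomes a move can have — so the Laplace prior (count 1) stays proper:
summing the prior over all states would drown data in prior mass on large
mazes. `R` is an exact running mean per transition, hence insensitive to
observation order. The optional reward-distribution variant keeps an exact
histogram per transition; `P(r|s,a,s')` applies add-one smoothing over the
set of reward values seen anywhere in the model, and a never-observed
transition contributes no reward evidence (factor 1), so a fresh model
scores any experience at exactly the transition prior.

For planning, an edge is considered passable if its most recent attempt
did not bounce (untried edges are optimistically passable). Recency rather
than lifetime counts matters here: after boundaries are inserted, one bump
must reroute plans immediately even if the edge succeeded a hundred times
before.

## Value computation and exploration

Backups are expectations of the one-step model-based return over the
candidate set, scheduled Moore–Atkeson style: a priority queue keyed by the
magnitude of the pending value change, a priority threshold of 1e-4, and a
per-step pop budget (20 per level; the single-level baseline receives the
hierarchy's total, e.g. 120 on the 16×48 arena). A converged model performs
no work. States re-enter the queue through observed predecessors, including
themselves via bounce self-loops.

Exploration is optimistic initialization, which travels with the cited
sweeping algorithm: every untried state-action pair holds Q = 100 (the
goal-reward magnitude, configurable) until first tried; actions with no
geometric successor hold 0, since they promise nothing and could never be
tried. Unexplored terrain therefore pulls the agent outward, and coverage
proceeds systematically rather than by random walk — a pure random walk
needs ~3.6k steps on average to first reach the far goal of the 768-state
arena (with 42% of walks exceeding the 5000-step cap), incompatible with
fast, low-variance first trials. Because a discovered goal is *not* treated
as terminal at the base level, its value bootstraps through the goal
state's own (still optimistic) action row and exceeds the optimism
constant; from that moment exploitation wins the cross-level argmax and the
agent stops exploring. This single mechanism produces the observed regime
change from systematic coverage to near-optimal routes.

At macro levels a rewarded self-transition (goal and predecessor inside one
macro-state) is marked *absorbing* — its successor value reads zero in
backups — because the trial ends there and bootstrapping it would compound
the reward without bound and pin goal selection at a coarse level.

## Hierarchy, goal selection, and refinement

Levels halve each grid dimension (2×2 blocks, partial at edges; groups of
four along the long axis once a dimension reaches 1) down to a single
macro-state; 16×48 yields six levels of 768, 192, 48, 12, 3, 1 states.
Discounts fall linearly from 0.9 (base) to 0.5 (top): coarse levels prefer
immediate reward so that no level dominates goal setting. Macro levels
observe a transition whenever a step crosses their partition boundary,
carrying the maximum base reward of the occupancy just ended (salience
screening), plus the goal-entry emission described above.

Goal selection takes the maximum action value across all levels and names
the state where that action is expected to lead (argmax of T, geometric
fallback). Exact value ties — which essentially only occur at the shared
optimism constant before reward is known — resolve toward the *finest*
level: consuming untried pairs in base-level index order turns exploration
into a near-deterministic raster, whereas preferring coarse levels scatters
it into cross-arena errands (measured: ~2.25k ± 0.14k vs ~3.2k ± 1.3k mean
three-trial totals on the 768 arena). For an exploratory (untried) pair the
agent routes to the pair's *source* cell and executes the action there;
planning to the predicted successor cannot consummate the pair and was
measured to thrash in the endgame.

Refinement plans with A* (unit costs, admissible Manhattan heuristic to the
nearest target, value-guided expansion tie-breaks) at the level below the
goal, then re-plans the first leg at each finer level restricted to the
children of the current and next macro-states; if a restricted plan fails
the level retries unrestricted, and only then falls back to a random
action. When every resolution says "already there" the agent follows its
local value gradient instead of acting randomly. The planned action
executes with probability ε = 0.8, else a uniform random action, giving the
planned move an empirical frequency of 0.85.

A single-level agent has no level above to set goals and acts ε-greedily on
its local action values (random tie-breaks): this is exactly conventional
tabular MBRL with prioritized sweeping, and `ConventionalAgent` is that
configuration. The distinction matters at scale: local greedy action
selection only feels value that has propagated to the current neighborhood
(bounded by the discount horizon and the priority threshold, ~130 steps at
γ = 0.9), while the hierarchical agent's goal selection is global.

## Lesions

* **vH** removes all levels above the base: the agent *is* the conventional
  baseline, with the full 120-update budget concentrated at level 0. It
  explores by full pair coverage instead of goal-directed raster, so early
  trials are slower, but converges to the same asymptote.
* **dH** keeps only the highest level with more than one macro-state, plus
  a base-level model-free Q-learner (α = 0.1, γ = 0.9, zero-initialized).
  Once the surviving model associates reward with a macro-state, a compass
  policy walks to the nearest cell of that region; inside it the model-free
  values (ε-greedy, random ties) take over, and before any reward has been
  seen the agent moves at random. The macro *reward-location association*
  rather than the macro Q magnitude names the goal, because a single goal
  entry competes against hundreds of reward-free crossings in the same
  table entry and its probability-weighted value is negligible. The result
  is the expected pattern: fast travel to the goal region, slow model-free
  convergence inside it, impaired asymptote.

## Context bank

Stored contexts are entire agents; switching swaps everything (global
remapping). Likelihoods use the base-level model only, over a ring buffer
of the m = 10 most recent experiences, compared as the geometric mean
g = P(H)^(1/m); re-selection (softmax over log-likelihoods, temperature 1)
happens whenever the active context is not the best explanation, with the
active context kept on ties.

Three rules keep the bank clean; all three respond to measured failure
modes of a plain likelihood-threshold design (a correct but once-observed
transition scores 0.67·0.5 ≈ 0.33 < 0.5 under the smoothing, so absolute
thresholds cannot distinguish "new context" from "young model"):

* **Exclusion on surprise.** Arriving where the active model predicts
  reward and finding none excludes, for the rest of the trial, every
  context predicting reward at that location; selection proceeds over the
  remaining candidates. A new context is created exactly when a surprise
  leaves no candidate. Behaviourally the bank visits its learned reward
  sites one after another until one pays — and recruits a fresh explorer
  when all known sites have failed.
* **Reward crediting.** A reward the active model did not predict is
  credited — before the experience is absorbed — to the context that
  predicts reward at that location; if none does and the active context is
  already committed to a different site, a fresh context takes the credit.
  Contexts therefore stay single-site experts instead of blending.
* **Pruning.** A context holding no reward association by a trial boundary
  is dropped: it encodes only geometry every context shares, and — having
  the highest visit counts on its own recent wanderings — would otherwise
  win the likelihood race while pursuing nothing.

On the four-site task the bank converges to exactly four contexts, one per
site, in every tested repetition, and does not grow thereafter.

## Experiments, seeding, and problem sizes

Drivers return one tidy table per study (rows: repetition × agent × trial;
columns include capped steps, goal-reached flag, cumulative model accesses,
bank size). One master seed spawns independent `SeedSequence` streams per
repetition and agent group, so every record is bit-for-bit reproducible.
"Model access" counts one unit per backup computed and per A* node
expansion — env steps and cached argmax reads are free; absolute counts
depend on this bookkeeping, so only comparisons between agents under the
same definition are meaningful. Percentile bands are 2.5/97.5 across
repetitions; two-group comparisons use the two-sided Wilcoxon rank-sum
test.

The boundary-adaptation driver trains each repetition once in the open
arena and branches all requested variants from a snapshot of the trained
agent (a within-repetition crossover); per-variant statistics are
unchanged and the arena phase is not re-simulated per variant.

Default sizes: step-count table, 20 repetitions × 3 trials at 768, 1728
and 3072 states; lesions, 20 × 30 trials; adaptation, 20 × (10+10) trials
per variant; contexts, 20 × 40 trials; scaling stress test, 5 seeds at
12,288 states. All are overridable.

## What the simulations do and do not show

The mazes are deterministic, fully discrete, and rewarded at a single cell
(or one of four known cells); there is no sensory noise, no stochastic
transition structure, and no partial observability beyond location-only
state. Conclusions about adaptation speed, computational load and scaling
therefore concern the algorithmic structure (abstraction, prioritized
updating, likelihood-based remapping), not robustness to noisy perception
or continuous space. Model accesses are a bookkeeping proxy, not a
physiological measurement. The context mechanism remaps wholesale and
cannot transfer abstract knowledge between contexts; tasks whose contexts
share high-level structure would be learned redundantly.
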