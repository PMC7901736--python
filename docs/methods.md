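# Methods

## Model summary and assumptions

The package implements a two-level game.  The lower level is a
two-patch congestion game played by a continuum (analytic layer) or a
finite population (agent-based layer) of foragers with heterogeneous
perceptual thresholds; the upper level evolves those thresholds under a
perception cost.  Core assumptions:

- Two patches only, total resources normalized to 1, equal-share
  competition within a patch, free and costless movement.
- Perception enters solely through the threshold `τ`: reward
  differences below `τ` are invisible, differences at or above it are
  acted on.  Agents that perceive nothing mix randomly between patches
  and therefore split evenly in expectation.
- Complete separation of time scales in the analytic layer: each
  evolutionary step sees the lower game at its exact equilibrium, as if
  infinitely many selection rounds had been played.  The agent-based
  layer deliberately mixes the scales (one game per generation by
  default) to probe the robustness of that idealization.
- The cost function `c(τ) = α/(1+τ)` is strictly decreasing, zero in
  the limit of indifference, finite at perfect perception.  An optional
  plateau freezes the cost above `τ_plateau`.

## Lower-level equilibrium: monotone market clearing

With rich-patch mass `μ` the implied reward difference
`ΔR(μ) = (1/(1+r))(r/μ − 1/(1−μ))` is strictly decreasing, while the
mass demanding the rich patch (everyone with `τ ≤ ΔR`, plus half of the
rest) is non-decreasing in `ΔR`.  The clearing point is therefore
unique and found by bisection on `μ ∈ [0.5, 1)` (tolerance 1e-13 in
`μ`).  The smooth-density derivation behind the clearing condition
assumes no atoms; real inputs here (strategy grids, simulation
populations) are purely atomic, so exact clearing requires the single
marginal atom at `τ = ΔR*` to split fractionally between patches.  This
convention recovers both limits exactly: a fully indifferent population
splits evenly (`ΔR* = 2(r−1)/(1+r)`), and a perfectly perceptive one
input-matches (`x = 1/(1+r)`, `ΔR* = 0`).

Boundary conventions: switching requires a strictly positive advantage
of at least `τ` (no churn at equality), and the strategy exactly at the
marginal threshold is placed on the rich patch, where it earns the full
difference — consistent with the reward assignment used by the fitness
function.  A small tolerance (1e-9) on the branch comparison keeps the
marginal strategy on the rich-patch branch despite solver round-off.

The explicit switching dynamics (directed switching at unit rate,
symmetric mixing at rate `γ = 0.1`) are integrated by explicit Euler
(`dt = 0.01`, convergence when all rates fall below 1e-8) purely as a
brute-force oracle.  When an atom is marginal the hybrid dynamics
chatter around the clearing point in a rate-asymmetric sawtooth of
O(dt) amplitude, so last-state error does not vanish with time; the
oracle tests therefore chain a coarse transient pass with a short fine
pass (`dt = 5e-4`) and time-average the tail, which agrees with the
clearing solver to better than 1e-3 on both occupancy and `ΔR*`.

## Upper-level equilibria

Single ratio: the marginal threshold solves `c(ΔR*) = ΔR*/2`
(bisection/Brent on a bracketed root; the closed-form quadratic for
this cost family serves as an independent oracle in the tests).  The
indifferent share follows from clearing with all informed mass on the
rich patch; if the required difference exceeds the even-split maximum
`2(r−1)/(1+r)` no informed strategy is sustainable.  With a plateau
below the plateau-free threshold, indifference loses its cost advantage
and the population collapses onto the single strategy `τ = τ_plateau`;
with a plateau above it, the bifurcation survives but the informed
threshold settles lower, because the indifferent class now pays the
residual plateau cost.

Multiple ratios (`r_1 > … > r_n`, frequencies `f_i`): thresholds are
solved sequentially from `c(ΔR_k*) = 0.5 Σ_{i≤k} f_i ΔR_i*`; the
construction itself guarantees they decrease.  Occupancies are
recovered recursively from the least sensitive strategy upward: the
cumulative informed mass at stage `k` must clear ratio `r_k`'s game at
difference `ΔR_k*`.  When no clearing solution in [0, 1] exists the
strategy's share is set to zero and earlier thresholds are **not**
re-solved.  This convention is a genuine modelling choice: re-solving
after each drop would change the threshold set.  We keep the
non-re-solving variant because it reproduces the reference behaviour of
the model throughout (including the critical-cost boundary of the
continuous environment below); its known consequence is that the
equal-fitness property across occupied strategies is exact only when no
strategy was dropped, which the tests respect.  Thresholds that
underflow numerical resolution (below 1e-12, or within 1e-12 of the
previous stage) are truncated; at the tiny costs where this happens the
affected strategies are indistinguishable from `τ = 0` and carry
negligible share.

Continuous environments are discretized by placing `q = r/(1+r)` at the
midpoints of 100 equal subintervals of (0.5, 1) — the open right
endpoint corresponds to `r = ∞` and must be avoided; midpoints are the
natural quadrature for the uniform density of `q` (equivalently
`p(r) = 2/(1+r)²`).  The resulting critical cost, located by bisection
on α of the "any informed strategy occupied" predicate (tolerance
1e-3), is ≈ 1.29 and is insensitive to the endpoint convention (left
edges or interior grids shift it by < 0.02).

Replicator dynamics on a fixed strategy grid use explicit Euler with
`dt = 0.05`, flooring negative shares at zero and renormalizing each
step (exact mass conservation holds only in continuous time).  Fitness
is always evaluated through reward *differences* anchored at the
poor-patch reward returned by the clearing solver, never through a
bare `1/(x(1+r))` that would diverge as `x → 0`.

## Agent-based model

- **Reward scaling.**  Total resources equal the number of agents, so
  the population-mean reward is 1 and rewards share the scale of the
  continuum analysis and of `c(τ)`; without this, per-agent rewards
  would be O(1/N) and swamped by an O(α) cost.
- **Switching rule.**  Candidates to move are agents whose anticipated
  reward on the other patch — evaluated at the occupancy *after* their
  own arrival — exceeds their current reward by at least `τ` and
  strictly.  One candidate, chosen uniformly at random, moves; the game
  ends when no candidate exists.  Anticipating one's own arrival makes
  each move increase the Rosenthal potential by exactly the mover's
  gain, which guarantees termination; evaluating the destination at its
  current count instead provably cycles for populations of perfect
  perceivers whenever `N/(1+r)` is not an integer (two adjacent integer
  splits each show a positive advantage in turn).  It also gives an
  empty patch a natural anticipated reward (the mover alone).  The two
  rules differ by O(1/N) in the resulting occupancies.  A sweep cap of
  50·N moves is kept as a safety net and has never been reached.
- **Reproduction.**  Roulette selection needs nonnegative weights but
  fitness can be negative, so weights are `F − min(F) + ε` with
  `ε = 1e-9·(max(F) − min(F) + 1)`: order-preserving, scale-insensitive,
  degrading gracefully to uniform when all fitnesses tie.  Children
  mutate on the logistic scale `s = logistic(τ)` with Gaussian scale σ
  and are *clipped* (not reflected) to [0.5, 1]; `s = 1` encodes
  `τ = ∞` exactly, so indifference is reachable and stable.
- **Recording.**  Each generation stores a 100-bin histogram uniform in
  `s` (i.e. logistically spaced in `τ`), the uninformed fraction
  (`τ > 2`, a conventional visual separator of the two clusters), mean
  fitness, the ratios played, and the realized equilibrium reward
  difference.

Nucleation detection (for runs started fully indifferent): a
generation's "deterministic choosers" are agents whose finite `τ` lies
at or below that generation's realized reward difference — they take
the rich patch by perception rather than luck, which is precisely the
source of their fitness edge.  Onset is declared when their fraction
reaches 1% and stays there for 30 consecutive generations, and the
nucleation threshold reported is the largest `τ` among them at onset.
Both quantities are measurements of the simulation; the detection
thresholds only need to separate sustained growth from the transient
singleton mutants seen before onset.  Nucleation from indifference is a
rare stochastic event (roughly half of 6000-generation replicates at
σ = 0.0075 show it), so reproduction scripts attempt a fixed series of
seed-derived replicates and report the first nucleating one.

## Study conditions and problem sizes

The full-scale conditions are those of the reference scenarios: 1000
agents, α = 0.5, r = 5, σ = 0.0025 (bifurcation from perfect
perception, 3000 generations) or σ = 0.0075 (nucleation from
indifference, capped at 6000 generations).  These run in seconds, so
the acceptance script and the test suite use them unreduced.  The
steady-state agreement check between the agent-based and analytic
uninformed fractions uses a reduced scale of 400 agents, 2000
generations, and σ = 0.005: at the smaller population the paper-scale
mutation rate σ = 0.0025 does not reliably complete the bifurcation
within the horizon, while σ = 0.005 reaches a stable steady state whose
uninformed share sits within 0.1 of the analytic prediction across
costs α ∈ {0.3, 0.6, 0.9}.  The CLI sweep command defaults to 200
agents and 600 generations for quick exploration.

## What the generator does and does not emulate

All experiments are self-generated from model parameters; there is no
external data.  The synthetic environments capture the structural
features the theory addresses — patch-quality ratios, their
frequencies, cost scale, mutation scale — but idealize away everything
a field population would add: more than two patches, travel costs,
unequal competitive abilities, spatial structure, age structure, and
learning within a lifetime.  Passing tests therefore validate the
internal consistency of the model and its finite-population robustness,
not the claim that any particular animal population follows it.

## Known limitations

- The multi-ratio occupancy recursion without threshold re-solving (see
  above) leaves the equal-fitness identity approximate when strategies
  are dropped; the no-drop case is exact to solver precision.
- The agent-based uninformed fraction sits systematically ~0.05–0.1
  below the analytic prediction at low-to-moderate costs: mutation
  keeps a cloud of weakly informed agents alive that the infinite-population
  analysis assigns to indifference.  This is a property of the model's
  mutation dynamics, not a numerical artifact.
- The informed cluster in simulations stabilizes slightly below the
  analytic threshold (asymmetric cost of mutating above versus below
  it); analytic predictions should be read as upper edges of the
  simulated clusters.
- Analytic stability is checked only through no-profitable-deviation
  tests at the computed equilibria, not a full dynamical classification.
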