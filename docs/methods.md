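# Methods

`stagcpt` studies how two cognitive mechanisms — risk sensitivity and
theory of mind — shape coordination between two self-regarding agents in
stag-hunt games. Risk sensitivity is modelled with cumulative prospect
theory (CPT); theory of mind with level-k recursion over best responses.
This note records the model, the numerical choices, and what the tests do
and do not establish.

## CPT valuation of discrete prospects

A prospect is a discrete random outcome `R` with finite support. Relative
to a reference point `b`, outcomes `r ≥ b` are gains and `r < b` losses.
Value is

```
V(R) = Σ_{r ∈ O+} u+(r − b) ψ+(r) + Σ_{r ∈ O−} u−(r − b) ψ−(r)
ψ+(r) = w(P(R ≥ r)) − w(P(R > r)),   ψ−(r) = w(P(R ≤ r)) − w(P(R < r))
```

with the piecewise power utility `u+(x) = x^γ`, `u−(x) = −λ|x|^γ` and a
probability weighting `w`. Supported weightings:

- **Prelec**: `w(p) = exp(−α(−log p)^δ)`. `α < 1` over-weights large
  probabilities (optimism about likely events); `α > 1` under-weights
  them (certainty effect); small probabilities are over-weighted for
  small `α` (possibility effect). `w(0)` is defined as 0 by continuity.
- **kt1992**: `w(p) = p^g / (p^g + (1−p)^g)^(1/g)`, provided for
  comparison and for normal-form experiments. Inside the Markov solver it
  is accepted but logged as a warning, as the value recursion with this
  weighting is prone to numerical instability.
- **identity**: `w(p) = p`. Identity utility + identity weighting +
  `b = 0` is exactly expected utility (EUT), and the implementation
  reduces to the arithmetic expectation in that limit (property-tested).

Implementation notes:

- Decision weights are computed positionally on the sorted support with
  telescoping cumulative sums. This makes the value invariant to outcome
  ordering and to splitting/merging equal outcomes, with no special tie
  handling.
- Rows are probability vectors; the full-mass cumulative is pinned to
  exactly 1 before weighting, because Prelec's unbounded slope at `p = 1`
  would amplify `1e-16` summation drift into `1e-12` weight error.
- Zero-probability atoms drop out (their decision weight is exactly 0),
  so `log 0` never arises.
- Prospect construction merges duplicate outcomes by summing probability;
  the merged representative is the probability-weighted mean, and
  unmerged outcomes are never perturbed by round-off.
- `rank_integral_oracle` recomputes the value as the exact piecewise
  integral of the weighted survival function of the utility magnitudes
  (the integrand is a step function; each piece is evaluated at its
  midpoint). It shares no code path with the rank-dependent sums and is
  used purely as a cross-check, at 1e-9.

Parameter defaults follow the experiment at hand: the gamble surfaces use
`γ = 0.85, λ = 2, δ = 0.75`; the normal-form sweeps use neutral utility
(`γ = λ = 1`) with `δ = 0.75`; the Markov game uses identity utility with
`w(x) = exp(−0.5(−log x)^0.9)`. The two `δ` values are kept as separate
per-experiment defaults rather than unified, since each analysis is
defined with its own weighting.

## Normal-form stag hunt

The 2×2 symmetric game has payoffs R=5 (both Stag), S=−1 (Stag vs Hare),
T=1, P=1. Against an opponent playing Stag with probability `p`, each
action is a two-outcome prospect and the mixed equilibrium is the `p*`
making both actions' CPT values equal. The solver samples the difference
on a 2001-point grid (resolving roots at least 5e-4 apart) and refines
each sign change by bisection to an interval below 1e-10. CPT can create
several indifference points; sweeps report the smallest root (all roots
remain available and are logged) so the surfaces are deterministic. When
no interior root exists, the dominating pure probability (0 or 1) is
reported, which keeps the surface continuous across region boundaries.
With identity parameters the closed form `(P−S)/(R−S−T+P) = 1/3` is
recovered to 1e-9.

## The canyon Markov game

Sixteen positions on a line; hares at position 3 (reward 1, collectable
alone), stags at position 11 (reward 5, paid only when both agents stand
there). Actions Left/Stay/Right succeed with probability 0.6, leave the
agent in place with 0.2 and slip the opposite way with 0.2; Stay slips one
step to each side with 0.2 each. Off-grid mass is clamped onto staying —
this is the unique simple slip rule whose default kernels contain exactly
the probability levels {0, 0.2, 0.4, 0.6, 0.8}, with 0.4 and 0.8 only at
the corner states, and no degenerate (probability-1) transitions.
Reflection at the walls was rejected because it cannot produce an 0.8
level. Left/right slips are assumed symmetric.

The stag and hare reward magnitudes in the Markov game are calibrated to
mirror the normal-form payoffs (hare 1, stag 5); a lone visit to the stag
position pays `lone_stag_reward` (default 0 — there is no analogue of the
normal-form −1 in the dynamic game, and the value is configurable). All
qualitative stationary-distribution results below are conditional on this
calibration.

The joint kernel is `P^(a1,a2) = (I ⊗ P^(a1) + P^(a2) ⊗ I)/2`: the
average over which agent's move resolves first, so exactly one agent
moves per step and neither agent's action affects the other's position.
Joint states are flattened as `index = s2·n + s1` (matching the Kronecker
ordering); the public API uses `(s1, s2)` pairs.

## CPT planning and level-k towers

Agent `i`'s value of a joint state under a joint policy is the fixed
point of a CPT Bellman backup: the one-step prospect is
`r_i(s) + β V(s')` with `s'` drawn from the kernel mixed over the other
agent's policy (and, for policy evaluation, over the agent's own policy —
the own-action mixture sits inside the probability weighting, not outside
it). The reward is earned in the current state; the reference point is
applied inside the valuation, not subtracted from the prospect.

Because the prospect is discrete, the CPT integrals over distorted tail
probabilities reduce exactly to the rank-dependent sums — the solver does
no quadrature. A vectorized backup evaluates all 256 states at once: the
continuation values are sorted once per iteration, so every state's
prospect is already rank-ordered.

- Best response: greedy value iteration, `V(s) ← max_a` CPT-backup; the
  returned policy is uniform over all actions within `tie_tol` (1e-9) of
  the per-state maximum, preserving the canyon's left/right symmetry.
  Whether strictly mixed policies could ever beat the greedy per-state
  choice under CPT (the backup is non-linear in the policy) is left open;
  the greedy scheme is the intended reading of the best-response
  recursion.
- Convergence: the CPT backup has no contraction guarantee. Iteration
  starts from `V ≡ 0` (reproducible, and consistent with the zero-reward
  framing), runs damped (damping 1.0 by default, configurable), stops at
  sup-norm residual `tol = 1e-8`, and raises a diagnostic error carrying
  the residual trace after `max_iter = 10000` sweeps. In the EUT limit the
  iteration is the classical one and matches exact linear solves to 1e-6.
- Level-k: level 0 is the uniform stereotype for both agents; level k is
  agent `i`'s best response (with its own parameters) to the opponent's
  level k−1 policy. Heterogeneous agents (EUT vs CPT) are supported.
  Everything is deterministic — two runs produce bit-identical towers.

Discount default `β = 0.9` (range (0,1)); higher β weighs the long-run
stag payoff more heavily.

## Stationary analysis

Conditioning the joint kernel on a joint policy gives a 256-state chain
whose stationary distribution `ρ = ρP` summarizes long-run behaviour.
Irreducibility is verified by strong-connectivity search on the
positive-entry graph before solving, turning silent eigenvalue degeneracy
into a diagnosable error; the slip noise makes every policy-conditioned
chain of the default canyon irreducible and aperiodic. The solver uses
eigen-decomposition of the transpose and polishes with power iteration to
a sup-norm residual below 1e-10. The initial state of the game is
irrelevant to this analysis for irreducible chains and is therefore not a
parameter.

Summaries: `stag_mass` (probability both agents on the stag position),
`hare_mass` (at least one agent on the hare position), and per-agent
positional marginals.

## What the experiments show (and what they do not)

The registered experiments reproduce, as data tables, the qualitative
findings: the stag state's value grows with sophistication; a level
pairing of (2,1) already coordinates at least as well as (1,1); raising
the reference point moves mass from stag to hare while deeper recursion
can undo that at `b = 1`; CPT agents out-coordinate EUT agents; patience
(β 0.95 vs 0.85) helps; even mild utility concavity (γ = 0.99, 0.95)
hurts. Two caveats: absolute masses depend on the reward calibration
above, and with identity utility any `b ≤ 0` produces identical policies
(the shift only adds a constant to an all-gains value function), so
stag mass is flat between `b = −1` and `b = 0` rather than strictly
decreasing.

These are statements about this stylized environment — a 1-D canyon, two
agents, uniform stereotypes, fully known parameters. They do not speak to
parameter estimation from human data, to populations of more than two
agents, or to learned (non-uniform) stereotype policies.

## Problem sizes and tolerances used in the test suite

The test suite exercises the full 256-state game for the EUT-limit
equivalences and for the qualitative stationary results (towers up to
k = 4), and a 2-position fixture canyon (4 joint states) wherever an
exhaustive oracle is used: enumeration of all 3^4 deterministic policies
against exact linear solves, brute-force successor enumerations, and
double-sum chain construction. Property tests are derandomized. The
level-k towers used by several tests are computed once per session and
shared.
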