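# Methods

## Task and environment

The environment is a deterministic gridworld shaped like a T: a vertical
stem (column 4, rows 1–8 of a 9×9 grid) joined to a horizontal bar (row 0,
columns 0–8), 17 corridor cells in all. Episodes start at the bottom of
the stem (8, 4); a unit reward sits at one bar end — (0, 0) or (0, 8) —
and relocates to the opposite end every 20 episodes. Reaching the reward
ends the episode with return 1; otherwise the episode ends with return 0
once the agent has made 500 actual moves. The shortest path from start to
either goal is 12 steps: 8 up the stem, 4 along the bar. The goal test is
applied before the cap test, so a goal reached exactly on the 500th move
still counts.

Two environment conventions are deliberate choices where the task
statement is silent, and both matter quantitatively:

* **Blocked moves.** An action into a wall leaves the agent in place, and
  the 500-step budget does **not** advance — the cap bounds the length of
  the path actually walked, not the number of action attempts. The agent
  still receives an observation after a blocked attempt and learns from the
  resulting self-transition. Under this convention a uniform random policy
  reaches a goal within the budget with probability ≈0.96 (vs ≈0.75 if
  wall bumps consumed budget), which is what makes near-perfect reward
  rates attainable for well-tuned agents. The per-step learning on
  blocked attempts is also what lets a post-relocation agent erode a stale
  value peak it is pressed against instead of idling on it.
* **Terminal transitions.** The TD bootstrap term is dropped on
  episode-ending transitions (goal or cap). Without this cut the
  successor-feature column of the goal inflates (the learned value of the
  goal observation reaches ≈3.7 rather than ≈1) and relearning after a
  relocation becomes erratic.

## Observations and the noise model

The agent observes `o_t = φ(s_t) + ε_t` with `ε_t ~ N(0, σ²I)`, σ = 0.05,
drawn freshly once per time step; the arrival observation of one transition
is reused as the departure observation of the next, so exactly one noise
vector is consumed per step. Features are one-hot over the 17 corridor
cells by default (`feature_space="corridor"`, d = 17); a variant over all
81 grid cells (`feature_space="full"`) is available and behaves very
similarly, since wall cells are never visited and their coordinates only
ever carry noise.

Noise enters **learning only**: action selection evaluates candidate
successor cells on their clean one-hot features (below). An interesting
emergent property of the tabular one-hot setting is that a little
observation noise *helps* navigation: with σ = 0 each TD update touches
only the coordinates of visited cells, so the Uniform[0,1)-initialised
weight entries of rarely visited cells survive indefinitely as spurious
value peaks, and greedy trajectories meander; with σ = 0.05 every update
perturbs all coordinates and the stale structure washes out, after which
agents reliably find the 12-step optimum (verified in the test suite).

## Agent

State: the d×d successor/predecessor-feature matrix `W` (initialised
i.i.d. Uniform[0,1), seedable), the reward vector `w_r` (zeros), and the
eligibility trace `e` (zeros, reset at each episode start). One update per
attempted action:

```
e    ← e + o_t
δpf  ← o_t + γ·W·o_{t+1} − W·o_t        (γ term dropped when the episode ends)
δr   ← r − o_{t+1}·w_r
W    ← W + α_W (δpf ⊗ e)
w_r  ← w_r + α_r δr o_{t+1}
e    ← γλ e
```

λ = 0 reduces exactly to successor features (TD(0)); the suite asserts
bit-identity against an independent SF implementation. The reward error is
evaluated at, and credited to, the arrived-at observation `o_{t+1}`, which
is the observation under which the reward was delivered.

**Policy.** ε-greedy over a one-step lookahead through the known
deterministic dynamics: `Q(a) = w_r · W φ(s'_a)` where `s'_a` is the cell
the action would reach (the current cell if blocked). Ties break uniformly
at random. The exploration rate is `ε_k = 0.9·0.8^k + 0.1` with k the
episode index within the run; it decays monotonically and does **not**
reset when the reward relocates — re-exploration after a relocation is
driven by the unlearning of `w_r`, not by the schedule. The alternative
reading (reset each block) was evaluated and rejected: it decouples
adaptation from the reward learning rate almost entirely, flattening the
α_r dependence that is the study's central effect, and it removes the
characteristic >400-step episode at each relocation.

**Action evaluation uses clean candidate features.** Evaluating candidates
on freshly noise-corrupted features was evaluated as an alternative; it
roughly doubles the α_r effect sizes while costing ≈3.5 reward units at the
best configuration, and it has no support in the learning algorithm, which
confines noise to the observation stream.

## Hyperparameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| α_r | reward-vector learning rate | swept {0.1,…,0.9} | the study's key adaptability knob |
| λ | eligibility-trace decay | swept {0,…,0.8} | 0 = SF, >0 = PF |
| α_W | feature-matrix learning rate | 0.1 | fixed |
| γ | discount | 0.95 | fixed; also decays the trace (γλ) |
| σ | observation noise s.d. | 0.05 | fixed, per coordinate |
| ε schedule | exploration | 0.9·0.8^k + 0.1 | floor 0.1, per-episode index |
| cap | episode step budget | 500 moves | blocked attempts excluded |
| switch period | episodes per goal block | 20 | 4 relocations per 100-episode run |

## Experiment design and reproducibility

A *run* is 100 episodes with persistent weights (only the trace and the
environment reset between episodes); the 5×5 grid × 100 runs yields 2 500
run-level observations and 12 500 run-by-block observations. Each run's
seed derives from `(base_seed, λ, α_r, run_id)` through a seed sequence, so
any sub-grid reproduces the same runs independently of what else is
simulated. One `numpy` generator per run drives, in order, W
initialisation, then each step's policy draws and observation noise; every
policy decision consumes exactly two uniforms so both engines advance the
stream identically. The compiled (numba) engine and the pure-Python
reference produce bit-identical logs — asserted in the tests — and either
can be selected per call.

## Metrics

* **Cumulative reward** — rewarded episodes per run (0–100).
* **Mean step length** — arithmetic mean of per-episode move counts.
* **Adaptation rate** — per goal block (the initial block and one per
  relocation, 5 per run): the block-local episode index (1–20) at which a
  streak of 5 consecutive rewarded episodes first completes; minimum 5,
  and blocks with no streak are assigned 20 and flagged censored rather
  than dropped, keeping the observation count balanced at runs × 5.
* **Adaptation step length** — moves summed from the block start through
  the episode the adaptation rate counts (the whole block when censored).

## Statistical analysis

Spearman rank correlations (mid-ranks for ties; two-sided p from the
t-approximation, n−2 df) relate each metric to each hyperparameter
separately; OLS with intercept relates each metric to α_r and λ jointly,
with classical normal-theory 95% confidence intervals (n−3 df).
Hyperparameters enter on their natural grid scales, uncentred. Reward and
step-length analyses use run-level observations (n = 2 500); adaptation
analyses use run-by-block observations (n = 12 500), censored blocks
included. The implementations delegate to `scipy.stats.spearmanr` and
`statsmodels` OLS; the test suite checks both against independent
first-principles oracles (rank-then-Pearson; normal equations) and verifies
~95% CI coverage on synthetic data with known coefficients.

## What the generator does and does not emulate

The simulator *is* the study: all data are generated internally under the
stated conditions (geometry, schedule, noise, grid, run counts), so the
pipeline's statistical outputs are Monte-Carlo estimates of the same
estimands. It does not emulate richer environments (larger or stochastic
mazes, continuous features), other noise levels or structured sensor
noise, or behavioural phenomena beyond the four metrics; conclusions about
those require new conditions, not larger n here. Two published
regularities are not fully reproduced by this implementation —
the α_r slopes of the OLS fits come out 20–25% smaller in magnitude, and
the (non-significant) λ correlation with cumulative reward has the
opposite sign — which we attribute to unstated implementation details of
the original environment/exploration loop; the rank correlations of α_r
with all metrics, the best-configuration reward level, and all effect
signs for step length and adaptation reproduce within tight tolerances.

## Numerical and engineering choices

* Exact float tie-breaking in the argmax (uniform among exact ties); ties
  in practice occur only while `w_r` is exactly zero.
* The compiled kernel mirrors the Python reference operation-for-operation
  (same BLAS calls, same elementwise order, same draw counts) so the two
  are bit-identical, not merely statistically equivalent.
* Per-run seeds are folded to < 2³¹ for portability; all randomness flows
  from the run seed — no global RNG state anywhere.
* CSVs are written with headers, UTF-8, '.' decimal, no index, and are
  byte-stable across reruns of the same configuration.
* Degenerate inputs fail loudly: disconnected mazes, off-corridor anchor
  cells, negative σ, constant Spearman inputs, rank-deficient designs and
  incomplete grids all raise with the offending item named.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the study at its native scale
(25 configurations × 100 runs × 100 episodes, ~1–2 minutes compiled);
property tests use reduced sizes (tens of episodes, 10³ random cases for
the brute-force oracles, 200 replicates for CI coverage) chosen to exercise
the code paths rather than to maximise statistical power.
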