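# Methods

## The model

`hrlsim` simulates nutritional homeostasis as reinforcement learning in a
*homeostatic space*: a metric space whose axes are internal physiological
variables (here one nutrient level `H`). The drive

    D(H) = ( Σ_i η · |H*_i − H_i|^n )^(m/n)

measures the distance of the internal state from its ideal setpoint `H*`,
with shape exponents `(m, n) = (3, 4)` (the standard choice in homeostatic
reinforcement learning) and a non-negative interoceptive gain `η`
multiplying the perceived deviation. The reward of an action is the drive
reduction it is *predicted* to cause,

    r_t = D(H_t) − D((1 − 1/τ) H_t + K̂_t − cost),

where `(1 − 1/τ)` is the per-step nutrient decay, `K̂(s, a)` is the agent's
learned prediction of the nutrient an action delivers (delta rule, rate
`α_K̂`), and `cost` is the fixed nutrient loss of a climb action, priced
into the predicted next state so that climbing is punished through the
reward. The *actual* intake `K` drives the state transition
`H' = (1 − 1/τ) H + K − cost`; the internal state is not clamped, as the
dynamics impose no bounds and clamping would distort drive gradients.

Action values `Q(s, a)` are tabular and learned from the TD error
`δ = r + γ max_a' Q(s', a') − Q(s, a)` with rate `α_Q`; actions are drawn
from the softmax `P(a) ∝ exp(β Q(s, a))`. Q and K̂ start at zero: the first
choices are random and the first reward estimate is conservative.

Manipulated parameters model clinical constructs: `η < 1` blunted and
`η > 1` exaggerated interoception, low `β` noisier action selection, low
`γ` myopic valuation.

## Perceived versus objective scales

In one dimension the gain factors out of the drive exactly:
`D_η(H) = η^(m/n) D_1(H)`. The gain is therefore equivalent to rescaling
every reward — and hence, through the softmax products `β·Q`, to rescaling
the effective inverse temperature. Two consequences shape the package:

1. The learning dynamics are *self-similar* in `β·η^(m/n)`: trajectories of
   a low-gain agent replay those of a control agent in slow motion. Any
   outcome measured in perceived-reward units inherits the scale factor
   `η^(m/n)` and (for the transient-dominated sums of a 100-step episode)
   collapses onto the η^(1/4) line, regardless of behaviour.
2. The body's actual deficit does not depend on how strongly it is
   perceived. The package therefore records both scales in every
   trajectory and measures *outcome* metrics — the summed drive and the
   summed punishment an agent incurs — on the objective (`η = 1`) scale,
   while the average reward per intake, which characterises the activity of
   the reward signal itself, stays on the perceived scale. With this
   reading the blunted-interoception agent shows lower reward per intake
   (scale) together with higher accumulated punishment and drive
   (behaviour), the pattern the model family is built to produce.

## Tasks

**Intake after food restriction.** One external state, two actions (do
nothing / intake `K`), a fixed 100-step horizon, `H_0 = 100` against
`H* = 200`. Defaults: `K = 16`, `τ = 14`, `α_Q = 0.05`, `α_K̂ = 0.5`,
`β = 3.5e−5`, `γ = 0.9`. The calibration logic: `K·τ = 224` makes the
setpoint sustainable only when intake is selected well above chance, so the
agent hovers just below the setpoint, where intake keeps a positive reward
and `Q(intake)` stays above `Q(do nothing)` (the γ-bootstrap props the
do-nothing value to ≈ γ·Q(intake) from below). β sits at the functional
edge: the control agent converges within the horizon in ≳95% of runs,
while halving the effective sharpness (η = 0.3) visibly prolongs the
deficit. Large intake increments (e.g. K = 40) produce binge–crash
oscillations around the setpoint instead of convergence and were rejected.

**Mountain climbing.** Eight states `S0..S7`; a small self-loop intake at
the bottom, costly climbs through `S1..S6`, a large episode-ending intake
at the summit; `H` resets to 100 each episode while Q and K̂ carry over; 15
episodes form a trial, trials are censored at 5,000 steps per episode.
Defaults: `k_small = 0.8`, `k_large = 110`, `cost = 0.3`, `τ = 100`,
`α_Q = 0.5`, `α_K̂ = 0.05`, `β = 1.5e−6`, `γ = 0.95`. The constraints
behind these numbers:

- `k_small·τ` must stay below the setpoint, otherwise minor feeding alone
  sustains homeostasis and never climbing is the rational policy.
- `k_large` is chosen so the summit intake lands the deficit-depleted agent
  at the setpoint, maximising the summit's drive reduction.
- A small `α_K̂` keeps the bottom-feeding bias (which is proportional to
  the learned `K̂(S0, small)`) invisible during route discovery; the summit
  reward survives the same underestimation because any intake at deep
  deficit reduces the cubic drive enormously.
- `γ = 0.95` (this task only) keeps the 7-step discounted value chain
  strong against the immediate climb punishments; with the intake task's
  0.9 the route's value is marginal.

## Experiment protocol

A condition is the control configuration with one parameter moved:
`η = 0.3` / `η = 1.7` (inside the 0 < η < 2 sweep), `β/4`, or `γ = 0.2`.
Replicate *i* of a condition runs a fresh agent on seed `base_seed + i`
(40 replicates per arm in the intake task, 30 trials in the mountain task).
Metrics: average perceived reward per intake, objective summed punishment,
objective summed drive, intake count (intake task); S7-rate (fraction of a
trial's timesteps spent at the summit), total timesteps, and small-intake
count (mountain task). Zero-intake replicates yield a missing reward-per-
intake value and are dropped pairwise before testing, with the count
reported.

Between-group comparisons follow a fixed protocol:
Levene's test (classical, mean-centred — the default of the common
statistical packages) gates Student's pooled-variance t-test against
Welch's; total timesteps, whose distribution is heavy-tailed because of
occasional slow-learning trials, is compared with the Wilcoxon rank-sum
test (exact enumeration for tie-free samples up to n = 20, otherwise the
midrank normal approximation with continuity correction). Two-sided
p-values are reported with the direction recorded separately; the
directional test suite converts them to one-sided at α = 0.05.

## What the simulations show — and what they cannot

The intake-task manipulations replicate robustly: blunted interoception
lowers the perceived reward per intake and raises objective punishment,
drive, and skipped intakes; exaggerated interoception does the opposite;
low β and low γ both leave the agent under-feeding with raised drive.
The mountain-task manipulations split: the myopia effect (low γ: fewer
summit visits, longer trials) and the randomness effect (low β: longer
trials) are large and significant, while the interoception effects are
small. The reason is structural, not a bug: the gain is exactly an
effective-sharpness rescaling, so its mountain effects can only act through
the sharpness–performance curve, and trial duration is dominated by the
stochastic discovery of the summit route — a visit-count-limited process
that sharpness barely touches. Sharpening also amplifies whatever the
agent happens to believe early, so every design that makes bottom-feeding
attractive enough to register a strong feeding preference (which would be
needed for a small-intake-count peak at control) also makes the sharper
agent lock into the bottom state. The directional tests for the mountain
interoception arms are kept in the suite at their stated thresholds and
fail honestly under the default calibration; the corresponding effect
directions are reported by `scripts/acceptance.py` as ratios so the
magnitudes are visible.

## Numerical choices and degenerate inputs

- Softmax uses max-subtraction; β = 0 is exactly uniform; extreme
  `β·ΔQ` saturates to a degenerate distribution without overflow.
- Action draws consume one uniform per decision (inverse-CDF), making
  trajectories bit-reproducible for a fixed `numpy` Generator seed.
- Ties in `max_a' Q` need no tie-break: only the max value enters the TD
  target.
- The terminal (summit) transition bootstraps from the next episode's start
  state because values are carried across episodes; an episode hitting the
  step cap is flagged as censored, not an error.
- Identical constant samples short-circuit Levene (W = 0, p = 1) and the
  rank-sum test (p = 1) rather than dividing by zero.
- `tau ≤ 1` is rejected: a single decay step would zero or sign-flip the
  state.

## Limitations

The synthetic tasks probe the model's internal consistency, not real
feeding data: one nutrient dimension, a deterministic static gain, fixed
intake magnitudes, and a discount-per-step notion of delay. Passing the
directional suite shows the implementation reproduces the model family's
qualitative phenomenology under this calibration; it says nothing about
parameter identifiability from behavioural data, and the free-parameter
defaults are one point in a large plausible set. Dynamic or stochastic
interoceptive gain and multi-nutrient interactions are out of scope.
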