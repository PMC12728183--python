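# Methods

## The task ecology

`cuelens` simulates a repeated three-option choice task in which one
stimulus characteristic is a probabilistic cue for the best option. On
each round a participant sees three geometric shapes (vertical/horizontal
rectangle, vertical/horizontal ellipse, square, circle) at the left,
middle and right screen positions. Each option has a visible **area** and
a **price** (experimental currency units); choosing it pays
`area − price`. The option with the largest payoff is the **superior
option**. Feedback is full: after every choice the payoffs of all three
options are revealed, so the cue's track record is observable whether or
not the cue option was chosen.

Option attributes are generated as follows: three payoffs are drawn from
one normal distribution and ranked; each option's price is drawn from a
second normal distribution (truncated below at 1 by resampling); the area
is payoff + price. Areas and prices are rounded to integers — the values
a participant would see on screen — and payoffs are recomputed on the
rounded values so the displayed arithmetic is exact (e.g. area 183, price
53, payoff 130). Rounds whose rounded payoffs tie are re-drawn, because
the superior option must be unique; a bounded retry count turns a
degenerate configuration (e.g. near-zero payoff spread) into an explicit
error rather than a hang.

Defaults: payoff ~ Normal(130, 30), price ~ Normal(55, 15). These are
configurable (`SessionConfig`); they were chosen once so that simulated
magnitudes resemble the displayed task values, and the analysis is
invariant to them (only cue placement and choices enter the regression).

## Cue types and cue placement

Each synthetic participant is assigned one condition and one **assigned
predictivity** `p` (drawn Uniform(0, 1) per participant by default):

- **decoy** — one option "has a decoy": a second option that shares its
  shape but is dominated by it in both attributes (smaller area *and*
  higher price). The decoy construction draws a proportion
  `q ~ Uniform[0, 1]` of the payoff gap `d` between target and decoy
  source: the decoy's price is `target.price + q·d` and its area is
  `target.area − (1−q)·d`. This conserves the decoy's payoff exactly and
  yields strict dominance for `q` in the open interval (weak in one
  attribute at the endpoints, a probability-zero event under the
  continuous draw).
- **default** — one option is pre-selected.
- **rule** — one per-session "indicator shape" (uniform over the six
  shapes) marks one option; the other two options are re-randomised to
  non-indicator shapes, so the indicator appears exactly once per round.

A session has 43 rounds: 3 practice rounds followed by a uniformly random
interleaving of 28 **treatment** rounds and 12 **test** rounds. Practice
rounds are generated exactly like treatment rounds. On treatment rounds
the cue marks the superior option with probability `p`; otherwise it
marks an inferior option — in the decoy condition the second-best option
has the decoy and the worst option is the decoy; in the default and rule
conditions one of the two inferior options is chosen uniformly (the
generation rule is stated only as "one of the two inferior options"; the
uniform choice is the maximum-entropy reading). When the decoy cue is on
the superior option, the decoy itself is the second- or third-best option
with equal probability.

Test rounds are unpredictive by construction: the decoy lands on the
superior or second-best option with probability ½ each (the worst option
is always the decoy), and the default/indicator lands uniformly on one of
the three options. Hence the test-round chance rate of the cue marking
the superior option is ½ (decoy) and ⅓ (default, rule) — properties the
test suite checks against exact binomial intervals.

## The predictivity statistics

For each round, `cue_predictive` is 1 iff the cue-indicated option is the
superior option. The running **historical predictivity** at round `r` is
the mean of the `cue_predictive` flags over rounds `1..r−1`. It is
undefined at `r = 1` (the code raises there; the regression never needs
it because test rounds start after the three practice rounds). Practice
rounds count toward the history by default; `simulate_session` exposes a
toggle for sensitivity analyses that exclude them.

## Synthetic agents

The agents are data generators with known statistics, not cognitive
models:

- `random`: uniform over positions — the null generator for calibration.
- `attribute`: argmax of perceived payoff `area·(1+ε) − price`,
  `ε ~ Normal(0, perceptual_sd)` per option. Noise is multiplicative on
  the area only: areas are judged visually while prices are printed
  numerals. Ties break to the leftmost position (only reachable with
  degenerate inputs).
- `cue_hybrid`: follows the cue with probability `w`, otherwise falls
  back to another policy. With `intercept_weight` set, `w` becomes the
  affine response `w0 + w1·h` in the historical predictivity `h` — the
  configuration used for parameter recovery, because its regression
  estimands are known exactly.
- `matching_learner`: probability matching — follows the cue with
  probability equal to `h` (⅓ before any feedback, the uninformed prior
  over three options).

The key identity: a cue-following probability `w` mixed with a uniform
fallback gives `P(choose cue) = w + (1−w)/3 = 1/3 + (2/3)w`. An affine
agent therefore has test-round choice probability
`1/3 + (2/3)(w0 + w1·h)`, exactly linear in `h`, so the linear
probability model is correctly specified for it: the OLS slope estimates
`(2/3)·w1` and the intercept `1/3 + (2/3)·w0`. A perfect matching agent
(`w = h`) yields slope 2/3 — not 1 — because of the same chance-mixture
correction.

## The preregistered analysis

For each condition separately, the pipeline subsets to the 12 test rounds
and fits by OLS the linear probability model

    chose_cue_option = a + b · historical_predictivity + e

with standard errors robust to heteroskedasticity and clustered on the
participant (the cluster sandwich with the standard finite-sample
correction, via statsmodels; an independent hand-rolled normal-equations
oracle in the tests agrees to ~1e-15). The slope `b` is the estimated
**cue weight**: the change in the probability of choosing the
cue-indicated option per unit historical predictivity;
`marginal_effect(fit, 0.10)` converts it to percentage points of choice
probability per 10-percentage-point predictivity change. Degenerate
designs error out explicitly: fewer than two clusters, zero variance in
the regressor, or test-round rows with undefined history.

`binned_choice_rates` groups test-round observations by historical
predictivity rounded to two decimals and reports local averages — the
standard display for a binary outcome. `chance_benchmark` gives the
analytic reference lines under two cue-blind chooser assumptions: a
chooser uniform over all three options picks the cue at ⅓ in every
condition; a chooser who never picks the dominated decoy but is otherwise
uniform picks the cue option at ½ in decoy test rounds (the cue is one of
the two non-decoy options) and ⅓ elsewhere. Both assumptions are
implemented because either is a defensible benchmark for the decoy
condition; neither is asserted to be uniquely correct.

## Validation design and problem sizes

- Construction invariants (dominance, payoff conservation, cue
  uniqueness) are checked over 10,000 generated decoy trials.
- Test-round neutrality is checked over 20,000 trials per condition
  against exact binomial 99% intervals.
- Parameter recovery uses 300 participants per condition: affine agents
  must land within 2 Monte-Carlo SEs of the analytic estimands; matching
  agents must produce positive slopes with |t| > 1.96 in all conditions.
- Null calibration runs 500 studies of 60 random-agent participants and
  requires the rejection rate of |t| > 1.96 to sit in the exact binomial
  95% interval around 0.05. Sixty clusters per study keeps the clustered
  t statistic close to its nominal distribution while the full
  1,500-session design stays desk-scale; `scripts/acceptance.py` uses 300
  replications for the same quantity.

## What the synthetic data does and does not show

The generator reproduces the *design* of the ecology — option
distributions, cue placement, round structure, feedback — and the agents
reproduce choice processes with known closed-form structure. Passing
tests therefore demonstrate that the pipeline estimates what it claims to
estimate on data whose generating process is known (no bugs in
construction, correct regression arithmetic, calibrated inference). They
say nothing about how *humans* behave in this task: human cue learning
has dynamics (learning curves, individual heterogeneity, thresholding vs
matching) that no agent here models, and the real stimulus parameters of
the original task may differ from the configurable defaults. Reanalysis
of archived human data goes through `read_study_data` with a `ColumnMap`
adapted to the deposited file layout.

## Known limitations

- The assigned-predictivity distribution and the payoff/price parameters
  are stand-ins where the task description leaves them open; both are
  configurable and the analysis is invariant to the latter.
- The linear probability model is exactly correct for the affine agents
  but only an approximation for agents whose cue response is nonlinear in
  `h`; the pipeline mirrors the preregistered specification rather than a
  random-effects alternative.
- Sessions are generated trial-by-trial in Python; throughput (~5 ms per
  43-round session) is ample for desk-scale studies but not optimised for
  millions of sessions.
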