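# Methods

This note documents the models implemented in `taskdelay`, the assumptions
behind them, the defaults of the synthetic-data generator, and the design
choices made where more than one reasonable convention exists.

## Subjective valuation

Participants state the quantity of an item they judge equivalent to 1 € and
to 5 € (q1, q5).  The per-unit value is obtained by averaging the two
implied *per-euro quantities* and inverting:

    Q = (q1 + q5/5) / 2,    value per unit = 1/Q  [€]

The statement "average the two ratings" is ambiguous between averaging
per-euro quantities (then inverting) and averaging the per-unit euro values
1/q1 and 5/q5 directly; the two differ by the harmonic/arithmetic ordering
whenever the ratings are mutually inconsistent.  The quantity convention is
the default; the euro convention is available via
`unit_value(..., convention="euros")`.  Option values are linear in
quantity (`V = N · unit_value`); curvature of the utility function is
deliberately not modeled — at stakes of a few euros a linear scaling is an
adequate first-order approximation, and fitting a power exponent would add
flexibility the choice models would have to pay for.

## Discounting and choice

Four model families generate option values at delay D (days):

- hyperbolic, category-specific: `V = A / (1 + k_c · D)` with separate
  rates k_R, k_E, k_P for reward, effort and punishment;
- hyperbolic, shared: one k for all categories;
- present bias: `V = A` if D = 0, else `β·A`;
- quasi-hyperbolic (βδ): `V = A` if D = 0, else `β·δᴰ·A`.

Values map to choice probabilities through the softmax
`P(A) = 1/(1 + exp(−θ·(V_A − V_B)))` with inverse temperature θ (per euro).
For aversive categories the discounted cost enters negated (desirability =
−cost), so one code path serves all categories and reproduces the
empirical preference for *later* efforts when k_E > 0: delaying a cost
shrinks it.  Bernoulli probabilities are clipped at 10⁻¹² so
log-likelihoods stay finite at extreme θ.

Mildly negative discount rates are admitted down to the denominator guard
k > −1/D_max (negative time preference is occasionally observed when
aversive events are tied to fixed dates), but priors and generator defaults
center on positive rates.

### Now/tomorrow model

The net value of performing a rewarded effortful task at delay D ∈ {0, 1}
is `V = N_R·R_i/(1+k_R·D) − N_E·E_j/(1+k_E·D)`; the choice between now and
tomorrow is a softmax over the two net values.  The discount rates and unit
values are *rigidly incorporated* from the intertemporal fits — only θ is
free, so the model can adjust choice stochasticity but never the mean
preference.  The same one-day delay applies to the reward and effort
components (task execution and payoff are nearly simultaneous at this time
scale); separate delays are a straightforward generalization and are not
enabled by default.  One θ is fitted per participant, shared across blocks.

## Bayesian estimation and model comparison

Parameters are estimated by multi-start MAP (L-BFGS-B; default 10 restarts:
the prior mean plus prior draws, deterministic given the seed).  Model
evidence uses the Laplace approximation at the MAP,

    log p(y) ≈ log p(y|x*) + log p(x*) + (p/2)·log 2π − ½·log det H,

with H the Hessian of the negative log joint, computed by central finite
differences with per-coordinate adaptive steps; non-positive-definite
Hessians are jitter-regularized and flagged.  Group-level comparison sums
log evidence over participants; differences are reported as log group
Bayes factors.

Priors: Gaussian N(0, 1) on the hyperbolic rates (native scale, with the
denominator guard as a box bound) and N(1, 1) on θ.  θ is optimized on the
log scale and β, δ on the logit scale to avoid boundary Hessians; the θ
prior is mapped through the transform with its Jacobian, so it remains the
stated native-scale density (the truncation constant P(θ>0) is common to
all families sharing θ and cancels in Bayes factors).  For β and δ, whose
priors are not prescribed anywhere, a standard Gaussian on the logit scale
is used — the analogue of the rate priors after transformation, centered
mid-interval.

Two numerical facts worth recording. First, a parameter that the likelihood
ignores *entirely* integrates out exactly under a proper prior and costs no
evidence; the Occam penalty appears for parameters the data constrain
without improving fit (this is how the model-comparison tests are
constructed).  Second, on 1–2 parameter problems the Laplace evidence
agrees with brute-force numerical integration of the posterior to well
under 0.1 nats at the trial counts used here.

### Fit diagnostics

Balanced accuracy is the mean of per-class accuracies at a 0.5 threshold; a
predicted probability of exactly 0.5 counts as half correct for either
class, which is unbiased under chance.  Calibration curves use 8
equal-count bins of modeled probability (fewer when trials are scarce,
flagged).

## Static and dynamic models of task-completion delay

A task (reward R, effort cost E, deadline D days) completed after a further
delay d has net value

    V_d = R/(1 + k_R·d) − E/(1 + k_E·d),   d = 0..D.

**Static model**: the completion day is chosen once, as the argmax of V_d
(ties break toward the earliest day); a softmax readout over days provides
the probabilistic version.  The argmax readout has a degenerate pmf and is
refused by the likelihood API — observed off-optimum days would have zero
probability — so model comparison always uses the softmax readout.

**Dynamic model**: the decision is revisited every day.  On day d the agent
compares doing the task now (V_0) with doing it on any of the D−d remaining
days, through a softmax over V_0..V_{D−d}; values are re-discounted from
the current day (the value function is time-invariant, only the horizon
shrinks — this is what produces deadline-driven completion).  The hazard at
the deadline is exactly 1, the pmf is `hazard · Π(1−hazard)` over preceding
days, and the predicted procrastination duration is E[τ] = Σ d·P(τ=d).
The deadline effect (earlier deadlines shorten delays) is emergent:
expected delay is nondecreasing in D at fixed parameters.

One decision per day is the default assumption; `decisions_per_day`
subdivides the grid for the reminder-rate generalization (more frequent
consideration of the task shortens expected delay).

### The k_R vs. k_E sign law

When k_R ≥ k_E *and* R ≥ E, the optimal static completion day is 0 for any
deadline: delaying then shrinks the larger, faster-discounting benefit at
least as much as the cost, so V_d − V_0 ≤ 0 everywhere.  The R ≥ E proviso
matters: if the cost dominates (E > R), postponing the task pays
asymptotically (V_d → 0⁻ from V_0 = R − E < 0) even with steeper reward
discounting.  All canonical simulation ranges used here (R ∈ 40–60,
E ∈ 20–40 a.u.) satisfy R > E, where the law holds unconditionally; tests
enforce it on those ranges.

### Value normalization

For *fitting across participants*, net-value curves are rescaled by the
maximum absolute net value over the horizon (`normalization="max_abs"`,
default on `ProcrastinationTask`; z-scoring available behind the flag) so a
single θ is comparable across people with very different value ranges.  The
rescaling leaves the curve's shape and argmax unchanged, and for
single-participant fits with free θ it is absorbed into θ entirely.  For
*simulation*, θ = 0.5 is stated for raw a.u. values, so the simulation
entry points (`simulate_form_delays`, `simulate_duration_grid`) default to
`normalization="none"` — on normalized values θ = 0.5 would make every
completion distribution near-uniform and erase the dependence of duration
on the discount rates that the grid simulations are meant to display.

### Grid simulations

`simulate_duration_grid` evaluates the mean expected delay over a
(k_R, k_E) grid, marginalizing R and E by Monte-Carlo draws from their
ranges.  Defaults reproduce the canonical design — 50×50 rate grid ×
400 (R, E) draws = 10⁶ model evaluations, deadline 30, θ = 0.5, k ranges
0–0.5, R ∈ 40–60, E ∈ 20–40 a.u.  Tests and the acceptance script use
reduced grids; the statistic per cell is an expectation, so grid
resolution trades smoothness, not correctness.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume; its
defaults are the study conditions.

- Cohort: 43 participants, ages 18–40, balanced gender, both independent
  of model parameters by default.
- Discount rates: log-normal across participants (positive,
  right-skewed, as is conventional for rates), medians k_R = 0.05,
  k_E = 0.12, k_P = 0.08 per day with σ_log = 0.5.  The medians encode the
  observed ordering (effort discounted more steeply than reward;
  punishment in between); the empirical distributions are not published,
  so these are field-typical conventions, fixed once.
- Inverse temperature: log-normal, median 1.0 per euro, σ_log = 0.3 — on
  option values of a few euros this yields the mixture of reliable and
  stochastic choices typical of such tasks.
- Intertemporal design: both delays drawn from the ten-delay set
  {0, 1, 2, 3, 5, 7, 10, 14, 21, 30}; 60 trials per category with no item
  repeated within a block; unit values log-normal (median 0.5 €/unit).
  To sample the decision space evenly, target discounted-value differences
  come from a uniform grid over ±2 € under an a-priori rate of 0.1/day and
  are inverted for the later quantity, rounded to a positive integer.
  Because the later option must carry the greater quantity, delay pairs
  are resampled until the gap provides enough discounting room for the
  target (plus a rounding margin); a residual clamp guards the rare
  leftover case.
- Now/tomorrow task: 150 offers per participant; reward values and effort
  costs drawn from a common uniform distribution (2–10 €), realized as
  integer quantities of rated items.
- Form-return delays: drawn from each participant's dynamic completion
  distribution (deadline 30 days, θ = 0.5, compensation 40–60 and form
  cost 20–40 a.u.); static variants available.
- Ratings: per-euro quantities implied by the true unit values with
  multiplicative log-normal jitter (σ = 0.1).

What the generator does **not** emulate: rating-scale truncation and
anchoring, reaction times, sequential effects, attrition
(never-returners), or any correlation between demographics and
parameters (available as knobs, off by default).  Passing tests therefore
demonstrate internal consistency of the estimation chain — that the
implemented models recover what the implemented generator produces — not
that real participants obey these models.

## Regression layer

Per-participant logistic regressions (statsmodels ML fit, with a small-L2
fallback under separation, flagged) quantify choice factors: value/cost and
delay differences for intertemporal choices; reward value, effort cost or
net value for now/tomorrow choices.  Factors are z-scored within
participant so coefficients are comparable across value scales; group-level
inference is a one-sample t test per coefficient.

Cross-participant OLS regresses procrastination (tomorrow-choice frequency,
or form-return delay with never-returners excluded) on discount rates —
log-transformed by default, given their right skew, with the raw scale
behind a flag — plus centered age and a binary gender indicator, all
z-scored, so coefficients are standardized effect sizes.  Pearson
correlations between alternative procrastination measures support one- or
two-tailed p values; one-tailed is appropriate only when the two measures
target the same construct and could only agree in one direction.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 8–50 participants with 60–120
trials per category, 10–20 replications for recovery claims, and 10⁵
Monte-Carlo agents when validating E[τ] against simulation; these sizes
give recovery correlations ≥ 0.9 and stable model-selection outcomes while
keeping a full run in minutes.  Optimization restarts default to 10 (3–5 in
the replication loops).  Argmax ties break early; probabilities are clipped
at 10⁻¹²; the completion cdf/pmf are pinned to their exact boundary values
(the deadline hazard is 1 by construction, not by rounding).

## Known limitations

- No hierarchical pooling across participants (each fit is independent);
  no MCMC — evidence rests on the Laplace approximation, which is accurate
  at these trial counts but untested here for multimodal posteriors beyond
  the multi-start guard.
- The dynamic model assumes a constant, known decision rate; forgetting
  and reminders enter only through the `decisions_per_day` knob.
- Continuous-time hazards, anticipation/dread utilities and
  reaction-time models are out of scope.
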