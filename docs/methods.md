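# Methods

This note documents the models behind each engine and estimator, the
defaults and why they were chosen, what the synthetic responders do and do
not emulate, and the numerical details that matter for reproducing results.

## Task engines

All engines are pure state machines: given a config and a seed they produce
identical session logs byte for byte. Reaction times and point values are
integers (milliseconds, points); all randomness flows through a single
`numpy` generator per session.

### Balloon risk (precommitment)

The responder commits a pump count at balloon onset; the balloon bursts when
the committed count reaches the trial's predetermined threshold and that
balloon's earnings are forfeited, otherwise it banks pumps × reward-per-pump.
The 30 test-trial burst thresholds are a frozen pseudorandom sequence of 15
symmetric pairs around 64 within [1, 128], so the design mean of 64 is exact
rather than statistical; `seeded_random` mode permutes the same multiset
under the session seed. For non-default trial counts or means an analogous
symmetric-pair construction preserves the exact mean. Practice thresholds
are seeded uniform draws and never enter scoring. Reward per pump defaults
to 1 currency unit (the currency scale is arbitrary; only relative money
matters downstream).

### Stop signal

Go trials are a two-choice reaction with points
`round(25 · (1 − rt/deadline))` clamped to [0, 25]; the deadline defaults to
2000 ms, beyond which a response is recorded as an omission. A stop signal
follows the go stimulus on 30% of trials after the current stop-signal delay
(SSD); the staircase is one-up/one-down in 50-ms steps with a floor at 0 ms,
so a stationary responder is driven to ~50% successful stopping. The
staircase starts at 200 ms and persists from practice into test (resetting
it would discard the calibration the practice block just performed). Stop
trials award no points — the point incentive exists to speed go responses.
The practice gate requires 70% correct go responses, with at most 3 repeats
before a gate error.

A bookkeeping identity worth knowing: over a session,
(#successful − #failed) stops = (final SSD − initial SSD)/step, so the
long-run success proportion is pinned to 0.5 + O(1/n) with very little
dispersion — much less than binomial — which is why the staircase
equilibrium check is so stable across seeds.

### Experiential delay discounting

Each trial offers a smaller sum of coins near the avatar against a larger
sum farther away; delays are experienced, derived as distance/travel-speed,
so the discount rate is per second and **not numerically comparable** to
questionnaire-based day-scale rates — cross-version comparisons should be
rank-based. Default generation draws smaller-sooner delays from 1–10 s and
larger-later delays up to 60 s with amount ratios up to ~10, which spans
indifference points for k roughly in [0.002, 3]/s. The default time budget
(3600 s) does not bind — the grid geometry and budget of the original game
are not part of the scored design — but budget exhaustion is implemented and
ends the session early when configured.

### Attentional capture with reversal

Each 24-trial block contains 20 distractor trials split 10/10 between the
two colours and 4 distractor-absent trials. During training one colour
(pink by default) signals 100 points and the other 10; the reversal phase
(blocks 5–6) swaps the contingency while records keep the physical colour,
so reversal scoring can reference "previously high". Correct responses
within 0–1000 ms earn `round(magnitude · (1 − rt/1000))` points — the
proportional-reward reading, which preserves the full magnitude at rt → 0;
responses at 1000–2000 ms or wrong earn nothing. Distractor-absent trials
carry the low magnitude.

### Two-step task

Four first-stage options (two teams of two) map deterministically onto two
terminal states; within each team the two options cover both states, so
model-based knowledge generalises across teams while model-free credit does
not. Terminal-state values drift as independent Gaussian random walks with
step SD 2 on [0, 9], reflecting at the boundaries (the standard settings for
the deterministic-transition variant); both walks advance every trial and
rewards are the current walk value rounded to an integer. Team presentation
is balanced (62/63 in 125 trials) in seeded random order.

## Synthetic responders

Each responder's parameters live in the same semantic space as the scored
metric, which is what makes parameter recovery a meaningful validation:

- **Balloon**: pumps ~ round(N(mean, sd)) clamped to [0, 128]; scored mean
  pumps recovers the generative mean.
- **Stop signal**: an independent horse race — go latencies are lognormal
  (default median 600 ms, log-SD 0.2, i.e. ~20% coefficient of variation,
  typical of choice RT), and a stop trial is failed iff the sampled go
  latency beats SSD + true SSRT. Go omission, choice error and
  trigger-failure rates exist but default to 0 (the scoring methods do not
  model trigger failures). The integration-method SSRT recovers the
  generative stop latency nearly unbiasedly; the mean method additionally
  carries the mean−median gap of the lognormal (~12 ms at the defaults),
  a known property of that estimator, not a bug.
- **Discounter**: values options by V = A/(1+kD) and chooses larger-later
  with probability σ(temperature · (V_LL − V_SS)); infinite temperature
  gives the deterministic argmax chooser.
- **Capture**: lognormal base RT plus `capture_effect` ms on currently
  high-value-distractor trials, plus `perseveration_effect` ms on
  previously-high-colour trials during reversal; errors flip the response
  side. The additive effect shifts the training score by exactly its value
  in expectation.
- **Hybrid learner**: exactly the choice model the fitter assumes (see
  below), so the fitter is consistent by construction — recovery failures
  would indicate optimisation or bookkeeping defects, which is the point of
  the check.

What the generators do **not** emulate: RT autocorrelation, fatigue and
learning drifts, strategic slowing ("waiting for the stop signal"),
trial-history effects, or any questionnaire-style self-report. Passing
recovery tests therefore demonstrates the correctness of the scoring
pipeline under the stated generative assumptions, not robustness to the
richer structure of human data.

Cohort simulation draws each participant's parameters once (traits) and
reuses the same engine seed across occasions, so with zero occasion noise a
retest replays identically and all occasion-level variability is explicit
via the `occasion_noise` argument. With two version tags, presentation
order alternates across participants (counterbalancing).

## Estimators

### SSRT

Go RT is the mean of correct responded go trials. The integration method
replaces go omissions with the maximum observed go RT, sorts all go RTs, and
takes the RT at rank ⌈p·n_go⌉ where p is the stop-failure rate; SSRT is that
quantile minus the mean SSD. Stop-failure rates of exactly 0 or 1 leave the
quantile meaningless, so the estimate is returned with an `unreliable` flag
and a warning rather than an error. Both estimators are exactly equivariant
to a constant shift of the go-RT distribution.

### Hyperbolic k

Because experiential choices are stochastic, indifference-point algebra is
ill-posed; k is instead estimated jointly with a choice temperature by
Bernoulli maximum likelihood. The likelihood is evaluated on a log₁₀ grid
(k ∈ [10⁻⁴, 10] with k_max = 10/s, τ ∈ [10⁻², 10²]) and the best grid point
is polished with L-BFGS-B on the log scale. One-sided choice sets
(all-sooner or all-later) contain no interior information and return the
corresponding boundary (k_max or 0) with a `boundary` flag instead of a
spurious interior estimate. Observed-information standard errors are
reported on the log₁₀ scale.

### Hybrid RL fit

Teacher-forced likelihood: value updates follow the *recorded* choices and
rewards with candidate rate α, values start at the reward-walk midpoint
(4.5 points), and the likelihood accumulates only over non-practice trials
(practice still warms the learning state). Optimisation is L-BFGS-B with
bounds w ∈ [0,1], β ∈ [0,20], α ∈ [0,1], multi-started from a seeded
Latin-hypercube design (10 restarts by default); the best restart is
returned with convergence metadata, and a brute-force parameter grid is used
in the tests to confirm the returned optimum is global to 1e-6 nats. When
β̂ ≤ 0.1 the softmax is essentially flat and w is flagged unidentifiable.
With 200-trial sessions at β = 3, α = 0.5, the mean recovered w over 20
agents sits within ~0.05 of the generative value at both extremes.

## Quality control

All rule inequalities are strict as printed, so boundary performances
(go accuracy exactly 0.90, inhibition exactly 0.25 or 0.75, accuracy exactly
at chance 0.5) pass. Chance for the capture task is 0.5 (binary left/right
response). The timing rule fails sessions whose total active time is below a
quarter of the task's nominal duration (5/12/6/12/25 minutes for the five
tasks); logs without per-trial timing (balloon, two-step) are flagged
indeterminate rather than failed. QC is pure and idempotent, and every
exclusion carries a machine-readable rule id.

## Psychometrics

The two-condition within-subject ANOVA is computed from the paired
differences (F = t², p from F(1, n−1)); zero difference variance with a
nonzero mean is reported as a degenerate infinite F rather than an error.
The normality gate for convergent correlations is Shapiro–Wilk at α = 0.05
on both variables, either failure selecting Kendall's τ. The ICC is the
single-rater absolute-agreement form computed directly from the two-way
ANOVA decomposition, with its p-value from F = MSR/MSE; zero between-subject
variance leaves it undefined and flagged. Band edges are inclusive at the
lower end. No multiple-testing correction is applied; the validation report
instead counts the tests it ran.

## Problem sizes and determinism

The validation harness uses desk-scale cohorts chosen to make Monte-Carlo
error small relative to each tolerance: 10,000 stop trials for the
staircase equilibrium (the bookkeeping identity above makes this extremely
precise), 50 sessions for SSRT and discount-rate recovery, 100 sessions for
the capture effect, and 20 agents × 200 trials per mixing-weight level for
the RL fit. Every simulation consumes an explicit integer seed;
sub-simulations derive independent child seeds via `numpy.random.SeedSequence`.

## Known limitations

- The discount-rate scale is per second and task-specific; only ranks
  transfer across versions.
- The hybrid fitter assumes the three-parameter (w, β, α) model with no
  perseveration or eligibility-trace terms; sessions generated by richer
  strategies will load those effects onto the fitted parameters.
- Standard errors come from the observed information at the MLE and are
  unreliable when the estimate sits on a bound (common for w near 0 or 1).
- The "standard" (non-gamified) versions of the paradigms are represented
  semantically through the shared session schema and version tags, not as
  separate engines; questionnaire-based instruments are out of scope.
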