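# Methods

This note documents the models, the synthetic-data generator, the estimation
machinery, and the numerical and design choices behind `pemem`.

## Task structure

Both experimental designs present six scene contexts, each probabilistically
predictive of an object category, over a feedback **learning phase** followed
by an **encoding phase** of trial-unique objects and a surprise old/new
**recognition test**.

* **Experiment 1** (3 categories): three 0.80–0.10–0.10 contexts and three
  uniform (1/3) contexts.  Encoding: per strong context, 24 unique objects
  (8 per category) plus 8 dominant-category fillers shown 7 times each
  (64/8/8 = 0.80/0.10/0.10 over 80 trials); uniform contexts contribute 24
  uniques each.  Totals: 312 encoding trials, 144 uniques.  Recognition: all
  144 old items plus 144 new distractors; the immediate test scores a seeded
  random half (72) of the old items (the other half is reserved for a
  delayed test that this package does not model).
* **Experiment 2** (2 categories): two contexts each of 0.90–0.10 (20
  uniques + 5 fillers × 16), 0.70–0.30 (20 uniques + 5 fillers × 3) and
  0.50–0.50 (10 uniques + 10 fillers × 2).  Totals: 330 trials
  (200/70/60 by condition), 100 uniques; recognition tests all 100 old items
  plus 80 new distractors.

Integer category counts use largest-remainder rounding.  The 0.70–0.30
condition cannot be realized exactly over 35 trials per context
(0.7 × 35 = 24.5); the schedule realizes 25/10 (71.4%/28.6%) and
`realized_proportions` exposes the empirical frequencies.  Context → dominant
category assignment is a Latin-square rotation over participants (a full
cycle of J participants pairs every category with every context condition
equally often).  Trial order is a uniform seeded permutation within each
phase; no run-length constraints are imposed.  The learning phase defaults
to 40 trials per context (configurable; the underlying experiments do not
pin this number in a way the generator can assert).

## Learning models

All four models maintain a category × context matrix of expected values
initialized at 1/J, with a per-context trial counter *t* that pools learning
and encoding phases (one continuing Q table, advanced before each update).
The prediction error is δ = r − Q with r the one-hot vector of the presented
category.

* **dLRI** — instructive, learning rate 1/t.  Exactly equivalent to the
  running mean of the presentation vectors (the prior is overwritten on the
  first trial of each context), which is the delta-rule form of the optimal
  Dirichlet–multinomial learner; this equivalence is enforced by a property
  test.  One free parameter (β).
* **dfLRI** — instructive, learning rate α/t.  Reduces to dLRI at α = 1.
* **fLRI** — instructive, constant learning rate α.
* **fLRE** — evaluative: only the chosen category's value is updated, with
  reward 1 for a correct and 0 for an incorrect prediction.  The update
  condition is read as selecting *which* entry updates, so values decrease
  after incorrect choices; a literal no-update-when-wrong reading would
  contradict the models' intended increase/decrease behaviour.

Choice probabilities are a softmax over the context's Q row with inverse
temperature β ≥ 0, computed with a max-shift guard (hence invariant to
adding a constant to Q) and exactly uniform at β = 0.  Q values stay in
[0, 1] for any admissible α and input sequence.

## Estimation and model comparison

Per subject, the negative log-likelihood of the observed category choices
(learning + encoding pooled, fillers included — they are modelled trials) is
minimized with L-BFGS-B under bounds α ∈ [0, 1], β ∈ [0, 10], taking the
best of 5 restarts started from the priors α ~ U(0, 1) and β ~ Exp(1)
truncated at the β bound (out-of-bound draws are resampled).  Choice
probabilities are floored at 1e−12 inside the log so the objective stays
finite.  BIC uses the natural log and T = number of modelled choice trials.
Evidence for the per-subject winning model is graded from the BIC gap to the
runner-up: [0, 2) weak, [2, 6) positive, [6, 10) strong, ≥ 10 very strong
(boundaries go to the higher band).  Ties are broken toward fewer
parameters, then by the fixed order dLRI, dfLRI, fLRI, fLRE.

**Recovery diagnostics.**  Parameter recovery simulates agents with
prior-sampled parameters on the learnable conditions only (0.80–0.20 in
Experiment 1; 0.90–0.10 and 0.70–0.30 in Experiment 2), refits, and reports
true/fitted correlations.  Model recovery simulates each model, fits all
four, and tallies the BIC winner into a confusion matrix.

A caveat that matters when interpreting these diagnostics: under the
Exp(1) prior, many simulated agents have β below ~0.5 and choose almost
uniformly.  For such agents α is barely identifiable, and when the fitted α
reaches 0 the likelihood is exactly flat in β, so bounded MLE can return
arbitrary β values.  Pearson true/fitted correlations are therefore
attenuated by a minority of heavy-tailed errors even though rank agreement
is high, and the confusion matrix drifts toward the one-parameter dLRI
(which dfLRI, nested in dLRI at α = 1, can essentially never beat by more
than the BIC penalty ln T).  These are properties of the simulation prior
and the comparison rule, not of the optimizer: audits show the fitted
likelihood matching or beating the likelihood at the generating parameters.
The recovery functions report what the procedure yields; they do not
restrict the prior to well-identified regions.

## Recognition memory analysis

Recognition responses are scored per subject into hits/misses/false
alarms/correct rejections; d′ = z(HR) − z(FAR) with the log-linear
correction (0.5 added to every cell) so extreme rates stay finite.
At-chance responders are excluded by a per-subject permutation test: the
response vector is permuted against the old/new labels (default 5000
permutations) and the subject is kept iff the observed d′ reaches the 95th
percentile of their own null distribution.  A degenerate null (e.g. a
constant responder, for whom every permutation gives the same d′) is never
included.  Because d′ is discrete, the realized false-inclusion rate for
true null responders sits slightly above the nominal 5% (ties at the
percentile count as inclusion); the calibration is checked by simulation.

The analysis table has one row per non-filler old item of the immediate
test, joining the item's encoding-phase unsigned PE (1 − Q of the presented
category, from replaying the subject's choices under their best-fitting fLRI
parameters) and prediction outcome (±0.5) with the later hit/miss.  Fillers
never enter; learning rate and experiment (±0.5) attach as subject-level
covariates and are permitted only as fixed effects — requesting a random
slope for a between-subject covariate is rejected.

The mixed logistic model (`basic`) is
`hit ~ pe * po + (1 + pe * po | subject)` with unstructured random-effect
covariance; `full` additionally crosses the fixed part with learning rate
and experiment (up to the four-way interaction).  Estimation is delegated to
an R engine over `Rscript` — `glmmTMB` by default, `lme4` as an independent
cross-check (both maximize the Laplace-approximated marginal likelihood and
agree to ~3 decimals on the fixed effects; glmmTMB is several times faster,
which matters for replicate studies, and jobs are batched into a single R
session to amortize startup).  The model specification, coding and contracts
live in this package; R returns estimates, standard errors and variance
components.  Inference is Wald throughout: z = estimate/SE, chi-square = z²
with 1 df, normal 95% CIs, OR = exp(estimate).  When generative
random-effect SDs are near zero (the defaults below include an SD of 0.03),
fits are frequently singular; estimates and Wald CIs remain well behaved and
the `converged` flag records the engine's strict convergence status.

Follow-ups: simple PE slopes refit `hit ~ pe + (1 + pe | subject)` within
each prediction outcome (under ±0.5 coding the implied slopes are
β₁ ± β₃/2); the binned analysis forms within-subject PE quartiles
(rank-based, bin sizes differing by at most one; subjects with fewer than 4
distinct PE values are dropped with a warning), aggregates hit rate per
subject × bin × outcome, fits a Gaussian mixed model with bin as a
four-level factor, and Bonferroni-corrects the three against-first-quartile
contrasts (p·k capped at 1); the signed-PE variant swaps in r − Q[chosen].

## Synthetic-data generator

`make_synthetic_study` chains: counterbalanced schedules → softmax RL agents
(per-subject α ~ U(0, 1), β ~ Exp(1) truncated at 10, fLRI by default) →
trial-level PE from the generating parameters → recognition outcomes from
the logistic memory model with subject random effects (independent normal
by default) → distractor responses at a constant false-alarm rate.  One
master seed; per-subject streams are derived as `default_rng([seed,
subject])`, so adding subjects never perturbs existing ones.

Generative defaults are the fitted values this paradigm typically produces:
fixed effects (0.66, −0.12, 0.10, 1.87) for intercept/PE/PO/PE·PO in
log-odds, random-effect SDs (0.55, 0.17, 0.03, 0.18), and a false-alarm
rate of 0.30 — together implying d′ ≈ 0.93, in the range of real
performance on this task.  `simulate_memory_table` is a lighter generator
(PE ~ U(0, 1), PO ± 0.5 equiprobable) for coverage and calibration studies
of the mixed model alone.

What the generator does *not* emulate: response times, trial-order or
run-length constraints, session breaks, the delayed recognition session,
arousal/valence effects of feedback, and any item- or category-level memory
heterogeneity (random effects are subject-level only).  Passing tests on
synthetic data therefore validate the machinery and its statistical
calibration, not claims about real participants.

## Problem sizes and determinism

Simulation-based checks in the test suite run at desk scale: 50 agents for
parameter recovery, 25 repetitions per model for the confusion matrix, 60
subjects for the end-to-end memory-pipeline check, 50 replicates of
60 × 150 items for CI coverage of the memory model, and 500 null subjects ×
1000 permutations for exclusion calibration.  Every stochastic component
takes an explicit seed and all generators are reproducible byte-for-byte
from it.

## Known limitations

* The signed-PE definition (r − Q of the chosen category) is one reasonable
  convention; others (e.g. signed PE of the presented category) exist.
* The permutation null is per-subject; pooling permutations across subjects
  would give a common threshold instead.
* No hierarchical (empirical-Bayes) parameter estimation; subjects are fit
  independently.
* The evidence grading applies fixed BIC-gap bands; no random-effects
  Bayesian model selection.
* Binned-PE contrasts are limited to quartiles against the first quartile;
  arbitrary contrast matrices are out of scope.
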