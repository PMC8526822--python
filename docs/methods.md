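# Methods

`srtlearn` reimplements, end to end, the analysis of a probabilistic serial
reaction time (SRT) experiment comparing motor sequence learning in autistic
and non-autistic adults, together with a generative participant model that
lets every stage be exercised and calibrated without access to the original
raw data.

## Task model

Four imperative stimuli map to four keys. Stimulus order is a first-order
Markov chain over ids 1–4 whose transition matrix depends on the block
condition:

* **unpredictable** — all 16 transitions have probability 0.25;
* **easy-predictable** — the cycle 1→2→3→4 occurs with probability
  `p_high`; each of the three violating transitions has `(1 − p_high)/3`;
* **difficult-predictable** — identical structure on the cycle 1→4→2→3.

A session is 7 blocks × 100 trials (block order shared by all participants
of a run); consecutive blocks chain their initial stimulus. Trials whose
generative transition probability falls below a threshold are labelled
*surprising*; trials at or above it *unsurprising*. Unpredictable-block
trials and each block's first trial carry no label.

**Parameter choices.** The original study reports the matrix structure and
the 0.75 surprising/unsurprising classification boundary but not the matrix
values or the block order. We default to `p_high = 0.85` (violations 0.05
each), which is consistent with the 0.75 boundary and with the
action-reprogramming task family this design descends from, and to the
block order `[unpredictable, easy, difficult, easy, difficult, easy,
unpredictable]`, which brackets the predictable blocks with baselines. Both
are configuration, and every analysis is order-agnostic. The published
description of the classification inequality is inverted relative to its
own task description (it would label the *high*-probability transitions
surprising); we implement surprising = improbable (`gen_prob <
threshold`), which matches the stated low rate of sequence violations.

## Ideal-observer surprise

The observer maintains counts of ordered stimulus pairs (j, i) — stimulus j
at trial t−1 followed by i at t — with additive smoothing `alpha` per cell.
The surprise of trial t is the negative log of the pair's predicted joint
probability estimated strictly causally:

    p(j, i) = (count(j, i) + alpha) / (n_pairs + 16 alpha)
    surprise_t = −ln p(j_t, i_t)   [nats]

Defaults: `alpha = 1` (uniform prior over the 16 pairs, keeps first
occurrences finite), natural log (regression on z-scored predictors is
base-invariant), and counts accumulated **per condition** — persisting
across same-condition blocks, reset between conditions, never spanning a
block boundary when forming pairs. Per-block and per-session scopes, and a
conditional variant p(i | j), are available for sensitivity analysis. The
joint (not conditional) form is the default because the original analysis
defines surprise on the pair's joint probability.

The production implementation is vectorised (per-pair cumulative occurrence
counts); the test suite checks it for exact agreement against an
independent online dict-counting observer.

## Generative participant model

Each synthetic participant runs the same pair-counting learner but utilises
it only partially. With prior-utilization weight `w ∈ [0, 1]`, the learned
conditional prediction is mixed toward uniform,

    p_eff(i | j) = w p̂(i | j) + (1 − w)/4,

and mapped to the joint scale by the learned predecessor marginal, so `w=1`
reproduces the analysis observer's joint surprise exactly and `w=0` yields
predictions with no sequence information (the attenuated-priors limit).
Behaviour is then

    RT_t = mu + beta_s · s_t + difficult_cost · [difficult] + N(0, sigma),
    floored at 150 ms;       P(error_t) = logistic(err0 + err1 · s_t),

with errors drawn uniformly over the three wrong keys. Trials without a
defined pair (block firsts) receive the fresh-observer surprise ln 16.

Cohort defaults emulate the study conditions: 28 ASD / 35 control
participants; `mu ~ N(650, 50²)` ms, `beta_s ~ N(30, 8²)` ms/nat (clipped
at 0), `sigma = 60` ms, `err0 = −3.5`, `err1 = 0.2` nat⁻¹ (error rates
≈ 5%, so IES ≈ RT/0.95, the regime the study reports). Two scenarios fix
`w` per group: **null** (both 0.9 — the outcome the study observed) and
**bayesian-accounts** (control 0.9, ASD 0.3 — the attenuated-priors
hypothesis it tested).

Two parameters encode condition difficulty: `w_difficult_scale = 0.15`
multiplies `w` in the difficult condition, and `difficult_cost = 20` ms adds
a baseline cost there. Without them an ideal learner masters the 1–4–2–3
cycle as easily as 1–2–3–4, whereas the empirical pattern is near-zero
learning of the difficult sequence and difficult RT/IES *above* the
unpredictable baseline; these two knobs reproduce that observed ordering
(easy < unpredictable < difficult) and near-zero difficult-condition
slowing. A log-normal RT-noise option exists; Gaussian with a floor is the
default because it keeps moments simple for closed-form checks.

Randomness descends from one master seed through named substreams
(cohort parameters; per-participant sequence and behavioural noise), so any
participant is reproducible in isolation.

**What the generator does not emulate:** training-phase learning of
stimulus–key mappings, fatigue/practice drifts in baseline RT, ex-Gaussian
RT skew, and any meta-learning of environmental volatility (the task
contains only probabilistic uncertainty). Passing tests therefore validate
the *pipeline's* correctness and operating characteristics under a
plausible data-generating process, not the empirical claims themselves.

## Outcome measures

Correct responses only. Per participant: condition-mean RT; proportion
correct; inverse efficiency score IES = mean correct RT / proportion
correct (the standard speed–accuracy correction; the original study's
verbal definition would give RT/error-rate, contradicting its own reported
IES ≈ RT/0.95 magnitudes, so we follow the numbers); sequence-learning index
RT(unpredictable) − RT(predictable condition); surprise-slowing index
RT(surprising) − RT(unsurprising) within each predictable condition.
Baseline correction subtracts the participant's unpredictable-condition
mean from all RT cells; difference indices are invariant to it. No outlier
trimming by default (the original study reports none); a configurable trim
exists.

## Inferential battery

* **Mixed RM-ANOVA** (one between factor, one or two within factors):
  orthonormal-contrast stratum decomposition. Each within effect is
  projected onto per-subject contrast scores; within a stratum the design
  is a one-way group layout with its own error term (effect × subject
  within groups). Unweighted group means give Type III tests of within
  effects under unequal group sizes (matching JASP-style output); the
  between factor is tested against subjects-within-groups. η² is
  SS_effect/SS_total over all strata (the convention that makes large F
  coexist with small η² in this design); partial η² uses the stratum error.
  No sphericity correction by default (the original study reports uncorrected df);
  Greenhouse–Geisser is available behind a flag.
* **Post-hocs:** all pairwise paired t-tests, p multiplied by the number of
  comparisons (capped at 1), paired Cohen's d = mean diff / SD diff.
* **Independent t:** pooled-variance Student t by default (this is the
  variant that reproduces the published demographic comparisons); Welch
  available. The published age comparison (1.496) reproduces under neither
  variant from the printed summaries (we obtain ≈ 0.84) and is reported as
  computed, not forced.
* **χ²:** Pearson 2×2 without continuity correction.
* **JZS Bayes factor t-test:** BF₁₀ = ∫ f_nct(t; ν, δ√n_eff) dCauchy(δ; 0, r)
  / f_t(t; ν), with `r = 0.707` (the common default, unstated by the
  source). Numerics: vectorised composite Simpson over a window covering
  the likelihood peak and prior bulk, grid-doubling until successive
  estimates agree to 1e−7 relative; non-convergence raises with
  diagnostics. Validated against a dense-grid oracle (≤1e−4 relative
  error required; achieved ~1e−9) and cross-checked against an independent
  implementation.
* **Inclusion Bayes factors:** BIC approximation over the
  marginality-closed fixed-effect model space, each model a random-intercept
  mixed model fitted by profiled ML (closed-form GLS given the variance
  ratio, bounded 1-D search), uniform model prior, matched-model inclusion
  odds. Exact replication of JASP's mixed-model inclusion numbers is out of
  scope; sign/threshold behaviour is what is validated.
* **Sequential BF:** the group comparison's BF₀₁ recomputed at each accrual
  step; reports the first n reaching the threshold (default 3) and whether
  it stays there. Degenerate-variance steps are skipped.
* **Correlation:** Pearson r with the equivalent simple-regression
  F = r²(n−2)/(1−r²), df (1, n−2).

## Trialwise regression

Per participant, OLS of RT (ms) on z-scored trial position, the condition
contrast (easy = −0.5, difficult = +0.5), z-scored surprise, and all
products of the centred components; correct predictable-condition trials
with defined surprise only. Betas are "ms per SD of predictor" — the
convention that matches the magnitude of the published coefficient table
(e.g., condition ≈ 19 ms, although "standardised β" is not further defined
there); fully standardized betas are a flag away. The two predictable
conditions are fitted jointly with the condition contrast, reconciling the
per-condition description with the published table's condition and
condition-interaction terms (the strict per-condition variant is obtainable
by filtering the input). Group level: one-sample t per predictor across all
participants; between-group t plus JZS BF for predictors that reliably
differ from zero.

## Calibration studies (src/srtlearn/validation.py)

Problem sizes were chosen to keep each study to a few minutes:

* **Null slowing:** 100 independent `w = 0` participants (700 trials each);
  the 95% CI of the mean easy-condition slowing must span 0.
* **Recovery:** 50 participants with `w = 1`, `beta_s = 30` ms/nat,
  `sigma = 60`; the regression's surprise coefficient, converted back to
  ms/nat, must average within ±20% of 30.
* **Scenario contrast:** 100 replicate cohorts per scenario at n = 28/35.
  Under attenuated priors, the surprise × group interaction must be
  significant with slowing-index BF₁₀ > 3 in ≥80% of replicates; under the
  null scenario BF₀₁ > 1 in a majority.

## Known limitations

* Inclusion BFs are BIC approximations; they agree with full Bayesian
  mixed-model machinery in order of magnitude and sign, not digit-for-digit.
* The simulator's Gaussian RT noise understates empirical RT skew; the
  log-normal option narrows but does not close this gap.
* `effective_prediction` at `w = 0` leaves a residual dependence on the
  learned predecessor *marginal* (not the transition), so single-trial
  surprise is not exactly constant early in a block; its expectation across
  surprise labels is still equal, which is what the null calibration tests.
* Reproduction of the original headline statistics on the deposited
  dataset requires downloading it and running `analyze_external`; it is not
  part of the self-contained build.
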