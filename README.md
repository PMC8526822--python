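# srtlearn

Analysis pipeline for probabilistic serial reaction time (SRT) experiments
that test Bayesian (attenuated-priors) accounts of autism in the motor
domain: first-order Markov stimulus-sequence generation, ideal-observer
trial-by-trial surprise, RT/IES outcome metrics, a frequentist + Bayesian
inferential battery, and a generative synthetic-participant model whose
prior-utilization parameter instantiates the hypothesis under test.

Intended for researchers who want to re-run, audit or power such an
analysis — on their own trial-level data or on simulated cohorts.

## The model in brief

Stimuli 1–4 follow a first-order Markov chain: uniform in *unpredictable*
blocks; in *predictable* blocks a 4-cycle (easy 1–2–3–4, difficult 1–4–2–3)
occurs with probability p_high = 0.85 and violations ("surprising" trials,
generative probability < 0.75) share the rest. An ideal observer assigns
each trial the surprise

  s_t = −ln p̂(j, i),  p̂(j, i) = (count(j,i) + α) / (n_pairs + 16α),

with counts accumulated causally per condition (α = 1). Outcomes per
participant: sequence learning = RT(unpredictable) − RT(predictable);
surprise slowing = RT(surprising) − RT(unsurprising); IES = mean correct
RT / accuracy. Inference: mixed repeated-measures ANOVAs (Type III, η² and
partial η²), Bonferroni post-hocs, pooled/Welch t, 2×2 χ², JZS
Bayes-factor t-tests (Cauchy r = 0.707), BIC inclusion Bayes factors,
sequential BF monitoring, and per-participant trialwise regression of RT on
time, condition, surprise and their interactions.

Synthetic participants run the same learner but mix its prediction toward
uniform by prior utilization w, with RT = mu + beta_s·s + noise and
surprise-dependent errors; w equal across groups is the "null" scenario,
lower w in the ASD group the "bayesian-accounts" scenario.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
simulated cohorts and write their tables to `results/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_surprise_traces.py
python analysis/03_outcome_metrics.py
python analysis/04_group_inference.py
python analysis/05_trialwise_regression.py
python analysis/06_operating_characteristics.py
```

`03_outcome_metrics.py` prints the group-mean outcome pattern, e.g.

```
== bayesian-accounts (group means, ms) ==
         rt_unpredictable  rt_easy  rt_difficult  seqlearn_easy  slowing_easy
ASD                 737.5    728.1         754.4            9.4          18.9
control             741.2    717.9         755.8           23.3          63.6
```

— under attenuated priors the ASD group learns the sequence less (9 vs
23 ms speeding) and slows less on surprising trials (19 vs 64 ms), while
both groups share the easy < unpredictable < difficult RT ordering.
`04_group_inference.py` then shows what the battery concludes: for the
equal-priors cohort the surprise × group interaction is null
(F(1,61) = 0.57, p = 0.45) and the slowing-index Bayes factor leans to the
null, while for the attenuated-priors cohort the interaction is decisive
(F(1,61) = 62.9, p < 0.001; BF₁₀ ≈ 4×10¹¹). `06_operating_characteristics.py`
summarises calibration: w = 0 agents show 1.5 ± 2.6 ms slowing (null
behaviour), an injected surprise sensitivity of 30 ms/nat is recovered at
30.6 ms/nat, and the scenario contrast is detected in 100% of replicates.

Library use mirrors the scripts:

```python
from srtlearn import simulate, surprise, metrics
trials = simulate.simulate_cohort("null", seed=1)
trials = surprise.add_surprise_column(trials)
summary = metrics.summarize_participants(trials)
```

External trial tables with the documented CSV schema (participant, group,
block, condition, trial, stimulus, response, correct, rt_ms, gen_prob,
surprise_label) run through `srtlearn.pipeline.analyze_external`, with a
column-mapping option for foreign headers.

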