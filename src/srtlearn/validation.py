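"""Simulation studies validating the pipeline's operating characteristics.

These are the package's own calibration experiments: null behaviour of the
surprise-slowing index when priors are ignored, recovery of the injected
surprise sensitivity by the trialwise regression, and the ability of the
inferential battery to separate the attenuated-priors scenario from the
equal-priors (null) scenario at the study's group sizes.
"""

from __future__ import annotations

import numpy as np

from . import inferential, metrics, sequences, simulate, surprise, trialwise


def null_slowing_study(seed: int, n_seeds: int = 100) -> dict:
    """Easy-condition surprise slowing of w=0 participants across seeds.

    With zero prior utilization the agent's predictions carry no sequence
    information, so the expected slowing index is zero; returns the mean
    index and its 95% confidence half-width over ``n_seeds`` independent
    participants.
    """
    root = np.random.SeedSequence(seed)
    vals = []
    for child in root.spawn(n_seeds):
        seq_ss, noise_ss = child.spawn(2)
        p = simulate.ParticipantParams(id="p", group="control", w=0.0)
        sess = sequences.build_session(seed=np.random.default_rng(seq_ss))
        out = simulate.simulate_participant(p, sess, rng=np.random.default_rng(noise_ss))
        vals.append(metrics.summarize_participant(out)["slowing_easy"])
    vals = np.asarray(vals, dtype=float)
    mean = float(np.nanmean(vals))
    half = float(1.96 * np.nanstd(vals, ddof=1) / np.sqrt(np.isfinite(vals).sum()))
    return {"mean_ms": mean, "ci_halfwidth_ms": half, "n_seeds": n_seeds,
            "ci_contains_zero": abs(mean) <= half}


def beta_recovery_study(seed: int, n_seeds: int = 50, beta_s: float = 30.0) -> dict:
    """Recovery of the injected surprise sensitivity (ms/nat) by regression.

    Simulates single participants with full prior utilization (w = 1, so the
    agent's surprise equals the analysis observer's trace), fits the
    trialwise regression, and converts the standardized surprise beta back
    to ms per nat.  Returns the across-seed mean recovered value.
    """
    root = np.random.SeedSequence(seed)
    recovered = []
    for child in root.spawn(n_seeds):
        seq_ss, noise_ss = child.spawn(2)
        p = simulate.ParticipantParams(
            id="p", group="control", w=1.0, beta_s=beta_s, sigma=60.0,
            w_difficult_scale=1.0, difficult_cost=0.0)
        sess = sequences.build_session(seed=np.random.default_rng(seq_ss))
        out = simulate.simulate_participant(p, sess, rng=np.random.default_rng(noise_ss))
        out = surprise.add_surprise_column(out)
        res = trialwise.fit_participant(out)
        recovered.append(res.raw_betas["surprise"])
    mean = float(np.mean(recovered))
    return {"beta_injected": beta_s, "beta_recovered_mean": mean,
            "relative_error": (mean - beta_s) / beta_s, "n_seeds": n_seeds,
            "n_trials": 700}


def _cohort_surprise_tests(trials, r_scale: float = inferential.DEFAULT_R_SCALE):
    """Group x surprise interaction p and the JZS BF on easy-condition slowing."""
    summary = metrics.summarize_participants(trials)
    cols = [f"rt_{c}_{s}" for c in ("easy", "difficult")
            for s in ("surprising", "unsurprising")]
    long = summary.melt(id_vars=["participant", "group"], value_vars=cols,
                        var_name="cell", value_name="rt")
    parts = long["cell"].str.split("_", expand=True)
    long["condition"], long["surprise"] = parts[1], parts[2]
    anova = {r.name: r for r in inferential.mixed_rm_anova(
        long, "rt", ["surprise", "condition"], "group")}
    g = sorted(summary["group"].unique())
    x = summary.loc[summary["group"] == g[0], "slowing_easy"].dropna()
    y = summary.loc[summary["group"] == g[1], "slowing_easy"].dropna()
    t_res = inferential.independent_t(x, y)
    bf = inferential.jzs_bf_ttest(t_res.statistic, len(x), len(y), r_scale=r_scale)
    return anova["surprise * group"].p, bf.bf10, float(x.mean() - y.mean())


def scenario_contrast_study(seed: int, n_reps: int = 100,
                            n_asd: int = 28, n_control: int = 35) -> dict:
    """Operating characteristics of the group x surprise tests per scenario.

    Under "bayesian-accounts" (prior utilization lowered in the ASD group)
    counts replicates where the surprise-by-group interaction is significant
    AND the slowing-index group BF10 exceeds 3; under "null" counts
    replicates where BF01 exceeds 1.
    """
    detect = 0
    bf10s = []
    for r in range(n_reps):
        trials = simulate.simulate_cohort(
            "bayesian-accounts", n_asd=n_asd, n_control=n_control,
            seed=(seed * 1_000_003 + r) % (2**31 - 1))
        p, bf10, _ = _cohort_surprise_tests(trials)
        bf10s.append(bf10)
        if p < 0.05 and bf10 > 3.0:
            detect += 1
    null_support = 0
    bf01s = []
    for r in range(n_reps):
        trials = simulate.simulate_cohort(
            "null", n_asd=n_asd, n_control=n_control,
            seed=(seed * 2_000_003 + r) % (2**31 - 1))
        _, bf10, _ = _cohort_surprise_tests(trials)
        bf01s.append(1.0 / bf10)
        if bf10 < 1.0:
            null_support += 1
    return {
        "n_reps": n_reps,
        "alternative_detection_rate": detect / n_reps,
        "alternative_median_bf10": float(np.median(bf10s)),
        "null_bf01_above_1_rate": null_support / n_reps,
        "null_median_bf01": float(np.median(bf01s)),
    }
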