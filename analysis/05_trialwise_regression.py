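#!/usr/bin/env python
"""Per-participant trialwise regression of RT and group-level beta tests.

Fits RT ~ time + condition + surprise + interactions for every participant
of both cohorts, writes the per-participant betas, and prints the
group-summary table (one-sample t per predictor; between-group t and JZS BF
for reliable predictors).
"""

from pathlib import Path

from srtlearn import inferential, trialwise
from srtlearn.pipeline import read_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for scenario in ("null", "bayesian-accounts"):
        trials = read_trials(OUT / f"trials_{scenario}_surprise.csv")
        betas = trialwise.fit_cohort(trials)
        betas.to_csv(OUT / f"trialwise_betas_{scenario}.csv", index=False)
        tests = trialwise.group_level(betas)
        inferential.results_frame(tests).to_csv(
            OUT / f"trialwise_tests_{scenario}.csv", index=False)
        print(f"== {scenario}: mean standardized betas (ms per SD) ==")
        print(betas.groupby("group")[list(trialwise.PREDICTORS)].mean().round(2).to_string())
        for r in tests:
            tag = f"BF01={r.bf01:.3f}" if r.bf01 else ""
            print(f"  {r.name}: t = {r.statistic:.3f}, p = {r.p:.4f} {tag}")
        print()


if __name__ == "__main__":
    main()
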