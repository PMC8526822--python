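#!/usr/bin/env python
"""Reduce the annotated cohorts to participant-level outcome measures.

Per participant and scenario: condition-mean RT, accuracy, inverse
efficiency scores, sequence-learning and surprise-slowing indices.  Prints
the group-mean pattern (speeding in the easy condition, slowing on
surprising trials) that the inferential stage tests.
"""

from pathlib import Path

from srtlearn import metrics
from srtlearn.pipeline import read_trials

OUT = Path(__file__).resolve().parents[1] / "results"

COLS = ["rt_unpredictable", "rt_easy", "rt_difficult",
        "seqlearn_easy", "slowing_easy", "slowing_difficult"]


def main() -> None:
    for scenario in ("null", "bayesian-accounts"):
        trials = read_trials(OUT / f"trials_{scenario}_surprise.csv")
        summary = metrics.summarize_participants(trials)
        summary.to_csv(OUT / f"summary_{scenario}.csv", index=False)
        print(f"== {scenario} (group means, ms) ==")
        print(summary.groupby("group")[COLS].mean().round(1).to_string())


if __name__ == "__main__":
    main()
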