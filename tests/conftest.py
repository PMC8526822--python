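import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Small null-scenario cohort (6 + 6 participants, 40-trial blocks)."""
    from srtlearn import simulate

    return simulate.simulate_cohort(
        "null", n_asd=6, n_control=6, seed=11, n_trials_per_block=40
    )


@pytest.fixture(scope="session")
def small_summary(small_cohort) -> pd.DataFrame:
    from srtlearn import metrics

    return metrics.summarize_participants(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def online_surprise_oracle(stimuli, alpha=1.0, kind="joint"):
    """Independent brute-force observer: explicit dict counts, updated online."""
    counts = {(j, i): alpha for j in range(1, 5) for i in range(1, 5)}
    out = [float("nan")]
    for t in range(1, len(stimuli)):
        j, i = int(stimuli[t - 1]), int(stimuli[t])
        if kind == "joint":
            p = counts[(j, i)] / sum(counts.values())
        else:
            p = counts[(j, i)] / sum(counts[(j, k)] for k in range(1, 5))
        out.append(-np.log(p))
        counts[(j, i)] += 1.0
    return np.array(out)
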