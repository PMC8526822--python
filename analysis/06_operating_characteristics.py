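#!/usr/bin/env python
"""Calibration and power of the whole pipeline (replicate simulation study).

Reports: (1) the slowing index of prior-free (w = 0) agents, whose expected
value is zero; (2) recovery of the injected surprise sensitivity by the
trialwise regression; (3) how often the battery detects the attenuated-
priors scenario and supports the null under the equal-priors scenario at
the study's sample sizes.  Replicate counts are reduced here for a quick
look; scripts/acceptance.py runs the full versions.
"""

import json
from pathlib import Path

from srtlearn import validation

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20_250_901


def main() -> None:
    res = {
        "null_slowing": validation.null_slowing_study(SEED, n_seeds=50),
        "beta_recovery": validation.beta_recovery_study(SEED + 1, n_seeds=25),
        "scenario_contrast": validation.scenario_contrast_study(SEED + 2, n_reps=25),
    }
    (OUT / "operating_characteristics.json").write_text(json.dumps(res, indent=2))
    n = res["null_slowing"]
    print(f"w=0 slowing: {n['mean_ms']:.2f} ms (95% CI half-width {n['ci_halfwidth_ms']:.2f})")
    r = res["beta_recovery"]
    print(f"beta_s recovery: {r['beta_recovered_mean']:.2f} ms/nat "
          f"(injected {r['beta_injected']}, rel. error {r['relative_error']:+.1%})")
    c = res["scenario_contrast"]
    print(f"detection rate (attenuated priors): {c['alternative_detection_rate']:.0%}; "
          f"null BF01>1 rate: {c['null_bf01_above_1_rate']:.0%}")


if __name__ == "__main__":
    main()
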