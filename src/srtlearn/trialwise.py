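"""Per-participant trialwise regression of RT on time, condition and surprise.

For each participant an ordinary-least-squares model predicts RT (ms, correct
predictable-condition trials with a defined surprise value) from

* ``time``       — trial position, z-scored within participant;
* ``condition``  — contrast easy = -0.5, difficult = +0.5;
* ``surprise``   — the ideal-observer trace, z-scored within participant;

plus all two- and three-way products of the centred components.  Betas are on
the standardized-predictor scale with the DV left in ms, so each reads as
"ms of RT per SD of predictor".  Group-level inference runs one-sample
t-tests on the betas across participants and, for reliable predictors,
between-group independent t-tests with JZS Bayes factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inferential import DEFAULT_R_SCALE, StatResult, independent_t, jzs_bf_ttest
from .sequences import PREDICTABLE

PREDICTORS = (
    "time", "condition", "surprise",
    "time * condition", "time * surprise", "condition * surprise",
    "time * condition * surprise",
)


@dataclass
class RegressionResult:
    participant: str
    group: str
    betas: dict[str, float]
    r2: float
    n_used: int
    raw_betas: dict[str, float] = field(default_factory=dict)
    sd_predictors: dict[str, float] = field(default_factory=dict)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance predictor")
    return (x - np.mean(x)) / sd


def fit_participant(
    trials: pd.DataFrame,
    surprise_col: str = "surprise",
    min_trials: int = 30,
    standardize_dv: bool = False,
) -> RegressionResult:
    """OLS fit of one participant's RT on time, condition, surprise and products.

    Uses correct trials from the two predictable conditions with a defined
    surprise value.  With ``standardize_dv`` the RT is z-scored too, giving
    fully standardized coefficients.
    """
    sel = (
        trials["correct"].astype(bool)
        & trials["condition"].isin(PREDICTABLE)
        & trials[surprise_col].notna()
    )
    d = trials.loc[sel]
    n = len(d)
    if n < min_trials:
        raise ValueError(f"only {n} usable trials (< {min_trials})")
    # session-wide trial position, recovered from row order
    time_raw = np.asarray(d.index, dtype=float)
    cond_raw = np.where(d["condition"] == "difficult", 0.5, -0.5)
    surp_raw = d[surprise_col].to_numpy(dtype=float)

    time = _zscore(time_raw)
    cond = cond_raw - cond_raw.mean()
    surp = _zscore(surp_raw)
    cols = {
        "time": time,
        "condition": cond,
        "surprise": surp,
        "time * condition": time * cond,
        "time * surprise": time * surp,
        "condition * surprise": cond * surp,
        "time * condition * surprise": time * cond * surp,
    }
    x = np.column_stack([np.ones(n)] + [cols[k] for k in PREDICTORS])
    y = d["rt_ms"].to_numpy(dtype=float)
    if standardize_dv:
        y = _zscore(y)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear columns among "
            + ", ".join(PREDICTORS)
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    betas = dict(zip(PREDICTORS, beta[1:]))
    sds = {"time": float(np.std(time_raw, ddof=1)),
           "surprise": float(np.std(surp_raw, ddof=1)), "condition": 1.0}
    raw = {
        "surprise": betas["surprise"] / sds["surprise"],
        "time": betas["time"] / sds["time"],
    }
    return RegressionResult(
        participant=str(trials["participant"].iloc[0]),
        group=str(trials["group"].iloc[0]),
        betas=betas, r2=1.0 - ss_res / ss_tot, n_used=n,
        raw_betas=raw, sd_predictors=sds,
    )


def fit_cohort(trials: pd.DataFrame, surprise_col: str = "surprise",
               min_trials: int = 30) -> pd.DataFrame:
    """Per-participant betas as a table (one row per participant)."""
    rows = []
    for _, g in trials.groupby("participant", sort=False):
        res = fit_participant(g.reset_index(drop=True), surprise_col, min_trials)
        row = {"participant": res.participant, "group": res.group,
               "r2": res.r2, "n_used": res.n_used}
        row.update({k: v for k, v in res.betas.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def group_level(
    betas: pd.DataFrame,
    r_scale: float = DEFAULT_R_SCALE,
    alpha_level: float = 0.05,
) -> list[StatResult]:
    """Group-level inference on per-participant betas.

    Per predictor: a one-sample t against zero over all participants; for
    predictors that reliably differ from zero, a between-group independent t
    with its JZS Bayes factor on the group contrast.
    """
    from scipy import stats as sps

    glabels = sorted(betas["group"].unique())
    out: list[StatResult] = []
    for pred in PREDICTORS:
        v = betas[pred].to_numpy(dtype=float)
        n = len(v)
        sd = np.std(v, ddof=1)
        t_val = float(np.mean(v) / (sd / np.sqrt(n))) if sd > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t_val), n - 1)) if sd > 0 else 1.0
        one = StatResult(
            name=f"beta[{pred}] vs 0", statistic=t_val, df=n - 1, p=p,
            effect_size=float(np.mean(v) / sd) if sd > 0 else 0.0,
            effect_size_type="cohen_d",
            extra={"mean_beta": float(np.mean(v)), "se_beta": float(sd / np.sqrt(n))},
        )
        out.append(one)
        if len(glabels) == 2 and p < alpha_level:
            x = betas.loc[betas["group"] == glabels[0], pred].to_numpy(dtype=float)
            y = betas.loc[betas["group"] == glabels[1], pred].to_numpy(dtype=float)
            res = independent_t(x, y)
            bf = jzs_bf_ttest(res.statistic, len(x), len(y), r_scale=r_scale)
            res.name = f"beta[{pred}]: {glabels[0]} vs {glabels[1]}"
            res.bf10, res.bf01 = bf.bf10, bf.bf01
            out.append(res)
    return out
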