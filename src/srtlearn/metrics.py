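"""Reduction of trial tables to the task's outcome measures.

All RT summaries use correct responses only.  Per participant the module
produces condition-mean RT, proportion correct, inverse efficiency scores
(IES = mean correct RT / proportion correct, guarding against speed-accuracy
trade-offs), surprise-cell means within the predictable conditions, and the
two derived indices:

* sequence-learning index  = mean RT(unpredictable) - mean RT(condition),
  positive when the sequence speeds responding;
* surprise-slowing index   = mean RT(surprising) - mean RT(unsurprising),
  positive when sequence violations slow responding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sequences import LABEL_SURPRISING, LABEL_UNSURPRISING, PREDICTABLE

log = logging.getLogger(__name__)


def mean_rt(
    trials: pd.DataFrame,
    condition: str | None = None,
    surprise_filter: str | None = None,
) -> float:
    """Mean RT over correct trials matching the given filters; NaN if empty."""
    # note: to_numpy on a bool column can be a zero-copy view; never modify in place
    sel = np.array(trials["correct"], dtype=bool)
    if condition is not None:
        sel = sel & (trials["condition"] == condition).to_numpy()
    if surprise_filter is not None:
        sel = sel & (trials["surprise_label"] == surprise_filter).to_numpy()
    if not sel.any():
        log.warning("empty RT cell (condition=%s, surprise=%s)", condition, surprise_filter)
        return float("nan")
    return float(trials.loc[sel, "rt_ms"].mean())


def prop_correct(trials: pd.DataFrame, condition: str | None = None) -> float:
    sel = np.ones(len(trials), dtype=bool)
    if condition is not None:
        sel = sel & (trials["condition"] == condition).to_numpy()
    if not sel.any():
        return float("nan")
    return float(trials.loc[sel, "correct"].mean())


def ies(mean_rt_ms: float, proportion_correct: float) -> float:
    """Inverse efficiency score: mean correct RT divided by accuracy."""
    if not 0.0 <= proportion_correct <= 1.0:
        raise ValueError(f"proportion correct must lie in [0, 1], got {proportion_correct}")
    if proportion_correct == 0.0:
        log.warning("IES undefined at zero accuracy")
        return float("nan")
    return mean_rt_ms / proportion_correct


def summarize_participant(trials: pd.DataFrame) -> dict:
    """One participant's outcome summary (one row of the summary table)."""
    conditions = [c for c in ("unpredictable", "easy", "difficult")
                  if (trials["condition"] == c).any()]
    row: dict = {
        "participant": trials["participant"].iloc[0],
        "group": trials["group"].iloc[0],
    }
    for c in conditions:
        m = mean_rt(trials, c)
        pc = prop_correct(trials, c)
        row[f"rt_{c}"] = m
        row[f"pc_{c}"] = pc
        row[f"ies_{c}"] = ies(m, pc) if np.isfinite(m) else float("nan")
    for c in PREDICTABLE:
        if c not in conditions:
            continue
        row[f"rt_{c}_surprising"] = mean_rt(trials, c, LABEL_SURPRISING)
        row[f"rt_{c}_unsurprising"] = mean_rt(trials, c, LABEL_UNSURPRISING)
        row[f"slowing_{c}"] = row[f"rt_{c}_surprising"] - row[f"rt_{c}_unsurprising"]
        if "rt_unpredictable" in row:
            row[f"seqlearn_{c}"] = row["rt_unpredictable"] - row[f"rt_{c}"]
        # IES per surprise cell, for the surprise ANOVA on IES
        for lab in (LABEL_SURPRISING, LABEL_UNSURPRISING):
            sel = (trials["condition"] == c) & (trials["surprise_label"] == lab)
            if sel.any():
                row[f"ies_{c}_{lab}"] = ies(
                    mean_rt(trials, c, lab), float(trials.loc[sel, "correct"].mean())
                )
    return row


def summarize_participants(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant-level summary table (one row per participant)."""
    rows = [summarize_participant(g) for _, g in trials.groupby("participant", sort=False)]
    return pd.DataFrame(rows)


def sequence_learning_index(summary_row: pd.Series | dict, condition: str) -> float:
    """RT(unpredictable) - RT(condition) for a predictable condition, ms."""
    if condition not in PREDICTABLE:
        raise ValueError(f"sequence learning is defined for predictable conditions, got {condition!r}")
    base = summary_row.get("rt_unpredictable", float("nan"))
    tgt = summary_row.get(f"rt_{condition}", float("nan"))
    if not np.isfinite(base):
        raise ValueError("sequence-learning index undefined: no unpredictable baseline")
    return float(base - tgt)


def surprise_slowing_index(summary_row: pd.Series | dict, condition: str) -> float:
    """RT(surprising) - RT(unsurprising) within a predictable condition, ms."""
    if condition not in PREDICTABLE:
        raise ValueError(f"surprise slowing is defined for predictable conditions, got {condition!r}")
    return float(
        summary_row[f"rt_{condition}_surprising"] - summary_row[f"rt_{condition}_unsurprising"]
    )


def baseline_correct(summary: pd.DataFrame) -> pd.DataFrame:
    """Subtract each participant's unpredictable-condition mean RT from all RT cells.

    Participants without a finite baseline are dropped (logged).  Derived
    difference indices are baseline-invariant and left untouched.
    """
    if "rt_unpredictable" not in summary.columns:
        raise ValueError("baseline correction requires an unpredictable-condition mean")
    out = summary.copy()
    good = np.isfinite(out["rt_unpredictable"])
    if not good.all():
        for p in out.loc[~good, "participant"]:
            log.warning("participant %s dropped in baseline correction (no baseline)", p)
        out = out.loc[good].reset_index(drop=True)
    base = out["rt_unpredictable"].to_numpy()
    for col in out.columns:
        if col.startswith("rt_"):
            out[col] = out[col] - base
    return out
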