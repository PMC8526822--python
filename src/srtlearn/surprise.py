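"""Ideal-observer trial-by-trial surprise from running stimulus-pair counts.

The observer tracks how often each ordered stimulus pair (j, i) — stimulus j
on trial t-1 followed by stimulus i on trial t — has occurred so far.  The
surprise of trial t is the negative log of the *predicted joint probability*
of its pair, estimated causally from the counts accumulated on preceding
trials only, with additive smoothing so that first occurrences remain finite:

    p(j, i) = (count(j, i) + alpha) / (n_pairs + 16 * alpha)
    surprise = -ln p(j, i)        [nats]

A conditional variant, p(i | j) = (count(j, i) + alpha) / (count(j, .) +
4 * alpha), is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

N_STIM = 4

Scope = Literal["per_condition", "per_block", "per_session"]


@dataclass
class PairCounts:
    """Smoothed running counts of ordered stimulus pairs (the observer state)."""

    alpha: float = 1.0
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_pairs_observed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.counts is None:
            self.counts = np.full((N_STIM, N_STIM), self.alpha, dtype=float)

    @property
    def total_mass(self) -> float:
        return N_STIM * N_STIM * self.alpha + self.n_pairs_observed

    def joint_probability(self, j: int, i: int) -> float:
        """Predicted joint probability of the pair (j, i)."""
        total = self.total_mass
        if total <= 0:
            raise ValueError("degenerate observer state: zero total mass (alpha=0, no data)")
        return float(self.counts[j - 1, i - 1] / total)

    def conditional_probability(self, j: int, i: int) -> float:
        """Predicted probability of i given predecessor j."""
        row = float(self.counts[j - 1].sum())
        if row <= 0:
            raise ValueError("degenerate observer state: empty predecessor row")
        return float(self.counts[j - 1, i - 1] / row)

    def update(self, j: int, i: int) -> "PairCounts":
        """Record one observation of the pair (j, i) in place."""
        _check_stim(j)
        _check_stim(i)
        self.counts[j - 1, i - 1] += 1.0
        self.n_pairs_observed += 1
        return self


def _check_stim(s: int) -> None:
    if s not in (1, 2, 3, 4):
        raise ValueError(f"stimulus id must be in 1..4, got {s}")


def surprise_value(p: float) -> float:
    """Surprise in nats of an event with probability ``p``: -ln p."""
    if p <= 0:
        raise ValueError(f"surprise requires p > 0, got {p}")
    if p > 1:
        raise ValueError(f"probability above 1: {p}")
    return -math.log(p)


def _cumcount(codes: np.ndarray) -> np.ndarray:
    """Occurrence index of each element among its equals up to (excluding) it."""
    out = np.empty(len(codes), dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    starts = np.r_[0, np.flatnonzero(sc[1:] != sc[:-1]) + 1]
    ranks = np.arange(len(codes)) - np.repeat(starts, np.diff(np.r_[starts, len(codes)]))
    out[order] = ranks
    return out


def surprise_of_pairs(
    prev: np.ndarray,
    cur: np.ndarray,
    alpha: float = 1.0,
    kind: Literal["joint", "conditional"] = "joint",
) -> np.ndarray:
    """Causal surprise of an ordered stream of stimulus pairs.

    ``prev[t]``/``cur[t]`` are the predecessor and current stimulus of the
    t-th pair in presentation order.  The surprise of pair t uses only pairs
    0..t-1.  Vectorised via cumulative per-pair occurrence counts, which is
    equivalent to the online count-update observer.
    """
    prev = np.asarray(prev, dtype=np.int64)
    cur = np.asarray(cur, dtype=np.int64)
    if prev.shape != cur.shape:
        raise ValueError("prev and cur must have equal length")
    n = len(prev)
    if n == 0:
        return np.empty(0)
    if alpha <= 0:
        raise ValueError("alpha must be positive for finite surprise")
    pair_code = (prev - 1) * N_STIM + (cur - 1)
    seen_pair = _cumcount(pair_code)  # pairs (j,i) observed before t
    if kind == "joint":
        p = (seen_pair + alpha) / (np.arange(n) + N_STIM * N_STIM * alpha)
    elif kind == "conditional":
        seen_row = _cumcount(prev)  # pairs with predecessor j before t
        p = (seen_pair + alpha) / (seen_row + N_STIM * alpha)
    else:
        raise ValueError(f"unknown surprise kind {kind!r}")
    return -np.log(p)


def surprise_trace(
    stimuli: np.ndarray,
    alpha: float = 1.0,
    kind: Literal["joint", "conditional"] = "joint",
) -> np.ndarray:
    """Surprise trace of one contiguous stimulus sequence.

    Element 0 is NaN (no predecessor); element t >= 1 is the surprise of the
    pair (stimuli[t-1], stimuli[t]) given the counts before trial t.
    """
    stimuli = np.asarray(stimuli, dtype=np.int64)
    if len(stimuli) < 2:
        raise ValueError("need at least 2 trials for a surprise trace")
    s = surprise_of_pairs(stimuli[:-1], stimuli[1:], alpha=alpha, kind=kind)
    return np.r_[np.nan, s]


def add_surprise_column(
    trials: pd.DataFrame,
    alpha: float = 1.0,
    scope: Scope = "per_condition",
    kind: Literal["joint", "conditional"] = "joint",
) -> pd.DataFrame:
    """Append a ``surprise`` column to a trial-level table.

    The observer accumulates counts separately per participant and, under the
    default ``per_condition`` scope, separately per condition — counts persist
    across blocks of the same condition but never across conditions.  Pairs
    are formed within blocks only (each block's first trial has no defined
    pair and gets NaN); pair *counting* likewise never spans a block boundary.
    """
    out = trials.copy()
    out["surprise"] = np.nan
    if scope == "per_condition":
        keys = ["participant", "condition"]
    elif scope == "per_block":
        keys = ["participant", "block"]
    elif scope == "per_session":
        keys = ["participant"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for _, idx in out.groupby(keys, sort=False).indices.items():
        idx = np.sort(idx)
        if len(idx) < 2:
            raise ValueError("surprise scope with fewer than 2 trials")
        sub = out.iloc[idx]
        stim = sub["stimulus"].to_numpy(dtype=np.int64)
        blocks = sub["block"].to_numpy()
        ok = np.r_[False, blocks[1:] == blocks[:-1]]  # within-block pairs only
        vals = surprise_of_pairs(stim[:-1][ok[1:]], stim[1:][ok[1:]], alpha=alpha, kind=kind)
        col = np.full(len(idx), np.nan)
        col[np.flatnonzero(ok)] = vals
        out.iloc[idx, out.columns.get_loc("surprise")] = col
    return out
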