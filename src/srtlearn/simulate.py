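"""Generative synthetic-participant model for the serial reaction time task.

Each simulated participant runs the same pair-counting learner as the
analysis observer, but *utilises* the learned statistics only partially: the
learned conditional prediction of the next stimulus is mixed toward the
uniform distribution by the prior-utilization weight ``w``,

    p_eff(i | j) = w * p_learned(i | j) + (1 - w) * 1/4,

then mapped to the joint scale by the learned predecessor marginal, so that
``w = 1`` reproduces the analysis observer's joint surprise exactly and
``w = 0`` yields predictions carrying no sequence information.  Reaction
time rises linearly with the agent's own surprise,

    RT = mu + beta_s * surprise + difficulty cost + noise,

and errors become more likely on surprising trials through a logistic link.
Setting ``w`` lower in one group instantiates the attenuated-priors
hypothesis (reduced sequence learning and reduced surprise-related slowing);
equal ``w`` in both groups is the null scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import sequences
from .sequences import DEFAULT_BLOCK_ORDER, DEFAULT_P_HIGH, DEFAULT_THRESHOLD, Session
from .surprise import N_STIM, _cumcount

RT_FLOOR_MS = 150.0
#: Agent surprise assigned to trials without a defined within-block pair
#: (first trial of each block): the fresh-observer joint value -ln(1/16).
SURPRISE_UNDEFINED = float(np.log(16.0))

#: Prior-utilization per group under the two study scenarios.  "null" is the
#: observed outcome (no group difference); "bayesian-accounts" encodes the
#: attenuated-priors hypothesis (lower utilization in the ASD group).
SCENARIOS = {
    "null": {"ASD": 0.9, "control": 0.9},
    "bayesian-accounts": {"ASD": 0.3, "control": 0.9},
}

GROUP_SIZES = {"ASD": 28, "control": 35}


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one synthetic participant.

    w                prior utilization in [0, 1]
    mu               baseline RT, ms
    beta_s           surprise sensitivity, ms per nat
    sigma            RT noise SD, ms
    err0, err1       error log-odds intercept / slope per nat of surprise
    w_difficult_scale  multiplier on w in the difficult-predictable condition
                     (the difficult 1-4-2-3 sequence is learned only weakly)
    difficult_cost   baseline RT cost of the difficult condition, ms
    """

    id: str
    group: str
    w: float
    mu: float = 650.0
    beta_s: float = 30.0
    sigma: float = 60.0
    err0: float = -3.5
    err1: float = 0.2
    w_difficult_scale: float = 0.15
    difficult_cost: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if self.mu <= 0:
            raise ValueError("baseline RT must be positive")
        if self.sigma < 0 or self.beta_s < 0:
            raise ValueError("sigma and beta_s must be nonnegative")
        if not 0.0 <= self.w_difficult_scale <= 1.0:
            raise ValueError("w_difficult_scale must lie in [0, 1]")


def effective_prediction(w: float, p_learned: float) -> float:
    """Mix a learned probability toward uniform by prior utilization ``w``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    if not 0.0 < p_learned < 1.0:
        raise ValueError(f"p_learned must lie in (0, 1), got {p_learned}")
    return w * p_learned + (1.0 - w) * 0.25


def agent_surprise(trials: pd.DataFrame, params: ParticipantParams, alpha: float = 1.0) -> np.ndarray:
    """Vectorised trace of the agent's own (prior-weighted) surprise.

    Counts accumulate per condition (persisting across same-condition blocks)
    and pairs are formed within blocks only, exactly as in the analysis
    observer; trials without a defined pair get :data:`SURPRISE_UNDEFINED`.
    """
    s_out = np.full(len(trials), SURPRISE_UNDEFINED)
    for cond, idx in trials.groupby("condition", sort=False).indices.items():
        idx = np.sort(idx)
        sub = trials.iloc[idx]
        stim = sub["stimulus"].to_numpy(dtype=np.int64)
        blocks = sub["block"].to_numpy()
        ok = np.r_[False, blocks[1:] == blocks[:-1]]
        prev, cur = stim[:-1][ok[1:]], stim[1:][ok[1:]]
        n = len(prev)
        if n == 0:
            continue
        pair_code = (prev - 1) * N_STIM + (cur - 1)
        seen_pair = _cumcount(pair_code)
        seen_row = _cumcount(prev)
        p_cond = (seen_pair + alpha) / (seen_row + N_STIM * alpha)
        p_marg = (seen_row + N_STIM * alpha) / (np.arange(n) + N_STIM * N_STIM * alpha)
        w = params.w * params.w_difficult_scale if cond == "difficult" else params.w
        p_eff = (w * p_cond + (1.0 - w) * 0.25) * p_marg
        s_out[idx[np.flatnonzero(ok)]] = -np.log(p_eff)
    return s_out


def simulate_participant(
    params: ParticipantParams,
    session: Session,
    alpha: float = 1.0,
    rng: np.random.Generator | int = 0,
    rt_noise: str = "gaussian",
) -> pd.DataFrame:
    """Simulate one participant's keypresses over a session.

    Returns the trial-level table with response, correctness and RT columns
    appended to the stimulus-stream schema.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    trials = sequences.session_to_frame(session, participant=params.id, group=params.group)
    s = agent_surprise(trials, params, alpha=alpha)
    n = len(trials)
    is_difficult = (trials["condition"] == "difficult").to_numpy()
    det = params.mu + params.beta_s * s + params.difficult_cost * is_difficult
    if rt_noise == "gaussian":
        rt = det + rng.normal(0.0, params.sigma, size=n)
    elif rt_noise == "lognormal":
        cv = params.sigma / params.mu
        rt = det * np.exp(rng.normal(0.0, cv, size=n) - 0.5 * cv * cv)
    else:
        raise ValueError(f"unknown rt_noise model {rt_noise!r}")
    rt = np.maximum(rt, RT_FLOOR_MS)
    p_err = 1.0 / (1.0 + np.exp(-(params.err0 + params.err1 * s)))
    is_err = rng.random(n) < p_err
    stim = trials["stimulus"].to_numpy(dtype=np.int64)
    resp = stim.copy()
    n_err = int(is_err.sum())
    if n_err:
        # wrong key drawn uniformly from the 3 alternatives
        shift = rng.integers(1, 4, size=n_err)
        resp[is_err] = (stim[is_err] - 1 + shift) % 4 + 1
    trials["response"] = resp
    trials["correct"] = resp == stim
    trials["rt_ms"] = rt
    trials["agent_surprise"] = s
    return trials


def draw_participant_params(
    group: str,
    w: float,
    pid: str,
    rng: np.random.Generator,
    mu_mean: float = 650.0,
    mu_sd: float = 50.0,
    beta_s_mean: float = 30.0,
    beta_s_sd: float = 8.0,
    sigma: float = 60.0,
) -> ParticipantParams:
    """Draw one participant's generative parameters from the cohort model."""
    mu = float(np.clip(rng.normal(mu_mean, mu_sd), 300.0, None))
    beta_s = float(np.clip(rng.normal(beta_s_mean, beta_s_sd), 0.0, None))
    return ParticipantParams(id=pid, group=group, w=w, mu=mu, beta_s=beta_s, sigma=sigma)


def simulate_cohort(
    scenario: str = "null",
    n_asd: int = GROUP_SIZES["ASD"],
    n_control: int = GROUP_SIZES["control"],
    seed: int = 0,
    p_high: float = DEFAULT_P_HIGH,
    threshold: float = DEFAULT_THRESHOLD,
    block_order: tuple[str, ...] = DEFAULT_BLOCK_ORDER,
    alpha: float = 1.0,
    n_trials_per_block: int = sequences.N_TRIALS_PER_BLOCK,
    param_overrides: dict | None = None,
) -> pd.DataFrame:
    """Simulate a two-group cohort and return the stacked trial table.

    Every participant shares the block order (as in the task) but experiences
    an independently drawn stimulus sequence.  All randomness descends from
    ``seed`` through named substreams (parameters, per-participant sequence
    and behavioural noise), so any participant is independently reproducible.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}")
    if min(n_asd, n_control) < 2:
        raise ValueError("need at least 2 participants per group")
    w_by_group = SCENARIOS[scenario]
    root = np.random.SeedSequence(seed)
    params_ss, participants_ss = root.spawn(2)
    params_rng = np.random.default_rng(params_ss)
    specs = [("control", k) for k in range(n_control)] + [("ASD", k) for k in range(n_asd)]
    child_ss = participants_ss.spawn(len(specs))
    frames = []
    for (group, k), ss in zip(specs, child_ss):
        pid = f"{'c' if group == 'control' else 'a'}{k + 1:03d}"
        params = draw_participant_params(group, w_by_group[group], pid, params_rng)
        if param_overrides:
            params = replace(params, **param_overrides)
        seq_ss, noise_ss = ss.spawn(2)
        session = sequences.build_session(
            block_order, p_high, np.random.default_rng(seq_ss),
            n_trials_per_block, threshold,
        )
        frames.append(simulate_participant(params, session, alpha, np.random.default_rng(noise_ss)))
    return pd.concat(frames, ignore_index=True)
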