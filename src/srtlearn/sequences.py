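"""Condition-specific Markov transition models and stimulus sequence generation.

The serial reaction time task presents one of four imperative stimuli per
trial.  Stimulus order is governed by a first-order Markov chain whose
transition matrix depends on the block condition:

* ``unpredictable`` — every transition equally likely (all entries 0.25);
* ``easy`` — the 4-cycle 1-2-3-4 occurs with high probability ``p_high``;
* ``difficult`` — the 4-cycle 1-4-2-3 occurs with high probability.

In the predictable conditions the three sequence-violating transitions share
the remaining mass equally, so each has probability ``(1 - p_high) / 3``.
Low-probability transitions are the task's "surprising" trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("unpredictable", "easy", "difficult")
PREDICTABLE = ("easy", "difficult")

#: High-probability stimulus cycles of the two predictable conditions.
PATHS = {"easy": (1, 2, 3, 4), "difficult": (1, 4, 2, 3)}

#: Default probability of the sequence-consistent transition.
DEFAULT_P_HIGH = 0.85
#: Generative-probability threshold separating surprising from unsurprising.
DEFAULT_THRESHOLD = 0.75
#: Default block order of a seven-block session.
DEFAULT_BLOCK_ORDER = (
    "unpredictable", "easy", "difficult", "easy", "difficult", "easy", "unpredictable",
)
N_TRIALS_PER_BLOCK = 100

LABEL_NA = "n/a"
LABEL_SURPRISING = "surprising"
LABEL_UNSURPRISING = "unsurprising"


@dataclass(frozen=True)
class TransitionModel:
    """A 4x4 row-stochastic transition matrix with its condition tag.

    ``matrix[j - 1, i - 1]`` is P(stimulus i at trial t | stimulus j at
    trial t-1); stimulus ids are 1-based.
    """

    condition: str
    matrix: np.ndarray
    p_high: float
    path: tuple[int, ...] | None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("every row of the transition matrix must sum to 1")
        object.__setattr__(self, "matrix", m)

    def transition_prob(self, j: int, i: int) -> float:
        return float(self.matrix[j - 1, i - 1])


@dataclass
class Block:
    """One block of trials: stimuli plus per-trial generative annotations.

    ``gen_prob[0]`` is NaN: the first trial of a block has no within-block
    predecessor, so its generative transition probability is undefined.
    """

    condition: str
    stimuli: np.ndarray
    gen_prob: np.ndarray
    surprise_label: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass
class Session:
    """Seven-block session: the stimulus stream one participant experiences."""

    block_order: tuple[str, ...]
    blocks: list[Block]
    seed: int
    p_high: float = DEFAULT_P_HIGH
    threshold: float = DEFAULT_THRESHOLD

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


def build_condition_matrix(condition: str, p_high: float = DEFAULT_P_HIGH) -> TransitionModel:
    """Build the transition model of one task condition.

    Parameters
    ----------
    condition
        One of ``unpredictable``, ``easy``, ``difficult``.
    p_high
        Probability of the sequence-consistent transition; ignored for the
        unpredictable condition.  Must satisfy ``0.25 <= p_high < 1``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if condition == "unpredictable":
        return TransitionModel(condition, np.full((4, 4), 0.25), 0.25, None)
    if not (0.25 <= p_high < 1.0):
        raise ValueError(f"p_high must lie in [0.25, 1) for predictable conditions, got {p_high}")
    path = PATHS[condition]
    m = np.full((4, 4), (1.0 - p_high) / 3.0)
    for k, j in enumerate(path):
        i = path[(k + 1) % 4]
        m[j - 1, i - 1] = p_high
    return TransitionModel(condition, m, p_high, path)


def generate_block(
    model: TransitionModel,
    n_trials: int,
    rng: np.random.Generator | int,
    initial: int,
) -> Block:
    """Iterate the Markov chain for ``n_trials`` trials starting from ``initial``.

    ``initial`` seeds the chain but is not itself emitted: the first emitted
    stimulus is drawn from ``initial``'s row, and its generative probability is
    flagged undefined (NaN) because the predecessor lies outside the block.
    """
    if n_trials < 2:
        raise ValueError("a block needs at least 2 trials")
    if initial not in (1, 2, 3, 4):
        raise ValueError(f"initial stimulus must be in 1..4, got {initial}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cum = np.cumsum(model.matrix, axis=1)
    u = rng.random(n_trials)
    stimuli = np.empty(n_trials, dtype=np.int64)
    gen_prob = np.empty(n_trials)
    prev = initial
    for t in range(n_trials):
        s = int(np.searchsorted(cum[prev - 1], u[t], side="right")) + 1
        s = min(s, 4)  # guard against u == 1.0 edge
        stimuli[t] = s
        gen_prob[t] = model.transition_prob(prev, s)
        prev = s
    gen_prob[0] = np.nan
    return Block(model.condition, stimuli, gen_prob)


def label_surprise_trials(block: Block, threshold: float = DEFAULT_THRESHOLD) -> Block:
    """Attach surprise labels from generative transition probabilities.

    In predictable blocks a trial is *surprising* when its generative
    transition probability falls below ``threshold`` and *unsurprising*
    otherwise.  All unpredictable-block trials, and the first trial of any
    block, are ``n/a``.
    """
    if not (0.25 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0.25, 1), got {threshold}")
    if block.condition == "unpredictable":
        block.surprise_label = [LABEL_NA] * len(block)
        return block
    labels = [LABEL_NA]
    for p in block.gen_prob[1:]:
        labels.append(LABEL_SURPRISING if p < threshold else LABEL_UNSURPRISING)
    block.surprise_label = labels
    return block


def build_session(
    block_order: tuple[str, ...] = DEFAULT_BLOCK_ORDER,
    p_high: float = DEFAULT_P_HIGH,
    seed: int | np.random.Generator = 0,
    n_trials_per_block: int = N_TRIALS_PER_BLOCK,
    threshold: float = DEFAULT_THRESHOLD,
) -> Session:
    """Generate and label a full session.

    Consecutive blocks chain: each block's Markov chain starts from the last
    stimulus of the previous block (the first block starts from a uniformly
    drawn stimulus).  Block order is shared by all participants of a run.
    """
    if len(block_order) != 7:
        raise ValueError(f"a session has 7 blocks, got {len(block_order)}")
    for c in block_order:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r} in block order")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    models = {c: build_condition_matrix(c, p_high) for c in set(block_order)}
    initial = int(rng.integers(1, 5))
    blocks: list[Block] = []
    for cond in block_order:
        b = generate_block(models[cond], n_trials_per_block, rng, initial)
        blocks.append(label_surprise_trials(b, threshold))
        initial = int(b.stimuli[-1])
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return Session(tuple(block_order), blocks, int(seed_val), p_high, threshold)


def session_to_frame(session: Session, participant: str = "p1", group: str = "") -> pd.DataFrame:
    """Flatten a session to the trial-level table schema.

    Columns: participant, group, block (1-based), condition, trial (1-based
    within block), stimulus, gen_prob, surprise_label.
    """
    rows = []
    for b_idx, block in enumerate(session.blocks, start=1):
        rows.append(pd.DataFrame({
            "participant": participant,
            "group": group,
            "block": b_idx,
            "condition": block.condition,
            "trial": np.arange(1, len(block) + 1),
            "stimulus": block.stimuli,
            "gen_prob": block.gen_prob,
            "surprise_label": block.surprise_label,
        }))
    return pd.concat(rows, ignore_index=True)
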