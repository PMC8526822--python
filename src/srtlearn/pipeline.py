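"""End-to-end orchestration: simulate -> surprise -> metrics -> inference.

The pipeline is deterministic under a fixed seed: a run writes the trial
table, the participant summary, tidy statistics tables and a manifest with a
content hash per file, and a rerun with the same config reproduces the
hashes.  ``analyze_external`` runs every post-simulation stage on a foreign
trial table with the documented schema, so deposited real data can be
analysed identically to synthetic cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inferential, metrics, simulate, surprise, trialwise
from .inferential import DEFAULT_R_SCALE, demographic_comparisons, results_frame
from .sequences import DEFAULT_BLOCK_ORDER, DEFAULT_P_HIGH, DEFAULT_THRESHOLD, PREDICTABLE

log = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant", "group", "block", "condition", "trial", "stimulus",
    "response", "correct", "rt_ms", "gen_prob", "surprise_label",
]


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level CSV preserving the literal ``n/a`` surprise label.

    Only empty fields become NaN (the ``gen_prob``/``surprise`` of trials
    without a defined transition); boolean ``correct`` round-trips.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    if "correct" in df.columns and df["correct"].dtype == object:
        df["correct"] = df["correct"].map({"True": True, "False": False}).astype(bool)
    return df


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    scenario: str = "null"
    n_asd: int = 28
    n_control: int = 35
    p_high: float = DEFAULT_P_HIGH
    threshold: float = DEFAULT_THRESHOLD
    block_order: tuple[str, ...] = DEFAULT_BLOCK_ORDER
    n_trials_per_block: int = 100
    alpha: float = 1.0
    observer_scope: str = "per_condition"
    observer_kind: str = "joint"
    r_scale: float = DEFAULT_R_SCALE
    sphericity_correction: bool = False
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_order"] = list(d["block_order"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "block_order" in raw:
            raw["block_order"] = tuple(raw["block_order"])
        return cls(**raw)


@dataclass
class AnalysisOutputs:
    """In-memory results of the post-simulation stages."""

    trials: pd.DataFrame
    summary: pd.DataFrame
    condition_anova: list
    surprise_anova: list
    posthoc_condition: list
    slowing_group_tests: dict
    betas: pd.DataFrame
    beta_tests: list
    sequential: pd.DataFrame
    inclusion: dict = field(default_factory=dict)


def analyze_trials(trials: pd.DataFrame, config: RunConfig,
                   with_inclusion_bf: bool = False) -> AnalysisOutputs:
    """All post-simulation stages on a trial table with the documented schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    trials = surprise.add_surprise_column(
        trials, alpha=config.alpha, scope=config.observer_scope, kind=config.observer_kind)
    summary = metrics.summarize_participants(trials)
    if "rt_unpredictable" not in summary.columns or summary["rt_unpredictable"].isna().all():
        raise ValueError("sequence-learning indices undefined: no unpredictable blocks")

    long_cond = summary.melt(
        id_vars=["participant", "group"],
        value_vars=[c for c in ("rt_unpredictable", "rt_easy", "rt_difficult")
                    if c in summary.columns],
        var_name="condition", value_name="rt")
    long_cond["condition"] = long_cond["condition"].str.removeprefix("rt_")
    condition_anova = inferential.mixed_rm_anova(
        long_cond, "rt", ["condition"], "group",
        sphericity_correction=config.sphericity_correction)

    surp_cols = [f"rt_{c}_{lab}" for c in PREDICTABLE for lab in ("surprising", "unsurprising")]
    long_surp = summary.melt(id_vars=["participant", "group"], value_vars=surp_cols,
                             var_name="cell", value_name="rt")
    parts = long_surp["cell"].str.split("_", expand=True)
    long_surp["condition"], long_surp["surprise"] = parts[1], parts[2]
    surprise_anova = inferential.mixed_rm_anova(
        long_surp, "rt", ["surprise", "condition"], "group",
        sphericity_correction=config.sphericity_correction)

    posthoc = inferential.bonferroni_posthoc(
        summary, [c for c in ("rt_easy", "rt_difficult", "rt_unpredictable")
                  if c in summary.columns])

    slowing_tests = {}
    for cond in PREDICTABLE:
        col = f"slowing_{cond}"
        if col not in summary.columns:
            continue
        g = sorted(summary["group"].unique())
        if len(g) == 2:
            x = summary.loc[summary["group"] == g[0], col].dropna()
            y = summary.loc[summary["group"] == g[1], col].dropna()
            res = inferential.independent_t(x, y)
            bf = inferential.jzs_bf_ttest(res.statistic, len(x), len(y), r_scale=config.r_scale)
            res.bf10, res.bf01 = bf.bf10, bf.bf01
            res.name = f"group difference in surprise slowing ({cond})"
            slowing_tests[cond] = res

    betas = trialwise.fit_cohort(trials)
    beta_tests = trialwise.group_level(betas, r_scale=config.r_scale)

    seq_df = summary.dropna(subset=["slowing_easy"])
    sequential = inferential.sequential_bf(
        seq_df["slowing_easy"].to_numpy(), seq_df["group"].to_numpy(),
        r_scale=config.r_scale)

    inclusion = {}
    if with_inclusion_bf:
        inclusion["condition"] = inferential.bf_inclusion(
            long_cond, "rt", ["condition", "group"])

    return AnalysisOutputs(trials, summary, condition_anova, surprise_anova,
                           posthoc, slowing_tests, betas, beta_tests,
                           sequential, inclusion)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, with_inclusion_bf: bool = False) -> dict:
    """Simulate a cohort under ``config`` and run the full analysis.

    Writes trials, summary, statistics and regression tables plus a manifest
    (config, package version, content hashes) under ``config.out_dir`` and
    returns the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = simulate.simulate_cohort(
        scenario=config.scenario, n_asd=config.n_asd, n_control=config.n_control,
        seed=config.seed, p_high=config.p_high, threshold=config.threshold,
        block_order=config.block_order, alpha=config.alpha,
        n_trials_per_block=config.n_trials_per_block)
    res = analyze_trials(trials, config, with_inclusion_bf=with_inclusion_bf)

    files = {
        "trials.csv": res.trials[TRIAL_COLUMNS + ["surprise"]],
        "participant_summary.csv": res.summary,
        "condition_anova.csv": results_frame(res.condition_anova),
        "surprise_anova.csv": results_frame(res.surprise_anova),
        "posthoc_condition.csv": results_frame(res.posthoc_condition),
        "slowing_group_tests.csv": results_frame(list(res.slowing_group_tests.values())),
        "trialwise_betas.csv": res.betas,
        "trialwise_group_tests.csv": results_frame(res.beta_tests),
        "sequential_bf.csv": res.sequential,
    }
    for name, df in files.items():
        _write_csv(df, out / name)
    if res.inclusion:
        (out / "inclusion_bf.json").write_text(json.dumps(res.inclusion, indent=2))

    from importlib.metadata import version
    try:
        pkg_version = version("srtlearn")
    except Exception:  # not installed as a distribution
        pkg_version = "unknown"
    manifest = {
        "config": config.to_dict(),
        "package_version": pkg_version,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def analyze_external(
    trials_path: str | Path,
    config: RunConfig | None = None,
    column_map: dict[str, str] | None = None,
) -> AnalysisOutputs:
    """Run all post-simulation stages on an external trial-level CSV.

    ``column_map`` translates foreign headers to the documented schema
    (foreign name -> schema name).  Missing required columns raise a
    descriptive error before any stage runs.
    """
    config = config or RunConfig()
    path = Path(trials_path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    trials = read_trials(path)
    if column_map:
        trials = trials.rename(columns=column_map)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(
            f"external table does not match the trial schema; missing columns: {missing}")
    return analyze_trials(trials, config)


def reproduce_table1() -> pd.DataFrame:
    """Recompute the cohort demographic comparisons from their summary statistics."""
    res = demographic_comparisons()
    rows = []
    for key, r in res.items():
        rows.append({"measure": key,
                     "test": "chi-square" if key == "gender" else "pooled t",
                     "statistic": r.statistic, "df": r.df, "p": r.p})
    return pd.DataFrame(rows)
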