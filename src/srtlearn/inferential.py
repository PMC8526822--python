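"""Frequentist and Bayesian inferential battery for the sequence-learning task.

Covers mixed repeated-measures ANOVA (one between-subject factor, one or two
within-subject factors, unequal group sizes handled with Type III sums of
squares), Bonferroni-corrected post-hoc paired t-tests, independent t-tests
(pooled or Welch), 2x2 Pearson chi-square, JZS Bayes-factor t-tests with a
Cauchy prior on the standardized effect size, BIC-approximated inclusion
Bayes factors for ANOVA designs, sequential Bayes-factor monitoring, and
Pearson correlation with its simple-regression F.

The mixed ANOVA uses an orthonormal-contrast stratum decomposition: each
within-subject effect is projected onto per-subject contrast scores, within
which the group structure is a one-way layout with its own error term
(effect x subject within group).  Unweighted group means give Type III tests
of within effects when group sizes differ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

DEFAULT_R_SCALE = 0.707


@dataclass
class StatResult:
    """One test outcome in the reporting style of the task literature."""

    name: str
    statistic: float
    df: tuple | float
    p: float
    effect_size: float | None = None
    effect_size_type: str | None = None
    bf10: float | None = None
    bf01: float | None = None
    correction: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bf10 is not None and self.bf01 is None:
            self.bf01 = 1.0 / self.bf10
        if self.p is not None and not (0.0 <= self.p <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p}")

    def as_dict(self) -> dict:
        d = {
            "name": self.name, "statistic": self.statistic, "df": self.df, "p": self.p,
            "effect_size": self.effect_size, "effect_size_type": self.effect_size_type,
            "bf10": self.bf10, "bf01": self.bf01, "correction": self.correction,
        }
        d.update(self.extra)
        return d


def results_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# --------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# --------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal rows, each orthogonal to the unit vector."""
    h = np.linalg.qr(np.c_[np.ones(levels), np.eye(levels)[:, : levels - 1]])[0]
    return h[:, 1:].T


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    between: str,
    subject: str = "participant",
    sphericity_correction: bool = False,
) -> list[StatResult]:
    """Mixed-design repeated-measures ANOVA.

    ``data`` is long format with one row per subject x within-cell; every
    subject must have every within-cell exactly once (subjects with missing
    cells are excluded listwise).  Returns main effects and all interactions;
    within-subject effects are tested against their own effect-by-subject
    error stratum, the between factor against subjects-within-groups.

    Effect sizes: ``eta2`` is SS_effect over total SS (all strata); partial
    eta squared uses the effect's own error stratum.  With
    ``sphericity_correction`` Greenhouse-Geisser epsilon adjusts df and p of
    multi-df within effects.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")
    d = data[[subject, between, *within, dv]].dropna()
    levels = [sorted(d[w].unique()) for w in within]
    n_cells = int(np.prod([len(lv) for lv in levels]))
    # pivot to subject x cell matrix, listwise exclusion of incomplete subjects
    wide = d.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    cols = list(itertools.product(*levels)) if len(within) > 1 else levels[0]
    wide = wide.reindex(columns=cols)
    complete = wide.notna().all(axis=1)
    if not complete.all():
        wide = wide.loc[complete]
    groups = d.drop_duplicates(subject).set_index(subject)[between].loc[wide.index]
    glabels = sorted(groups.unique())
    n_g = np.array([(groups == g).sum() for g in glabels], dtype=float)
    if len(glabels) < 2 or n_g.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    y = wide.to_numpy()                      # (N, n_cells)
    n_subj = y.shape[0]
    gidx = np.array([glabels.index(g) for g in groups])

    c_mats = [_orthonormal_contrasts(len(lv)) for lv in levels]
    u_vecs = [np.full((1, len(lv)), 1.0 / math.sqrt(len(lv))) for lv in levels]

    def _proj(which: tuple[bool, ...]) -> np.ndarray:
        mats = [c_mats[k] if use else u_vecs[k] for k, use in enumerate(which)]
        m = mats[0]
        for nxt in mats[1:]:
            m = np.kron(m, nxt)
        return m

    ss_entries: list[dict] = []
    total_ss = 0.0

    # between-subject stratum: scaled subject means
    z = y @ _proj(tuple(False for _ in within)).T  # (N, 1)
    zbar_g = np.array([z[gidx == k].mean(axis=0) for k in range(len(glabels))])
    zbar_w = (n_g[:, None] * zbar_g).sum(axis=0) / n_g.sum()
    ss_group = float((n_g[:, None] * (zbar_g - zbar_w) ** 2).sum())
    ss_err_between = float(((z - zbar_g[gidx]) ** 2).sum())
    df_group, df_err_between = len(glabels) - 1, n_subj - len(glabels)
    total_ss += ss_group + ss_err_between
    ss_entries.append(dict(name=between, ss=ss_group, df=df_group,
                           ss_err=ss_err_between, df_err=df_err_between, eps=1.0))

    # one stratum per nonempty within-effect subset
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            which = tuple(k in combo for k in range(len(within)))
            scores = y @ _proj(which).T          # (N, d_w)
            d_w = scores.shape[1]
            if d_w == 0:  # single-level within factor: nothing to test
                continue
            sbar_g = np.array([scores[gidx == k].mean(axis=0) for k in range(len(glabels))])
            sbar_u = sbar_g.mean(axis=0)          # unweighted: Type III
            sbar_w = (n_g[:, None] * sbar_g).sum(axis=0) / n_g.sum()
            resid = scores - sbar_g[gidx]
            ss_err = float((resid ** 2).sum())
            df_err = (n_subj - len(glabels)) * d_w
            ss_main = float((sbar_u ** 2).sum()) * len(glabels) ** 2 / (1.0 / n_g).sum()
            ss_int = float((n_g[:, None] * (sbar_g - sbar_w) ** 2).sum())
            eps = 1.0
            if sphericity_correction and d_w > 1:
                s_pool = resid.T @ resid / (n_subj - len(glabels))
                eps = float(np.trace(s_pool) ** 2 / (d_w * np.trace(s_pool @ s_pool)))
                eps = min(max(eps, 1.0 / d_w), 1.0)
            wname = " * ".join(within[k] for k in combo)
            total_ss += ss_main + ss_int + ss_err
            ss_entries.append(dict(name=wname, ss=ss_main, df=d_w,
                                   ss_err=ss_err, df_err=df_err, eps=eps))
            ss_entries.append(dict(name=f"{wname} * {between}", ss=ss_int,
                                   df=(len(glabels) - 1) * d_w,
                                   ss_err=ss_err, df_err=df_err, eps=eps))

    results = []
    for e in ss_entries:
        ms, ms_err = e["ss"] / e["df"], e["ss_err"] / e["df_err"]
        f_val = ms / ms_err
        df1, df2 = e["df"] * e["eps"], e["df_err"] * e["eps"]
        p = float(stats.f.sf(f_val, df1, df2))
        results.append(StatResult(
            name=e["name"], statistic=f_val, df=(df1, df2), p=p,
            effect_size=e["ss"] / total_ss, effect_size_type="eta2",
            correction="greenhouse-geisser" if e["eps"] < 1.0 else None,
            extra={"partial_eta2": e["ss"] / (e["ss"] + e["ss_err"]),
                   "ss": e["ss"], "ss_error": e["ss_err"]},
        ))
    return results


# --------------------------------------------------------------------------
# t-tests and chi-square
# --------------------------------------------------------------------------

def cohens_d_paired(diff: np.ndarray) -> float:
    return float(np.mean(diff) / np.std(diff, ddof=1))


def bonferroni_posthoc(
    summary: pd.DataFrame, cells: list[str], r_scale: float = DEFAULT_R_SCALE,
    with_bf: bool = False,
) -> list[StatResult]:
    """All pairwise paired t-tests between summary columns, Bonferroni-corrected."""
    if len(cells) < 2:
        raise ValueError("need at least 2 cells for post-hoc comparisons")
    pairs = list(itertools.combinations(cells, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        sub = summary[[a, b]].dropna()
        if len(sub) != len(summary):
            raise ValueError(f"unequal pairing between {a} and {b}")
        diff = sub[a].to_numpy() - sub[b].to_numpy()
        n = len(diff)
        sd = np.std(diff, ddof=1)
        if sd == 0:
            t_val, p = 0.0, 1.0
        else:
            t_val = float(np.mean(diff) / (sd / math.sqrt(n)))
            p = float(2 * stats.t.sf(abs(t_val), n - 1))
        res = StatResult(
            name=f"{a} vs {b}", statistic=t_val, df=n - 1, p=min(m * p, 1.0),
            effect_size=cohens_d_paired(diff) if sd > 0 else 0.0,
            effect_size_type="cohen_d", correction=f"bonferroni x{m}",
            extra={"p_uncorrected": p, "mean_difference": float(np.mean(diff))},
        )
        if with_bf:
            res.bf10 = jzs_bf_ttest(t_val, n, r_scale=r_scale).bf10
            res.bf01 = 1.0 / res.bf10
        out.append(res)
    return out


def independent_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> StatResult:
    """Independent-samples t from summary statistics; t = (mean1 - mean2) / SE."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        d = (mean1 - mean2) / math.sqrt(sp2)
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        d = (mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t_val = (mean1 - mean2) / se
    p = float(2 * stats.t.sf(abs(t_val), df))
    return StatResult(name="independent t", statistic=t_val, df=df, p=p,
                      effect_size=d, effect_size_type="cohen_d",
                      extra={"variant": variant})


def independent_t(x, y, variant: str = "pooled") -> StatResult:
    """Independent-samples t from raw vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return independent_t_from_stats(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y), variant=variant,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    cells = np.array([[a, b], [c, d]], dtype=float)
    if np.any(cells < 0) or not np.allclose(cells, np.round(cells)):
        raise ValueError("cells must be nonnegative integers")
    if np.any(cells.sum(axis=0) == 0) or np.any(cells.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(cells, correction=False)
    n = cells.sum()
    return StatResult(name="chi-square 2x2", statistic=float(chi2), df=dof, p=float(p),
                      effect_size=float(math.sqrt(chi2 / n)), effect_size_type="phi",
                      extra={"n": int(n)})


# --------------------------------------------------------------------------
# JZS Bayes factors
# --------------------------------------------------------------------------

def jzs_bf_ttest(
    t: float, n1: int, n2: int | None = None, r_scale: float = DEFAULT_R_SCALE,
) -> StatResult:
    """JZS Bayes factor for a t statistic (Cauchy prior on effect size delta).

    One-sample/paired when ``n2`` is None (effective n = n1, df = n1 - 1);
    independent two-sample otherwise (effective n = n1 n2 / (n1 + n2),
    df = n1 + n2 - 2).  BF10 is the marginal likelihood of t under
    delta ~ Cauchy(0, r_scale) divided by its density under delta = 0,
    computed by adaptive quadrature over the prior.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        nu, n_eff = n1 - 1, float(n1)
    else:
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per group")
        nu, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    sqrt_n = math.sqrt(n_eff)
    d_hat = t / sqrt_n
    # integration window covers the likelihood peak and the bulk of the prior;
    # outside it the noncentral-t likelihood is numerically zero
    sd_lik = math.sqrt((1.0 + t * t / (2.0 * nu)) / n_eff)
    lo = min(d_hat - 12.0 * sd_lik, -10.0 * r_scale)
    hi = max(d_hat + 12.0 * sd_lik, 10.0 * r_scale)

    def simpson_at(n_pts: int) -> float:
        grid = np.linspace(lo, hi, n_pts)
        dens = stats.nct.pdf(t, nu, grid * sqrt_n) * stats.cauchy.pdf(grid, 0.0, r_scale)
        return float(integrate.simpson(dens, x=grid))

    num_prev, num = simpson_at(513), simpson_at(1025)
    n_pts = 1025
    while abs(num - num_prev) > 1e-7 * max(num, 1e-300) and n_pts < 70_000:
        n_pts = 2 * n_pts - 1
        num_prev, num = num, simpson_at(n_pts)
    den = float(stats.t.pdf(t, nu))
    if den <= 0 or num <= 0 or not np.isfinite(num) or (
            abs(num - num_prev) > 1e-5 * num):
        raise ArithmeticError(
            f"JZS integration did not converge (num={num}, prev={num_prev}, "
            f"den={den}) at t={t}, nu={nu}, n_eff={n_eff}"
        )
    bf10 = num / den
    return StatResult(name="jzs t-test", statistic=t, df=nu, p=float(2 * stats.t.sf(abs(t), nu)),
                      bf10=bf10, extra={"r_scale": r_scale, "n_eff": n_eff})


# --------------------------------------------------------------------------
# inclusion Bayes factors (BIC approximation over a marginality-closed space)
# --------------------------------------------------------------------------

def _effect_space(factors: list[str]) -> list[tuple[str, ...]]:
    effects = []
    for r in range(1, len(factors) + 1):
        effects.extend(itertools.combinations(factors, r))
    return effects


def _models(effects: list[tuple[str, ...]], cap: int = 256) -> list[frozenset]:
    """All subsets of the effect space closed under marginality (an
    interaction never appears without all of its lower-order terms)."""
    models = []
    for bits in itertools.product([0, 1], repeat=len(effects)):
        m = frozenset(e for e, b in zip(effects, bits) if b)
        marginal_ok = all(
            sub in m
            for e in m
            for r in range(1, len(e))
            for sub in itertools.combinations(e, r)
        )
        if marginal_ok:
            models.append(m)
    if len(models) > cap:
        raise ValueError(f"model space of {len(models)} exceeds cap {cap}; reduce the design")
    return models


def _sum_code(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    k = len(levels)
    m = np.zeros((len(values), k - 1))
    for row, v in enumerate(values):
        j = levels.index(v)
        if j < k - 1:
            m[row, j] = 1.0
        else:
            m[row, :] = -1.0
    return m


def _random_intercept_ml(y: np.ndarray, x: np.ndarray, subj_idx: np.ndarray) -> float:
    """Maximised log-likelihood of y = X b + u_subject + e (ML, not REML).

    Profiles the fixed effects and residual variance in closed form via GLS
    for a given variance ratio theta = var(u)/var(e), then maximises over
    theta by bounded 1-D search.  V_s^{-1} = I - theta/(1 + theta m_s) J for
    a subject with m_s rows, so no matrix larger than the design is formed.
    """
    from scipy.optimize import minimize_scalar

    n = len(y)
    n_subj = subj_idx.max() + 1
    m_s = np.bincount(subj_idx, minlength=n_subj).astype(float)

    def neg_ll(log_theta: float) -> float:
        theta = math.exp(log_theta)
        w = theta / (1.0 + theta * m_s)           # per-subject shrinkage
        sx = np.zeros((n_subj, x.shape[1]))
        sy = np.zeros(n_subj)
        np.add.at(sx, subj_idx, x)
        np.add.at(sy, subj_idx, y)
        xtvx = x.T @ x - (sx * w[:, None]).T @ sx
        xtvy = x.T @ y - (sx * w[:, None]).T @ sy
        beta = np.linalg.solve(xtvx, xtvy)
        r = y - x @ beta
        sr = np.zeros(n_subj)
        np.add.at(sr, subj_idx, r)
        quad = r @ r - w @ sr**2
        sigma2 = quad / n
        logdet = np.log1p(theta * m_s).sum()
        return 0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)

    # include the theta -> 0 (pure OLS) limit in the search
    best = min(neg_ll(lt) for lt in (-30.0,))
    opt = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    return -min(best, float(opt.fun))


def bf_inclusion(
    data: pd.DataFrame,
    dv: str,
    factors: list[str],
    subject: str = "participant",
    cap: int = 256,
) -> dict[str, float]:
    """Matched-model inclusion Bayes factor per effect of an ANOVA design.

    Enumerates all fixed-effect models over the factors (main effects and
    interactions) that respect marginality, each with a random intercept per
    subject; approximates each model's marginal likelihood by exp(-BIC/2)
    from an ML mixed-model fit; and reports, per effect, the posterior-odds
    ratio of matched models with versus without that effect divided by the
    corresponding prior odds (uniform prior over models).
    """
    effects = _effect_space(factors)
    models = _models(effects, cap=cap)
    d = data.dropna(subset=[dv]).reset_index(drop=True)
    yv = d[dv].to_numpy(dtype=float)
    codes = {f: _sum_code(d[f]) for f in factors}
    subj_idx = pd.factorize(d[subject])[0]

    def design(model: frozenset) -> np.ndarray:
        cols = [np.ones((len(d), 1))]
        for e in sorted(model, key=lambda e: (len(e), e)):
            block = codes[e[0]]
            for f in e[1:]:
                block = np.concatenate(
                    [block[:, [i]] * codes[f] for i in range(block.shape[1])], axis=1)
            cols.append(block)
        return np.concatenate(cols, axis=1)

    log_ml = {}
    for m in models:
        x = design(m)
        llf = _random_intercept_ml(yv, x, subj_idx)
        k = x.shape[1] + 2  # fixed effects + random-intercept var + residual var
        bic = -2.0 * llf + k * math.log(len(d))
        log_ml[m] = -bic / 2.0
    mx = max(log_ml.values())
    post = {m: math.exp(v - mx) for m, v in log_ml.items()}

    out = {}
    for e in effects:
        supers = [o for o in effects if set(e) < set(o)]
        subs = [o for o in effects if set(o) < set(e)]
        matched = [m for m in models
                   if not any(s in m for s in supers) and all(s in m for s in subs)]
        with_e = [m for m in matched if e in m]
        without_e = [m for m in matched if e not in m]
        if not with_e or not without_e:
            continue
        post_odds = sum(post[m] for m in with_e) / sum(post[m] for m in without_e)
        prior_odds = len(with_e) / len(without_e)
        out[" * ".join(e)] = post_odds / prior_odds
    return out


# --------------------------------------------------------------------------
# sequential Bayes-factor monitoring and correlation
# --------------------------------------------------------------------------

def sequential_bf(
    values: np.ndarray,
    groups: np.ndarray,
    order: np.ndarray | None = None,
    r_scale: float = DEFAULT_R_SCALE,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """BF01 of the two-group comparison recomputed at each accrual step.

    Rows: total n, per-group n, t, BF01.  Attributes ``first_n_above`` (first
    total n with BF01 >= threshold) and ``stays_above`` (whether it stays at
    or above threshold from that point on) are attached to ``df.attrs``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    order = np.arange(len(values)) if order is None else np.asarray(order)
    glabels = sorted(pd.unique(groups))
    if len(glabels) != 2:
        raise ValueError("sequential BF needs exactly 2 groups")
    rows = []
    for step in range(len(order)):
        sel = order[: step + 1]
        v, g = values[sel], groups[sel]
        x, y = v[g == glabels[0]], v[g == glabels[1]]
        if min(len(x), len(y)) < 2:
            continue
        res = independent_t(x, y)
        if not np.isfinite(res.statistic):
            continue  # degenerate variance at small n
        bf = jzs_bf_ttest(res.statistic, len(x), len(y), r_scale=r_scale)
        rows.append({"n_total": len(v), "n1": len(x), "n2": len(y),
                     "t": res.statistic, "bf01": bf.bf01, "bf10": bf.bf10})
    df = pd.DataFrame(rows)
    above = df["bf01"] >= threshold
    first = int(df.loc[above, "n_total"].iloc[0]) if above.any() else None
    stays = bool(above[above.idxmax():].all()) if above.any() else False
    df.attrs["first_n_above"] = first
    df.attrs["stays_above"] = stays
    return df


def symptom_correlation(scores, index_values) -> StatResult:
    """Pearson r with the equivalent simple-regression F = t^2, df (1, n-2)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(index_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined with zero variance")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    f_val = r**2 * (n - 2) / (1 - r**2) if abs(r) < 1 else float("inf")
    return StatResult(name="pearson r", statistic=float(r), df=(1, n - 2), p=float(p),
                      effect_size=float(r), effect_size_type="r",
                      extra={"F": float(f_val)})


# --------------------------------------------------------------------------
# demographic group comparisons from cohort summary statistics
# --------------------------------------------------------------------------

#: Published cohort demographics of the motor sequence-learning study this
#: pipeline reimplements (mean, SD per group; gender as male:female counts).
STUDY_DEMOGRAPHICS: dict = {
    "n": {"control": 35, "ASD": 28},
    "gender_mf": {"control": (22, 13), "ASD": (13, 15)},
    "age": {"control": (27.6, 10.5), "ASD": (29.8, 10.2)},
    "training_trials": {"control": (178.86, 177.16), "ASD": (222.86, 133.19)},
    "iq": {"control": (107.51, 13.17), "ASD": (108.679, 16.31)},
    "aq": {"control": (15.09, 8.42), "ASD": (36.46, 8.08)},
    "tas": {"control": (43.03, 10.67), "ASD": (64.11, 10.51)},
}


def demographic_comparisons(demographics: dict | None = None) -> dict[str, StatResult]:
    """Group comparisons on cohort demographics: 2x2 chi-square for gender,
    pooled-variance independent t (ASD minus control) for continuous measures."""
    demo = STUDY_DEMOGRAPHICS if demographics is None else demographics
    n_c, n_a = demo["n"]["control"], demo["n"]["ASD"]
    out: dict[str, StatResult] = {}
    cm, cf = demo["gender_mf"]["control"]
    am, af = demo["gender_mf"]["ASD"]
    out["gender"] = chi_square_2x2(cm, cf, am, af)
    for key in demo:
        if key in ("n", "gender_mf"):
            continue
        (m_c, s_c), (m_a, s_a) = demo[key]["control"], demo[key]["ASD"]
        out[key] = independent_t_from_stats(m_a, s_a, n_a, m_c, s_c, n_c, variant="pooled")
        out[key].name = f"independent t: {key}"
    return out
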