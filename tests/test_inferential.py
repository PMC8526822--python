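"""Statistical battery: ANOVA, t-tests, chi-square, Bayes factors, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from srtlearn import inferential as inf
from srtlearn.inferential import (
    StatResult,
    bf_inclusion,
    bonferroni_posthoc,
    chi_square_2x2,
    demographic_comparisons,
    independent_t,
    independent_t_from_stats,
    jzs_bf_ttest,
    mixed_rm_anova,
    sequential_bf,
    symptom_correlation,
)


def _toy_mixed(n1=3, n2=3, seed=0, effect=5.0, group_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n1 + n2):
        g = "g1" if s < n1 else "g2"
        base = rng.normal(0, 4)
        for k, c in enumerate(["a", "b", "c"]):
            rows.append(dict(
                participant=f"s{s}", group=g, condition=c,
                rt=600 + base + k * effect + (group_effect if g == "g2" else 0)
                + rng.normal(0, 2)))
    return pd.DataFrame(rows)


def anova_ss_oracle(df):
    """Brute-force sums-of-squares decomposition for the balanced 2-group,
    one-within-factor design (explicit textbook arithmetic)."""
    wide = df.pivot(index="participant", columns="condition", values="rt")
    grp = df.drop_duplicates("participant").set_index("participant")["group"].loc[wide.index]
    y = wide.to_numpy()
    n, a = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    glab = sorted(grp.unique())
    gmask = [grp.to_numpy() == g for g in glab]
    group_means = [y[m].mean() for m in gmask]
    ss_group = a * sum(m.sum() * (gm - grand) ** 2 for m, gm in zip(gmask, group_means))
    ss_subj = a * sum((subj_means - [group_means[0] if m else group_means[1]
                                     for m in gmask[0]]) ** 2)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    cell = np.array([[y[m][:, k].mean() for k in range(a)] for m in gmask])
    ss_int = sum(m.sum() * ((cell[i] - group_means[i] - cond_means + grand) ** 2).sum()
                 for i, m in enumerate(gmask))
    cell_of_subj = np.array([cell[0] if m else cell[1] for m in gmask[0]])
    gmean_of_subj = np.array([group_means[0] if m else group_means[1] for m in gmask[0]])
    ss_err = ((y - subj_means[:, None] - cell_of_subj + gmean_of_subj[:, None]) ** 2).sum()
    f_group = (ss_group / 1) / (ss_subj / (n - 2))
    f_cond = (ss_cond / (a - 1)) / (ss_err / ((n - 2) * (a - 1)))
    f_int = (ss_int / (a - 1)) / (ss_err / ((n - 2) * (a - 1)))
    return f_group, f_cond, f_int


class TestMixedAnova:
    def test_matches_ss_oracle_on_balanced_toy(self):
        df = _toy_mixed(3, 3, seed=5, effect=6.0, group_effect=3.0)
        res = {r.name: r.statistic for r in mixed_rm_anova(df, "rt", ["condition"], "group")}
        f_group, f_cond, f_int = anova_ss_oracle(df)
        assert res["group"] == pytest.approx(f_group, abs=1e-9)
        assert res["condition"] == pytest.approx(f_cond, abs=1e-9)
        assert res["condition * group"] == pytest.approx(f_int, abs=1e-9)

    def test_location_invariance(self):
        df = _toy_mixed(4, 3, seed=1)
        shifted = df.assign(rt=df["rt"] + 100.0)
        a = mixed_rm_anova(df, "rt", ["condition"], "group")
        b = mixed_rm_anova(shifted, "rt", ["condition"], "group")
        for ra, rb in zip(a, b):
            assert ra.statistic == pytest.approx(rb.statistic)
            assert ra.p == pytest.approx(rb.p)
            assert ra.effect_size == pytest.approx(rb.effect_size)

    def test_unbalanced_groups_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_mixed(5, 8, seed=2, effect=4.0, group_effect=2.0)
        res = {r.name: r for r in mixed_rm_anova(df, "rt", ["condition"], "group")}
        aov = pg.mixed_anova(df, dv="rt", within="condition", between="group",
                             subject="participant").set_index("Source")
        # group and interaction F agree exactly; the within main effect is
        # Type III here (unweighted means) while pingouin pools, so compare
        # those two only
        assert res["group"].statistic == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert res["condition * group"].statistic == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)
        assert res["group"].extra["partial_eta2"] == pytest.approx(
            aov.loc["group", "np2"], rel=1e-9)

    def test_between_f_equals_squared_t_with_single_within_level(self):
        rng = np.random.default_rng(3)
        rows = [dict(participant=f"s{k}", group="g1" if k < 10 else "g2",
                     condition="only", rt=rng.normal(600 + (5 if k < 10 else 0), 10))
                for k in range(22)]
        df = pd.DataFrame(rows)
        res = mixed_rm_anova(df, "rt", ["condition"], "group")
        assert len(res) == 1
        t = independent_t(df.loc[df.group == "g1", "rt"], df.loc[df.group == "g2", "rt"])
        assert res[0].statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_three_way_design_runs_and_partitions(self, small_summary):
        cols = [f"rt_{c}_{s}" for c in ("easy", "difficult")
                for s in ("surprising", "unsurprising")]
        long = small_summary.melt(id_vars=["participant", "group"], value_vars=cols,
                                  var_name="cell", value_name="rt")
        parts = long["cell"].str.split("_", expand=True)
        long["condition"], long["surprise"] = parts[1], parts[2]
        res = mixed_rm_anova(long, "rt", ["surprise", "condition"], "group")
        names = {r.name for r in res}
        assert names == {"group", "surprise", "surprise * group", "condition",
                         "condition * group", "surprise * condition",
                         "surprise * condition * group"}
        total_eta = sum(r.effect_size for r in res)
        assert 0 < total_eta < 1  # error strata absorb the rest

    def test_null_group_p_uniform_over_replicates(self):
        """Type-I calibration: under a true null the group-effect p-value is
        uniform across simulated replicates."""
        ps = []
        for seed in range(200):
            df = _toy_mixed(6, 7, seed=seed, effect=5.0, group_effect=0.0)
            res = {r.name: r for r in mixed_rm_anova(df, "rt", ["condition"], "group")}
            ps.append(res["group"].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPosthocAndT:
    def test_three_cells_three_comparisons_with_bonferroni(self):
        rng = np.random.default_rng(0)
        summ = pd.DataFrame({
            "a": rng.normal(600, 10, 12), "b": rng.normal(610, 10, 12),
            "c": rng.normal(620, 10, 12)})
        res = bonferroni_posthoc(summ, ["a", "b", "c"])
        assert len(res) == 3
        for r in res:
            assert r.p == pytest.approx(min(3 * r.extra["p_uncorrected"], 1.0))
            assert r.p >= r.extra["p_uncorrected"]

    def test_identical_cells_null_result(self):
        summ = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        r = bonferroni_posthoc(summ, ["a", "b"])[0]
        assert r.statistic == 0.0 and r.p == 1.0

    def test_paired_t_and_d_hand_computed(self):
        a = np.array([650.0, 660.0, 700.0, 640.0])
        b = np.array([600.0, 630.0, 660.0, 625.0])
        diff = a - b
        t_hand = diff.mean() / (diff.std(ddof=1) / 2)
        d_hand = diff.mean() / diff.std(ddof=1)
        r = bonferroni_posthoc(pd.DataFrame({"a": a, "b": b}), ["a", "b"])[0]
        assert r.statistic == pytest.approx(t_hand, abs=1e-12)
        assert r.effect_size == pytest.approx(d_hand, abs=1e-12)

    @given(st.integers(0, 10**6))
    def test_bonferroni_never_decreases_p(self, seed):
        rng = np.random.default_rng(seed)
        summ = pd.DataFrame(rng.normal(0, 1, (6, 3)), columns=["a", "b", "c"])
        for r in bonferroni_posthoc(summ, ["a", "b", "c"]):
            assert r.p >= r.extra["p_uncorrected"] - 1e-15

    def test_identical_groups_t_zero(self):
        r = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0

    def test_matches_scipy_on_raw_vectors(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        mine = independent_t(x, y)
        ref_t, ref_p = stats.ttest_ind(x, y)
        assert mine.statistic == pytest.approx(ref_t)
        assert mine.p == pytest.approx(ref_p)
        mine_w = independent_t(x, y, variant="welch")
        ref_wt, ref_wp = stats.ttest_ind(x, y, equal_var=False)
        assert mine_w.statistic == pytest.approx(ref_wt)
        assert mine_w.p == pytest.approx(ref_wp)


class TestChiSquare:
    def test_cohort_gender_table(self):
        r = chi_square_2x2(22, 13, 13, 15)
        assert r.statistic == pytest.approx(1.700, abs=5e-4)
        assert r.p == pytest.approx(0.192, abs=5e-4)

    def test_independent_table_zero(self):
        assert chi_square_2x2(10, 10, 10, 10).statistic == 0.0

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_matches_direct_formula(self, cells):
        a, b, c, d = cells
        obs = np.array([[a, b], [c, d]], dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert chi_square_2x2(a, b, c, d).statistic == pytest.approx(chi2_hand, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestJZSBayesFactor:
    def test_null_t_supports_null(self):
        assert jzs_bf_ttest(0.0, 30, 30).bf10 < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf_ttest(t, 35, 28).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)

    def test_diverges_for_large_t(self):
        assert jzs_bf_ttest(12.0, 35, 28).bf10 > 1e8

    def test_bf01_is_reciprocal(self):
        r = jzs_bf_ttest(1.3, 20, 24)
        assert r.bf10 * r.bf01 == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.5])
    @pytest.mark.parametrize("n1,n2", [(35, 28), (12, 12)])
    def test_dense_grid_quadrature_oracle(self, t, n1, n2):
        nu, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
        grid = np.linspace(-12, 12, 240_001)
        dens = stats.nct.pdf(t, nu, grid * math.sqrt(n_eff)) * stats.cauchy.pdf(grid, 0, 0.707)
        ref = np.trapezoid(dens, grid) / stats.t.pdf(t, nu)
        mine = jzs_bf_ttest(t, n1, n2, r_scale=0.707).bf10
        assert mine == pytest.approx(ref, rel=1e-4)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n1, n2 in [(0.8, 35, 28), (2.4, 15, 18)]:
            ref = float(pg.bayesfactor_ttest(t, n1, n2, paired=False, r=0.707))
            assert jzs_bf_ttest(t, n1, n2).bf10 == pytest.approx(ref, rel=1e-6)
        ref1 = float(pg.bayesfactor_ttest(1.5, 25, paired=True, r=0.707))
        assert jzs_bf_ttest(1.5, 25).bf10 == pytest.approx(ref1, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(float("nan"), 10, 10)
        with pytest.raises(ValueError):
            jzs_bf_ttest(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf_ttest(1.0, 10, 10, r_scale=0.0)


class TestInclusionBF:
    def test_two_model_space_reduces_to_pairwise_bic_bf(self):
        rng = np.random.default_rng(4)
        rows = [dict(participant=f"s{k}", g="g1" if k < 10 else "g2",
                     y=rng.normal(5 if k < 10 else 0, 2))
                for k in range(20)]
        df = pd.DataFrame(rows)
        incl = bf_inclusion(df, "y", ["g"])
        # direct pairwise BIC BF between null and one-effect model
        from srtlearn.inferential import _random_intercept_ml, _sum_code
        yv = df["y"].to_numpy()
        subj = pd.factorize(df["participant"])[0]
        x0 = np.ones((len(df), 1))
        x1 = np.c_[x0, _sum_code(df["g"])]
        bic0 = -2 * _random_intercept_ml(yv, x0, subj) + 3 * math.log(len(df))
        bic1 = -2 * _random_intercept_ml(yv, x1, subj) + 4 * math.log(len(df))
        assert incl["g"] == pytest.approx(math.exp((bic0 - bic1) / 2), rel=1e-6)

    def test_null_effects_below_one(self):
        rng = np.random.default_rng(9)
        below = 0
        for rep in range(6):
            rows = []
            for s in range(30):
                g = "g1" if s < 15 else "g2"
                for c in ["a", "b", "c"]:
                    rows.append(dict(participant=f"s{s}", group=g, condition=c,
                                     rt=rng.normal(600, 10)))
            incl = bf_inclusion(pd.DataFrame(rows), "rt", ["condition", "group"])
            below += sum(v < 1 for v in incl.values())
        assert below >= 0.7 * 6 * 3  # most effects unsupported under the null

    def test_strong_condition_effect_overwhelming(self):
        rng = np.random.default_rng(10)
        rows = []
        for s in range(63):
            g = "g1" if s < 35 else "g2"
            base = rng.normal(0, 10)
            for c, off in zip(["a", "b", "c"], [0, 10, 20]):
                rows.append(dict(participant=f"s{s}", group=g, condition=c,
                                 rt=600 + base + off + rng.normal(0, 5)))
        incl = bf_inclusion(pd.DataFrame(rows), "rt", ["condition", "group"])
        assert incl["condition"] > 100
        assert incl["group"] < 1

    def test_marginality_respected_in_model_space(self):
        effects = inf._effect_space(["a", "b"])
        models = inf._models(effects)
        assert frozenset([("a", "b")]) not in models
        assert frozenset([("a",), ("b",), ("a", "b")]) in models
        assert len(models) == 5


class TestSequentialBF:
    def test_final_step_equals_one_shot(self):
        rng = np.random.default_rng(6)
        vals = np.r_[rng.normal(50, 20, 30), rng.normal(45, 20, 25)]
        groups = np.array(["a"] * 30 + ["b"] * 25)
        curve = sequential_bf(vals, groups)
        t = independent_t(vals[groups == "a"], vals[groups == "b"]).statistic
        ref = jzs_bf_ttest(t, 30, 25).bf01
        assert curve["bf01"].iloc[-1] == pytest.approx(ref, rel=1e-9)

    def test_same_distribution_mostly_favours_null(self):
        rng = np.random.default_rng(7)
        finals = []
        for _ in range(40):
            vals = rng.normal(50, 15, 40)
            groups = np.array(["a", "b"] * 20)
            finals.append(sequential_bf(vals, groups)["bf01"].iloc[-1])
        assert np.median(finals) > 1.0

    def test_large_difference_rarely_plateaus_above_threshold(self):
        rng = np.random.default_rng(8)
        plateaued = 0
        for _ in range(40):
            vals = np.r_[rng.normal(0, 1, 32), rng.normal(1.2, 1, 31)]
            groups = np.array(["a"] * 32 + ["b"] * 31)
            order = rng.permutation(63)
            curve = sequential_bf(vals, groups, order=order)
            if curve.attrs["first_n_above"] is not None and curve.attrs["stays_above"]:
                plateaued += 1
        assert plateaued <= 0.05 * 40

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            sequential_bf(np.ones(5), np.array(["a"] * 5))


class TestCorrelation:
    def test_perfect_line(self):
        r = symptom_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r.statistic == pytest.approx(1.0)

    def test_f_identity_on_random_data(self, rng):
        x, y = rng.normal(0, 1, 28), rng.normal(0, 1, 28)
        res = symptom_correlation(x, y)
        r, n = res.statistic, 28
        assert res.extra["F"] == pytest.approx(r**2 * (n - 2) / (1 - r**2), rel=1e-12)
        assert res.df == (1, 26)

    def test_hand_computed_five_points(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([60.0, 55.0, 70.0, 80.0, 75.0])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert symptom_correlation(x, y).statistic == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            symptom_correlation([1, 1, 1], [2, 3, 4])


class TestDemographics:
    def test_group_comparisons_reproduce_reported_statistics(self):
        res = demographic_comparisons()
        assert res["gender"].statistic == pytest.approx(1.700, abs=5e-4)
        assert res["training_trials"].statistic == pytest.approx(1.090, abs=0.02)
        assert res["iq"].statistic == pytest.approx(0.314, abs=0.02)
        assert res["aq"].statistic == pytest.approx(10.196, abs=0.02)
        assert res["tas"].statistic == pytest.approx(7.842, abs=0.02)

    def test_statresult_bf_consistency(self):
        r = StatResult("x", 1.0, 10, 0.3, bf10=2.0)
        assert r.bf01 == pytest.approx(0.5)
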