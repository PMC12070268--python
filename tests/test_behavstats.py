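"""Behavioural statistics: ANOVA against a first-principles
sums-of-squares oracle, rank tests against exhaustive enumeration,
effect sizes, chi-square, power analysis and LOO correlations."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegbind import behavstats as bs
from eegbind import synthgen as sg


def table_from_matrix(values):
    """values[group][condition] -> list of per-subject scores."""
    rows = []
    for g, conds in values.items():
        n = len(next(iter(conds.values())))
        for i in range(n):
            for c, v in conds.items():
                rows.append(dict(subject=f"{g}{i:02d}", group=g, overlap=c, dv=v[i]))
    return pd.DataFrame(rows)


def anova_ss_oracle(y):
    """Split-plot sums-of-squares decomposition from first principles.

    y has shape (groups, subjects, conditions).  Returns F ratios for
    the between factor, within factor and interaction.
    """
    g, n, m = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=2)                    # (g, n)
    group_means = y.mean(axis=(1, 2))              # (g,)
    cond_means = y.mean(axis=(0, 1))               # (m,)
    cell_means = y.mean(axis=1)                    # (g, m)
    ss_group = n * m * ((group_means - grand) ** 2).sum()
    ss_subj_within = m * ((subj_means - group_means[:, None]) ** 2).sum()
    ss_cond = g * n * ((cond_means - grand) ** 2).sum()
    ss_inter = n * ((cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter
    df_sw, df_err = g * (n - 1), g * (n - 1) * (m - 1)
    return dict(
        group=(ss_group / (g - 1)) / (ss_subj_within / df_sw),
        overlap=(ss_cond / (m - 1)) / (ss_err / df_err),
        interaction=(ss_inter / ((g - 1) * (m - 1))) / (ss_err / df_err),
    )


class TestMixedAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        y = rng.normal(size=(2, 6, 2))
        y[1, :, 1] += 0.8  # some interaction
        values = {
            g: {c: y[gi, :, ci] for ci, c in enumerate(sg.CONDITIONS)}
            for gi, g in enumerate(sg.GROUPS)
        }
        table = table_from_matrix(values)
        res = bs.mixed_anova_2x2(table, "dv")
        oracle = anova_ss_oracle(y)
        for effect in ("group", "overlap", "interaction"):
            assert res[effect].F == pytest.approx(oracle[effect], rel=1e-6)
            assert res[effect].df1 == 1
            assert res[effect].df2 == 10

    def test_identical_group_means_f_near_zero(self, rng):
        base = rng.normal(size=(6, 2))
        y = np.stack([base, base])                 # groups identical
        values = {
            g: {c: y[gi, :, ci] for ci, c in enumerate(sg.CONDITIONS)}
            for gi, g in enumerate(sg.GROUPS)
        }
        res = bs.mixed_anova_2x2(table_from_matrix(values), "dv")
        assert res["group"].F == pytest.approx(0.0, abs=1e-10)

    def test_interaction_grows_with_effect(self, rng):
        fs = []
        for delta in (0.0, 0.5, 1.5):
            y = rng.normal(size=(2, 12, 2))
            y[1, :, 1] += delta
            values = {
                g: {c: y[gi, :, ci] for ci, c in enumerate(sg.CONDITIONS)}
                for gi, g in enumerate(sg.GROUPS)
            }
            fs.append(bs.mixed_anova_2x2(table_from_matrix(values), "dv")["interaction"].F)
        assert fs[0] < fs[2] and fs[1] < fs[2]

    def test_incomplete_design_rejected(self):
        table = table_from_matrix(
            {"NT": {c: np.arange(4.0) for c in sg.CONDITIONS}}
        )
        with pytest.raises(ValueError):
            bs.mixed_anova_2x2(table, "dv")


class TestEffectSizes:
    @pytest.mark.parametrize(
        "f,expected",
        [(462.87, 0.889), (12.93, 0.182), (18.54, 0.242), (7.61, 0.116), (14.67, 0.202)],
    )
    def test_partial_eta_sq_identity(self, f, expected):
        assert bs.partial_eta_sq(f, 1, 58) == pytest.approx(expected, abs=5e-4)

    def test_partial_eta_zero(self):
        assert bs.partial_eta_sq(0.0, 1, 58) == 0.0


class TestShapiroGate:
    def test_normal_quantiles_pass(self):
        x = stats.norm.ppf(np.linspace(0.02, 0.98, 30))
        gate = bs.shapiro_gate({"g": x})
        assert gate.parametric

    def test_bimodal_fails(self):
        x = np.concatenate([np.full(15, -3.0), np.full(15, 3.0)]) + \
            np.linspace(-0.01, 0.01, 30)
        gate = bs.shapiro_gate({"g": x})
        assert not gate.parametric

    def test_constant_degenerate(self):
        gate = bs.shapiro_gate({"g": np.full(10, 2.0)})
        assert not gate.parametric and gate.degenerate == ["g"]


class TestWelch:
    def test_equal_samples_zero(self, rng):
        x = rng.normal(size=12)
        res = bs.welch_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=14)
        res = bs.welch_t(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2

    def test_published_d_convention(self):
        """At equal n the pooled-SD d equals t*sqrt(2/n): the overlap
        difference t(47.7)=3.81 with n=30 per group gives d~0.98."""
        assert 3.81 * math.sqrt(2 / 30) == pytest.approx(0.982, abs=0.003)


def exact_mannwhitney_p(a, b):
    """Exhaustive enumeration of all group assignments; two-sided p of
    |U - mu| as extreme as observed."""
    pooled = np.concatenate([a, b])
    na = len(a)
    mu = na * len(b) / 2.0
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    return count / total


def exact_wilcoxon_p(d):
    """Exhaustive sign-flip enumeration; two-sided p of |W+ - mu|."""
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    mu = n * (n + 1) / 4.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / 2**n


class TestRankTests:
    @pytest.mark.parametrize("seed", range(6))
    def test_mann_whitney_approximation_vs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(5, 8), rng.integers(5, 8)
        a = np.round(rng.normal(0.4, 1.0, na), 1)  # rounding induces ties
        b = np.round(rng.normal(0.0, 1.0, nb), 1)
        res = bs.mann_whitney(a, b)
        p_exact = exact_mannwhitney_p(a, b)
        assert res.p == pytest.approx(p_exact, abs=0.17)
        if p_exact < 0.2:
            assert res.p == pytest.approx(p_exact, abs=0.06)

    @pytest.mark.parametrize("seed", range(6))
    def test_wilcoxon_approximation_vs_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 8))
        d = np.round(rng.normal(0.5, 1.0, n), 1)
        if (d == 0).all():
            d[0] = 0.5
        res = bs.wilcoxon_signed_rank(d)
        p_exact = exact_wilcoxon_p(d)
        assert res.p == pytest.approx(p_exact, abs=0.17)
        if p_exact < 0.2:
            assert res.p == pytest.approx(p_exact, abs=0.06)

    def test_mann_whitney_z_sign_follows_shift(self, rng):
        a = rng.normal(2.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        assert bs.mann_whitney(a, b).z > 0
        assert bs.mann_whitney(b, a).z < 0

    def test_wilcoxon_symmetric_null_z_small(self, rng):
        d = rng.normal(0.0, 1.0, 200)
        assert abs(bs.wilcoxon_signed_rank(d).z) < 2.5

    def test_wilcoxon_all_zero_degenerate(self):
        res = bs.wilcoxon_signed_rank(np.zeros(10))
        assert res.z == 0.0 and res.p == 1.0

    def test_mann_whitney_u_matches_scipy(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=11)
        res = bs.mann_whitney(a, b)
        assert res.statistic == stats.mannwhitneyu(a, b).statistic


class TestOverlapEffect:
    def test_difference_and_antisymmetry(self):
        table = sg.simulate_behavior(10, seed=0)
        eff = bs.overlap_effect(table, "fa_rate")
        wide = table.pivot(index="subject", columns="overlap", values="fa_rate")
        np.testing.assert_allclose(
            eff, wide["overlapping"] - wide["non-overlapping"]
        )

    def test_arithmetic(self):
        table = pd.DataFrame([
            dict(subject="s", group="GTS", overlap="overlapping", fa_rate=0.35),
            dict(subject="s", group="GTS", overlap="non-overlapping", fa_rate=0.02),
        ])
        assert bs.overlap_effect(table).iloc[0] == pytest.approx(0.33)

    def test_missing_condition_error(self):
        table = pd.DataFrame([
            dict(subject="s", group="GTS", overlap="overlapping", fa_rate=0.35),
        ])
        with pytest.raises(ValueError):
            bs.overlap_effect(table)


class TestChiSquare:
    def test_sex_table(self):
        chi2, p = bs.chi_square_2x2([[18, 12], [11, 19]])
        assert chi2 == pytest.approx(3.27, abs=0.005)
        assert p == pytest.approx(0.071, abs=0.002)

    def test_proportional_table_zero(self):
        chi2, _ = bs.chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        c = rng.integers(5, 30, size=(2, 2)).astype(float)
        chi2, _ = bs.chi_square_2x2(c)
        expected = np.outer(c.sum(1), c.sum(0)) / c.sum()
        assert chi2 == pytest.approx((((c - expected) ** 2) / expected).sum())

    def test_zero_margin_error(self):
        with pytest.raises(ValueError):
            bs.chi_square_2x2([[0, 0], [5, 5]])


class TestSensitivity:
    def test_reference_design(self):
        assert bs.sensitivity_f() == pytest.approx(0.237, abs=5e-4)

    def test_power_at_alpha_needs_no_effect(self):
        f = bs.sensitivity_f(power=0.051)
        assert f < 0.03

    def test_monte_carlo_power_check(self, rng):
        """Simulating the 2x2 mixed design at the returned f reproduces
        the target power within binomial error."""
        f = bs.sensitivity_f(power=0.80)
        n, rho, m = 30, 0.5, 2
        # effect pattern with Cohen's f for the interaction; total
        # within-cell variance 1, compound symmetry correlation rho
        # one cell offset by delta puts interaction deviations at
        # +/- delta/4, so Cohen's f = delta / (4 sigma)
        delta = f * 4.0
        cov = np.array([[1.0, rho], [rho, 1.0]])
        hits = 0
        reps = 400
        for _ in range(reps):
            y1 = rng.multivariate_normal([0, 0], cov, size=n)
            y2 = rng.multivariate_normal([0, delta], cov, size=n)
            y = np.stack([y1, y2])
            oracle = anova_ss_oracle(y)
            crit = stats.f.ppf(0.95, 1, (2 * n - 2))
            hits += oracle["interaction"] > crit
        assert hits / reps == pytest.approx(0.80, abs=0.07)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            bs.sensitivity_f(alpha=0.2, power=0.1)


class TestLooCorrelations:
    def test_loo_means(self):
        x = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(bs.loo_means(x), [4.0, 3.5, 1.5])

    def test_identical_and_reversed_series(self):
        x = np.arange(10.0)
        assert bs.loo_spearman(x, x).rho == pytest.approx(1.0)
        assert bs.loo_spearman(x, -x).rho == pytest.approx(-1.0)

    def test_null_rarely_significant_at_bonferroni(self, rng):
        raw, bonf = 0, 0
        for _ in range(300):
            a, b = rng.normal(size=20), rng.normal(size=20)
            res = bs.loo_spearman(a, b)
            raw += res.p < 0.05
            bonf += res.significant
        assert 4 <= raw <= 32          # ~5% of 300
        assert bonf <= 2               # alpha = 0.001

    def test_misaligned_error(self):
        with pytest.raises(ValueError):
            bs.loo_spearman(np.arange(5.0), np.arange(6.0))


def test_full_behavioral_stage_interaction_power():
    """Synthetic cohorts parameterised from the published cell means
    yield a significant Overlap x Group false-alarm interaction in at
    least 80% of replicate studies."""
    hits = 0
    for seed in range(10):
        table = sg.simulate_behavior(30, seed=seed)
        res = bs.mixed_anova_2x2(table, "fa_rate")
        hits += res["interaction"].p < 0.05
    assert hits >= 8


def test_behavioral_report_structure():
    table = sg.simulate_behavior(30, seed=1)
    report = bs.behavioral_report(table)
    assert set(report) == {"hit_rate", "rt_ms", "fa_rate"}
    fa = report["fa_rate"]
    assert fa["anova"]["overlap"].p < 0.001  # overwhelming overlap effect
    assert "overlap effect (between groups)" in fa["posthoc"]
    for res in fa["posthoc"].values():
        assert res.test in {"paired t", "Welch t", "wilcoxon", "mann-whitney"}
        assert res.gate  # every post hoc carries its normality gate
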