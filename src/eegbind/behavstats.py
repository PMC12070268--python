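"""Behavioural and demographic statistics.

The behavioural stage mirrors a case-control Go/Nogo analysis: 2x2
mixed (split-plot) ANOVAs with the within-subject factor overlap and
the between-subject factor group, partial eta squared effect sizes,
Shapiro-Wilk-gated post hoc tests (paired/Welch t when normal,
Wilcoxon signed-rank / Mann-Whitney U otherwise, with normal
approximation Z, tie correction and no continuity correction),
Pearson chi-square for the sex table, a sensitivity power analysis for
the within-between interaction via the noncentral F distribution, and
leave-one-out Spearman correlations with a Bonferroni-corrected alpha.

Effect-size conventions follow the published values: rank tests report
r = Z / sqrt(n) with n the per-group sample size, and Cohen's d uses
the pooled SD (equal to t * sqrt(1/n1 + 1/n2) at equal group sizes).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthgen import CONDITIONS, GROUPS


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass
class PosthocResult:
    test: str                       # "paired t" | "Welch t" | "wilcoxon" | "mann-whitney"
    statistic: float
    p: float
    df: float | None = None
    z: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    gate: dict = field(default_factory=dict)   # Shapiro-Wilk records behind the choice


@dataclass
class GateDecision:
    parametric: bool
    results: dict[str, tuple[float, float]]    # sample name -> (W, p)
    degenerate: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p: float
    alpha: float
    significant: bool


# ---------------------------------------------------------------------------
# ANOVA and effect sizes
# ---------------------------------------------------------------------------

def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be non-negative and dfs positive")
    return F * df1 / (F * df1 + df2)


def mixed_anova_2x2(table: pd.DataFrame, dv: str) -> dict[str, AnovaResult]:
    """Split-plot ANOVA with within factor overlap and between factor
    group, on a complete balanced behavioural table.

    Returns results keyed "overlap", "group" and "interaction"; for
    this balanced design the classical sums-of-squares F tests have
    df1 = 1 and df2 = N - 2.
    """
    import pingouin as pg

    required = {"subject", "group", "overlap", dv}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["group", "overlap"], observed=True)["subject"].nunique()
    if len(counts) != 4 or counts.nunique() != 1:
        raise ValueError("design must be complete and balanced (2 groups x 2 conditions)")
    aov = pg.mixed_anova(data=table, dv=dv, within="overlap",
                         subject="subject", between="group")
    key_map = {"overlap": "overlap", "group": "group", "interaction": "Interaction"}
    out: dict[str, AnovaResult] = {}
    for effect, source in key_map.items():
        row = aov.loc[aov["Source"].str.lower() == source.lower()].iloc[0]
        f, df1, df2 = float(row["F"]), int(row["DF1"]), int(row["DF2"])
        out[effect] = AnovaResult(
            effect=effect, F=f, df1=df1, df2=df2,
            p=float(row["p_unc"]), eta_p_sq=partial_eta_sq(f, df1, df2),
        )
    return out


# ---------------------------------------------------------------------------
# normality gate and post hoc tests
# ---------------------------------------------------------------------------

def shapiro_gate(samples: dict[str, np.ndarray], alpha: float = 0.05) -> GateDecision:
    """Parametric tests are allowed iff every sample passes Shapiro-Wilk
    at ``alpha``; constant samples are flagged degenerate and force the
    nonparametric path."""
    if not samples:
        raise ValueError("no samples to gate")
    results: dict[str, tuple[float, float]] = {}
    degenerate: list[str] = []
    parametric = True
    for name, x in samples.items():
        x = np.asarray(x, float)
        if len(x) < 3:
            raise ValueError(f"sample {name!r} too small for Shapiro-Wilk")
        if np.ptp(x) == 0:
            degenerate.append(name)
            parametric = False
            results[name] = (math.nan, math.nan)
            continue
        w, p = stats.shapiro(x)
        results[name] = (float(w), float(p))
        if p <= alpha:
            parametric = False
    return GateDecision(parametric=parametric, results=results, degenerate=degenerate)


def welch_t(values_a, values_b) -> PosthocResult:
    """Welch two-sample t with Welch-Satterthwaite df and pooled-SD
    Cohen's d."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else math.inf
    return PosthocResult(test="Welch t", statistic=float(t), p=float(p),
                         df=float(df), effect_size=float(d), effect_size_name="d")


def paired_t(values_a, values_b) -> PosthocResult:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    t, p = stats.ttest_rel(a, b)
    d = (a - b).mean() / (a - b).std(ddof=1)
    return PosthocResult(test="paired t", statistic=float(t), p=float(p),
                         df=float(len(a) - 1), effect_size=float(d),
                         effect_size_name="d")


def _rank_effect_n(n_convention: str, n_per_group: int, n_total: int) -> int:
    if n_convention == "per_group":
        return n_per_group
    if n_convention == "total":
        return n_total
    raise ValueError(f"unknown n convention {n_convention!r}")


def wilcoxon_signed_rank(values_a, values_b=None, n_convention: str = "per_group") -> PosthocResult:
    """Wilcoxon signed-rank test (zero differences dropped, average
    ranks for ties, normal approximation without continuity
    correction).  Z is signed positive when a > b; the effect size is
    r = Z / sqrt(n) with n the number of supplied pairs."""
    a = np.asarray(values_a, float)
    d = a if values_b is None else a - np.asarray(values_b, float)
    n_pairs = len(d)
    if n_pairs < 5:
        raise ValueError("need at least five pairs for the normal approximation")
    d_nz = d[d != 0]
    if len(d_nz) == 0:
        return PosthocResult(test="wilcoxon", statistic=0.0, p=1.0, z=0.0,
                             effect_size=0.0, effect_size_name="r",
                             gate={"degenerate": "all differences zero"})
    n = len(d_nz)
    ranks = stats.rankdata(np.abs(d_nz))
    w_plus = float(ranks[d_nz > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    n_eff = _rank_effect_n(n_convention, n_pairs, n_pairs)
    return PosthocResult(test="wilcoxon", statistic=w_plus, p=float(p), z=float(z),
                         effect_size=float(z / math.sqrt(n_eff)), effect_size_name="r")


def mann_whitney(values_a, values_b, n_convention: str = "per_group") -> PosthocResult:
    """Mann-Whitney U test (normal approximation, tie correction, no
    continuity correction).  The statistic is U of the first sample; Z
    is signed positive when the first sample ranks higher.  The effect
    size is r = Z / sqrt(n) with n the (larger) per-group size."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per group")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u1 = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    n_tot = na + nb
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n_tot * (n_tot - 1))
    sigma2 = na * nb / 12.0 * (n_tot + 1 - tie_term)
    if sigma2 <= 0:
        raise ValueError("degenerate sample: all values tied")
    z = (u1 - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    n_eff = _rank_effect_n(n_convention, max(na, nb), n_tot)
    return PosthocResult(test="mann-whitney", statistic=u1, p=float(p), z=float(z),
                         effect_size=float(z / math.sqrt(n_eff)), effect_size_name="r")


# ---------------------------------------------------------------------------
# overlap effect, chi square, power
# ---------------------------------------------------------------------------

def overlap_effect(table: pd.DataFrame, dv: str = "fa_rate") -> pd.Series:
    """Per-subject overlap effect: overlapping minus non-overlapping."""
    wide = table.pivot(index="subject", columns="overlap", values=dv)
    if wide.isna().any().any() or set(CONDITIONS) - set(wide.columns):
        raise ValueError("every subject needs both overlap conditions")
    return wide["overlapping"] - wide["non-overlapping"]


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2
    count table."""
    c = np.asarray(counts, float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(c, correction=False)
    return float(res.statistic), float(res.pvalue)


def interaction_power(
    f: float,
    n_total: int,
    groups: int = 2,
    measurements: int = 2,
    alpha: float = 0.05,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Power of the within-between interaction F test of a mixed design
    at effect size f, using a noncentral F with noncentrality
    lambda = f^2 * N * m / (1 - rho)."""
    df1 = (groups - 1) * (measurements - 1) * epsilon
    df2 = (n_total - groups) * (measurements - 1) * epsilon
    lam = f * f * n_total * measurements / (1.0 - rho)
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sensitivity_f(
    n_total: int = 60,
    groups: int = 2,
    measurements: int = 2,
    alpha: float = 0.05,
    power: float = 0.95,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Smallest detectable Cohen's f for the within-between interaction
    (sensitivity power analysis)."""
    if not (0 < alpha < 1 and alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    if n_total <= groups or not 0 <= rho < 1:
        raise ValueError("infeasible design parameters")

    def gap(f: float) -> float:
        return interaction_power(f, n_total, groups, measurements, alpha, rho, epsilon) - power

    return float(optimize.brentq(gap, 1e-9, 10.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# leave-one-out correlations
# ---------------------------------------------------------------------------

def loo_means(values) -> np.ndarray:
    """Leave-one-out means: element i is the mean of all values with
    subject i excluded."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    return (x.sum() - x) / (len(x) - 1)


def loo_spearman(
    values_a,
    values_b,
    pair: tuple[str, str] = ("A", "B"),
    alpha: float = 0.001,
) -> CorrelationResult:
    """Spearman rank correlation between two aligned leave-one-out
    series, flagged at the Bonferroni-corrected alpha."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("leave-one-out series are misaligned")
    rho, p = stats.spearmanr(a, b)
    return CorrelationResult(pair=pair, rho=float(rho), p=float(p),
                             alpha=alpha, significant=bool(p < alpha))


# ---------------------------------------------------------------------------
# full behavioural stage
# ---------------------------------------------------------------------------

def _group_values(table: pd.DataFrame, dv: str, group: str, cond: str) -> np.ndarray:
    sel = table[(table["group"] == group) & (table["overlap"] == cond)]
    return sel.sort_values("subject")[dv].to_numpy(float)


def behavioral_report(table: pd.DataFrame, dvs=("hit_rate", "rt_ms", "fa_rate")) -> dict:
    """ANOVA plus Shapiro-Wilk-gated post hoc tests for each dependent
    variable: between-group comparisons per condition, within-group
    overlap effects, and the between-group overlap-effect comparison."""
    report: dict = {}
    for dv in dvs:
        entry: dict = {"anova": mixed_anova_2x2(table, dv)}
        posthoc: dict = {}
        for cond in CONDITIONS:
            vals = {g: _group_values(table, dv, g, cond) for g in GROUPS}
            gate = shapiro_gate({f"{g}/{cond}": v for g, v in vals.items()})
            res = (welch_t if gate.parametric else mann_whitney)(vals[GROUPS[1]], vals[GROUPS[0]])
            res.gate = {"parametric": gate.parametric, "shapiro": gate.results}
            posthoc[f"group difference ({cond})"] = res
        effects = {}
        for g in GROUPS:
            sub = table[table["group"] == g]
            eff = overlap_effect(sub, dv).to_numpy(float)
            effects[g] = eff
            gate = shapiro_gate({f"{g} overlap effect": eff})
            res = (
                paired_t(_group_values(table, dv, g, "overlapping"),
                         _group_values(table, dv, g, "non-overlapping"))
                if gate.parametric
                else wilcoxon_signed_rank(eff)
            )
            res.gate = {"parametric": gate.parametric, "shapiro": gate.results}
            posthoc[f"overlap effect ({g})"] = res
        gate = shapiro_gate({f"{g} overlap effect": effects[g] for g in GROUPS})
        res = (welch_t if gate.parametric else mann_whitney)(effects[GROUPS[1]], effects[GROUPS[0]])
        res.gate = {"parametric": gate.parametric, "shapiro": gate.results}
        posthoc["overlap effect (between groups)"] = res
        entry["posthoc"] = posthoc
        report[dv] = entry
    return report
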