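"""Statistical models and tests over per-dish network metrics.

Topology outcomes (B, C, E, or S) are fit with an identity-link normal GLM
against the treatment design — an MPEP indicator, a Sham indicator (1 =
uninjured, so injury effects appear as negative Sham coefficients), their
interaction — plus a nuisance covariate (mean nodal strength for topology
outcomes, event rate for S). Actual-versus-null metric differences use
two-sided one-sample t tests; group comparisons use ANOVA with Tukey or
Holm-Sidak corrections and paired/unpaired t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

GLM_TERMS = ("Intercept", "MPEP", "Sham", "MPEP:Sham")


@dataclass
class GlmResult:
    """Identity-link normal GLM fit of one topology outcome."""

    outcome: str
    covariate: str
    table: pd.DataFrame  # term, coef, se, z, p
    n: int

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    def z(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "z"])


@dataclass
class InjuryEffectTests:
    """Per-arm injury contrasts from the fitted GLM.

    The injury effect in the untreated (MEM) arm is -beta_Sham; in the MPEP
    arm it is -(beta_Sham + beta_interaction).
    """

    mem_effect: float
    mem_p: float
    mpep_effect: float
    mpep_p: float


def fit_topology_glm(
    metrics: pd.DataFrame,
    outcome: str,
    covariate: str = "S",
) -> GlmResult:
    """Fit ``outcome ~ MPEP + Sham + MPEP:Sham + covariate`` per dish.

    ``metrics`` must hold one row per dish with columns ``drug``, ``injury``,
    the outcome, and the covariate. Coefficients are tested with two-sided
    z tests; the identity-link normal GLM reproduces OLS estimates exactly.
    """
    df = metrics.dropna(subset=[outcome, covariate]).copy()
    if df["drug"].nunique() < 2 and df["injury"].nunique() < 2:
        raise ValueError("need at least two treatment groups represented")
    mpep = (df["drug"] == "MPEP").astype(float).to_numpy()
    sham = (df["injury"] == "Sham").astype(float).to_numpy()
    cov = df[covariate].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), mpep, sham, mpep * sham, cov])
    names = list(GLM_TERMS) + [covariate]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    fit = sm.GLM(df[outcome].to_numpy(dtype=float), X,
                 family=sm.families.Gaussian()).fit()
    table = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return GlmResult(outcome=outcome, covariate=covariate, table=table, n=len(df))


def injury_effect_tests(metrics: pd.DataFrame, outcome: str,
                        covariate: str = "S") -> InjuryEffectTests:
    """Injury contrasts within the MEM and MPEP arms from one GLM fit."""
    df = metrics.dropna(subset=[outcome, covariate]).copy()
    mpep = (df["drug"] == "MPEP").astype(float).to_numpy()
    sham = (df["injury"] == "Sham").astype(float).to_numpy()
    cov = df[covariate].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), mpep, sham, mpep * sham, cov])
    fit = sm.GLM(df[outcome].to_numpy(dtype=float), X,
                 family=sm.families.Gaussian()).fit()
    mem = fit.t_test(np.array([0.0, 0.0, -1.0, 0.0, 0.0]))
    mpep_c = fit.t_test(np.array([0.0, 0.0, -1.0, -1.0, 0.0]))
    return InjuryEffectTests(
        mem_effect=float(np.squeeze(mem.effect)),
        mem_p=float(np.squeeze(mem.pvalue)),
        mpep_effect=float(np.squeeze(mpep_c.effect)),
        mpep_p=float(np.squeeze(mpep_c.pvalue)),
    )


@dataclass
class TestReport:
    name: str
    statistic: float
    df: float
    p: float
    n: tuple[int, ...] = ()
    correction: str | None = None
    extra: dict = field(default_factory=dict)


def null_delta_ttest(deltas, name: str = "delta") -> TestReport:
    """Two-sided one-sample t test of observed-minus-null deltas against 0."""
    d = np.asarray(deltas, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 3:
        raise ValueError("need at least 3 deltas")
    if np.ptp(d) == 0 and d[0] != 0:
        raise ValueError("zero variance in deltas")
    if np.ptp(d) == 0:  # all exactly zero: t = 0, p = 1 by convention
        return TestReport(name=name, statistic=0.0, df=len(d) - 1, p=1.0, n=(len(d),))
    t, p = sps.ttest_1samp(d, 0.0)
    return TestReport(name=name, statistic=float(t), df=len(d) - 1, p=float(p),
                      n=(len(d),))


def one_way_anova(table: pd.DataFrame, value: str, group: str,
                  name: str | None = None) -> TestReport:
    groups = [g[value].dropna().to_numpy() for _, g in table.groupby(group)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return TestReport(
        name=name or f"anova[{value}~{group}]",
        statistic=float(f),
        df=df1,
        p=float(p),
        n=tuple(len(g) for g in groups),
        extra={"df_resid": df2},
    )


def tukey_posthoc(table: pd.DataFrame, value: str, group: str) -> list[TestReport]:
    """All-pairs comparisons with Tukey's multiple-comparison correction."""
    sub = table.dropna(subset=[value])
    counts = sub.groupby(group)[value].count()
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    res = pairwise_tukeyhsd(sub[value].to_numpy(), sub[group].to_numpy())
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return [
        TestReport(
            name=f"tukey[{row['group1']} vs {row['group2']}]",
            statistic=float(row["meandiff"]),
            df=float(res.df_total),
            p=float(row["p-adj"]),
            correction="tukey",
        )
        for _, row in frame.iterrows()
    ]


def holm_sidak_ttests(
    table: pd.DataFrame, value: str, group: str, pairs: list[tuple[str, str]]
) -> list[TestReport]:
    """Selected pairwise unpaired t tests with Holm-Sidak adjustment."""
    raw = []
    for a, b in pairs:
        xa = table.loc[table[group] == a, value].dropna().to_numpy()
        xb = table.loc[table[group] == b, value].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("every group needs n >= 2")
        t, p = sps.ttest_ind(xa, xb)
        raw.append((a, b, float(t), float(p), len(xa), len(xb)))
    adj = multipletests([r[3] for r in raw], method="holm-sidak")[1]
    return [
        TestReport(
            name=f"holm-sidak[{a} vs {b}]",
            statistic=t,
            df=na + nb - 2,
            p=float(p_adj),
            n=(na, nb),
            correction="holm-sidak",
        )
        for (a, b, t, _, na, nb), p_adj in zip(raw, adj)
    ]


def paired_ttest(x, y, name: str = "paired") -> TestReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must align")
    if len(x) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.ptp(x - y) == 0:
        t, p = (0.0, 1.0) if np.allclose(x, y) else sps.ttest_rel(x, y)[:2]
    else:
        t, p = sps.ttest_rel(x, y)
    return TestReport(name=name, statistic=float(t), df=len(x) - 1, p=float(p),
                      n=(len(x),))


def two_way_anova(table: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction via statsmodels OLS/anova_lm."""
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = table.dropna(subset=[value]).rename(columns={value: "_y"})
    model = ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return anova_lm(model, typ=2)
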