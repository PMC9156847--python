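"""Cohort statistics for per-child DNM counts.

Implements the statistical battery of a trio-WGS cohort comparison:
descriptive group means, multiple linear regression of DNM count on method
of conception and parental ages, pooled two-sample t-test between
paternal-age groups, multi-factorial ANOVA with Tukey post hoc comparisons
(optionally Bonferroni-multiplied), negative-binomial regression for
origin-proportion analyses, and a two-sample normal-approximation power
calculation.

Model fitting is delegated to statsmodels; this module owns the cohort
schema, the reported quantities and the power formula.  A 53-child cohort
table (per-child DNM count, parental ages at conception, conception method)
is packaged as ``dnmsuite/data/table1.csv`` and loaded by default.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .models import CohortRecord, RegressionFit, TestResult

METHODS = ("spontaneous", "IVF", "ICSI-TESE")
AGE_GROUPS = ("<35", ">45")

_COLUMNS = ["child_id", "method", "dnm_count", "maternal_age",
            "paternal_age", "fertility_status"]


def packaged_cohort_path():
    """Path to the packaged 53-child cohort fixture."""
    return importlib.resources.files("dnmsuite") / "data" / "table1.csv"


def load_cohort(path=None) -> pd.DataFrame:
    """Load and validate a cohort CSV; defaults to the packaged fixture.

    The paternal-age group (``<35`` / ``>45``) is derived from paternal age
    at conception; the cohort design has no fathers between 35 and 45.
    """
    if path is None:
        path = packaged_cohort_path()
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"cohort file {path} contains no records")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["method"] not in METHODS:
            raise ValueError(
                f"row {line}: unknown conception method {row['method']!r}")
        if not 0 <= row["dnm_count"] < 1000:
            raise ValueError(f"row {line}: implausible DNM count "
                             f"{row['dnm_count']}")
        for col in ("maternal_age", "paternal_age"):
            if not 14 <= row[col] <= 80:
                raise ValueError(f"row {line}: implausible {col} {row[col]}")
    df = df.copy()
    df["age_group"] = np.where(df["paternal_age"] < 35, "<35", ">45")
    mid = (df["paternal_age"] >= 35) & (df["paternal_age"] <= 45)
    if mid.any():
        raise ValueError(
            "paternal ages between 35 and 45 do not fit the cohort's "
            f"age-group design: children {df.loc[mid, 'child_id'].tolist()}")
    return df


def cohort_records(df: pd.DataFrame) -> list[CohortRecord]:
    return [CohortRecord(child_id=str(r.child_id), method=str(r.method),
                         age_group=str(r.age_group),
                         dnm_count=int(r.dnm_count),
                         maternal_age=float(r.maternal_age),
                         paternal_age=float(r.paternal_age),
                         fertility_status=str(r.fertility_status))
            for r in df.itertuples(index=False)]


def group_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean / SD / SEM / n of DNM counts per (method, age group).

    ``mean_rounded`` matches the convention of reporting whole DNMs; SD and
    SEM are NaN (flagged) for single-record groups.
    """
    g = df.groupby(["method", "age_group"])["dnm_count"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["mean_rounded"] = out["mean"].round().astype(int)
    return out[["method", "age_group", "n", "mean", "mean_rounded",
                "sd", "sem"]]


def _fit_to_regressionfit(fit, n: int) -> RegressionFit:
    return RegressionFit(
        params=dict(fit.params),
        bse=dict(fit.bse),
        tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        f_pvalue=float(fit.f_pvalue),
        n=n,
    )


def ols_regression(df: pd.DataFrame,
                   formula: str = "dnm_count ~ C(method) + paternal_age"
                                  " + maternal_age") -> RegressionFit:
    """OLS of DNM count on conception method and parental ages.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = model.exog_names
        _, r = np.linalg.qr(model.exog)
        bad = [names[j] for j in range(len(names))
               if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"design matrix is rank-deficient; collinear "
                         f"terms: {bad}")
    fit = model.fit()
    return _fit_to_regressionfit(fit, n=len(df))


def two_sample_t(df: pd.DataFrame, grouping: str = "age_group",
                 welch: bool = False) -> TestResult:
    """Two-sample t-test of DNM counts between the two paternal-age groups.

    Pooled-variance Student's t by default (Welch via flag); the sign
    convention is (<35 group) − (>45 group).
    """
    levels = sorted(df[grouping].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, "
                         f"got {levels}")
    a = df.loc[df[grouping] == levels[0], "dnm_count"].to_numpy(float)
    b = df.loc[df[grouping] == levels[1], "dnm_count"].to_numpy(float)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df_used = res.df if welch else len(a) + len(b) - 2
    return TestResult(name="t", statistic=float(res.statistic),
                      df=float(df_used), pvalue=float(res.pvalue),
                      term=f"{levels[0]} - {levels[1]}")


def factorial_anova(df: pd.DataFrame, ss_type: int = 1,
                    interaction: bool = True) -> list[TestResult]:
    """Multi-factorial ANOVA of DNM count on method and paternal-age group.

    Sequential (Type I) sums of squares by default, factors ordered
    (method, age group, interaction); Type II by flag.
    """
    if ss_type not in (1, 2):
        raise ValueError("ss_type must be 1 or 2")
    rhs = "C(method) + C(age_group)"
    if interaction:
        cells = df.groupby(["method", "age_group"]).size()
        if (len(cells) < df["method"].nunique() * df["age_group"].nunique()):
            raise ValueError("empty factor cell: interaction model "
                             "cannot be fitted")
        rhs += " + C(method):C(age_group)"
    fit = smf.ols(f"dnm_count ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=ss_type)
    constant = df["dnm_count"].nunique() == 1
    out = []
    resid_df = float(table.loc["Residual", "df"])
    for term in table.index:
        if term == "Residual":
            continue
        f = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        if constant or not np.isfinite(f) and table.loc[term, "sum_sq"] == 0:
            f, p = 0.0, 1.0   # constant response: no explained variance
        out.append(TestResult(
            name="F", statistic=f,
            df=(float(table.loc[term, "df"]), resid_df),
            pvalue=p, term=term))
    return out


def tukey_posthoc(df: pd.DataFrame, grouping: str = "group",
                  bonferroni: bool = False,
                  alpha: float = 0.05) -> list[TestResult]:
    """Tukey HSD pairwise comparisons of DNM counts between groups.

    ``grouping="group"`` compares the six method x age-group cells.  With
    ``bonferroni=True`` the studentized-range p-values are additionally
    multiplied by the number of comparisons (capped at 1) — a conservative
    hybrid correction.
    """
    data = df.copy()
    if grouping == "group" and "group" not in data.columns:
        data["group"] = data["method"] + " " + data["age_group"]
    res = pairwise_tukeyhsd(data["dnm_count"], data[grouping], alpha=alpha)
    n_pairs = len(res.pvalues)
    names = list(res.groupsunique)
    pairs = list(itertools.combinations(names, 2))
    assert len(pairs) == n_pairs
    out = []
    for (g1, g2), p, md in zip(pairs, res.pvalues, res.meandiffs):
        adj = min(1.0, float(p) * n_pairs) if bonferroni else float(p)
        out.append(TestResult(
            name="q", statistic=float(md), df=float(res.df_total),
            pvalue=float(p), adjusted_pvalue=adj,
            term=f"{g1} vs {g2}"))
    return out


def nb_regression(counts: Sequence[int], exog: pd.DataFrame | np.ndarray,
                  offsets: Optional[np.ndarray] = None,
                  maxiter: int = 100) -> RegressionFit:
    """Negative-binomial GLM (log link) with moment-based dispersion.

    The dispersion alpha is estimated from Poisson-fit residual moments
    (Cameron–Trivedi), then a NB GLM is fitted by IRLS.  z statistics are
    reported in ``tvalues``.
    """
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    X = sm.add_constant(np.asarray(exog, dtype=float), has_constant="add")
    offset = None if offsets is None else np.asarray(offsets, dtype=float)
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
        maxiter=maxiter)
    mu = pois.fittedvalues
    # moment estimator of alpha in Var = mu + alpha * mu^2
    num = ((y - mu) ** 2 - mu)
    alpha = float(max((num / mu ** 2).sum() / max(len(y) - X.shape[1], 1),
                      1e-8))
    fam = sm.families.NegativeBinomial(alpha=alpha)
    fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=maxiter)
    if not fit.converged:
        raise RuntimeError(
            f"negative-binomial IRLS did not converge in {maxiter} "
            f"iterations (alpha={alpha:.4g}, deviance trace tail="
            f"{getattr(fit, 'fit_history', {}).get('deviance', [])[-3:]})")
    if isinstance(exog, pd.DataFrame):
        names = ["const"] + list(exog.columns)
    else:
        names = ["const"] + [f"x{i}" for i in range(1, X.shape[1])]
    return RegressionFit(
        params=dict(zip(names, fit.params)),
        bse=dict(zip(names, fit.bse)),
        tvalues=dict(zip(names, fit.tvalues)),
        pvalues=dict(zip(names, fit.pvalues)),
        df_resid=int(fit.df_resid),
        r_squared=None, f_stat=None, f_df=None, f_pvalue=None,
        n=len(y),
    )


def power_two_means(delta: float, sd: float, alpha: float = 0.05,
                    power: float = 0.8) -> int:
    """Smallest per-group n detecting a mean difference ``delta`` between
    two groups with common SD ``sd``.

    Normal-approximation two-sided two-sample formula
    ``n = 2 (z_{1-alpha/2} + z_{power})^2 / (delta/sd)^2``, rounded up;
    never below 2 (a variance estimate needs two observations per group).
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = 2 * (z_a + z_b) ** 2 / (delta / sd) ** 2
    return max(2, math.ceil(n - 1e-12))


def minimum_detectable_effect(n: int, sd: float, alpha: float = 0.05,
                              power: float = 0.8) -> float:
    """Inverse of :func:`power_two_means`: smallest detectable mean
    difference at per-group sample size ``n``."""
    if n < 2 or sd <= 0:
        raise ValueError("need n >= 2 and sd > 0")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return float(sd * (z_a + z_b) * math.sqrt(2.0 / n))
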