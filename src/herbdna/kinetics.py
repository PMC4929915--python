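"""Cross-sample inference: decay rate k, time regressions, ANCOVA.

The per-sample damage fraction lambda relates to sample age through
lambda = k * age, so the slope of the (age, lambda) regression is the
per-site per-year decay rate k. The literal model has no intercept, so the
headline k comes from a through-origin fit; a free-intercept fit is always
reported alongside as a sensitivity check (a nonzero intercept indicates
age-independent fragmentation, e.g. from specimen preparation).

Compartment and protocol contrasts use an analysis of covariance on the
model response ~ covariate * factor with sequential (Type I) sums of
squares, followed by an F-test of the full model against the additive
response ~ covariate + factor: a significant interaction means the slopes
differ; otherwise a significant factor effect in the additive model means
the intercepts differ.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .fraglen import DecayFit


@dataclass
class RegressionResult:
    """Ordinary least-squares line fit with an F-test of the slope."""

    slope: float
    intercept: float | None  # None for a through-origin fit
    r_squared: float
    p_value: float
    n: int
    df_resid: int
    slope_se: float
    intercept_se: float | None = None


def regress(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> RegressionResult:
    """OLS of y on x; through-origin mode omits the intercept.

    The p-value is the F-test of the slope (equivalently the two-sided
    t-test). Through-origin R-squared is uncentered (1 - RSS/sum(y^2)),
    the convention R's lm uses for intercept-free models.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    min_n = 2 if through_origin else 3
    if n < min_n:
        raise ValueError(f"need >= {min_n} points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if through_origin:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y)) / sxx
        resid = y - slope * x
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum(y**2))
        df_resid = n - 1
        intercept = None
    else:
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        slope = float(np.sum((x - xbar) * (y - ybar))) / sxx
        b0 = ybar - slope * xbar
        resid = y - (b0 + slope * x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - ybar) ** 2))
        df_resid = n - 2
        intercept = float(b0)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    sigma2 = ss_res / df_resid if df_resid > 0 else float("nan")
    slope_se = math.sqrt(sigma2 / sxx)
    intercept_se = None
    if not through_origin:
        intercept_se = math.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))
    if sigma2 == 0:
        p = 0.0
        f = float("inf")
    else:
        f = slope**2 / (sigma2 / sxx)
        p = float(stats.f.sf(f, 1, df_resid))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(r2),
        p_value=p,
        n=n,
        df_resid=df_resid,
        slope_se=slope_se,
        intercept_se=intercept_se,
    )


@dataclass
class DecayRateEstimate:
    """k from the lambda-vs-age regression, in both intercept modes."""

    through_origin: RegressionResult
    free_intercept: RegressionResult
    n_excluded: int

    @property
    def k(self) -> float:
        """Headline per-site per-year decay rate (through-origin slope)."""
        return self.through_origin.slope


def estimate_decay_rate(
    samples: Iterable[tuple[float, "DecayFit | float"]],
) -> DecayRateEstimate:
    """Estimate k from (age, lambda) pairs across samples.

    Accepts DecayFit records or plain lambda values; fits flagged as
    non-decaying (ok=False) and non-positive ages are excluded with a
    warning. Needs >= 3 usable samples.
    """
    ages, lams = [], []
    n_excluded = 0
    for age, lam in samples:
        if isinstance(lam, DecayFit):
            if not lam.ok:
                n_excluded += 1
                continue
            lam = lam.lambda_hat
        if age <= 0 or not np.isfinite(lam):
            n_excluded += 1
            continue
        ages.append(float(age))
        lams.append(float(lam))
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} samples from the decay-rate regression "
            "(flagged fits or non-positive ages)",
            stacklevel=2,
        )
    if len(ages) < 3:
        raise ValueError(f"need >= 3 usable samples, got {len(ages)}")
    return DecayRateEstimate(
        through_origin=regress(ages, lams, through_origin=True),
        free_intercept=regress(ages, lams, through_origin=False),
        n_excluded=n_excluded,
    )


def cohort_table(
    per_sample_stats: Iterable[dict], metadata: Iterable
) -> pd.DataFrame:
    """Join per-sample (x compartment) statistics with sample metadata.

    ``per_sample_stats`` rows must carry ``sample_id``; metadata supplies
    collection_year, age and factor labels. Rows keep missing statistics as
    NaN (they are excluded from individual regressions only, never silently
    dropped). Errors on a stats row whose sample_id has no metadata.
    """
    meta_by_id = {}
    for m in metadata:
        meta_by_id[m.sample_id] = m
    rows = []
    for s in per_sample_stats:
        sid = s.get("sample_id")
        if sid not in meta_by_id:
            raise KeyError(f"sample id {sid!r} not found in the sample table")
        m = meta_by_id[sid]
        row = dict(s)
        row["collection_year"] = m.collection_year
        row["age"] = m.age
        for k, v in m.factors.items():
            row[k] = v
        rows.append(row)
    if not rows:
        raise ValueError("no per-sample statistics given")
    return pd.DataFrame(rows)


@dataclass
class AncovaResult:
    """Sequential ANOVA of response ~ covariate * factor plus model comparison."""

    table: pd.DataFrame  # full-model sequential (Type I) ANOVA table
    interaction_p: float
    factor_p_additive: float
    comparison_F: float
    comparison_p: float
    alpha: float
    conclusion: str  # 'slopes differ' | 'intercepts differ' | 'no difference'
    n: int


def ancova(
    table: pd.DataFrame,
    response: str,
    covariate: str,
    factor: str,
    alpha: float = 0.05,
) -> AncovaResult:
    """Analysis of covariance comparing regression lines across factor levels.

    Fits ``response ~ covariate * factor`` and reports the sequential
    (Type I) ANOVA table (covariate, factor, interaction), then tests the
    full model against the additive ``response ~ covariate + factor`` with
    an F-test. Interpretation at level ``alpha``: a significant interaction
    means the slopes differ between levels; otherwise a significant factor
    term in the additive model means the intercepts differ.
    """
    df = table[[response, covariate, factor]].dropna().copy()
    levels = df[factor].unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    for lev, sub in df.groupby(factor):
        if len(sub) < 3:
            raise ValueError(f"factor level {lev!r} has fewer than 3 observations")
        if sub[covariate].nunique() < 2:
            raise ValueError(f"covariate is constant within level {lev!r}")
    # plain column names for the formula interface
    df = df.rename(columns={response: "y", covariate: "x", factor: "g"})
    # nested fits in entry order (patsy would reorder the categorical term
    # ahead of the covariate, which breaks the aov-style sequential table)
    m0 = smf.ols("y ~ 1", data=df).fit()
    m1 = smf.ols("y ~ x", data=df).fit()
    additive = smf.ols("y ~ x + C(g)", data=df).fit()
    full = smf.ols("y ~ x * C(g)", data=df).fit()
    mse_full = full.ssr / full.df_resid
    rows = []
    for name, lo, hi in (("x", m0, m1), ("g", m1, additive), ("x:g", additive, full)):
        ss = lo.ssr - hi.ssr
        dof = lo.df_resid - hi.df_resid
        F = (ss / dof) / mse_full
        rows.append(
            {"term": name, "df": dof, "sum_sq": ss, "F": F,
             "PR(>F)": float(stats.f.sf(F, dof, full.df_resid))}
        )
    rows.append(
        {"term": "Residual", "df": full.df_resid, "sum_sq": full.ssr,
         "F": np.nan, "PR(>F)": np.nan}
    )
    seq = pd.DataFrame(rows).set_index("term")
    comp = anova_lm(additive, full)
    interaction_p = float(seq.loc["x:g", "PR(>F)"])
    # factor term adjusted for the covariate, tested against the additive MSE
    ss_g = m1.ssr - additive.ssr
    df_g = m1.df_resid - additive.df_resid
    F_g = (ss_g / df_g) / (additive.ssr / additive.df_resid)
    factor_p_additive = float(stats.f.sf(F_g, df_g, additive.df_resid))
    comparison_F = float(comp.loc[1, "F"])
    comparison_p = float(comp.loc[1, "Pr(>F)"])
    if interaction_p < alpha:
        conclusion = "slopes differ"
    elif factor_p_additive < alpha:
        conclusion = "intercepts differ"
    else:
        conclusion = "no difference"
    seq = seq.rename(index={"x": covariate, "g": factor, "x:g": f"{covariate}:{factor}"})
    return AncovaResult(
        table=seq,
        interaction_p=interaction_p,
        factor_p_additive=factor_p_additive,
        comparison_F=comparison_F,
        comparison_p=comparison_p,
        alpha=alpha,
        conclusion=conclusion,
        n=len(df),
    )
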