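"""Seasonal contrasts of ecological-opportunity variables.

Campaign-level variables retained by the path models are tested for
seasonal differences with a linear mixed model (season fixed effect,
crossed site and year random intercepts); prey-abundance variables are
ln+1 transformed first.  All pairwise season differences of estimated
marginal means are then tested with a Tukey-style familywise adjustment
(studentized-range distribution; Bonferroni available as a fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class SeasonFit:
    """Mixed-model fit of one variable on season (site/year random)."""

    variable: str
    levels: list[str]
    emm: pd.Series            # estimated marginal mean per season
    coef_cov: pd.DataFrame    # covariance of the EMM vector
    df_resid: int
    wald_p: float             # joint test of any seasonal difference
    n: int


def season_model(
    data: pd.DataFrame,
    variable: str,
    season_col: str = "season",
    group_cols: tuple[str, ...] = ("site", "year"),
    campaign_col: str = "campaign_id",
    ln1p: bool = False,
) -> SeasonFit:
    """Fit variable ~ season with crossed site/year random intercepts.

    Operates at campaign level (the variables are campaign summaries).
    Seasons must be explicit labels in the metadata; they are never
    inferred from dates.
    """
    cols = [campaign_col, season_col, *group_cols, variable]
    frame = data[cols].dropna().drop_duplicates(subset=campaign_col).reset_index(drop=True)
    levels = sorted(frame[season_col].unique())
    if len(levels) < 2:
        raise ValueError("seasonal model requires at least two seasons")
    y = np.log1p(frame[variable]) if ln1p else frame[variable]
    work = frame.assign(_y=y)
    vc = {g: f"0 + C({g})" for g in group_cols}
    import warnings

    from .paths import robust_mixedlm_fit

    k = len(levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"_y ~ C({season_col})", work, groups=np.ones(len(work)),
            vc_formula=vc, re_formula="0",
        )
        res = robust_mixedlm_fit(model, reml=True)
        if res is not None:
            fe = res.fe_params
            cov_fe = np.asarray(res.cov_params())[: len(fe), : len(fe)]
        else:
            # zero-variance boundary: the mixed model degenerates to OLS
            logger.warning("season model for %s fell back to the OLS limit", variable)
            ols = smf.ols(f"_y ~ C({season_col})", work).fit()
            fe = ols.params
            cov_fe = np.asarray(ols.cov_params())
    if fe.isna().any() or np.isnan(cov_fe).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(f"_y ~ C({season_col})", work).fit()
        fe = ols.params
        cov_fe = np.asarray(ols.cov_params())
    # map fixed effects (reference coding) to per-season means
    L = np.zeros((k, len(fe)))
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    emm = pd.Series(L @ fe.values, index=levels)
    emm_cov = pd.DataFrame(L @ cov_fe @ L.T, index=levels, columns=levels)
    # Wald chi-square on the seasonal contrasts
    beta = fe.values[1:k]
    vb = cov_fe[1:k, 1:k]
    wald = float(beta @ np.linalg.solve(vb, beta))
    wald_p = float(stats.chi2.sf(wald, k - 1))
    return SeasonFit(
        variable=variable,
        levels=levels,
        emm=emm,
        coef_cov=emm_cov,
        df_resid=max(len(work) - k, 2),
        wald_p=wald_p,
        n=len(work),
    )


def pairwise_seasons(fit: SeasonFit, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise season contrasts with familywise-adjusted p-values.

    Tukey adjustment uses the studentized-range distribution with k groups
    and the model's residual degrees of freedom; with two seasons it
    reduces exactly to the unadjusted t-test.
    """
    if adjust not in {"tukey", "bonferroni"}:
        raise ValueError("adjust must be 'tukey' or 'bonferroni'")
    k = len(fit.levels)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = fit.levels[i], fit.levels[j]
            diff = float(fit.emm[a] - fit.emm[b])
            var = float(
                fit.coef_cov.loc[a, a] + fit.coef_cov.loc[b, b] - 2 * fit.coef_cov.loc[a, b]
            )
            se = np.sqrt(var)
            t = diff / se
            p_raw = 2 * float(stats.t.sf(abs(t), fit.df_resid))
            if adjust == "tukey":
                p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, fit.df_resid))
            else:
                p_adj = min(1.0, p_raw * n_pairs)
            p_adj = min(max(p_adj, np.nextafter(0, 1)), 1.0)
            rows.append(
                {
                    "variable": fit.variable,
                    "season_a": a,
                    "season_b": b,
                    "estimate": diff,
                    "se": se,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "code": significance_code(p_adj),
                }
            )
    return pd.DataFrame(rows)


def seasonal_contrast_table(
    data: pd.DataFrame,
    variables: list[str],
    ln1p_vars: set[str] | None = None,
    season_col: str = "season",
    group_cols: tuple[str, ...] = ("site", "year"),
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Pairwise seasonal contrasts for each variable (one tidy table)."""
    ln1p_vars = ln1p_vars or set()
    out = []
    for var in variables:
        fit = season_model(
            data, var, season_col=season_col, group_cols=group_cols,
            ln1p=var in ln1p_vars,
        )
        out.append(pairwise_seasons(fit, adjust=adjust))
    return (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(
            columns=["variable", "season_a", "season_b", "estimate", "se", "p_raw", "p_adj", "code"]
        )
    )


def residual_display(
    data: pd.DataFrame, variable: str, site_col: str = "site", year_col: str = "year"
) -> pd.Series:
    """Residuals of variable ~ site + year (fixed-effect OLS), for plotting."""
    frame = data[[variable, site_col, year_col]].dropna()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(f"Q('{variable}') ~ C({site_col}) + C({year_col})", frame).fit()
    return fit.resid
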