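"""Piecewise path analysis: direct vs prey-mediated habitat effects.

The causal question is whether habitat conditions shape individual trophic
traits directly (e.g., by altering foraging behaviour) or indirectly via
the prey community.  The hypothesised structure is a DAG with four
variable roles: habitat variables H may point at prey variables P and at
the trait T; prey and size-structure variables point at T; the trait has
no outgoing edges.  Residual covariances are allowed among the prey/size
block and among habitat variables (estimated as residual correlations, not
directed paths).

The machinery is piecewise structural equation modelling in Shipley's
d-separation form: each endogenous variable gets its own linear mixed
model (crossed random intercepts for site and year), the DAG's missing
edges imply conditional-independence claims (the union basis set), each
claim is tested by adding the supposedly-independent variable to the
response's parent model, and the claim p-values combine into Fisher's
C = −2 Σ ln p with 2k degrees of freedom; a non-significant C (p > 0.05)
means the data are consistent with the DAG.

Effect sizes are standardized regression estimates
(β_std = β_raw · SD(x)/SD(y)); the indirect effect of a habitat variable is
the sum over prey mediators of the products of standardized estimates
along H→P→T, and the total effect is direct + indirect.

Variable pruning before modelling removes one member of each highly
correlated pair (|Pearson r| > 0.70, preferring to retain mean over CV
variables) and then predictors with variance inflation factor above 5,
dropped sequentially from the highest.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# variable pruning
# --------------------------------------------------------------------------

def _is_cv(name: str) -> bool:
    return name.startswith("cv-") or name.startswith("cv_")


def _drop_preference(a: str, b: str) -> str:
    """Which of a correlated/tied pair to drop: CV before mean, then later name."""
    if _is_cv(a) != _is_cv(b):
        return a if _is_cv(a) else b
    return max(a, b)


def prune_correlated(
    data: pd.DataFrame, variables: list[str] | None = None, r_max: float = 0.70
) -> list[str]:
    """Greedily drop one variable of each pair with |Pearson r| > r_max.

    Pairs are processed from the highest |r| down (ties alphabetical);
    constant columns are removed first (correlation undefined).  CV
    variables are dropped in preference to mean variables.
    """
    cols = list(variables) if variables is not None else list(data.columns)
    keep = []
    for c in cols:
        if data[c].nunique() <= 1:
            logger.warning("dropping constant column %s (correlation undefined)", c)
        else:
            keep.append(c)
    while len(keep) >= 2:
        corr = data[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (corr.loc[a, b], a, b)
            for a, b in itertools.combinations(sorted(keep), 2)
            if corr.loc[a, b] > r_max
        ]
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, a, b = pairs[0]
        victim = _drop_preference(a, b)
        logger.info("pruning %s (|r|=%.3f with %s)", victim, corr.loc[a, b], a if victim == b else b)
        keep.remove(victim)
    return keep


def vif_scores(data: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """VIF_j = 1 / (1 − R²_j) from OLS of predictor j on the others."""
    X = data[predictors].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(
    data: pd.DataFrame, predictors: list[str], threshold: float = 5.0
) -> list[str]:
    """Sequentially drop the predictor with the largest VIF until all <= threshold."""
    keep = list(predictors)
    while len(keep) >= 2:
        scores = vif_scores(data, keep)
        worst = scores.max()
        if worst <= threshold:
            break
        tied = sorted(scores.index[scores >= worst - 1e-12])
        victim = tied[0]
        for cand in tied[1:]:
            victim = _drop_preference(victim, cand)
        if np.isinf(worst):
            logger.warning("dropping %s: perfect collinearity", victim)
        else:
            logger.info("dropping %s (VIF=%.2f)", victim, worst)
        keep.remove(victim)
    return keep


# --------------------------------------------------------------------------
# mixed-model fitting
# --------------------------------------------------------------------------

@dataclass
class FitRecord:
    """One linear mixed model fit (crossed site/year random intercepts)."""

    response: str
    predictors: list[str]
    params: pd.Series          # raw fixed-effect coefficients (incl. Intercept)
    bse: pd.Series
    pvalues: pd.Series         # large-sample normal approximation on t-ratios
    cov_params: pd.DataFrame
    vcomp: dict[str, float]    # random-intercept variances by factor
    scale: float               # residual variance
    fitted_fixed: np.ndarray   # X @ beta over the modelling frame
    frame: pd.DataFrame        # the modelling frame actually used
    converged: bool
    singular: bool
    n: int


def _safe(name: str) -> str:
    return name.replace("-", "_")


def _collapse_frame(
    data: pd.DataFrame, cols: list[str], campaign_col: str, group_cols: tuple[str, ...]
) -> pd.DataFrame:
    """One row per campaign when every modelling column is campaign-constant.

    Campaign-level variables repeated across individuals would otherwise
    inflate the sample size of campaign-level regressions.
    """
    need = [campaign_col, *group_cols, *cols]
    sub = data[need].dropna()
    nun = sub.groupby(campaign_col)[list(cols)].nunique()
    if (nun <= 1).all().all():
        return sub.drop_duplicates(subset=campaign_col).reset_index(drop=True)
    return sub.reset_index(drop=True)


def robust_mixedlm_fit(model, reml: bool = True):
    """Fit a MixedLM with several optimizers, keeping the best REML criterion.

    Quasi-Newton optimizers occasionally report convergence at a poor point
    or crash when the variance surface degenerates at the zero boundary.
    Returns None when no optimizer converges (callers fall back to the OLS
    zero-variance limit).
    """
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            if candidates and method == "powell":
                break
            try:
                cand = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and np.isfinite(cand.llf):
                candidates.append(cand)
    if not candidates:
        return None
    return max(candidates, key=lambda r: r.llf)


def _ols_limit_record(
    work: pd.DataFrame,
    frame: pd.DataFrame,
    response: str,
    predictors: list[str],
    group_names,
) -> FitRecord:
    """The zero-random-variance limit of the mixed model (GLS -> OLS)."""
    X = np.column_stack(
        [np.ones(len(work))] + [work[_safe(p)].to_numpy(dtype=float) for p in predictors]
    )
    y = work[_safe(response)].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(work) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    covX = sigma2 * np.linalg.inv(X.T @ X)
    names = ["Intercept", *predictors]
    params = pd.Series(beta, index=names)
    bse = pd.Series(np.sqrt(np.diag(covX)), index=names)
    pvalues = pd.Series(2 * stats.norm.sf(np.abs(beta) / bse.values), index=names)
    return FitRecord(
        response=response,
        predictors=list(predictors),
        params=params,
        bse=bse,
        pvalues=pvalues,
        cov_params=pd.DataFrame(covX, index=names, columns=names),
        vcomp={g: 0.0 for g in group_names},
        scale=sigma2,
        fitted_fixed=X @ beta,
        frame=frame,
        converged=True,
        singular=True,
        n=len(frame),
    )


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group_cols: tuple[str, ...] = ("site", "year"),
    campaign_col: str = "campaign_id",
    collapse: bool = True,
    reml: bool = True,
) -> FitRecord:
    """REML fit of response ~ predictors with crossed random intercepts.

    The random structure is encoded as one variance component per grouping
    factor (site, year), which yields crossed — not nested — intercepts.
    Campaign-level regressions (all variables constant within campaign) are
    collapsed to one row per campaign first.
    """
    cols = [response, *predictors]
    frame = (
        _collapse_frame(data, cols, campaign_col, group_cols)
        if collapse
        else data[[campaign_col, *group_cols, *cols]].dropna().reset_index(drop=True)
    )
    if frame[response].nunique() <= 1:
        raise ValueError(f"response {response} has zero variance")
    for p in predictors:
        if frame[p].nunique() <= 1:
            raise ValueError(f"predictor {p} is constant (rank deficiency)")
    work = frame.rename(columns={c: _safe(c) for c in cols})
    rhs = " + ".join(_safe(p) for p in predictors) if predictors else "1"
    formula = f"{_safe(response)} ~ {rhs}"
    vc = {g: f"0 + C({g})" for g in group_cols}
    model = smf.mixedlm(
        formula, work, groups=np.ones(len(work)), vc_formula=vc, re_formula="0"
    )
    res = robust_mixedlm_fit(model, reml=reml)
    if res is None:
        # every optimizer failed; this happens when the variance surface is
        # degenerate at the zero boundary, where the model is plain OLS
        logger.warning("no mixed-model optimizer converged for %s: OLS limit", response)
        return _ols_limit_record(work, frame, response, predictors, vc.keys())

    # the REML optimum may sit on the zero-variance boundary, which the
    # gradient optimizers approach but do not reach; compare the criterion
    # at the boundary and take the OLS limit when it is at least as good
    if (np.asarray(res.vcomp) < 0.05 * res.scale).all():
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        boundary = MixedLMParams.from_components(
            fe_params=None, cov_re=np.empty((0, 0)), vcomp=np.full(len(res.vcomp), 1e-10)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ll_boundary = model.loglike(boundary, profile_fe=True)
            except np.linalg.LinAlgError:
                ll_boundary = -np.inf
        if ll_boundary >= res.llf - 1e-8:
            logger.info("REML optimum for %s is on the zero-variance boundary", response)
            return _ols_limit_record(work, frame, response, predictors, vc.keys())

    k_fixed = len(res.fe_params)
    names_map = {_safe(c): c for c in cols}
    fe_names = [names_map.get(n, n) for n in res.fe_params.index]
    params = pd.Series(res.fe_params.values, index=fe_names)
    bse = pd.Series(res.bse.values[:k_fixed], index=fe_names)
    pvalues = pd.Series(res.pvalues.values[:k_fixed], index=fe_names)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k_fixed, :k_fixed], index=fe_names, columns=fe_names
    )
    vcomp = {g: float(v) for g, v in zip(vc.keys(), res.vcomp)}
    if bse.isna().any():
        # variance components pinned at the zero boundary can leave the REML
        # information matrix singular; the fit then *is* the OLS limit
        logger.warning("NaN standard errors for %s: using the zero-variance OLS limit", response)
        return _ols_limit_record(work, frame, response, predictors, vc.keys())
    singular = any(v <= 1e-10 for v in vcomp.values())
    if singular:
        logger.warning("singular fit for %s: a variance component is ~0", response)
    X = model.exog
    fitted_fixed = X @ res.fe_params.values
    return FitRecord(
        response=response,
        predictors=list(predictors),
        params=params,
        bse=bse,
        pvalues=pvalues,
        cov_params=cov,
        vcomp=vcomp,
        scale=float(res.scale),
        fitted_fixed=fitted_fixed,
        frame=frame,
        converged=bool(res.converged),
        singular=singular,
        n=len(frame),
    )


def standardized_estimates(fit: FitRecord) -> pd.Series:
    """β_std = β_raw · SD(x)/SD(y) with sample SDs over the modelling frame."""
    sd_y = fit.frame[fit.response].std(ddof=1)
    if sd_y == 0:
        raise ValueError("zero-variance response")
    out = {}
    for p in fit.predictors:
        out[p] = fit.params[p] * fit.frame[p].std(ddof=1) / sd_y
    return pd.Series(out)


def r2_mixed(fit: FitRecord) -> tuple[float, float]:
    """Marginal and conditional R² (fixed vs fixed+random variance shares)."""
    var_f = float(np.var(fit.fitted_fixed, ddof=1)) if fit.n > 1 else 0.0
    var_r = sum(fit.vcomp.values())
    denom = var_f + var_r + fit.scale
    return var_f / denom, (var_f + var_r) / denom


# --------------------------------------------------------------------------
# DAG machinery
# --------------------------------------------------------------------------

@dataclass
class PathSpec:
    """Roles, directed edges and correlated-error links of a path model."""

    habitat: list[str]
    prey: list[str]
    size: list[str]
    trait: str
    edges: set[tuple[str, str]]
    correlated: set[frozenset]
    group_cols: tuple[str, ...] = ("site", "year")
    campaign_col: str = "campaign_id"

    @property
    def variables(self) -> list[str]:
        return [*self.habitat, *self.prey, *self.size, self.trait]

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path specification is cyclic")
        return g


def initial_path_spec(
    habitat: list[str],
    prey: list[str],
    size: list[str],
    trait: str,
    group_cols: tuple[str, ...] = ("site", "year"),
) -> PathSpec:
    """Saturated starting topology: H→P, H→T, P→T, S→T.

    Correlated errors among the prey/size block and among habitat variables
    (both treated as adjacency for d-separation, tested as residual
    correlations).
    """
    edges: set[tuple[str, str]] = set()
    for h in habitat:
        for p in prey:
            edges.add((h, p))
        edges.add((h, trait))
    for p in prey:
        edges.add((p, trait))
    for s in size:
        edges.add((s, trait))
    correlated: set[frozenset] = set()
    block = [*prey, *size]
    for a, b in itertools.combinations(sorted(block), 2):
        correlated.add(frozenset((a, b)))
    for a, b in itertools.combinations(sorted(habitat), 2):
        correlated.add(frozenset((a, b)))
    return PathSpec(
        habitat=list(habitat),
        prey=list(prey),
        size=list(size),
        trait=trait,
        edges=edges,
        correlated=correlated,
        group_cols=group_cols,
    )


def basis_set(
    dag: nx.DiGraph, correlated: set[frozenset] | None = None
) -> list[tuple[str, str, tuple[str, ...]]]:
    """Union basis set of independence claims implied by missing edges.

    One claim per non-adjacent pair (directed edges and correlated-error
    links both count as adjacency): the pair is independent conditional on
    the union of both variables' parents.  The claim is returned as
    (x, y, conditioning-set) with y the causally-downstream variable (the
    later of the two in a deterministic topological order when neither
    descends from the other).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph is cyclic")
    correlated = correlated or set()
    order = list(nx.lexicographical_topological_sort(dag))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for a, b in itertools.combinations(sorted(dag.nodes), 2):
        if dag.has_edge(a, b) or dag.has_edge(b, a) or frozenset((a, b)) in correlated:
            continue
        if b in nx.descendants(dag, a):
            x, y = a, b
        elif a in nx.descendants(dag, b):
            x, y = b, a
        else:
            x, y = (a, b) if pos[a] < pos[b] else (b, a)
        cond = (set(dag.predecessors(x)) | set(dag.predecessors(y))) - {x, y}
        claims.append((x, y, tuple(sorted(cond))))
    return claims


def fishers_c(pvalues: list[float]) -> tuple[float, int, float]:
    """Fisher's C = −2 Σ ln p, df = 2k, chi-square upper-tail p."""
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"claim p-value outside (0, 1]: {p}")
    k = len(pvalues)
    if k == 0:
        return 0.0, 0, 1.0
    c = float(-2.0 * np.sum(np.log(pvalues)))
    return c, 2 * k, float(stats.chi2.sf(c, 2 * k))


# --------------------------------------------------------------------------
# model fitting, selection and reporting
# --------------------------------------------------------------------------

@dataclass
class PathModel:
    """A fitted path model: per-edge estimates and global d-separation fit."""

    spec: PathSpec
    fits: dict[str, FitRecord]
    edges: pd.DataFrame          # response predictor estimate se p std_estimate
    correlated: pd.DataFrame     # var_a var_b r p
    claims: pd.DataFrame         # x y conditioning p
    fisher_c: float
    df: int
    p_value: float
    r2: pd.DataFrame             # response marginal conditional

    @property
    def saturated(self) -> bool:
        return self.df == 0

    def to_report(self) -> dict:
        return {
            "trait": self.spec.trait,
            "edges": self.edges.to_dict(orient="records"),
            "correlated": self.correlated.to_dict(orient="records"),
            "claims": self.claims.to_dict(orient="records"),
            "fisher_c": self.fisher_c,
            "df": self.df,
            "p_value": self.p_value,
            "r2": self.r2.to_dict(orient="records"),
        }


def _parents(spec: PathSpec, node: str) -> list[str]:
    return sorted(u for (u, v) in spec.edges if v == node)


def _residuals(data: pd.DataFrame, spec: PathSpec, var: str) -> pd.Series:
    """Residual of ``var`` after OLS on its parents, at the native level."""
    parents = _parents(spec, var)
    cols = [var, *parents]
    frame = _collapse_frame(data, cols, spec.campaign_col, spec.group_cols)
    y = frame[var].to_numpy(dtype=float)
    if parents:
        X = np.column_stack([np.ones(len(frame)), frame[parents].to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        res = y - X @ beta
    else:
        res = y - y.mean()
    return pd.Series(res, index=frame[spec.campaign_col].values)


def correlated_link_tests(data: pd.DataFrame, spec: PathSpec) -> pd.DataFrame:
    """Residual correlation and Pearson p-value for each correlated link."""
    rows = []
    for link in sorted(spec.correlated, key=lambda s: tuple(sorted(s))):
        a, b = sorted(link)
        ra, rb = _residuals(data, spec, a), _residuals(data, spec, b)
        if len(ra) != len(rb):
            # mixed levels (e.g., campaign-level prey vs individual-level size):
            # align both residual series on campaign means
            ra, rb = ra.groupby(ra.index).mean().align(rb.groupby(rb.index).mean(), join="inner")
        r, p = stats.pearsonr(ra.to_numpy(), rb.to_numpy())
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p"])


def _claim_pvalue(data: pd.DataFrame, spec: PathSpec, claim) -> float:
    x, y, cond = claim
    fit = fit_lmm(
        data,
        response=y,
        predictors=sorted({x, *cond}),
        group_cols=spec.group_cols,
        campaign_col=spec.campaign_col,
    )
    return float(fit.pvalues[x])


def fit_path_model(data: pd.DataFrame, spec: PathSpec) -> PathModel:
    """Fit every endogenous variable's mixed model and the global d-sep test."""
    dag = spec.dag()
    fits: dict[str, FitRecord] = {}
    edge_rows = []
    r2_rows = []
    for node in sorted(dag.nodes):
        parents = _parents(spec, node)
        if not parents:
            continue
        fit = fit_lmm(
            data, response=node, predictors=parents,
            group_cols=spec.group_cols, campaign_col=spec.campaign_col,
        )
        fits[node] = fit
        std = standardized_estimates(fit)
        for pred in parents:
            edge_rows.append(
                {
                    "response": node,
                    "predictor": pred,
                    "estimate": float(fit.params[pred]),
                    "se": float(fit.bse[pred]),
                    "p": float(fit.pvalues[pred]),
                    "std_estimate": float(std[pred]),
                }
            )
        rm, rc = r2_mixed(fit)
        r2_rows.append({"response": node, "marginal": rm, "conditional": rc})
    claims = basis_set(dag, spec.correlated)
    claim_rows = []
    pvals = []
    for claim in claims:
        p = _claim_pvalue(data, spec, claim)
        pvals.append(p)
        claim_rows.append(
            {"x": claim[0], "y": claim[1], "conditioning": ",".join(claim[2]), "p": p}
        )
    c, df, p_global = fishers_c(pvals)
    corr = correlated_link_tests(data, spec)
    return PathModel(
        spec=spec,
        fits=fits,
        edges=pd.DataFrame(
            edge_rows,
            columns=["response", "predictor", "estimate", "se", "p", "std_estimate"],
        ),
        correlated=corr,
        claims=pd.DataFrame(claim_rows, columns=["x", "y", "conditioning", "p"]),
        fisher_c=c,
        df=df,
        p_value=p_global,
        r2=pd.DataFrame(r2_rows, columns=["response", "marginal", "conditional"]),
    )


def _trait_pvalues(data: pd.DataFrame, spec: PathSpec) -> pd.Series:
    parents = _parents(spec, spec.trait)
    if not parents:
        return pd.Series(dtype=float)
    fit = fit_lmm(
        data, response=spec.trait, predictors=parents,
        group_cols=spec.group_cols, campaign_col=spec.campaign_col,
    )
    return fit.pvalues[parents]


def select_model(data: pd.DataFrame, spec: PathSpec, alpha: float = 0.05) -> PathModel:
    """Four-step backward selection, refitting after every single removal.

    (i) drop non-significant correlated-error links; (ii) sequentially drop
    non-significant paths into the trait, highest p first (ties broken
    alphabetically by predictor); (iii) drop prey/size variables left
    without a path to the trait; (iv) sequentially drop non-significant
    habitat→prey paths, highest p first.  Isolated habitat variables are
    dropped at the end.  The procedure is deterministic and idempotent.
    """
    spec = replace(
        spec,
        edges=set(spec.edges),
        correlated=set(spec.correlated),
        habitat=list(spec.habitat),
        prey=list(spec.prey),
        size=list(spec.size),
    )
    # (i) covariate (correlated-error) links
    corr = correlated_link_tests(data, spec)
    for _, row in corr.iterrows():
        if row["p"] > alpha:
            spec.correlated.discard(frozenset((row["var_a"], row["var_b"])))
            logger.info("step i: removed covariance %s~%s (p=%.3f)", row["var_a"], row["var_b"], row["p"])
    # (ii) paths into the trait
    while True:
        pvals = _trait_pvalues(data, spec)
        if pvals.empty:
            break
        bad = pvals[pvals > alpha]
        if bad.empty:
            break
        worst_p = bad.max()
        victim = sorted(bad.index[bad >= worst_p - 1e-15])[0]
        spec.edges.discard((victim, spec.trait))
        logger.info("step ii: removed %s -> %s (p=%.3f)", victim, spec.trait, worst_p)
    # (iii) prey/size variables without a path to the trait
    kept_parents = set(_parents(spec, spec.trait))
    for var in sorted([*spec.prey, *spec.size]):
        if var not in kept_parents:
            spec.edges = {e for e in spec.edges if var not in e}
            spec.correlated = {l for l in spec.correlated if var not in l}
            if var in spec.prey:
                spec.prey.remove(var)
            else:
                spec.size.remove(var)
            logger.info("step iii: removed variable %s", var)
    # (iv) habitat -> prey paths
    while True:
        candidates = []
        for prey_var in sorted(spec.prey):
            parents = _parents(spec, prey_var)
            if not parents:
                continue
            fit = fit_lmm(
                data, response=prey_var, predictors=parents,
                group_cols=spec.group_cols, campaign_col=spec.campaign_col,
            )
            for h in parents:
                p = float(fit.pvalues[h])
                if p > alpha:
                    candidates.append((p, h, prey_var))
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        p, h, prey_var = candidates[0]
        spec.edges.discard((h, prey_var))
        logger.info("step iv: removed %s -> %s (p=%.3f)", h, prey_var, p)
    # drop habitat variables with no remaining edges or links
    for h in list(spec.habitat):
        in_edges = any(h in e for e in spec.edges)
        in_links = any(h in l for l in spec.correlated)
        if not in_edges and not in_links:
            spec.habitat.remove(h)
            logger.info("removed isolated habitat variable %s", h)
    return fit_path_model(data, spec)


def effect_decomposition(model: PathModel) -> pd.DataFrame:
    """Direct, indirect (prey-mediated) and total standardized habitat effects."""
    edges = model.edges
    trait = model.spec.trait

    def std(u: str, v: str) -> float:
        row = edges[(edges["predictor"] == u) & (edges["response"] == v)]
        return float(row["std_estimate"].iloc[0]) if len(row) else 0.0

    rows = []
    for h in model.spec.habitat:
        direct = std(h, trait)
        indirect = sum(std(h, p) * std(p, trait) for p in model.spec.prey)
        rows.append(
            {"habitat": h, "direct": direct, "indirect": indirect, "total": direct + indirect}
        )
    return pd.DataFrame(rows, columns=["habitat", "direct", "indirect", "total"])


def path_diagram(model: PathModel) -> str:
    """Plain-text summary of the fitted paths."""
    lines = [f"Path model for trait {model.spec.trait}"]
    for _, e in model.edges.sort_values(["response", "predictor"]).iterrows():
        flag = "*" if e["p"] <= 0.05 else " "
        lines.append(
            f"  {e['predictor']:>16s} -> {e['response']:<16s} "
            f"std={e['std_estimate']:+.3f} p={e['p']:.4f}{flag}"
        )
    lines.append(
        f"  Fisher's C = {model.fisher_c:.3f}, df = {model.df}, p = {model.p_value:.4f}"
        + ("  (saturated)" if model.saturated else "")
    )
    for _, r in model.r2.iterrows():
        lines.append(
            f"  R2[{r['response']}] marginal={r['marginal']:.3f} conditional={r['conditional']:.3f}"
        )
    return "\n".join(lines)
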