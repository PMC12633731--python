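"""Mixed-effects comparison tables and the fluorescence (Evans Blue) analysis.

Responses are modelled with linear mixed-effects models carrying a random
intercept per fish (REML).  Results are reported the way comparative
biomechanics papers print them: ANOVA-type F tests per fixed term with
containment denominator degrees of freedom, marginal/conditional R^2
(fixed-effects-only vs whole-model variance explained), estimated
marginal means +/- s.e.m. over a balanced reference grid, and
Bonferroni-corrected pairwise contrasts.

The Evans Blue analysis takes a cell-level fluorescence table, subtracts
the per-section background, and fits per size-class linear models of
intensity on distance along the fin (% fin length) and treatment, with
Cohen's d quantifying the treatment effect per muscle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import dmatrix
from scipy import stats as sps

__all__ = [
    "LMEFit",
    "AnovaRow",
    "EmmeanRow",
    "PairwiseRow",
    "fit_lme",
    "anova_table",
    "emmeans",
    "emmeans_by",
    "pairwise_bonferroni",
    "cohens_d",
    "evans_blue_analysis",
    "nakagawa_r2",
]


@dataclass
class LMEFit:
    response: str
    fixed: list
    data: pd.DataFrame
    design_info: object
    X: pd.DataFrame
    result: object
    converged: bool
    varcomps: dict
    groups_col: str = "fish"
    variance_structure: str | None = None
    group_scales: dict | None = None
    fit_log: list = field(default_factory=list)
    is_mixed: bool = True
    blocked: bool = True  # fish enters the model (random or fixed block)

    @property
    def fe_params(self) -> pd.Series:
        names = list(self.X.columns)
        return pd.Series(np.asarray(self.result.params)[: len(names)],
                         index=names)

    @property
    def fe_cov(self) -> pd.DataFrame:
        names = list(self.X.columns)
        cov = np.asarray(self.result.cov_params())[: len(names), : len(names)]
        return pd.DataFrame(cov, index=names, columns=names)


@dataclass(frozen=True)
class AnovaRow:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    R2m: float
    R2c: float


@dataclass(frozen=True)
class EmmeanRow:
    group: str
    emmean: float
    sem: float


@dataclass(frozen=True)
class PairwiseRow:
    contrast: str
    estimate: float
    sem: float
    p: float
    p_bonf: float


def _rhs(fixed: list) -> str:
    return " + ".join(fixed) if fixed else "1"


def fit_lme(
    table: pd.DataFrame,
    response: str,
    fixed: list,
    groups: str = "fish",
    variance_structure: str | None = None,
    reml: bool = True,
    random_intercept: bool = True,
) -> LMEFit:
    """REML fit of ``response ~ fixed`` with a random intercept per fish.

    ``variance_structure="per_behaviour"`` (or ``"per_<column>"``) applies
    feasible-GLS weights: per-level residual standard deviations are
    estimated from a first homoskedastic fit, every row of the response and
    design is rescaled by its level's 1/sd, and the random intercept column
    is scaled to match, so the refit is the heteroskedastic model on a
    homoskedastic scale.  A singular random-intercept fit falls back to an
    ordinary linear model with fish as a fixed blocking factor (logged).
    """
    log: list[str] = []
    data = table.dropna(subset=[response]).reset_index(drop=True).copy()
    if random_intercept and data[groups].nunique() < 2:
        raise ValueError("need at least 2 fish for a random intercept")
    X = dmatrix(_rhs(fixed), data, return_type="dataframe")
    di = X.design_info
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    y = data[response].astype(float).to_numpy()
    if not random_intercept:
        ols = sm.OLS(y, X).fit()
        return LMEFit(response, fixed, data, di, X, ols, True,
                      {"fish": 0.0, "residual": float(ols.mse_resid)},
                      groups, None, None, log, is_mixed=False, blocked=False)
    w = np.ones(len(data))
    group_scales = None
    if variance_structure:
        col = variance_structure.removeprefix("per_")
        pre = sm.MixedLM(y, X, groups=data[groups]).fit(reml=reml)
        resid = pd.Series(np.asarray(pre.resid), index=data.index)
        sds = data.assign(_r=resid).groupby(col, observed=True)["_r"].std()
        sds = sds / sds.mean()
        group_scales = sds.to_dict()
        log.append(f"per-{col} FGLS scales: {group_scales}")
        w = data[col].map(sds).astype(float).to_numpy()
    Xw = X.div(w, axis=0)
    yw = y / w
    exog_re = pd.DataFrame({"fish_intercept": 1.0 / w})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yw, Xw, groups=data[groups], exog_re=exog_re)
        result = model.fit(reml=reml)
        for method in ("powell", "cg"):
            if result.converged:
                break
            log.append(f"optimizer retry: {method}")
            result = model.fit(reml=reml, method=method)
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    # boundary estimate: intercept variance negligible on the data's scale
    singular = re_var <= 1e-10 * max(float(np.var(yw)), 1e-300)
    if not result.converged or singular:
        log.append("singular random-intercept fit; fish used as fixed block")
        warnings.warn("singular LME fit: using fish as fixed blocking factor")
        dummies = pd.get_dummies(data[groups], prefix="block", drop_first=True,
                                 dtype=float).div(w, axis=0)
        ols = sm.OLS(yw, pd.concat([Xw, dummies], axis=1)).fit()
        return LMEFit(response, fixed, data, di, X, ols, True,
                      {"fish": 0.0, "residual": float(ols.mse_resid)},
                      groups, variance_structure, group_scales, log,
                      is_mixed=False)
    varcomps = {"fish": re_var, "residual": float(result.scale)}
    return LMEFit(response, fixed, data, di, X, result, result.converged,
                  varcomps, groups, variance_structure, group_scales, log)


# --- ANOVA-type tables -------------------------------------------------------


def _containment_df(fit: LMEFit) -> dict[str, int]:
    """nlme-style containment denominator df per fixed term.

    Terms whose factors vary within fish get N - M - p_inner; terms
    constant within every fish get M - p_outer (M = number of fish).
    """
    di = fit.design_info
    data = fit.data
    N = len(data)
    if not fit.blocked:
        resid_df = max(N - fit.X.shape[1], 1)
        return {t.name(): resid_df for t in di.terms}
    M = data[fit.groups_col].nunique()
    inner, outer = [], []
    for term in di.terms:
        if term.name() == "Intercept":
            outer.append(term)
            continue
        cols = [f.name().removeprefix("C(").removesuffix(")")
                for f in term.factors]
        varies = any(
            data.groupby(fit.groups_col, observed=True)[c].nunique().max() > 1
            for c in cols if c in data.columns
        )
        (inner if varies else outer).append(term)

    def ncols(t):
        sl = di.term_slices[t]
        return sl.stop - sl.start

    p_inner = sum(ncols(t) for t in inner)
    p_outer = sum(ncols(t) for t in outer)
    out = {}
    for t in di.terms:
        if t in inner:
            out[t.name()] = max(N - M - p_inner, 1)
        else:
            out[t.name()] = max(M - p_outer, 1)
    return out


def nakagawa_r2(fit: LMEFit) -> tuple[float, float]:
    """Marginal and conditional R^2 by the variance-decomposition definition."""
    yhat = fit.X.values @ fit.fe_params.values
    var_f = float(np.var(yhat, ddof=0))
    var_re = fit.varcomps.get("fish", 0.0)
    var_e = fit.varcomps.get("residual", 0.0)
    tot = var_f + var_re + var_e
    return var_f / tot, (var_f + var_re) / tot


def anova_table(fit: LMEFit) -> list[AnovaRow]:
    """Wald F test per fixed term with containment denominator df."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    params = fit.fe_params
    cov = fit.fe_cov
    di = fit.design_info
    dfs = _containment_df(fit)
    r2m, r2c = nakagawa_r2(fit)
    rows = []
    for term in di.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = di.term_slices[term]
        names = di.column_names[sl]
        b = params[names].values
        V = cov.loc[names, names].values
        q = len(names)
        F = float(b @ np.linalg.solve(V, b)) / q
        dden = dfs[name]
        rows.append(AnovaRow(name, F, q, dden, float(sps.f.sf(F, q, dden)),
                             r2m, r2c))
    return rows


# --- estimated marginal means ------------------------------------------------


def _grid_factors(fit: LMEFit) -> list[str]:
    cols = set()
    for term in fit.design_info.terms:
        for f in term.factors:
            nm = f.name().removeprefix("C(").removesuffix(")")
            if nm in fit.data.columns:
                cols.add(nm)
    return sorted(cols)


def _grid_design(fit: LMEFit) -> tuple[pd.DataFrame, np.ndarray]:
    factors = _grid_factors(fit)
    levels = {f: sorted(fit.data[f].dropna().unique()) for f in factors}
    grid = pd.DataFrame(list(itertools.product(*levels.values())),
                        columns=factors)
    X = np.asarray(dmatrix(fit.design_info, grid, return_type="dataframe"))
    return grid, X


def _emmean_vectors(fit: LMEFit, by: str,
                    within: tuple[str, object] | None = None) -> dict[str, np.ndarray]:
    grid, X = _grid_design(fit)
    if by not in grid.columns:
        raise ValueError(f"{by!r} is not a model factor ({list(grid.columns)})")
    out = {}
    for lev in sorted(fit.data[by].dropna().unique()):
        m = (grid[by] == lev).values
        if within is not None:
            m &= (grid[within[0]] == within[1]).values
        if not m.any():
            warnings.warn(f"empty reference-grid cell for {by}={lev}")
            continue
        out[str(lev)] = X[m].mean(axis=0)
    return out


def emmeans(fit: LMEFit, by: str) -> list[EmmeanRow]:
    """Estimated marginal means +/- s.e.m. over a balanced reference grid."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    params, cov = fit.fe_params.values, fit.fe_cov.values
    return [EmmeanRow(lev, float(L @ params), float(np.sqrt(L @ cov @ L)))
            for lev, L in _emmean_vectors(fit, by).items()]


def emmeans_by(fit: LMEFit, by: str, within: str) -> dict[str, list[EmmeanRow]]:
    """emmeans of ``by`` at each level of ``within`` (interaction layout)."""
    params, cov = fit.fe_params.values, fit.fe_cov.values
    out: dict[str, list[EmmeanRow]] = {}
    for w in sorted(fit.data[within].dropna().unique()):
        vecs = _emmean_vectors(fit, by, within=(within, w))
        out[str(w)] = [EmmeanRow(lev, float(L @ params),
                                 float(np.sqrt(L @ cov @ L)))
                       for lev, L in vecs.items()]
    return out


def pairwise_bonferroni(fit: LMEFit, by: str, within: str | None = None,
                        family_size: int | None = None) -> list[PairwiseRow]:
    """All pairwise contrasts of ``by`` with Bonferroni-corrected p-values.

    With ``within`` set, contrasts are computed at each level of that factor
    and the Bonferroni family spans every contrast produced, matching the
    muscle-within-behaviour table layout (6 pairs x 2 behaviours).
    ``family_size`` overrides the number of comparisons.
    """
    params, cov = fit.fe_params.values, fit.fe_cov.values
    dfs = _containment_df(fit)
    dden = max(dfs.values()) if dfs else len(fit.data) - 2

    def contrasts(vectors: dict[str, np.ndarray], prefix: str = ""):
        out = []
        for (la, va), (lb, vb) in itertools.combinations(vectors.items(), 2):
            L = va - vb
            est = float(L @ params)
            sem = float(np.sqrt(L @ cov @ L))
            if sem < 1e-300:
                raise ValueError(f"inestimable contrast {prefix}{la} vs {lb}")
            p = 2 * float(sps.t.sf(abs(est / sem), dden))
            out.append((f"{prefix}{la} vs {lb}", est, sem, p))
        return out

    raw = []
    if within is None:
        raw += contrasts(_emmean_vectors(fit, by))
    else:
        for w in sorted(fit.data[within].dropna().unique()):
            raw += contrasts(_emmean_vectors(fit, by, within=(within, w)),
                             prefix=f"{w}: ")
    m_comp = family_size if family_size is not None else len(raw)
    return [PairwiseRow(c, est, sem, p, min(1.0, p * m_comp))
            for c, est, sem, p in raw]


# --- effect sizes and fluorescence -------------------------------------------


def cohens_d(x, y) -> float:
    """Standardized mean difference (pooled-sd denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def evans_blue_analysis(table: pd.DataFrame,
                        interaction: bool = False) -> dict:
    """Per-size-class fluorescence models and treatment effect sizes.

    Background is subtracted from each cell intensity (negative values are
    kept: dark cells are informative).  For every size class with both
    treatments present, an OLS of adjusted intensity on % fin length and
    treatment is fit (optionally with their interaction), and Cohen's d for
    walked vs control is reported per muscle alongside per-muscle means.
    """
    df = table.copy()
    df["adj_intensity"] = df["cell_intensity"] - df["background"]
    out: dict[str, dict] = {}
    for size, sub in df.groupby("size_class", observed=True):
        if sub["treatment"].nunique() < 2:
            warnings.warn(f"size class {size!r} has a single treatment; skipped")
            continue
        formula = ("adj_intensity ~ pct_fin_length * treatment" if interaction
                   else "adj_intensity ~ pct_fin_length + treatment")
        fit = smf.ols(formula, sub).fit()
        d_by_muscle = {}
        means = {}
        for muscle, ms in sub.groupby("muscle", observed=True):
            walked = ms.loc[ms.treatment == "walked", "adj_intensity"]
            control = ms.loc[ms.treatment == "control", "adj_intensity"]
            if len(walked) >= 2 and len(control) >= 2:
                d_by_muscle[muscle] = cohens_d(walked, control)
            means[muscle] = {
                "walked": float(walked.mean()) if len(walked) else float("nan"),
                "control": float(control.mean()) if len(control) else float("nan"),
            }
        out[str(size)] = {
            "model": fit,
            "coefficients": fit.params.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "cohens_d": d_by_muscle,
            "muscle_means": means,
        }
    return out
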