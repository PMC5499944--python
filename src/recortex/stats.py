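"""Statistical layer: ANOVA families, binomial GLM interaction, correlations.

The contract of this module is the returned statistics and their
degrees-of-freedom structure — for a mixed design with N subjects, g
between-subject levels and t within-subject levels, the interaction F is on
((g−1)(t−1), (N−g)(t−1)) df; a between main effect on (g−1, N−g); an
independent factorial with c cells and n observations has error df n − c.
Established routines (pingouin, statsmodels, scipy) do the fitting behind
this surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "GlmInteractionResult",
    "CorrelationResult",
    "mixed_anova",
    "one_way_anova",
    "factorial_anova",
    "tukey_posthoc",
    "binomial_glm_interaction",
    "pearson_with_bisquare",
    "bonferroni_alpha",
]


@dataclass
class AnovaResult:
    """Per-effect F table with explicit numerator/denominator df.

    ``table`` columns: ``effect, F, df_num, df_den, p``.
    """

    table: pd.DataFrame
    sqrt_transformed: bool = False
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(
                f"no effect {name!r}; available: {list(self.table['effect'])}"
            )
        return hit.iloc[0]

    def df_pair(self, name: str) -> tuple[int, int]:
        row = self.effect(name)
        return int(row["df_num"]), int(row["df_den"])


@dataclass(frozen=True)
class GlmInteractionResult:
    wald_chi2: float
    df: int
    p: float
    separation: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float            # robust bisquare slope
    intercept: float
    ols_slope: float
    converged: bool


def _maybe_sqrt(values: pd.Series, apply: bool) -> pd.Series:
    if not apply:
        return values
    if (values < 0).any():
        raise ValueError("square-root transform requires nonnegative data")
    return np.sqrt(values)


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    sqrt_transform: bool = False,
) -> AnovaResult:
    """Two-way mixed (split-plot) ANOVA: between-subject × repeated factor.

    Subjects with any missing cell are excluded listwise (reported in
    ``notes``).  Uncorrected (sphericity-assuming) df are reported, matching
    the classical split-plot layout; apply a Greenhouse–Geisser correction
    downstream if sphericity is in doubt.
    """
    import pingouin as pg

    df = table[[subject, between, within, dv]].dropna().copy()
    n_within = df[within].nunique()
    complete = df.groupby(subject)[within].nunique() == n_within
    keep = complete[complete].index
    dropped = sorted(set(df[subject]) - set(keep))
    df = df[df[subject].isin(keep)]
    if df.empty or df[between].nunique() < 2 or n_within < 2:
        raise ValueError("need >=2 levels per factor and complete cases")
    df[dv] = _maybe_sqrt(df[dv], sqrt_transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=df, dv=dv, between=between, within=within,
            subject=subject, correction=False,
        )
    out = pd.DataFrame(
        {
            "effect": aov["Source"].replace({"Interaction": f"{between}*{within}"}),
            "F": aov["F"],
            "df_num": aov["DF1"],
            "df_den": aov["DF2"],
            "p": aov["p_unc"] if "p_unc" in aov else aov["p-unc"],
        }
    )
    notes = []
    if dropped:
        notes.append(f"listwise-excluded subjects with missing cells: {dropped}")
    return AnovaResult(table=out.reset_index(drop=True),
                       sqrt_transformed=sqrt_transform, notes=notes)


def one_way_anova(table: pd.DataFrame, factor: str, dv: str,
                  sqrt_transform: bool = False) -> AnovaResult:
    """One-way independent ANOVA with df (g−1, N−g)."""
    df = table[[factor, dv]].dropna()
    groups = [g[dv].to_numpy(dtype=float) for _, g in df.groupby(factor)]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    if sqrt_transform:
        groups = [np.sqrt(x) for x in groups]
        if any((x < 0).any() for x in groups):
            raise ValueError("square-root transform requires nonnegative data")
    N = sum(len(x) for x in groups)
    notes = []
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        F, p = 0.0, 1.0
        notes.append("constant dv: zero between- and within-group SS")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = sps.f_oneway(*groups)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
            notes.append("degenerate within-group variance")
    out = pd.DataFrame(
        {"effect": [factor], "F": [float(F)], "df_num": [g - 1],
         "df_den": [N - g], "p": [float(p)]}
    )
    return AnovaResult(table=out, sqrt_transformed=sqrt_transform, notes=notes)


def factorial_anova(table: pd.DataFrame, factors: list[str], dv: str,
                    sqrt_transform: bool = False, typ: int = 2) -> AnovaResult:
    """Independent-samples factorial ANOVA (2-way or 3-way, full model).

    Type II sums of squares by default (robust to the unbalanced group
    sizes of this design without an interaction-priority convention).
    Error df = n − (number of cells); a saturated design with one
    observation per cell has error df 0 and is flagged, not fitted around.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if len(factors) not in (2, 3):
        raise ValueError("factorial_anova supports 2 or 3 factors")
    df = table[factors + [dv]].dropna().copy()
    df["_dv"] = _maybe_sqrt(df[dv].astype(float), sqrt_transform)
    n = len(df)
    levels = [df[f].nunique() for f in factors]
    cells = int(np.prod(levels))
    notes = []
    if n - cells <= 0:
        # no residual variance to test against: report the df structure only
        notes.append(f"saturated design: error df = {n - cells}")
        rows = []
        from itertools import combinations

        for k in range(1, len(factors) + 1):
            for combo in combinations(range(len(factors)), k):
                rows.append(
                    {
                        "effect": "*".join(factors[i] for i in combo),
                        "F": np.nan,
                        "df_num": int(np.prod([levels[i] - 1 for i in combo])),
                        "df_den": n - cells,
                        "p": np.nan,
                    }
                )
        return AnovaResult(table=pd.DataFrame(rows),
                           sqrt_transformed=sqrt_transform, notes=notes)
    rhs = "*".join(f"C({f})" for f in factors)
    model = smf.ols(f"_dv ~ {rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(model, typ=typ)
    resid_df = int(aov.loc["Residual", "df"])
    rows = []
    for term, row in aov.iterrows():
        if term == "Residual":
            continue
        name = term.replace("C(", "").replace(")", "").replace(":", "*")
        rows.append(
            {"effect": name, "F": float(row["F"]), "df_num": int(row["df"]),
             "df_den": resid_df, "p": float(row["PR(>F)"])}
        )
    return AnovaResult(table=pd.DataFrame(rows),
                       sqrt_transformed=sqrt_transform, notes=notes)


def tukey_posthoc(table: pd.DataFrame, factor: str, dv: str,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one factor.

    Returns a frame with columns ``group1, group2, meandiff, p_adj,
    reject``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[factor, dv]].dropna()
    res = pairwise_tukeyhsd(df[dv].to_numpy(dtype=float),
                            df[factor].to_numpy(), alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )


def _ridge_logit_wald(X: np.ndarray, y: np.ndarray, k_int: int,
                      lam: float = 1e-4) -> tuple[float, int]:
    """Ridge-penalized logistic Newton fit + Wald test of the last k_int terms.

    Fallback for complete separation, where the unpenalized MLE diverges.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + lam * np.eye(p)
        grad = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]) + lam * np.eye(p))
    b = beta[-k_int:]
    V = cov[-k_int:, -k_int:]
    chi2 = float(b @ np.linalg.solve(V, b))
    return chi2, k_int


def binomial_glm_interaction(table: pd.DataFrame, outcome: str,
                             factor_a: str, factor_b: str) -> GlmInteractionResult:
    """Wald test of the A×B interaction in a binomial logit model.

    Binary outcomes (e.g. responding / non-responding neurons, neurons as
    samples) are modeled with a logistic GLM containing main effects and
    the full interaction; the Wald χ² jointly tests the (a−1)(b−1)
    interaction coefficients against the additive model.  Complete
    separation is detected and handled with a ridge-penalized fit, flagged
    in the result.
    """
    import statsmodels.api as sm
    from patsy import dmatrices

    df = table[[outcome, factor_a, factor_b]].dropna().copy()
    y_vals = df[outcome].astype(float)
    if not set(np.unique(y_vals)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    a = df[factor_a].nunique()
    b = df[factor_b].nunique()
    df_int = (a - 1) * (b - 1)
    formula = f"{outcome} ~ C({factor_a}) * C({factor_b})"
    y, X = dmatrices(formula, df, return_type="dataframe")
    int_cols = [c for c in X.columns if ":" in c]
    assert len(int_cols) == df_int
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            separated = (not fit.converged) or np.any(np.abs(fit.params) > 15)
        except Exception:
            fit, separated = None, True
    if separated:
        chi2, k = _ridge_logit_wald(X.to_numpy(), y.to_numpy().ravel(),
                                    k_int=df_int)
        p = float(sps.chi2.sf(chi2, k))
        return GlmInteractionResult(wald_chi2=chi2, df=k, p=p, separation=True)
    R = np.zeros((df_int, X.shape[1]))
    for i, c in enumerate(int_cols):
        R[i, X.columns.get_loc(c)] = 1.0
    wt = fit.wald_test(R, scalar=True)
    chi2 = float(wt.statistic)
    return GlmInteractionResult(
        wald_chi2=chi2, df=df_int, p=float(sps.chi2.sf(chi2, df_int)),
        separation=False,
    )


def pearson_with_bisquare(x, y, max_iter: int = 100,
                          tol: float = 1e-8) -> CorrelationResult:
    """Pearson correlation plus a robust bisquare (Tukey biweight) line.

    The robust fit is iteratively reweighted least squares with tuning
    constant 4.685 (95% Gaussian efficiency); ``converged`` reports whether
    IRLS reached ``tol`` within ``max_iter`` iterations.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    r, p = sps.pearsonr(x, y)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits report scale 0
        fit = rlm.fit(maxiter=max_iter, tol=tol)
    n_iter = len(fit.fit_history.get("params", [])) or max_iter
    return CorrelationResult(
        r=float(r), p=float(p),
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        ols_slope=float(ols.params[1]),
        converged=bool(n_iter < max_iter),
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold α/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m
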