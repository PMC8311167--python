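"""Eye-clustered statistical inference.

Two eyes from one participant are correlated, so ordinary regression
understates uncertainty. All group comparisons here use generalized
estimating equations (GEE) with an exchangeable working correlation over
the subject, with robust (sandwich) standard errors; diagnostic models are
logistic GEEs whose fitted probabilities feed ROC analysis. Effect sizes
are Cohen's d with the unweighted root-mean-square of the two group SDs,
d = |m1 - m2| / sqrt((s1^2 + s2^2)/2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import FitError, InputError

__all__ = [
    "cohens_d",
    "GeeFit",
    "RocResult",
    "fit_gee",
    "adjusted_comparison",
    "diagnostic_model",
    "roc_from_scores",
    "delong_auc_ci",
]


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Absolute standardized mean difference, |m1-m2| / sqrt((s1^2+s2^2)/2)."""
    if s1 <= 0 or s2 <= 0:
        raise InputError("standard deviations must be positive")
    return float(abs(m1 - m2) / np.sqrt((s1**2 + s2**2) / 2.0))


@dataclass
class GeeFit:
    """A fitted clustered-regression result with robust inference."""

    formula: str
    family: str  # "gaussian-identity" | "binomial-logit"
    params: pd.Series
    robust_se: pd.Series
    z: pd.Series
    p: pd.Series
    alpha: float  # exchangeable working-correlation estimate
    fitted: np.ndarray
    n_obs: int
    n_clusters: int
    n_dropped: int
    converged: bool
    separation: bool = False
    _result: object = field(default=None, repr=False)

    def wald_test(self, terms: Sequence[str]) -> tuple[float, float, int]:
        """Joint Wald test that the given coefficients are all zero.

        Returns (chi2 statistic, p-value, df); used to compare a model to
        the nested null obtained by deleting ``terms``.
        """
        names = list(self.params.index)
        idx = [names.index(t) for t in terms]
        R = np.zeros((len(idx), len(names)))
        for i, j in enumerate(idx):
            R[i, j] = 1.0
        res = self._result.wald_test(R, scalar=True)
        return float(res.statistic), float(res.pvalue), len(idx)


@dataclass
class RocResult:
    """ROC curve with AUC and a DeLong 95% confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


_FAMILIES = {
    "gaussian": (sm.families.Gaussian(), "gaussian-identity"),
    "binomial": (sm.families.Binomial(), "binomial-logit"),
}


class _BoundedExchangeable(sm.cov_struct.Exchangeable):
    """Exchangeable working correlation with the estimate kept inside (-1, 1).

    With a cluster-constant binary outcome (both eyes share the diagnosis)
    the moment estimator of the common correlation can run past 1, after
    which the working covariance is no longer positive definite and the
    coefficient updates diverge. Clipping to [-0.49, 0.95] keeps cluster
    weighting meaningful for clusters of two.
    """

    def update(self, params):
        super().update(params)
        self.dep_params = float(np.clip(self.dep_params, -0.49, 0.95))


def fit_gee(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    family: str = "gaussian",
    groups: str = "subject_id",
) -> GeeFit:
    """GEE with exchangeable working correlation and sandwich errors.

    Rows with missing values in the used columns are dropped (their count
    is reported on the fit). With one observation per cluster the gaussian
    fit reduces to ordinary least squares.
    """
    if family not in _FAMILIES:
        raise InputError(f"family must be one of {sorted(_FAMILIES)}")
    fam, fam_label = _FAMILIES[family]
    cols = [outcome, groups]
    for term in covariates:  # terms may be patsy expressions like C(group)
        names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term)) - {"C", "Q", "T"}
        cols.extend(n for n in names if n not in cols)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise InputError(f"columns not in data: {missing}")
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    if sub[groups].nunique() < 2:
        raise FitError("need at least 2 clusters")
    rhs = " + ".join(covariates) if covariates else "1"
    formula = f"Q('{outcome}') ~ {rhs}"
    model = smf.gee(
        formula, groups=groups, data=sub, family=fam,
        cov_struct=_BoundedExchangeable(),
    )
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # point at the guilty columns for the caller
        names = model.exog_names
        bad = []
        for j in range(exog.shape[1]):
            others = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise FitError(f"singular design; collinear columns: {bad}")
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:
        raise FitError(f"GEE failed to converge: {exc}") from exc
    fitted = np.asarray(res.fittedvalues)
    separation = False
    if family == "binomial":
        endog = np.asarray(res.model.endog)
        separation = bool(np.all(np.abs(fitted - endog) < 1e-6))
    params = res.params.copy()
    params.index = [n.replace("Q('", "").replace("')", "") for n in params.index]
    se = pd.Series(np.asarray(res.bse), index=params.index)
    z = params / se
    p = pd.Series(2 * sps.norm.sf(np.abs(z)), index=params.index)
    return GeeFit(
        formula=formula,
        family=fam_label,
        params=params,
        robust_se=se,
        z=z,
        p=p,
        alpha=float(np.atleast_1d(res.cov_struct.dep_params)[0]),
        fitted=fitted,
        n_obs=len(sub),
        n_clusters=sub[groups].nunique(),
        n_dropped=n_dropped,
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
        _result=res,
    )


def _group_term(fit: GeeFit, group_col: str) -> str:
    terms = [n for n in fit.params.index if n.startswith(f"C({group_col}")
             or n.startswith(group_col)]
    if not terms:
        raise FitError(f"no {group_col} coefficient in fit: {list(fit.params.index)}")
    return terms[0]


def adjusted_comparison(
    data: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    adjust: Sequence[str] = ("age", "sex", "hypertension"),
) -> dict:
    """One comparison row: group means +- SD, Cohen's d, GEE p-values.

    The univariate p comes from ``outcome ~ group``; the multivariate p from
    the same model additionally adjusted for the listed confounders. Both
    are robust Wald p-values of the group coefficient under inter-eye
    clustering.
    """
    if group_col not in data.columns:
        raise InputError(f"missing {group_col!r} column")
    levels = sorted(data[group_col].dropna().unique())
    if len(levels) != 2:
        raise InputError(f"need exactly 2 groups, got {levels}")
    g1, g2 = levels
    s1 = data.loc[data[group_col] == g1, outcome].dropna()
    s2 = data.loc[data[group_col] == g2, outcome].dropna()
    uni = fit_gee(data, outcome, [f"C({group_col})"])
    adj = fit_gee(data, outcome, [f"C({group_col})", *adjust])
    term = _group_term(uni, group_col)
    term_adj = _group_term(adj, group_col)
    return {
        "outcome": outcome,
        "group1": g1, "mean1": float(s1.mean()), "sd1": float(s1.std(ddof=1)),
        "group2": g2, "mean2": float(s2.mean()), "sd2": float(s2.std(ddof=1)),
        "cohens_d": cohens_d(s1.mean(), s1.std(ddof=1), s2.mean(), s2.std(ddof=1)),
        "univariate_p": float(uni.p[term]),
        "multivariate_p": float(adj.p[term_adj]),
        "group_estimate": float(adj.params[term_adj]),
    }


def delong_auc_ci(
    labels: np.ndarray, scores: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval.

    The AUC is the Mann-Whitney pair-counting statistic; its variance comes
    from the structural components V10 (per case) and V01 (per control).
    """
    labels = np.asarray(labels).astype(bool)
    x = np.asarray(scores, dtype=float)[labels]  # cases
    y = np.asarray(scores, dtype=float)[~labels]  # controls
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise InputError("need both cases and controls")
    # pairwise win matrix with half-credit ties
    diff = x[:, None] - y[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(var)
    zq = sps.norm.ppf(0.5 + level / 2)
    return float(auc), float(max(auc - zq * se, 0.0)), float(min(auc + zq * se, 1.0))


def roc_from_scores(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    """ROC curve + AUC (DeLong CI) from arbitrary scores."""
    auc, lo, hi = delong_auc_ci(labels, scores)
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), scores)
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, fpr=fpr, tpr=tpr, thresholds=thr)


def diagnostic_model(
    data: pd.DataFrame,
    predictors: Sequence[str],
    group_col: str = "group",
    case_label: str = "PD",
    confounders: Sequence[str] = ("age", "sex", "hypertension"),
    groups: str = "subject_id",
) -> tuple[GeeFit, RocResult, dict]:
    """Logistic GEE diagnostic model with ROC from fitted probabilities.

    Fits the null model (confounders only) and the full model (confounders
    plus ``predictors``), compares them with a joint Wald test on the added
    coefficients, and returns the full fit, its ROC, and a summary dict
    with both AUCs and the Wald p-value.
    """
    df = data.copy()
    df["_case"] = (df[group_col] == case_label).astype(int)
    used = ["_case", groups, *confounders, *predictors]
    df = df[used].dropna()
    null_fit = fit_gee(df, "_case", list(confounders), family="binomial", groups=groups)
    full_fit = fit_gee(
        df, "_case", [*confounders, *predictors], family="binomial", groups=groups
    )
    added = [t for t in full_fit.params.index if t not in null_fit.params.index]
    wald_chi2, wald_p, wald_df = full_fit.wald_test(added)
    labels = df["_case"].to_numpy()
    roc_full = roc_from_scores(labels, full_fit.fitted)
    roc_null = roc_from_scores(labels, null_fit.fitted)
    summary = {
        "auc_full": roc_full.auc, "auc_full_ci": (roc_full.ci_low, roc_full.ci_high),
        "auc_null": roc_null.auc, "auc_null_ci": (roc_null.ci_low, roc_null.ci_high),
        "wald_chi2": wald_chi2, "wald_p": wald_p, "wald_df": wald_df,
        "separation": full_fit.separation,
        "n_obs": full_fit.n_obs, "n_clusters": full_fit.n_clusters,
    }
    return full_fit, roc_full, summary
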