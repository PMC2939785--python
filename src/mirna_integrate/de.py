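"""Differential miRNA / gene discovery between two sample groups.

The two-group comparison is a two-sided Mann-Whitney U test per feature with
Benjamini-Hochberg FDR control; candidate miRNAs are then confirmed in a
covariate-adjusted logistic model (group ~ miRNA + clinical covariates) with
a ridge-stabilized fallback when the likelihood is separable, as happens
easily with ~70 samples and several binary covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

PROCESSING_GENES = ("TRBP2", "DICER1", "AGO1", "AGO2", "DROSHA")


@dataclass
class AdjustedAssociation:
    coef: float
    se: float
    p: float
    method: str  # "mle" or "ridge"


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_test(expr: pd.DataFrame, groups: pd.Series | np.ndarray) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature between two groups.

    ``groups`` is boolean (True = group of interest, e.g. IBC).  Direction is
    from the median difference (mean as tie-break).  Missing values are
    excluded per feature.  Constant features get p = 1 and are flagged.
    Returns a DataFrame indexed by feature with columns direction, stat, p,
    q, constant.
    """
    g = np.asarray(pd.Series(groups).to_numpy(), dtype=bool)
    if g.size != expr.shape[1]:
        raise ValueError("groups length must match sample count")
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for feat, row in expr.iterrows():
        x = row.to_numpy(dtype=float)
        a, b = x[g], x[~g]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            rows.append((feat, "na", np.nan, 1.0, True))
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            rows.append((feat, "na", np.nan, 1.0, True))
            continue
        res = mannwhitneyu(a, b, alternative="two-sided")
        diff = np.median(a) - np.median(b)
        if diff == 0:
            diff = a.mean() - b.mean()
        rows.append((feat, "up" if diff > 0 else "down", float(res.statistic), float(res.pvalue), False))
    out = pd.DataFrame(rows, columns=["feature_id", "direction", "stat", "p", "constant"])
    out = out.set_index("feature_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["direction", "stat", "p", "q", "constant"]]


def _neg_loglik(beta, x, y, alpha):
    eta = x @ beta
    # log(1+exp) computed stably
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    pen = 0.5 * alpha * np.sum(beta[1:] ** 2)  # intercept unpenalized
    return -ll + pen


def _neg_grad(beta, x, y, alpha):
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    g = x.T @ (y - mu)
    g[1:] -= alpha * beta[1:]
    return -g


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1.0):
    beta0 = np.zeros(x.shape[1])
    res = optimize.minimize(
        _neg_loglik, beta0, args=(x, y, alpha), jac=_neg_grad, method="BFGS",
        options={"maxiter": 500},
    )
    beta = res.x
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    w = mu * (1 - mu)
    h = x.T @ (x * w[:, None])
    h[1:, 1:] += alpha * np.eye(x.shape[1] - 1)
    cov = np.linalg.inv(h)
    return beta, np.sqrt(np.diag(cov))


def independent_association(
    mirna_expr: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    ridge_alpha: float = 1.0,
) -> AdjustedAssociation:
    """Covariate-adjusted association of one miRNA with a binary group label.

    Fits logistic ``group ~ miRNA + covariates`` by maximum likelihood and
    reports the miRNA coefficient with its Wald p-value.  On (quasi-)
    separation or non-convergence it refits with an L2 penalty on the slopes
    (``ridge_alpha``), flagged as method="ridge".  Categorical covariates are
    dummy-coded with the first level as reference.
    """
    x = np.asarray(pd.Series(mirna_expr).to_numpy(), dtype=float)
    y = np.asarray(pd.Series(group).to_numpy(), dtype=float)
    if np.all(x == x[0]):
        raise ValueError("degenerate predictor: miRNA vector is constant")
    cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
    const_cols = [c for c in cov.columns if cov[c].nunique() < 2]
    if const_cols:
        raise ValueError(f"constant covariate(s): {const_cols}")
    n_params = 2 + cov.shape[1]
    if len(y) < 10 * (n_params - 1):
        warnings.warn(
            f"n={len(y)} is below 10 events per predictor for {n_params - 1} predictors",
            stacklevel=2,
        )
    design = np.column_stack([np.ones_like(x), x, cov.to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            ok = (
                fit.mle_retvals.get("converged", False)
                and np.all(np.isfinite(fit.bse))
                and np.all(np.abs(fit.params) < 15)
                and np.all(fit.bse < 50)
            )
        except (PerfectSeparationWarning, Exception):
            ok = False
    if ok:
        return AdjustedAssociation(
            coef=float(fit.params[1]), se=float(fit.bse[1]),
            p=float(fit.pvalues[1]), method="mle",
        )
    beta, se = _ridge_logit(design, y, alpha=ridge_alpha)
    if not np.all(np.isfinite(se)):
        raise RuntimeError("penalized logistic fit failed to produce standard errors")
    z = beta[1] / se[1]
    return AdjustedAssociation(
        coef=float(beta[1]), se=float(se[1]),
        p=float(2 * stats.norm.sf(abs(z))), method="ridge",
    )


def processing_gene_de(
    mrna_expr: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    genes: tuple[str, ...] = PROCESSING_GENES,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank-test the miRNA-processing genes (TRBP2, DICER1, AGO1, AGO2, DROSHA).

    BH correction is applied within this small family only.  Genes absent
    from the matrix are reported in the second return value, not fatal.
    """
    present = [gn for gn in genes if gn in mrna_expr.index]
    missing = [gn for gn in genes if gn not in mrna_expr.index]
    if missing:
        warnings.warn(f"processing genes absent from matrix: {missing}", stacklevel=2)
    if not present:
        return pd.DataFrame(columns=["direction", "stat", "p", "q", "constant"]), missing
    return rank_test(mrna_expr.loc[present], groups), missing
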