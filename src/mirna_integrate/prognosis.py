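"""Signed target-gene expression score and its survival evaluation.

The score is a per-sample proxy for a miRNA's level built from its direct
target genes: mean expression of the positively correlated targets minus
mean expression of the negatively correlated targets, standardized within a
dataset (median 0, s.d. 1) so it is comparable across expression platforms.
The standardized score is evaluated against follow-up with Cox proportional
hazards (per dataset and pooled by dataset-stratified partial likelihood)
and Kaplan-Meier strata split at the standardized median (0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import spearmanr


@dataclass
class TargetScore:
    mirna_id: str
    scores: pd.Series                 # sample id -> standardized score
    pos_set: set[str] = field(default_factory=set)
    neg_set: set[str] = field(default_factory=set)


@dataclass
class CoxResult:
    dataset_id: str
    endpoint: str
    hazard_ratio: float
    p: float
    n: int
    n_events: int
    setting: str  # "univariate" or "multivariate"


def target_score(
    mrna_expr: pd.DataFrame, pos_set: set[str], neg_set: set[str]
) -> pd.Series:
    """Raw signed target-set score per sample.

    score_s = mean(expr of pos_set) - mean(expr of neg_set).  Genes missing
    from the matrix are dropped with a warning; an empty side contributes 0.
    """
    pos = sorted(pos_set & set(mrna_expr.index))
    neg = sorted(neg_set & set(mrna_expr.index))
    missing = (pos_set | neg_set) - set(mrna_expr.index)
    if missing:
        warnings.warn(f"{len(missing)} score genes absent from matrix", stacklevel=2)
    if not pos and not neg:
        raise ValueError("both gene sets empty after intersection with the matrix")
    if not pos or not neg:
        warnings.warn("one side of the score is empty and contributes 0", stacklevel=2)
    zero = pd.Series(0.0, index=mrna_expr.columns)
    pos_mean = mrna_expr.loc[pos].mean(axis=0) if pos else zero
    neg_mean = mrna_expr.loc[neg].mean(axis=0) if neg else zero
    return (pos_mean - neg_mean).rename("score")


def standardize(scores: pd.Series, mirna_id: str = "", pos_set=None, neg_set=None) -> TargetScore:
    """Standardize a raw score to median 0 and s.d. 1 (the hybrid convention).

    Subtracts the median and divides by the (median-centred) standard
    deviation, so the output is affine-invariant and comparable across
    datasets.
    """
    x = scores.astype(float)
    if x.nunique() < 2:
        raise ValueError("cannot standardize a constant score")
    centred = x - x.median()
    sd = float(centred.std(ddof=1))
    out = centred / sd
    return TargetScore(
        mirna_id=mirna_id, scores=out,
        pos_set=set(pos_set or ()), neg_set=set(neg_set or ()),
    )


def score_from_pairs(
    mrna_expr: pd.DataFrame, pairs: pd.DataFrame, mirna_id: str,
    restrict_to: set[str] | None = None,
) -> TargetScore:
    """Build a standardized TargetScore from a significant-pair table.

    ``pairs`` is the output of ``mirna_mrna_correlations``; positively and
    negatively correlated genes of ``mirna_id`` form the two sides.
    ``restrict_to`` (e.g. the concordant/direct target set) intersects both
    sides first.
    """
    sub = pairs[pairs["mirna_id"] == mirna_id]
    if sub.empty:
        raise KeyError(f"no significant pairs for {mirna_id}")
    pos = set(sub.loc[sub["sign"] == "pos", "gene_id"])
    neg = set(sub.loc[sub["sign"] == "neg", "gene_id"])
    if restrict_to is not None:
        pos &= restrict_to
        neg &= restrict_to
    raw = target_score(mrna_expr, pos, neg)
    return standardize(raw, mirna_id=mirna_id, pos_set=pos, neg_set=neg)


def score_mirna_concordance(score: TargetScore, mirna_expr: pd.Series) -> float:
    """Spearman rho between the target-gene score and the miRNA's own expression."""
    shared = [s for s in score.scores.index if s in mirna_expr.index]
    x = score.scores[shared]
    y = mirna_expr[shared]
    ok = x.notna() & y.notna()
    if int(ok.sum()) < 5:
        raise ValueError("need >= 5 shared samples with observed values")
    rho = spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def _km_strata(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label, sub in df.groupby("stratum"):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        rows.append((label, len(sub), int(sub["event"].sum()), float(km.median_survival_time_)))
    return pd.DataFrame(rows, columns=["stratum", "n", "events", "median_time"]).set_index("stratum")


def cox_evaluate(
    score: TargetScore,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    pooled: str = "stratified",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cox proportional-hazards evaluation of a standardized score.

    ``survival`` columns: sample_id, dataset_id, endpoint, time, event.  For
    every (endpoint, dataset) with >= 10 events a per-unit hazard ratio with
    Wald p is fitted, plus a pooled "Total" row per endpoint: by default a
    dataset-stratified partial likelihood (``pooled="stratified"``), or a
    single model with dataset fixed effects (``pooled="fixed"``).  Also
    returns a Kaplan-Meier summary of strata split at score 0.

    Raises on no events; monotone-likelihood (non-converging) fits are
    reported as NaN rows with a warning.
    """
    if pooled not in ("stratified", "fixed"):
        raise ValueError("pooled must be 'stratified' or 'fixed'")
    df = survival.copy()
    df["score"] = df["sample_id"].map(score.scores)
    df = df.dropna(subset=["score"])
    if int(df["event"].sum()) == 0:
        raise ValueError("no events in the survival table")
    setting = "univariate"
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        df = df.join(cov, on="sample_id")
        setting = "multivariate"
        cov_cols = list(cov.columns)
    else:
        cov_cols = []

    def _fit(sub: pd.DataFrame, dataset_label: str, endpoint: str, strata=None):
        n_events = int(sub["event"].sum())
        if n_events < 10:
            warnings.warn(
                f"{dataset_label}/{endpoint}: {n_events} events < 10, skipped", stacklevel=3
            )
            return None
        cols = ["time", "event", "score"] + cov_cols + ([strata] if strata else [])
        cph = CoxPHFitter()
        try:
            cph.fit(sub[cols], duration_col="time", event_col="event",
                    strata=[strata] if strata else None)
        except ConvergenceError:
            warnings.warn(f"{dataset_label}/{endpoint}: monotone likelihood, fit failed",
                          stacklevel=3)
            return CoxResult(dataset_label, endpoint, np.nan, np.nan, len(sub), n_events, setting)
        return CoxResult(
            dataset_label, endpoint,
            float(np.exp(cph.params_["score"])),
            float(cph.summary.loc["score", "p"]),
            len(sub), n_events, setting,
        )

    results: list[CoxResult] = []
    for endpoint, esub in df.groupby("endpoint"):
        for ds, dsub in esub.groupby("dataset_id"):
            res = _fit(dsub, str(ds), str(endpoint))
            if res:
                results.append(res)
        if esub["dataset_id"].nunique() > 1:
            if pooled == "stratified":
                res = _fit(esub, "Total", str(endpoint), strata="dataset_id")
            else:
                dummies = pd.get_dummies(esub["dataset_id"], prefix="ds", drop_first=True, dtype=float)
                esub2 = pd.concat([esub, dummies], axis=1)
                cov_cols_saved = list(cov_cols)
                cov_cols.extend(dummies.columns)
                res = _fit(esub2, "Total", str(endpoint))
                cov_cols[:] = cov_cols_saved
            if res:
                results.append(res)
    cox_table = pd.DataFrame([vars(r) for r in results])
    df["stratum"] = np.where(df["score"] > 0, "high score", "low score")
    return cox_table, _km_strata(df)
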