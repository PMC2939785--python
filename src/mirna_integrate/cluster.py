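"""Unsupervised sample clustering and cluster-clinical association tests.

Complete-linkage hierarchical clustering on Euclidean sample distances over
the most-varying miRNAs; the number of clusters is chosen by maximizing the
average silhouette width, with a feature-shuffle permutation test for its
significance.  Cluster-clinical associations use the Pearson chi-square test
(no continuity correction) and a permutation-calibrated global (Goeman-style)
test of whole-profile association with a binary outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency
from sklearn.metrics import silhouette_score

DEFAULT_K_RANGE = range(2, 7)


@dataclass
class ClusterResult:
    labels: pd.Series            # sample id -> cluster index (1-based)
    k: int
    avg_silhouette: float
    silhouettes_by_k: dict[int, float] = field(default_factory=dict)
    permutation_p: float | None = None


@dataclass
class AssociationResult:
    variable: str
    statistic: float
    df: int
    p: float


@dataclass
class GlobalTestResult:
    statistic: float
    p: float
    n_perm: int


def impute_feature_min(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by the feature's minimum observed expression.

    Undetected qPCR reactions carry no magnitude, but detection failure at a
    fixed cycle cutoff is itself evidence of low abundance, so the feature
    minimum is a conservative stand-in for distance computations.
    """
    mins = expr.min(axis=1)
    return expr.apply(lambda row: row.fillna(mins[row.name]), axis=1)


def top_varying(expr: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Subset to the ``k`` features with largest per-feature standard deviation.

    Ties are broken lexicographically on the feature id so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds feature count {expr.shape[0]}")
    sd = expr.std(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda f: (-sd[f], f))
    chosen = sorted(order[:k], key=list(expr.index).index)
    return expr.loc[chosen]


def _avg_silhouette_at_k(x: np.ndarray, z: np.ndarray, k: int) -> tuple[float, np.ndarray] | None:
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        return None
    return float(silhouette_score(x, labels, metric="euclidean")), labels


def hierarchical_cluster(
    expr: pd.DataFrame, k_range: range | list[int] = DEFAULT_K_RANGE
) -> ClusterResult:
    """Complete-linkage Euclidean clustering with silhouette-selected k.

    Samples (columns) are clustered; missing values are imputed with the
    per-feature minimum first.  The returned ``k`` maximizes average
    silhouette width over ``k_range`` (ties go to the smaller k).
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    ks = sorted(set(int(k) for k in k_range) & set(range(2, n)))
    if not ks:
        raise ValueError(f"k_range must intersect [2, {n - 1}]")
    x = impute_feature_min(expr).to_numpy(dtype=float).T  # samples x features
    d = pdist(x, metric="euclidean")
    if np.allclose(d, 0):
        raise ValueError("all samples are identical: distances degenerate")
    z = linkage(d, method="complete")
    best = None
    by_k: dict[int, float] = {}
    for k in ks:
        res = _avg_silhouette_at_k(x, z, k)
        if res is None:
            continue
        s, labels = res
        by_k[k] = s
        if best is None or s > best[0]:
            best = (s, k, labels)
    if best is None:
        raise ValueError("no k in k_range produced >= 2 distinct clusters")
    s, k, labels = best
    return ClusterResult(
        labels=pd.Series(labels, index=expr.columns, name="cluster"),
        k=k,
        avg_silhouette=s,
        silhouettes_by_k=by_k,
    )


def silhouette_permutation_p(
    expr: pd.DataFrame,
    observed_avg_silhouette: float,
    k_range: range | list[int] = DEFAULT_K_RANGE,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for an observed average silhouette width.

    The null is generated by independently shuffling each feature's values
    across samples, which preserves marginal feature distributions while
    destroying inter-sample structure; each shuffled matrix is re-clustered
    with the same silhouette-maximizing pipeline.  p uses the add-one rule
    (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    x = impute_feature_min(expr).to_numpy(dtype=float)
    hits = 0
    for _ in range(n_perm):
        xp = np.array([rng.permutation(row) for row in x])
        perm_expr = pd.DataFrame(xp, index=expr.index, columns=expr.columns)
        try:
            res = hierarchical_cluster(perm_expr, k_range)
        except ValueError:
            continue
        if res.avg_silhouette >= observed_avg_silhouette:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def chi_square_association(
    labels_or_group: pd.Series, variable: pd.Series, name: str | None = None
) -> AssociationResult:
    """Pearson chi-square test (no continuity correction) on a contingency table."""
    a = pd.Series(labels_or_group).astype(str)
    b = pd.Series(variable).astype(str)
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 non-empty levels in both variables")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: zero margin")
    stat, p, df, _ = chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(
        variable=name or (variable.name or "variable"),
        statistic=float(stat),
        df=int(df),
        p=float(p),
    )


def chi_square_from_table(table: np.ndarray, name: str = "table") -> AssociationResult:
    """Pearson chi-square directly from counts (rows x groups), no correction."""
    stat, p, df, _ = chi2_contingency(np.asarray(table), correction=False)
    return AssociationResult(variable=name, statistic=float(stat), df=int(df), p=float(p))


def global_test(
    expr: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> GlobalTestResult:
    """Permutation-calibrated global test of expression-outcome association.

    Features are standardized, then Q = || Z y_c ||^2 where Z is the
    standardized feature x sample matrix and y_c the centred binary outcome;
    this is the quadratic score statistic of a random-effects alternative
    (the Goeman global-test statistic up to a constant).  Significance comes
    from outcome-label permutations, which makes the p-value exact under
    exchangeability and invariant to feature rescaling.
    """
    y = np.asarray(pd.Series(outcome).to_numpy(), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if expr.shape[1] != y.size:
        raise ValueError("outcome length must match sample count")
    x = impute_feature_min(expr).to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features constant")
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    yc = y - y.mean()
    q_obs = float(np.sum((z @ yc) ** 2))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(yc) for _ in range(n_perm)]).T  # n x B
    q_perm = np.sum((z @ perms) ** 2, axis=0)
    p = (1 + int(np.sum(q_perm >= q_obs))) / (n_perm + 1)
    return GlobalTestResult(statistic=q_obs, p=p, n_perm=n_perm)
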