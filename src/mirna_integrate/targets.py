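"""Correlation-based miRNA target inference and hypergeometric enrichment.

Putative targets of a miRNA are genes whose expression correlates (Spearman,
either sign) with the miRNA's relative expression across matched samples,
with BH FDR control applied jointly over all tested miRNA-gene pairs.
Putative targets are then checked for concordance with a sequence-based
prediction database (TargetScan-style flat miRNA -> gene lists) by
hypergeometric enrichment, and concordant (direct) targets are functionally
profiled against GMT gene-set collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom, rankdata

from .de import bh_fdr, rank_test


@dataclass
class TargetDB:
    """Flat mapping from miRNA (family) id to predicted target gene symbols."""

    targets: dict[str, set[str]]
    source_label: str = "unspecified"

    def __post_init__(self):
        for m, genes in self.targets.items():
            if any(not g for g in genes):
                raise ValueError(f"empty gene symbol under {m}")

    def restricted_to(self, universe: set[str]) -> "TargetDB":
        return TargetDB(
            {m: g & universe for m, g in self.targets.items()},
            source_label=self.source_label,
        )

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __getitem__(self, mirna: str) -> set[str]:
        return self.targets[mirna]


@dataclass
class GeneSetEnrichmentResult:
    term_id: str
    overlap_k: int
    set_size: int
    reference_size: int
    universe_size: int
    p: float
    q: float | None = None
    genes: set[str] = field(default_factory=set)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, a)


def spearman_matrix(
    x: pd.DataFrame, y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p between rows of x and rows of y.

    Uses midranks for ties and the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)) for p-values.  Columns (samples) must
    already be aligned.  Missing values are handled pairwise-complete:
    each (x-row, y-row) pair is correlated over the samples observed in
    both.  Pairs with < 5 complete samples or zero rank variance yield NaN.
    """
    if not x.columns.equals(y.columns):
        raise ValueError("sample columns must be aligned")
    if x.shape[1] < 5:
        raise ValueError("need >= 5 shared samples")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    y_ok = ~np.isnan(yv)
    rho = np.full((xv.shape[0], yv.shape[0]), np.nan)
    pmat = np.full_like(rho, np.nan)
    # group x-rows by their missingness mask; within a group, genes complete
    # on the mask are fully vectorized, the rest fall back to per-pair ranks
    for i in range(xv.shape[0]):
        x_ok = ~np.isnan(xv[i])
        cols = np.where(x_ok)[0]
        if cols.size < 5:
            continue
        rx = rankdata(xv[i, cols])
        rxc = rx - rx.mean()
        sx = np.sqrt(np.sum(rxc**2))
        complete = y_ok[:, cols].all(axis=1)
        if sx > 0 and complete.any():
            ry = _rank_rows(yv[np.where(complete)[0]][:, cols])
            ryc = ry - ry.mean(axis=1, keepdims=True)
            sy = np.sqrt(np.sum(ryc**2, axis=1))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (ryc @ rxc) / (sy * sx)
            rho[i, complete] = r
            pmat[i, complete] = _t_pvalue(r, cols.size)
        for j in np.where(~complete)[0]:
            both = x_ok & y_ok[j]
            nb = int(both.sum())
            if nb < 5:
                continue
            rxj = rankdata(xv[i, both])
            ryj = rankdata(yv[j, both])
            if np.all(rxj == rxj[0]) or np.all(ryj == ryj[0]):
                continue
            r = np.corrcoef(rxj, ryj)[0, 1]
            rho[i, j] = r
            pmat[i, j] = _t_pvalue(np.array([r]), nb)[0]
    rho = np.clip(rho, -1.0, 1.0)
    return (
        pd.DataFrame(rho, index=x.index, columns=y.index),
        pd.DataFrame(pmat, index=x.index, columns=y.index),
    )


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def mirna_mrna_correlations(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    mirna_ids: list[str] | None = None,
    fdr: float = 0.1,
    return_all: bool = False,
) -> pd.DataFrame:
    """Significant Spearman-correlated miRNA-mRNA pairs at a joint BH FDR.

    Both matrices are restricted to their shared samples; BH is applied
    jointly over every tested pair (one family).  Pairs with constant
    vectors are skipped with a warning.  Returns a DataFrame with columns
    mirna_id, gene_id, rho, p, q, sign; only pairs with q < ``fdr`` unless
    ``return_all``.
    """
    if mirna_ids is not None:
        missing = [m for m in mirna_ids if m not in mirna_expr.index]
        if missing:
            raise KeyError(f"miRNAs absent from expression matrix: {missing}")
        mirna_expr = mirna_expr.loc[mirna_ids]
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if len(shared) < 5:
        raise ValueError("need >= 5 shared samples between the two matrices")
    mi = mirna_expr[shared]
    mr = mrna_expr[shared]
    rho, p = spearman_matrix(mi, mr)
    long = (
        rho.stack().rename("rho").to_frame()
        .join(p.stack().rename("p"))
        .reset_index()
        .rename(columns={"level_0": "mirna_id", "level_1": "gene_id"})
    )
    bad = long["rho"].isna()
    if bad.any():
        warnings.warn(f"skipped {int(bad.sum())} pairs with constant vectors", stacklevel=2)
        long = long[~bad]
    long["q"] = bh_fdr(long["p"].to_numpy())
    long["sign"] = np.where(long["rho"] > 0, "pos", "neg")
    if not return_all:
        long = long[long["q"] < fdr]
    return long.reset_index(drop=True)


def correlated_gene_sets(pairs: pd.DataFrame) -> dict[str, set[str]]:
    """Group a significant-pair table into per-miRNA correlated gene sets."""
    return {m: set(sub["gene_id"]) for m, sub in pairs.groupby("mirna_id")}


def hypergeometric_test(
    set_a: set[str], reference: set[str], universe: set[str], term_id: str = ""
) -> GeneSetEnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``set_a`` in ``reference``.

    p = P(overlap >= observed) when ``len(set_a)`` genes are drawn without
    replacement from ``universe`` containing ``len(reference)`` successes.
    """
    if not set_a <= universe or not reference <= universe:
        raise ValueError("set and reference must be subsets of the universe")
    m, k_ref, n_draw = len(universe), len(reference), len(set_a)
    overlap = set_a & reference
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, m, k_ref, n_draw)) if n_draw else 1.0
    return GeneSetEnrichmentResult(
        term_id=term_id, overlap_k=k, set_size=n_draw,
        reference_size=k_ref, universe_size=m, p=min(p, 1.0), genes=overlap,
    )


def de_concordance_gsea(
    correlated: dict[str, set[str]],
    de_reference: set[str],
    universe: set[str],
    mrna_expr: pd.DataFrame | None = None,
    groups: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-miRNA enrichment of correlated genes in the group-differential genes.

    ``de_reference`` is the set of genes differential between the two groups
    (reference set); each miRNA's correlated gene set is tested against it.
    If expression and group labels are given, a direction summary (increased
    or decreased in the group of interest) is computed from the mean
    expression difference of the correlated set.  Empty sets yield NA rows.
    """
    rows = []
    qs_input = []
    for mirna, genes in correlated.items():
        genes = genes & universe
        if not genes:
            rows.append((mirna, 0, np.nan, None))
            continue
        res = hypergeometric_test(genes, de_reference & universe, universe)
        direction = None
        if mrna_expr is not None and groups is not None:
            g = np.asarray(pd.Series(groups).to_numpy(), dtype=bool)
            sub = mrna_expr.loc[sorted(genes & set(mrna_expr.index))].to_numpy(dtype=float)
            diff = np.nanmean(sub[:, g]) - np.nanmean(sub[:, ~g])
            direction = "increased" if float(diff) > 0 else "decreased"
        rows.append((mirna, res.overlap_k, res.p, direction))
        qs_input.append(res.p)
    df = pd.DataFrame(rows, columns=["mirna_id", "overlap_k", "p", "direction"]).set_index("mirna_id")
    tested = df["p"].notna()
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    return df


def concordant_targets(
    pairs: pd.DataFrame,
    db: TargetDB,
    universe: set[str],
    fdr: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Concordance of correlation-defined targets with predicted targets.

    For each miRNA with significant correlated genes, tests whether its
    database-predicted targets (intersected with the universe) are enriched
    among the correlated genes: universe = all testable genes, reference =
    the miRNA's correlated genes, draws = predicted targets.  miRNAs flagged
    concordant at BH q < ``fdr``; the per-miRNA intersection (correlated AND
    predicted) is what downstream analyses should use.  miRNAs absent from
    the database get NA.
    """
    corr_sets = correlated_gene_sets(pairs)
    counts = pairs.groupby(["mirna_id", "sign"]).size().unstack(fill_value=0)
    db_u = db.restricted_to(universe)
    rows = []
    intersections: dict[str, set[str]] = {}
    for mirna in sorted(corr_sets):
        correlated = corr_sets[mirna] & universe
        n_neg = int(counts.loc[mirna, "neg"]) if "neg" in counts.columns else 0
        n_pos = int(counts.loc[mirna, "pos"]) if "pos" in counts.columns else 0
        if mirna not in db_u or not db_u[mirna]:
            rows.append((mirna, len(correlated), n_neg, n_pos, np.nan, 0, np.nan, False))
            continue
        predicted = db_u[mirna]
        res = hypergeometric_test(predicted, correlated, universe)
        inter = correlated & predicted
        intersections[mirna] = inter
        rows.append((mirna, len(correlated), n_neg, n_pos, len(predicted), len(inter), res.p, False))
    df = pd.DataFrame(
        rows,
        columns=["mirna_id", "n_correlated", "n_negative", "n_positive",
                 "n_predicted", "n_intersect", "p", "concordant"],
    ).set_index("mirna_id")
    tested = df["p"].notna()
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    df["concordant"] = df["q"] < fdr
    return df, intersections


def de_reference_genes(
    mrna_expr: pd.DataFrame, groups: pd.Series | np.ndarray, fdr: float = 0.1
) -> set[str]:
    """Genes differential between the two groups at BH q < ``fdr`` (rank test)."""
    res = rank_test(mrna_expr, groups)
    return set(res.index[res["q"] < fdr])


def functional_enrichment(
    genes: set[str],
    collections: dict[str, set[str]],
    universe: set[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``genes`` against GMT-style term sets.

    Terms are intersected with the universe first; terms with no universe
    overlap are skipped.  Results are ranked ascending by p with BH q
    computed across all tested terms; the ``top_n`` head is returned.
    """
    if not collections:
        raise ValueError("empty gene-set collection")
    genes = genes & universe
    rows = []
    for term, members in collections.items():
        if len(members) > len(universe):
            raise ValueError(f"term {term} larger than the universe")
        members = members & universe
        if not members:
            continue
        res = hypergeometric_test(genes, members, universe, term_id=term)
        rows.append((term, res.overlap_k, len(members), res.p))
    df = pd.DataFrame(rows, columns=["term_id", "overlap_k", "term_size", "p"]).set_index("term_id")
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else np.nan
    df = df.sort_values(["p", "term_id"], kind="mergesort")
    return df.head(top_n)
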