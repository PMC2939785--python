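import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mirna_integrate import (
    TargetDB,
    concordant_targets,
    de_concordance_gsea,
    functional_enrichment,
    hypergeometric_test,
    mirna_mrna_correlations,
)
from mirna_integrate.datasets import direct_target_genes
from mirna_integrate.targets import spearman_matrix

from conftest import toy_ct


def enumeration_hypergeom_p(universe_n, ref_n, draw_n, k_obs):
    """Exact upper-tail overlap probability by counting combinations."""
    total = comb(universe_n, draw_n)
    return sum(
        comb(ref_n, k) * comb(universe_n - ref_n, draw_n - k)
        for k in range(k_obs, min(ref_n, draw_n) + 1)
    ) / total


class TestSpearmanMatrix:
    def test_matches_scipy_with_ties(self, rng):
        x = toy_ct(rng.integers(0, 4, size=(4, 8)).astype(float))
        y = toy_ct(rng.integers(0, 4, size=(6, 8)).astype(float), mirnas=[f"g{i}" for i in range(6)])
        rho, p = spearman_matrix(x, y)
        for i in x.index:
            for j in y.index:
                ref = spearmanr(x.loc[i], y.loc[j])
                assert rho.loc[i, j] == pytest.approx(ref.statistic, abs=1e-12)
                assert p.loc[i, j] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_rank_then_pearson_oracle(self, rng):
        # rho equals Pearson correlation of midranks
        x = toy_ct(rng.integers(0, 3, size=(1, 8)).astype(float))
        y = toy_ct(rng.integers(0, 3, size=(1, 8)).astype(float), mirnas=["g0"])
        rho, _ = spearman_matrix(x, y)
        rx = pd.Series(x.iloc[0]).rank().to_numpy()
        ry = pd.Series(y.iloc[0]).rank().to_numpy()
        assert rho.iloc[0, 0] == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_pairwise_complete_with_missing(self, rng):
        xv = rng.normal(size=(1, 12))
        xv[0, 2] = np.nan
        yv = rng.normal(size=(2, 12))
        yv[1, 5] = np.nan
        x, y = toy_ct(xv), toy_ct(yv, mirnas=["g0", "g1"])
        rho, _ = spearman_matrix(x, y)
        for j, gene in enumerate(["g0", "g1"]):
            mask = ~(np.isnan(xv[0]) | np.isnan(yv[j]))
            ref = spearmanr(xv[0, mask], yv[j, mask]).statistic
            assert rho.loc["m0", gene] == pytest.approx(ref, abs=1e-12)


class TestCorrelationPairs:
    def test_monotone_gene_perfect_rho(self, rng):
        m = toy_ct(rng.normal(size=(1, 10)))
        g = toy_ct(np.exp(m.to_numpy()) * 2 + 1, mirnas=["g0"])
        pairs = mirna_mrna_correlations(m, g, fdr=0.1)
        assert len(pairs) == 1
        assert pairs["rho"].iloc[0] == pytest.approx(1.0)
        assert pairs["sign"].iloc[0] == "pos"

    def test_null_matrix_yields_no_pairs(self, rng):
        m = toy_ct(rng.normal(size=(3, 44)))
        g = toy_ct(rng.normal(size=(500, 44)), mirnas=[f"g{i}" for i in range(500)])
        pairs = mirna_mrna_correlations(m, g, fdr=0.1)
        assert len(pairs) <= 2  # joint BH keeps the null family nearly empty

    def test_sign_flip_preserves_magnitudes(self, rng):
        m = toy_ct(rng.normal(size=(2, 20)))
        g = toy_ct(rng.normal(size=(30, 20)), mirnas=[f"g{i}" for i in range(30)])
        a = mirna_mrna_correlations(m, g, return_all=True).set_index(["mirna_id", "gene_id"])
        b = mirna_mrna_correlations(m, -g, return_all=True).set_index(["mirna_id", "gene_id"])
        assert np.allclose(a["rho"], -b["rho"])
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["q"], b["q"])
        assert ((a["sign"] == "pos") == (b["sign"] == "neg")).all()

    def test_requires_shared_samples(self, rng):
        m = toy_ct(rng.normal(size=(1, 6)), samples=[f"a{j}" for j in range(6)])
        g = toy_ct(rng.normal(size=(1, 6)), samples=[f"b{j}" for j in range(6)])
        with pytest.raises(ValueError, match="shared"):
            mirna_mrna_correlations(m, g)


class TestHypergeometric:
    def test_worked_example(self):
        u = {f"g{i}" for i in range(10)}
        ref = {f"g{i}" for i in range(5)}
        res = hypergeometric_test({"g0", "g1", "g2"}, ref, u)
        assert res.p == pytest.approx(10 / 120)

    def test_empty_set_p_one(self):
        u = {"a", "b", "c"}
        assert hypergeometric_test(set(), {"a"}, u).p == 1.0

    def test_set_equals_universe_certain(self):
        u = {f"g{i}" for i in range(8)}
        ref = {f"g{i}" for i in range(3)}
        res = hypergeometric_test(u, ref, u)
        assert res.overlap_k == 3
        assert res.p == pytest.approx(1.0)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test({"x"}, {"a"}, {"a", "b"})

    def test_matches_enumeration_on_random_configs(self, rng):
        for _ in range(100):
            nu = int(rng.integers(3, 13))
            u = {f"g{i}" for i in range(nu)}
            ref = set(rng.choice(sorted(u), size=rng.integers(1, nu), replace=False))
            sa = set(rng.choice(sorted(u), size=rng.integers(0, nu), replace=False))
            res = hypergeometric_test(sa, ref, u)
            exact = enumeration_hypergeom_p(nu, len(ref), len(sa), res.overlap_k)
            assert res.p == pytest.approx(exact, abs=1e-12)


class TestDeConcordance:
    def test_fully_contained_set_matches_oracle(self, rng):
        u = {f"g{i}" for i in range(20)}
        ref = {f"g{i}" for i in range(10)}
        corr = {"miR-x": {"g0", "g1", "g2"}}
        res = de_concordance_gsea(corr, ref, u)
        exact = enumeration_hypergeom_p(20, 10, 3, 3)
        assert res.loc["miR-x", "p"] == pytest.approx(exact)

    def test_empty_set_reported_na(self):
        res = de_concordance_gsea({"miR-x": set()}, {"a"}, {"a", "b"})
        assert np.isnan(res.loc["miR-x", "p"])

    def test_direction_summary(self, rng):
        u = {"a", "b"}
        expr = toy_ct(np.array([[5.0, 5, 1, 1], [6, 6, 2, 2]]), mirnas=["a", "b"])
        g = [True, True, False, False]
        res = de_concordance_gsea({"m": {"a", "b"}}, {"a"}, u, mrna_expr=expr, groups=g)
        assert res.loc["m", "direction"] == "increased"


def _pairs_frame(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "rho", "p", "q", "sign"])


class TestConcordantTargets:
    def test_disjoint_sets_p_one(self):
        u = {f"g{i}" for i in range(10)}
        pairs = _pairs_frame([("m1", "g0", 0.9, 1e-4, 1e-3, "pos")])
        db = TargetDB({"m1": {"g5", "g6"}})
        res, inter = concordant_targets(pairs, db, u)
        assert res.loc["m1", "p"] == pytest.approx(1.0)
        assert inter["m1"] == set()

    def test_absent_mirna_is_na(self):
        u = {"g0", "g1"}
        pairs = _pairs_frame([("m1", "g0", 0.9, 1e-4, 1e-3, "pos")])
        res, inter = concordant_targets(pairs, TargetDB({}), u)
        assert np.isnan(res.loc["m1", "p"])
        assert not res.loc["m1", "concordant"]
        assert "m1" not in inter

    def test_totals_equal_pos_plus_neg(self, small_cohort):
        from mirna_integrate import filter_informative, mirna_mrna_correlations, normalize_global_centre

        c = small_cohort
        expr = normalize_global_centre(filter_informative(c.ct))[c.mrna.columns]
        pairs = mirna_mrna_correlations(expr.loc[sorted(set(c.truth.de_mirnas) & set(expr.index))], c.mrna)
        res, _ = concordant_targets(pairs, c.target_db, set(c.mrna.index))
        assert (res["n_correlated"] == res["n_negative"] + res["n_positive"]).all()

    def test_planted_concordance_recovered(self, small_cohort):
        from mirna_integrate import filter_informative, mirna_mrna_correlations, normalize_global_centre

        c = small_cohort
        expr = normalize_global_centre(filter_informative(c.ct))[c.mrna.columns]
        truth = set(c.truth.de_mirnas)
        pairs = mirna_mrna_correlations(expr.loc[sorted(truth & set(expr.index))], c.mrna)
        res, _ = concordant_targets(pairs, c.target_db, set(c.mrna.index))
        planted = res.loc[res.index.isin(truth)]
        assert planted["concordant"].mean() >= 0.9

    def test_packaged_direct_target_counts(self):
        db = direct_target_genes()
        assert len(db["miR-342-3p"]) == 19
        assert len(db["miR-520a-5p"]) == 13
        assert len(db["miR-29a"]) == 121
        assert len(db["miR-30b"]) == 140


class TestFunctionalEnrichment:
    def test_exact_term_ranks_first(self):
        u = {f"g{i}" for i in range(30)}
        genes = {f"g{i}" for i in range(5)}
        colls = {"exact": set(genes), "other": {f"g{i}" for i in range(10, 20)}}
        res = functional_enrichment(genes, colls, u)
        assert res.index[0] == "exact"
        assert res["p"].iloc[0] < res["p"].iloc[1]

    def test_term_larger_than_universe_rejected(self):
        u = {"a", "b"}
        with pytest.raises(ValueError, match="larger"):
            functional_enrichment({"a"}, {"big": {"a", "b", "c"}}, u)

    def test_minimum_p_matches_order_statistic_oracle(self, rng):
        # smallest p over K independent null terms ~ Beta(1, K) approximately;
        # check the median of the simulated minimum against the closed form
        nu, term_size, n_genes, k_terms = 40, 8, 8, 50
        u = [f"g{i}" for i in range(nu)]
        mins = []
        for r in range(60):
            r2 = np.random.default_rng(r)
            genes = set(r2.choice(u, size=n_genes, replace=False))
            colls = {
                f"t{t}": set(r2.choice(u, size=term_size, replace=False))
                for t in range(k_terms)
            }
            res = functional_enrichment(genes, colls, set(u), top_n=1)
            mins.append(res["p"].iloc[0])
        # conservative discrete p => median of min-p at or above Beta(1,K) median
        beta_median = 1 - 0.5 ** (1 / k_terms)
        assert np.median(mins) > 0.2 * beta_median
        assert np.median(mins) < 20 * beta_median

    def test_planted_gene_set_recovered(self, small_cohort):
        c = small_cohort
        mirna = sorted(c.truth.de_mirnas)[0]
        planted = {g for m, g, _, _ in c.truth.planted_pairs if m == mirna}
        res = functional_enrichment(planted, c.gene_sets, set(c.mrna.index), top_n=3)
        assert res.index[0].startswith("SET_PLANTED")
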