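"""Exact tests, enrichment folds, correlations, ligand repertoires."""

from math import comb, inf

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichestate.enrichment import (
    StatsError,
    accessibility_expression_correlation,
    cluster_sensitivity_enrichment,
    deg_dar_association,
    fisher_2x2,
    hypergeom_enrichment,
    lfc_by_cluster,
    ligand_repertoire_compare,
)


class TestHypergeom:
    def test_zero_overlap_degenerate_tail(self):
        res = hypergeom_enrichment(0, 5, 5, 20)
        assert res.p == 1.0
        assert res.fold == 0.0

    def test_complete_overlap_exact_value(self):
        # P(X = 5) with N=10, K=5, n=5 is 1 / C(10,5) = 1/252
        res = hypergeom_enrichment(5, 5, 5, 10)
        assert res.p == pytest.approx(1 / 252, abs=1e-12)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(StatsError):
            hypergeom_enrichment(6, 5, 5, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pmf_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            N = int(rng.integers(2, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            res = hypergeom_enrichment(k, K, n, N)
            oracle = sum(
                comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
            ) / comb(N, n)
            assert abs(res.p - oracle) < 1e-12

    def test_fold_is_one_at_expected_overlap(self):
        # K=10, n=20, N=100 -> expected overlap 2
        res = hypergeom_enrichment(2, 10, 20, 100)
        assert res.fold == pytest.approx(1.0)


class TestFisher:
    def test_balanced_table(self):
        res = fisher_2x2([[5, 5], [5, 5]])
        assert res.p == 1.0
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_organ_specific_susceptibility_table(self):
        # 68/275 intestine DEGs vs 90/650 stomach DEGs PRC2-susceptible
        res = fisher_2x2([[68, 207], [90, 560]])
        assert 1e-5 < res.p < 1e-3

    def test_zero_margin_flags_undefined(self):
        res = fisher_2x2([[0, 0], [3, 4]])
        assert res.p == 1.0
        assert np.isnan(res.odds_ratio)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            t = rng.integers(0, 40, size=4)
            mine = fisher_2x2([[t[0], t[1]], [t[2], t[3]]])
            ref = stats.fisher_exact([[t[0], t[1]], [t[2], t[3]]])
            assert abs(mine.p - ref.pvalue) < 1e-9

    def test_large_table_log_space_path(self):
        res = fisher_2x2([[600, 1500], [900, 1200]])
        ref = stats.fisher_exact([[600, 1500], [900, 1200]])
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDegDarAssociation:
    def test_independent_flags_near_unit_fold(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(4000)]
        deg = pd.Series(rng.random(4000) < 0.2, index=idx)
        dar = pd.Series(rng.random(4000) < 0.3, index=idx)
        res = deg_dar_association(deg, dar)
        assert 0.85 < res.fold < 1.15
        assert res.p > 1e-4

    def test_maximal_association(self):
        idx = [f"g{i}" for i in range(100)]
        deg = pd.Series([i < 10 for i in range(100)], index=idx)
        res = deg_dar_association(deg, deg.copy())
        assert res.fold == pytest.approx(100 / 10)

    def test_empty_universe_rejected(self):
        with pytest.raises(StatsError):
            deg_dar_association(pd.Series(dtype=bool), pd.Series(dtype=bool))


class TestClusterSensitivity:
    def _series(self, sizes, rates, seed=0):
        rng = np.random.default_rng(seed)
        clusters, flags = [], []
        for c, (n, r) in enumerate(zip(sizes, rates)):
            lbl = f"C{c + 1}"
            k = int(round(n * r))
            clusters += [lbl] * n
            flags += [True] * k + [False] * (n - k)
        idx = [f"g{i}" for i in range(len(clusters))]
        return pd.Series(clusters, index=idx), pd.Series(flags, index=idx)

    def test_equal_rates_give_unit_fold(self):
        cl, fl = self._series([100, 100, 100], [0.3, 0.3, 0.3])
        assert cluster_sensitivity_enrichment(cl, fl).fold == pytest.approx(1.0)

    def test_sensitivity_only_in_c1_flags_infinite_fold(self):
        cl, fl = self._series([100, 100, 100], [0.5, 0.0, 0.0])
        res = cluster_sensitivity_enrichment(cl, fl)
        assert res.fold == inf
        assert res.p < 1e-6

    def test_planted_fourfold_recovered(self):
        cl, fl = self._series([200, 200, 200], [0.4, 0.4, 0.1])
        res = cluster_sensitivity_enrichment(cl, fl)
        assert res.fold == pytest.approx(4.0)


class TestAccessibilityExpressionCorrelation:
    def test_perfect_coupling(self):
        idx = [f"g{i}" for i in range(20)]
        x = pd.Series(np.linspace(-3, 3, 20), index=idx)
        res = accessibility_expression_correlation(x, x * 0.5, pd.Series(True, index=idx))
        sig = [s for s in res if s.stratum == "DEG-or-DAR-proximal"][0]
        assert sig.r == pytest.approx(1.0)

    def test_coupled_stratum_beats_null_stratum(self):
        rng = np.random.default_rng(3)
        idx = [f"g{i}" for i in range(600)]
        sig = pd.Series([i < 200 for i in range(600)], index=idx)
        rna = pd.Series(rng.normal(0, 2, 600), index=idx)
        atac = pd.Series(
            np.where(sig, rna * 0.8 + rng.normal(0, 0.5, 600), rng.normal(0, 1, 600)),
            index=idx,
        )
        out = {s.stratum: s for s in accessibility_expression_correlation(rna, atac, sig)}
        assert out["DEG-or-DAR-proximal"].r > out["non-significant"].r + 0.3

    def test_constant_vector_flagged_not_crashed(self):
        idx = ["a", "b", "c", "d"]
        rna = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        atac = pd.Series(0.0, index=idx)
        out = accessibility_expression_correlation(rna, atac, pd.Series(True, index=idx))
        sig = [s for s in out if s.stratum == "DEG-or-DAR-proximal"][0]
        assert np.isnan(sig.r) and sig.n == 4


class TestLfcByCluster:
    def test_all_zero_lfc(self):
        idx = [f"g{i}" for i in range(30)]
        tab = lfc_by_cluster(
            pd.Series(0.0, index=idx),
            pd.Series(["C1", "C2", "C3"] * 10, index=idx),
            pd.Series(["St-up"] * 30, index=idx),
            organ="Int",
        )
        assert (tab["median"] == 0).all()

    def test_quartiles_match_type7_quantiles(self):
        vals = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        idx = [f"g{i}" for i in range(5)]
        tab = lfc_by_cluster(
            pd.Series(vals, index=idx),
            pd.Series("C1", index=idx),
            pd.Series("St-up", index=idx),
            organ="Int",
        )
        row = tab.iloc[0]
        assert row["q1"] == np.percentile(vals, 25)
        assert row["median"] == np.percentile(vals, 50)
        assert row["q3"] == np.percentile(vals, 75)


class TestLigandRepertoire:
    def _tpm(self, cols):
        idx = [f"lig{i}" for i in range(10)]
        return pd.DataFrame(cols, index=idx), idx

    def test_identical_vectors_rho_one(self):
        v = np.arange(10, dtype=float)
        tpm, ligs = self._tpm({"a": v, "b": v})
        _, rho = ligand_repertoire_compare(tpm, ligs)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        v = np.arange(10, dtype=float)
        tpm, ligs = self._tpm({"a": v, "b": v[::-1]})
        _, rho = ligand_repertoire_compare(tpm, ligs)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=10).astype(float)
        b = rng.integers(0, 5, size=10).astype(float)
        tpm, ligs = self._tpm({"a": a, "b": b})
        _, rho = ligand_repertoire_compare(tpm, ligs)
        ra = stats.rankdata(np.log(a + 1))
        rb = stats.rankdata(np.log(b + 1))
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert abs(rho.loc["a", "b"] - oracle) < 1e-12

    def test_star_tiers_follow_padj(self):
        v = np.arange(10, dtype=float)
        tpm, ligs = self._tpm({"a": v, "b": v})
        de = pd.DataFrame(
            {"padj": [0.2, 0.04, 0.009, 0.0005] + [1.0] * 6},
            index=ligs,
        )
        tab, _ = ligand_repertoire_compare(tpm, ligs, {"ko": de})
        assert list(tab["stars.ko"][:4]) == ["", "*", "**", "***"]

    def test_too_few_ligands_rejected(self):
        tpm = pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"])
        with pytest.raises(StatsError):
            ligand_repertoire_compare(tpm, ["x", "y"])
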