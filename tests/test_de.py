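"""Spike-in normalization, NB Wald testing, interaction contrast, TPM."""

import numpy as np
import pandas as pd
import pytest

from nichestate.de import (
    CountMatrix,
    DEError,
    call_degs,
    compute_tpm,
    interaction_contrast,
    median_of_ratios_size_factors,
    nb_wald_test,
    spikein_size_factors,
)


def _cm(counts: dict, meta_rows, spikes=()):
    counts = pd.DataFrame(counts)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "tissue", "genotype", "replicate"]
    ).set_index("sample")
    spike = pd.Series([i in spikes for i in counts.index], index=counts.index)
    return CountMatrix(counts, meta, spike)


def _two_group_cm(a, b, spikes=()):
    """3+3 samples, groups A=St, B=Int; a/b are per-feature count vectors."""
    n = len(a)
    idx = [f"f{i}" for i in range(n)]
    data = {f"A{j}": pd.Series(a, index=idx) for j in range(3)}
    data |= {f"B{j}": pd.Series(b, index=idx) for j in range(3)}
    meta = [(f"A{j}", "St", "WT", j) for j in range(3)] + [
        (f"B{j}", "Int", "WT", j) for j in range(3)
    ]
    return _cm(data, meta, spikes)


class TestSpikeinSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _two_group_cm([100] * 10, [100] * 10, spikes=[f"f{i}" for i in range(6)])
        sf = spikein_size_factors(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_forced_by_geometric_mean_rescaling(self):
        idx = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(
            {"a": [100, 200, 50, 400, 120, 80], "b": [200, 400, 100, 800, 240, 160]},
            index=idx,
        )
        meta = pd.DataFrame(
            [("a", "Int", "WT", 1), ("b", "Int", "WT", 2)],
            columns=["sample", "tissue", "genotype", "replicate"],
        ).set_index("sample")
        cm = CountMatrix(counts, meta, pd.Series(True, index=idx))
        sf = spikein_size_factors(cm)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_all_zero_spikeins_name_the_sample(self):
        cm = _two_group_cm([100] * 10, [0] * 10, spikes=[f"f{i}" for i in range(10)])
        with pytest.raises(DEError, match="B0"):
            spikein_size_factors(cm)

    def test_too_few_spikeins_rejected(self):
        cm = _two_group_cm([100] * 10, [100] * 10, spikes=["f0", "f1"])
        with pytest.raises(DEError, match=">= 5"):
            spikein_size_factors(cm)

    def test_recovers_planted_distortions_from_nb_spikeins(self):
        rng = np.random.default_rng(0)
        distort = np.array([0.5, 1.0, 2.0, 1.0, 0.8, 1.6])
        mu = np.exp(rng.normal(np.log(1000), 0.5, size=40))
        counts = rng.poisson(mu[:, None] * distort[None, :])
        idx = [f"sp{i}" for i in range(40)]
        cols = [f"s{j}" for j in range(6)]
        meta = pd.DataFrame(
            [(c, "Int", "WT", j) for j, c in enumerate(cols)],
            columns=["sample", "tissue", "genotype", "replicate"],
        ).set_index("sample")
        cm = CountMatrix(
            pd.DataFrame(counts, index=idx, columns=cols), meta, pd.Series(True, index=idx)
        )
        sf = spikein_size_factors(cm)
        truth = distort / np.exp(np.mean(np.log(distort)))
        assert np.max(np.abs(sf.to_numpy() / truth - 1)) < 0.05


class TestNbWald:
    def test_identical_groups_are_null(self):
        vals = list(np.random.default_rng(1).integers(10, 500, size=50))
        cm = _two_group_cm(vals, vals)
        res = nb_wald_test(cm, cm.group("St"), cm.group("Int"), pd.Series(1.0, index=cm.samples))
        assert np.allclose(res["log2fc"], 0)
        assert (res["p"] > 0.5).all()

    def test_fourfold_ratio_forced(self):
        cm = _two_group_cm([100] * 30, [400] * 30)
        res = nb_wald_test(cm, cm.group("St"), cm.group("Int"), pd.Series(1.0, index=cm.samples))
        assert np.allclose(res["log2fc"], 2.0, atol=0.02)

    def test_group_size_validated(self):
        cm = _two_group_cm([100] * 5, [100] * 5)
        with pytest.raises(DEError, match="group"):
            nb_wald_test(cm, cm.group("St")[:1], cm.group("Int"), pd.Series(1.0, index=cm.samples))

    def test_null_simulation_type_I_error(self, null_cohort):
        """Raw p < 0.05 fraction on a 2,000-gene null cohort sits near alpha."""
        rna = null_cohort.rna_counts()
        sf = spikein_size_factors(rna)
        res = nb_wald_test(rna, rna.group("St", "WT"), rna.group("Int", "WT"), sf)
        rate = float((res["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_bh_adjustment_properties(self, null_cohort):
        rna = null_cohort.rna_counts()
        sf = spikein_size_factors(rna)
        res = nb_wald_test(rna, rna.group("St", "WT"), rna.group("Int", "WT"), sf)
        assert (res["padj"] >= res["p"] - 1e-15).all()
        # padj is monotone in the rank of p
        srt = res.sort_values("p")
        assert (np.diff(srt["padj"]) >= -1e-12).all()

    def test_size_factor_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(50, 500, size=40)
        b = rng.integers(50, 500, size=40)
        cm = _two_group_cm(list(a), list(b))
        sf = pd.Series(1.0, index=cm.samples)
        res1 = nb_wald_test(cm, cm.group("St"), cm.group("Int"), sf)
        counts2 = cm.counts.copy()
        counts2["B1"] = counts2["B1"] * 3
        sf2 = sf.copy()
        sf2["B1"] = 3.0
        cm2 = CountMatrix(counts2, cm.meta, cm.spikein)
        res2 = nb_wald_test(cm2, cm.group("St"), cm.group("Int"), sf2)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=1e-6)


class TestCallDegs:
    @pytest.mark.parametrize(
        "padj,lfc,called",
        [(0.04, 1.2, True), (0.04, 0.9, False), (0.06, 3.0, False), (0.04, -1.2, True)],
    )
    def test_threshold_rules(self, padj, lfc, called):
        res = pd.DataFrame({"log2fc": [lfc], "padj": [padj], "p": [padj / 2]})
        out = call_degs(res)
        assert bool(out["call"].iloc[0]) is called


class TestInteraction:
    def _four_group(self, means: dict, disp_rng=None, n=3):
        """means maps (tissue, geno) -> per-feature mean vector."""
        rng = disp_rng or np.random.default_rng(0)
        nfeat = len(next(iter(means.values())))
        idx = [f"f{i}" for i in range(nfeat)]
        data, meta = {}, []
        for (t, g), mu in means.items():
            for j in range(n):
                s = f"{t}_{g}_{j}"
                lam = rng.gamma(1 / 0.05, np.asarray(mu) * 0.05)
                data[s] = pd.Series(rng.poisson(lam), index=idx)
                meta.append((s, t, g, j))
        return _cm(data, meta)

    def test_equal_tissue_effect_cancels(self):
        mu = np.full(300, 200.0)
        cm = self._four_group(
            {("Int", "WT"): mu * 4, ("St", "WT"): mu, ("Int", "KO"): mu * 4, ("St", "KO"): mu}
        )
        res = interaction_contrast(cm, pd.Series(1.0, index=cm.samples))
        assert abs(res["estimate"].mean()) < 0.1
        assert res["call"].mean() < 0.05

    def test_loss_of_organ_difference_detected(self):
        mu = np.full(300, 200.0)
        cm = self._four_group(
            {("Int", "WT"): mu * 4, ("St", "WT"): mu, ("Int", "KO"): mu, ("St", "KO"): mu}
        )
        res = interaction_contrast(cm, pd.Series(1.0, index=cm.samples))
        assert res["estimate"].median() == pytest.approx(2.0, abs=0.3)
        assert res["call"].mean() > 0.85

    def test_tissue_label_swap_negates_estimates(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.normal(np.log(200), 1, size=200))
        cm = self._four_group(
            {("Int", "WT"): mu * 2, ("St", "WT"): mu, ("Int", "KO"): mu, ("St", "KO"): mu * 2}
        )
        sf = pd.Series(1.0, index=cm.samples)
        res = interaction_contrast(cm, sf)
        meta_sw = cm.meta.copy()
        meta_sw["tissue"] = meta_sw["tissue"].map({"Int": "St", "St": "Int"})
        cm_sw = CountMatrix(cm.counts, meta_sw, cm.spikein)
        res_sw = interaction_contrast(cm_sw, sf)
        assert np.allclose(res["estimate"], -res_sw["estimate"], atol=1e-9)

    def test_missing_group_is_design_error(self):
        cm = _two_group_cm([10] * 5, [10] * 5)  # WT only
        with pytest.raises(DEError, match="KO"):
            interaction_contrast(cm, pd.Series(1.0, index=cm.samples))


class TestTpm:
    def test_uniform_case(self):
        cm = _two_group_cm([100] * 4, [100] * 4)
        lengths = pd.Series(1000.0, index=cm.counts.index)
        tpm, avg = compute_tpm(cm, lengths, pd.Series(1.0, index=cm.samples))
        assert np.allclose(tpm, 250_000.0)

    def test_length_scaling(self):
        cm = _two_group_cm([100] * 4, [100] * 4)
        lengths = pd.Series([1000.0, 2000.0, 1000.0, 1000.0], index=cm.counts.index)
        tpm, _ = compute_tpm(cm, lengths, pd.Series(1.0, index=cm.samples))
        col = tpm.iloc[:, 0]
        assert col.iloc[1] == pytest.approx(col.iloc[0] / 2)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 1000, size=50)
        b = rng.integers(0, 1000, size=50)
        cm = _two_group_cm(list(a), list(b))
        lengths = pd.Series(rng.integers(500, 5000, size=50).astype(float), index=cm.counts.index)
        sf = pd.Series(rng.uniform(0.5, 2, size=6), index=cm.samples)
        tpm, avg = compute_tpm(cm, lengths, sf)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)
        assert set(avg.columns) == {"St.WT", "Int.WT"}


def test_median_of_ratios_recovers_depth():
    rng = np.random.default_rng(9)
    mu = np.exp(rng.normal(np.log(200), 1, size=500))
    depth = np.array([0.8, 1.0, 1.25, 1.0])
    counts = rng.poisson(mu[:, None] * depth[None, :])
    df = pd.DataFrame(counts, columns=list("abcd"))
    sf = median_of_ratios_size_factors(df)
    truth = depth / np.exp(np.mean(np.log(depth)))
    assert np.max(np.abs(sf.to_numpy() / truth - 1)) < 0.05
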