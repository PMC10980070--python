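"""Spike-in normalization, noise model, enrichment z-scores, folds, and NMF."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import bisect
from scipy.stats import norm, pearsonr

from soilregimes.abundance import (
    CountTable,
    NoiseModel,
    aggregate_enriched,
    critical_z,
    enrichment_zscores,
    estimate_noise_model,
    growth_fold_matrix,
    nmf_rank2,
    normalize_spike_in,
    phylum_abundance,
    survival_folds,
    total_biomass,
)
from soilregimes.synthetic import replicate_count_tables


def small_table():
    counts = pd.DataFrame(
        {"s1": [100, 0, 7], "s2": [40, 12, 0]}, index=["a", "b", "c"]
    )
    spike = pd.Series({"s1": 50.0, "s2": 20.0})
    tax = pd.Series({"a": "Proteobacteria", "b": "Firmicutes"}, name="phylum")
    return CountTable(counts=counts, spike_in=spike, taxonomy=tax)


class TestNormalization:
    def test_pseudocounted_division(self):
        table = small_table()
        abs_ = normalize_spike_in(table)
        assert abs_.loc["a", "s1"] == pytest.approx((100 + 0.5) / 50)  # 2.01
        assert abs_.loc["b", "s1"] == pytest.approx(0.5 / 50)  # 0.01 floor

    def test_total_biomass_without_pseudocount(self):
        table = small_table()
        assert total_biomass(table)["s1"] == pytest.approx(107 / 50)

    def test_scale_free(self):
        table = small_table()
        k = 7.0
        scaled = CountTable(counts=table.counts * k, spike_in=table.spike_in * k)
        a, b = normalize_spike_in(table), normalize_spike_in(scaled)
        # identical up to the pseudocount term
        assert np.allclose(a - b, 0.5 / table.spike_in - 0.5 / (k * table.spike_in))

    def test_zero_spike_sample_dropped(self):
        counts = pd.DataFrame({"ok": [5], "bad": [9]}, index=["a"])
        spike = pd.Series({"ok": 10.0, "bad": 0.0})
        with pytest.warns(UserWarning, match="spike-in"):
            table = CountTable(counts=counts, spike_in=spike)
        assert list(table.counts.columns) == ["ok"]

    def test_spike_in_pair_correlation(self, count_panel):
        table, _ = count_panel
        m = table.meta
        rho = pearsonr(m["spike1"], m["spike2"])[0]
        assert rho >= 0.9


class TestNoiseModel:
    def test_identical_replicates_give_zero_noise(self):
        counts = pd.DataFrame({"r1": [100, 60, 3000], "r2": [100, 60, 3000]})
        nm = estimate_noise_model(counts)
        assert nm.c_frac == pytest.approx(0.0)
        assert nm.c0 == pytest.approx(0.0, abs=1e-6)

    def test_recovery_of_planted_parameters(self):
        rng = np.random.default_rng(1)
        means = np.exp(rng.uniform(np.log(1), np.log(5000), 2000))
        tbl = replicate_count_tables(means, n_reps=3, c_frac=0.21, c0=4.5, seed=1)
        nm = estimate_noise_model(tbl)
        assert nm.c_frac == pytest.approx(0.21, abs=0.04)
        assert nm.c0 == pytest.approx(4.5, abs=0.7)

    def test_cfrac_scale_invariance(self):
        # doubling all counts leaves the fractional component unchanged
        rng = np.random.default_rng(3)
        means = np.exp(rng.uniform(np.log(100), np.log(5000), 1500))
        tbl = replicate_count_tables(means, n_reps=3, c_frac=0.15, c0=4.5, seed=3)
        nm1 = estimate_noise_model(tbl)
        nm2 = estimate_noise_model(tbl * 2)
        assert nm2.c_frac == pytest.approx(nm1.c_frac, abs=0.01)

    def test_no_moderate_asvs_raises(self):
        counts = pd.DataFrame({"r1": [3, 5], "r2": [4, 2]})
        with pytest.raises(ValueError, match="inestimable"):
            estimate_noise_model(counts)

    def test_sigma_monotone(self):
        nm = NoiseModel(c_frac=0.2, c0=4.0)
        n = np.linspace(0, 1000, 50)
        assert np.all(np.diff(nm.sigma(n)) >= 0)


class TestCriticalZ:
    @pytest.mark.parametrize("n_asv,expected", [(2000, 4.2), (2500, 4.3)])
    def test_printed_one_decimal_values(self, n_asv, expected):
        assert round(critical_z(0.05, n_asv), 1) == expected

    def test_alpha_one_single_test(self):
        assert critical_z(1.0, 1) == pytest.approx(0.0)

    def test_agrees_with_bisection_of_normal_cdf(self):
        for n_asv in (10, 2000):
            target = 1 - 0.05 / 2 / n_asv
            z_ref = bisect(lambda z: norm.cdf(z) - target, 0, 10, xtol=1e-12)
            assert critical_z(0.05, n_asv) == pytest.approx(z_ref, abs=1e-6)


class TestEnrichment:
    def test_identical_arms_nothing_enriched(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (200, 3)).astype(float))
        nm = NoiseModel(c_frac=0.2, c0=4.0)
        z = enrichment_zscores(counts, counts.copy(), nm)
        assert np.allclose(z["median_z"], 0.0)
        assert not z["enriched"].any()

    def test_planted_growers_recalled(self):
        # 20 true 8-fold growers among 2000 ASVs in a quiet condition
        # (fractional noise 0.10; at 0.21 an 8-fold change is statistically
        # invisible because z saturates near (F-1)/(c_frac*sqrt(F^2+1)))
        rng = np.random.default_rng(8)
        c_frac, c0 = 0.10, 4.5
        means = np.exp(rng.uniform(np.log(20), np.log(2000), 2000))
        grower_idx = rng.choice(2000, 20, replace=False)
        fold = np.ones(2000)
        fold[grower_idx] = 8.0
        plus = replicate_count_tables(means, 3, c_frac, c0, seed=1)
        minus = replicate_count_tables(means * fold, 3, c_frac, c0, seed=2)
        nm = estimate_noise_model([minus, plus])
        z = enrichment_zscores(minus, plus, nm)
        called = set(z.index[z["enriched"]])
        planted = {f"ASV{i + 1}" for i in grower_idx}
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        # false positives at most at the Bonferroni alpha expectation
        assert len(called - planted) <= 2

    def test_no_nitrate_responders_filtered(self):
        enriched_sets = [{"a", "b"}, {"b", "c"}]
        final = aggregate_enriched(enriched_sets, nn_responders={"b"})
        assert final == {"a", "c"}

    def test_mismatched_replicates_warn(self):
        rng = np.random.default_rng(0)
        minus = pd.DataFrame(rng.integers(0, 100, (50, 3)).astype(float))
        plus = minus.iloc[:, :2].copy()
        nm = NoiseModel(c_frac=0.2, c0=4.0)
        with pytest.warns(UserWarning, match="unequal replicate"):
            z = enrichment_zscores(minus, plus, nm)
        assert {"z_pair1", "z_pair2"} <= set(z.columns)

    def test_type_i_error_control(self):
        # Monte Carlo null through the pipeline: with no true enrichment the
        # expected number of false calls per condition family stays at or
        # below the Bonferroni alpha budget
        nm = NoiseModel(c_frac=0.2, c0=4.5)
        n_asv, n_fam = 2000, 200
        false_calls = 0
        rng = np.random.default_rng(12)
        for fam in range(n_fam):
            means = np.exp(rng.uniform(np.log(5), np.log(3000), n_asv))
            minus = replicate_count_tables(means, 3, nm.c_frac, nm.c0, seed=2 * fam)
            plus = replicate_count_tables(means, 3, nm.c_frac, nm.c0, seed=2 * fam + 1)
            z = enrichment_zscores(minus, plus, nm)
            false_calls += int(z["enriched"].sum())
        assert false_calls / n_fam <= 0.05


class TestGrowthFolds:
    def test_equal_abundance_zero_fold(self):
        a = pd.DataFrame({"c1": [0.5, 0.2]}, index=["p1", "p2"])
        assert np.allclose(growth_fold_matrix(a, a.copy()), 0.0)

    def test_pseudo_abundance_arithmetic(self):
        am = pd.DataFrame({"c": [0.1]}, index=["p"])
        ap = pd.DataFrame({"c": [0.001]}, index=["p"])
        g = growth_fold_matrix(am, ap)
        assert g.loc["p", "c"] == pytest.approx(np.log(0.101 / 0.002), rel=1e-9)  # ~3.92

    def test_negative_folds_clipped(self):
        am = pd.DataFrame({"c": [0.01]}, index=["p"])
        ap = pd.DataFrame({"c": [0.5]}, index=["p"])
        assert growth_fold_matrix(am, ap).loc["p", "c"] == 0.0

    def test_unassigned_phylum_grouping(self):
        abund = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "zz"])
        tax = pd.Series({"a": "Firmicutes"}, name="phylum")
        phy = phylum_abundance(abund, tax)
        assert phy.loc["unassigned", "s"] == pytest.approx(2.0)

    def test_survival_folds(self):
        plus = pd.Series({"p1": 0.5, "p2": 0.05})
        t0 = pd.Series({"p1": 0.5, "p2": 0.5})
        sf = survival_folds(plus, t0)
        assert sf["p1"] == pytest.approx(1.0)
        assert sf["p2"] < 0.2


class TestNMF:
    def test_exact_rank2_recovered(self):
        rng = np.random.default_rng(0)
        W = rng.random((12, 2))
        H = rng.random((2, 30))
        res = nmf_rank2(pd.DataFrame(W @ H), seed=0)
        assert res.variance_explained >= 0.999

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        G = pd.DataFrame(rng.random((15, 40)))
        res = nmf_rank2(G, seed=0, n_restarts=1)
        assert np.all(np.diff(res.objective_history) <= 1e-10)

    def test_factors_nonnegative_and_deterministic(self):
        rng = np.random.default_rng(2)
        G = pd.DataFrame(rng.random((10, 20)))
        r1 = nmf_rank2(G, seed=3)
        r2 = nmf_rank2(G, seed=3)
        assert (r1.W.to_numpy() >= 0).all() and (r1.H.to_numpy() >= 0).all()
        assert np.allclose(r1.W, r2.W) and np.allclose(r1.H, r2.H)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            nmf_rank2(pd.DataFrame(np.zeros((4, 5))))

    def test_matches_sklearn_reconstruction_quality(self):
        # independent cross-check: same objective value class as sklearn's
        # multiplicative-update NMF on the same matrix
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        G = np.abs(rng.normal(1, 0.5, (20, 50)))
        mine = nmf_rank2(pd.DataFrame(G), seed=0)
        sk = sklearn.NMF(n_components=2, solver="mu", init="random",
                         random_state=0, max_iter=2000, tol=1e-9).fit(G)
        err_sk = np.linalg.norm(G - sk.transform(G) @ sk.components_, "fro")
        err_mine = mine.objective_history[-1]
        assert err_mine <= err_sk * 1.02

    def test_planted_modes_recovered(self, small_panel, count_panel):
        from soilregimes.synthetic import DOSE_X_COLLAPSE

        table, truth = count_panel
        m = table.meta
        end = m[(m["timepoint"] == "end") & (m["nitrate"] == 1)]
        absn = normalize_spike_in(table)
        gm, gp, doses, regs = {}, {}, [], []
        for (soil, ph), grp in end.groupby(["soil_id", "perturbed_pH"]):
            key = f"{soil}@{ph:.2f}"
            gm[key] = phylum_abundance(absn[grp.index[grp["chl"] == 0]], table.taxonomy).mean(axis=1)
            gp[key] = phylum_abundance(absn[grp.index[grp["chl"] == 1]], table.taxonomy).mean(axis=1)
            cond = small_panel.conditions
            row = cond[(cond["soil_id"] == soil) & np.isclose(cond["perturbed_ph"], ph)].iloc[0]
            doses.append(float(row["dose_mM"]))
            regs.append(row["regime"])
        G = growth_fold_matrix(pd.DataFrame(gm), pd.DataFrame(gp))
        res = nmf_rank2(G, seed=0)
        doses = np.array(doses)
        truth_firm = (doses > DOSE_X_COLLAPSE).astype(float) * np.log(200)
        truth_dom = np.where(
            (np.array(regs) == "II") & (doses >= 0),
            np.log1p(0.2 * np.clip(doses, 0, None)),
            0.0,
        )
        H = res.H.to_numpy()

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))

        sims = np.array([[cos(H[i], t) for t in (truth_firm, truth_dom)] for i in range(2)])
        # each planted mode is captured by one recovered mode
        best = sims.max(axis=0)
        assert best[0] > 0.9 and best[1] > 0.9
        assert res.variance_explained > 0.9
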