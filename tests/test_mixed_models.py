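import numpy as np
import pandas as pd
import pytest

from soyblup import (
    GBLUP,
    TrialVarComps,
    adjust_phenotypes,
    fit_gblup,
    heritability,
    simulate_genotypes,
    simulate_phenotypes,
    trial_varcomps,
)
from soyblup.kernels import KernelMatrix, additive_kernel, hadamard_epistasis, standardize
from soyblup.mixed_models import variance_partition
from soyblup.synthetic_data import SimConfig
from conftest import make_matrix


def _random_kernel(n, p, seed):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, p))
    return KernelMatrix(W @ W.T / p, "G", [f"L{i}" for i in range(n)]), rng


class TestAdjustPhenotypes:
    def test_single_plot_design_returns_plot_values(self):
        plots = pd.DataFrame(
            {
                "line_id": ["a", "b", "c"],
                "location": "LOC1",
                "replicate": "R1",
                "block": "B1",
                "GY": [1.0, 2.0, 4.0],
            }
        )
        blues = adjust_phenotypes(plots, "GY").set_index("line_id")["blue"]
        np.testing.assert_allclose(blues[["a", "b", "c"]], [1.0, 2.0, 4.0])

    def test_recovers_line_means_under_location_shifts(self):
        """Known line means plus +/-1 location effects, no noise: exact recovery."""
        lines = [f"L{i}" for i in range(10)]
        mu = np.linspace(-2, 2, 10)
        rows = []
        for j, (loc, eff) in enumerate([("LOC1", 1.0), ("LOC2", -1.0)]):
            for r in ("R1", "R2"):
                for i, lid in enumerate(lines):
                    rows.append((lid, loc, r, "B1", mu[i] + eff))
        plots = pd.DataFrame(rows, columns=["line_id", "location", "replicate",
                                            "block", "GY"])
        blues = adjust_phenotypes(plots, "GY").set_index("line_id")["blue"]
        np.testing.assert_allclose(blues[lines], mu, atol=1e-8)

    def test_augmented_design_blues_beat_raw_means(self):
        """Adjusting for design effects must track true genetic values better
        than raw plot means, on average over simulated trials."""
        wins = []
        for seed in range(6):
            cfg = SimConfig(
                n_lines=80, n_families=12, n_chromosomes=2,
                markers_per_chromosome=40, n_qtl=30, n_locations=2, seed=seed,
                location_sd=5.0, block_sd=3.0, replicate_sd=2.0,
            )
            m, _ = simulate_genotypes(cfg)
            plots, truth = simulate_phenotypes(m, cfg)
            g = truth.breeding_values
            blues = adjust_phenotypes(plots, "GY").set_index("line_id")["blue"]
            raw = plots.groupby("line_id")["GY"].mean()
            ids = [l for l in m.line_ids]
            r_blue = np.corrcoef(blues[ids], g[ids])[0, 1]
            r_raw = np.corrcoef(raw[ids], g[ids])[0, 1]
            wins.append(r_blue - r_raw)
        assert np.mean(wins) > 0

    def test_missing_trait_column_rejected(self):
        plots = pd.DataFrame(
            {"line_id": ["a"], "location": ["x"], "replicate": ["r"],
             "block": ["b"], "GY": [1.0]}
        )
        with pytest.raises(ValueError, match="PH"):
            adjust_phenotypes(plots, "PH")


class TestTrialVarcomps:
    def test_zero_genetic_signal(self):
        rng = np.random.default_rng(0)
        rows = []
        for loc in ("LOC1", "LOC2"):
            for r in ("R1", "R2"):
                for i in range(80):
                    rows.append((f"L{i}", loc, r, f"B{i // 30}", rng.normal(0, 2)))
        plots = pd.DataFrame(rows, columns=["line_id", "location", "replicate",
                                            "block", "GY"])
        vc = trial_varcomps(plots, "GY")
        assert vc.sigma2_g < vc.sigma2_e / 10

    def test_single_location_flags_gxe(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"L{i}", "LOC1", rep, "B1", rng.normal(i * 0.1, 1.0))
            for i in range(40) for rep in ("R1", "R2")
        ]
        plots = pd.DataFrame(rows, columns=["line_id", "location", "replicate",
                                            "block", "PH"])
        with pytest.warns(UserWarning, match="single location"):
            vc = trial_varcomps(plots, "PH")
        assert not vc.ge_estimable
        assert vc.sigma2_ge == 0.0
        assert vc.n_env == 1

    def test_component_recovery_from_simulated_trial(self):
        ests = []
        for seed in range(4):
            cfg = SimConfig(n_lines=150, n_families=20, n_chromosomes=2,
                            markers_per_chromosome=50, n_qtl=40, seed=seed)
            m, _ = simulate_genotypes(cfg)
            plots, _ = simulate_phenotypes(m, cfg)
            vc = trial_varcomps(plots, "GY")
            ests.append([vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e])
        mean = np.mean(ests, axis=0)
        np.testing.assert_allclose(mean, [12.9, 7.28, 31.4], rtol=0.35)


class TestHeritability:
    def test_multi_location_grain_yield_values(self):
        vc = TrialVarComps(12.9, 7.28, 31.4, n_env=4, n_rep=2)
        assert round(heritability(vc), 2) == 0.69

    def test_single_location_plant_height_values(self):
        vc = TrialVarComps(67.0, 0.0, 33.0, n_env=1, n_rep=2, ge_estimable=False)
        assert round(heritability(vc), 2) == 0.80

    def test_noise_free_trial(self):
        assert heritability(TrialVarComps(5.0, 0.0, 0.0, 2, 2)) == 1.0

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(heritability(TrialVarComps(0.0, 0.0, 0.0, 2, 2)))


class TestGBLUPFit:
    def test_single_kernel_variance_recovery(self):
        ests = []
        for seed in range(6):
            K, rng = _random_kernel(200, 300, seed)
            L = np.linalg.cholesky(K.K + 1e-8 * np.eye(200))
            y = 3.0 + np.sqrt(2.0) * (L @ rng.standard_normal(200)) \
                + rng.standard_normal(200)
            res = fit_gblup(y, K)
            ests.append([res.varcomps["G"], res.sigma2_e])
        mean = np.mean(ests, axis=0)
        np.testing.assert_allclose(mean, [2.0, 1.0], rtol=0.3)

    def test_spectral_optimum_matches_grid_search(self):
        """The 1-D profile REML must beat a dense grid over the variance ratio."""
        K, rng = _random_kernel(30, 60, 3)
        L = np.linalg.cholesky(K.K + 1e-8 * np.eye(30))
        y = 1.0 + L @ rng.standard_normal(30) + 0.5 * rng.standard_normal(30)
        res = GBLUP(y, K).fit()
        neg2 = res._neg2ll_fun
        grid = np.linspace(np.log(1e-6), np.log(1e6), 20001)
        grid_min = min(neg2(g) for g in grid)
        assert -2.0 * res.reml_loglik <= grid_min + 1e-6

    def test_constant_phenotype_hits_zero_variance_boundary(self):
        K, _ = _random_kernel(25, 40, 4)
        res = fit_gblup(np.full(25, 7.0), K)
        assert res.varcomps["G"] <= 1e-4 * max(res.sigma2_e, 1e-12) + 1e-12
        assert np.allclose(res.predict(), res.predict().iloc[0], atol=1e-6)

    def test_translation_invariance(self):
        K, rng = _random_kernel(60, 100, 5)
        y = rng.standard_normal(60)
        r1 = fit_gblup(y, K)
        r2 = fit_gblup(y + 10.0, K)
        assert r2.mu == pytest.approx(r1.mu + 10.0, abs=1e-6)
        np.testing.assert_allclose(r2.gvalues["total"], r1.gvalues["total"], atol=1e-6)

    def test_rrblup_equivalence(self):
        """Kernel BLUPs equal ridge-regression marker-effect predictions."""
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (30, 200)).astype(float)
        poly = d.std(axis=0) > 0
        std = standardize(make_matrix(d[:, poly]))
        G = additive_kernel(std)
        y = rng.standard_normal(30) * 2 + 1
        res = fit_gblup(y, G)
        lam = res.varcomps["G"] / res.sigma2_e
        W, p = std.W, std.n_markers
        b = W.T @ np.linalg.solve(W @ W.T + (p / lam) * np.eye(30), y - res.mu)
        np.testing.assert_allclose(res.gvalues["G"].to_numpy(), W @ b, atol=1e-8)

    def test_unphenotyped_lines_predicted_by_borrowing(self):
        K, rng = _random_kernel(120, 200, 7)
        L = np.linalg.cholesky(K.K + 1e-8 * np.eye(120))
        g = 2.0 * (L @ rng.standard_normal(120))
        y = pd.Series(g[:90] + rng.standard_normal(90),
                      index=[f"L{i}" for i in range(90)])
        res = GBLUP(y, K).fit()
        holdout = res.gvalues["total"].to_numpy()[90:]
        assert np.corrcoef(holdout, g[90:])[0, 1] > 0.3

    def test_two_kernel_partition_and_summary(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (80, 120)).astype(float)
        poly = d.std(axis=0) > 0
        std = standardize(make_matrix(d[:, poly]))
        G = additive_kernel(std)
        GG = hadamard_epistasis(G)
        L = np.linalg.cholesky(G.K + 1e-8 * np.eye(80))
        y = L @ rng.standard_normal(80) * 1.5 + rng.standard_normal(80)
        res = fit_gblup(y, [G, GG])
        pct = res.variance_partition()
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert set(pct.index) == {"G", "GoG", "residual"}
        text = res.summary()
        assert "G-BLUP REML fit" in text and "residual" in text
        np.testing.assert_allclose(variance_partition(res), pct)

    def test_epistatic_terms_absorb_additive_variance(self):
        """On additive simulated data the G + GoG model splits the variance the
        additive model gives to G, leaving the residual share stable."""
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, (120, 150)).astype(float)
        poly = d.std(axis=0) > 0
        std = standardize(make_matrix(d[:, poly]))
        G = additive_kernel(std)
        GG = hadamard_epistasis(G)
        L = np.linalg.cholesky(G.K + 1e-8 * np.eye(120))
        diffs_g, diffs_res = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = 2.0 * (L @ rng.standard_normal(120)) + rng.standard_normal(120)
            p1 = fit_gblup(y, G).variance_partition()
            p4 = fit_gblup(y, [G, GG]).variance_partition()
            diffs_g.append((p4["G"] + p4["GoG"]) - p1["G"])
            diffs_res.append(p4["residual"] - p1["residual"])
        assert abs(np.mean(diffs_g)) < 10.0
        assert abs(np.mean(diffs_res)) < 10.0

    def test_simple_partition_arithmetic(self):
        res = fit_gblup(np.random.default_rng(0).standard_normal(30),
                        _random_kernel(30, 50, 10)[0])
        res.varcomps = {"G": 3.0}
        res.sigma2_e = 1.0
        pct = res.variance_partition()
        assert pct["G"] == pytest.approx(75.0)
        assert pct["residual"] == pytest.approx(25.0)

    def test_from_dataframe_and_line_checks(self):
        K, rng = _random_kernel(10, 20, 11)
        df = pd.DataFrame({"line_id": [f"L{i}" for i in range(10)],
                           "blue": rng.standard_normal(10)})
        res = GBLUP.from_dataframe(df, K, value_col="blue").fit()
        assert res.n_train == 10
        with pytest.raises(ValueError, match="absent"):
            GBLUP(pd.Series([1.0], index=["nope"]), K)
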