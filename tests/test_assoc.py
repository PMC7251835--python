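"""Mixed-model association scan: calibration, power, and GLS↔OLS reduction."""

import numpy as np
import pytest
from scipy import stats as sps

import seqgp
from seqgp.assoc import NullModelFit, fit_null_mlm, mlma_scan
from seqgp.iofmt import read_ma, write_ma


@pytest.fixture(scope="module")
def structured_population():
    cfg = seqgp.SimConfig(
        n_discovery={"A": 250, "B": 250}, n_prediction={"X": 30, "Y": 30},
        n_variants_wgs=1500, panel_sizes={"6K": 100, "50K": 300, "800K": 800},
        n_qtl=0, h2_discovery=0.0, h2_prediction=0.0, fst=0.1, seed=11,
    )
    study = seqgp.simulate_study(cfg)
    g = seqgp.GenotypeSet.concatenate([s[0] for s in study.discovery.values()])
    grm = seqgp.build_grm(g, g.panel_ids("800K"))
    return g, grm


class TestNullModel:
    def test_null_trait_gives_near_zero_h2(self, structured_population):
        g, grm = structured_population
        successes = 0
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=g.n_individuals)
            fit = fit_null_mlm(y, np.ones((g.n_individuals, 1)), grm)
            successes += fit.h2 < 0.05
        assert successes >= 4

    def test_h2_recovery(self):
        import pandas as pd

        h2s = []
        for seed in (7, 8, 9):
            cfg = seqgp.SimConfig(
                n_discovery={"A": 500, "B": 500}, n_prediction={"X": 30, "Y": 30},
                n_variants_wgs=4000, panel_sizes={"6K": 200, "50K": 1000, "800K": 3000},
                n_qtl=200, h2_discovery=0.5, fst=0.05, large_qtl=False, seed=seed,
            )
            study = seqgp.simulate_study(cfg)
            g = seqgp.GenotypeSet.concatenate([s[0] for s in study.discovery.values()])
            tables = [s[1].drop(columns=["bos_indicus_fraction"], errors="ignore")
                      for s in study.discovery.values()]
            pt = pd.concat(tables, ignore_index=True)
            y = pt["trait"].to_numpy()
            X = seqgp.design_matrix(pt, categorical=("contemporary_group", "dam_age"))
            grm = seqgp.build_grm(g, g.panel_ids("WGS"))  # all causal variants captured
            h2s.append(fit_null_mlm(y, X, grm).h2)
        assert 0.4 <= np.mean(h2s) <= 0.6

    def test_identity_grm_flagged_unidentifiable(self, caplog):
        rng = np.random.default_rng(0)
        y = rng.normal(size=300)
        with caplog.at_level("WARNING"):
            fit = fit_null_mlm(y, np.ones((300, 1)), np.eye(300))
        # the variance split is arbitrary but the total matches the OLS residual
        total = fit.sigma_g2 + fit.sigma_e2
        np.testing.assert_allclose(total, np.var(y, ddof=1), rtol=0.05)
        assert any("identifiable" in r.message for r in caplog.records)


class TestScan:
    def test_gls_reduces_to_ols_when_variance_zero(self, structured_population):
        """With σg² = 0 the scan is per-variant weighted OLS with known σe²."""
        import statsmodels.api as sm

        g, _ = structured_population
        rng = np.random.default_rng(1)
        y = rng.normal(size=g.n_individuals)
        null = NullModelFit(0.0, float(np.var(y)), 0.0, None,
                            np.zeros((g.n_individuals, g.n_individuals)))
        ids = g.variant_ids[:50]
        scan = mlma_scan(g, y, np.ones((g.n_individuals, 1)), null, ids).set_index("SNP")
        for vid in ids[:10]:
            x = g.dosages[:, g.column_index([vid])[0]]
            if x.std() == 0:
                continue
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            np.testing.assert_allclose(scan.loc[vid, "b"], ols.params[1], atol=1e-10)
            se_known = np.sqrt(null.sigma_e2 / np.sum((x - x.mean()) ** 2))
            np.testing.assert_allclose(scan.loc[vid, "se"], se_known, rtol=1e-10)
            p_known = 2 * sps.norm.sf(abs(ols.params[1]) / se_known)
            assert abs(scan.loc[vid, "p"] - p_known) < 1e-8

    def test_power_detects_large_qtl(self):
        successes = 0
        for seed in range(5):
            cfg = seqgp.SimConfig(
                n_discovery={"A": 500}, n_prediction={"X": 30, "Y": 30},
                n_variants_wgs=800, panel_sizes={"6K": 50, "50K": 150, "800K": 400},
                n_qtl=0, h2_discovery=0.0, h2_prediction=0.0, fst=0.05, seed=seed,
            )
            study = seqgp.simulate_study(cfg)
            g = study.discovery["A"][0]
            rng = np.random.default_rng(seed)
            sd = g.dosages.std(0)
            qtl = rng.choice(np.where(sd > 0.5)[0])
            x = g.dosages[:, qtl]
            # one QTL explaining ~20% of phenotypic variance
            beta = np.sqrt(0.2 / 0.8) / x.std()
            y = beta * x + rng.normal(0, 1, 500)
            grm = seqgp.build_grm(g, g.panel_ids("800K"))
            null = fit_null_mlm(y, np.ones((500, 1)), grm)
            scan = mlma_scan(g, y, np.ones((500, 1)), null)
            top = scan.loc[scan["p"].idxmin()]
            successes += (top["SNP"] == g.variants["id"].iloc[qtl]) and top["p"] < 1e-8
        assert successes >= 4

    def test_monomorphic_variant_record(self, structured_population):
        g, grm = structured_population
        g2 = seqgp.GenotypeSet(g.individual_ids, g.breed_labels,
                               g.dosages.copy(), g.variants.copy())
        g2.dosages[:, 0] = 2.0
        rng = np.random.default_rng(3)
        y = rng.normal(size=g2.n_individuals)
        null = fit_null_mlm(y, np.ones((g2.n_individuals, 1)), grm)
        rec = mlma_scan(g2, y, np.ones((g2.n_individuals, 1)), null,
                        g2.variant_ids[:1]).iloc[0]
        assert rec["b"] == 0 and np.isinf(rec["se"]) and rec["p"] == 1.0

    def test_scan_round_trips_through_ma(self, structured_population, tmp_path):
        g, grm = structured_population
        rng = np.random.default_rng(4)
        y = rng.normal(size=g.n_individuals)
        null = fit_null_mlm(y, np.ones((g.n_individuals, 1)), grm)
        scan = mlma_scan(g, y, np.ones((g.n_individuals, 1)), null, g.variant_ids[:100])
        scan = scan[np.isfinite(scan["se"])]
        write_ma(scan, tmp_path / "scan.ma")
        back = read_ma(tmp_path / "scan.ma")
        np.testing.assert_allclose(back["b"], scan["b"], rtol=1e-12)

    def test_p_monotone_in_z(self, structured_population):
        g, grm = structured_population
        rng = np.random.default_rng(5)
        y = rng.normal(size=g.n_individuals)
        null = fit_null_mlm(y, np.ones((g.n_individuals, 1)), grm)
        scan = mlma_scan(g, y, np.ones((g.n_individuals, 1)), null)
        scan = scan[np.isfinite(scan["se"])]
        z = np.abs(scan["b"] / scan["se"])
        order = np.argsort(z.to_numpy())
        p_sorted = scan["p"].to_numpy()[order]
        assert (np.diff(p_sorted) <= 1e-12).all()

    def test_permuted_phenotype_p_values_uniform(self, structured_population):
        g, grm = structured_population
        rng = np.random.default_rng(6)
        y = rng.normal(size=g.n_individuals)
        perm = rng.permutation(g.n_individuals)
        null = fit_null_mlm(y[perm], np.ones((g.n_individuals, 1)), grm)
        scan = mlma_scan(g, y[perm], np.ones((g.n_individuals, 1)), null)
        p = scan.loc[np.isfinite(scan["se"]), "p"]
        assert sps.kstest(p, "uniform").pvalue > 0.01
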