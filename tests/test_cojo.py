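"""COJO stepwise selection against individual-level regression oracles."""

import numpy as np
import pandas as pd
import pytest

import seqgp
from seqgp.assoc import NullModelFit, mlma_scan
from seqgp.cojo import cojo_select, ld_r2
from seqgp.iofmt import GenotypeSet, make_variant_table


def _gset(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = ["1"] * m if chrom is None else chrom
    variants = make_variant_table([f"v{i}" for i in range(m)], chrom,
                                  np.arange(1, m + 1) * 1000, ["A"] * m, ["B"] * m)
    return GenotypeSet([f"i{k}" for k in range(n)], ["b"] * n, dosages, variants)


def _ols_scan(gset, y):
    """Marginal OLS summary statistics (the COJO input format)."""
    null = NullModelFit(0.0, float(np.var(y)), 0.0, None, np.eye(len(y)))
    return mlma_scan(gset, y, np.ones((len(y), 1)), null)


class TestLdR2:
    def test_identical_and_complement_columns(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 200).astype(float)
        g = _gset(np.column_stack([x, x, 2 - x]))
        r2 = ld_r2(g, ["v0", "v1", "v2"])
        np.testing.assert_allclose(r2[0, 1], 1.0)
        np.testing.assert_allclose(r2[0, 2], 1.0)  # perfect negative LD

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        g = _gset(rng.binomial(2, 0.5, size=(1000, 200)).astype(float))
        r2 = ld_r2(g, g.variant_ids)
        off = r2[np.triu_indices(200, 1)]
        assert np.median(off) < 0.005

    def test_monomorphic_rejected(self):
        g = _gset(np.column_stack([np.full(10, 2.0), np.arange(10) % 3]))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(g, ["v0", "v1"])


class TestCojoSelect:
    def _sim(self, seed, h=(0.4, 0.3)):
        """LD-structured genotypes with two causal variants in moderate LD."""
        cfg = seqgp.SimConfig(
            n_discovery={"A": 500}, n_prediction={"X": 30, "Y": 30},
            n_variants_wgs=600, panel_sizes={"6K": 40, "50K": 80, "800K": 200},
            n_chromosomes=2, n_qtl=0, h2_discovery=0.0, h2_prediction=0.0,
            fst=0.05, seed=seed,
        )
        discovery, _, _ = seqgp.simulate_genotypes(cfg, np.random.default_rng(seed))
        g = discovery["A"]
        D = g.dosages
        rng = np.random.default_rng(seed + 1000)
        chrom1 = np.where((g.variants["chrom"] == "1").to_numpy())[0]
        informative = chrom1[D[:, chrom1].var(axis=0) > 0.3]
        pair = None
        for a in rng.permutation(informative):
            for b in informative[informative > a]:
                if 0.1 <= np.corrcoef(D[:, a], D[:, b])[0, 1] ** 2 <= 0.3:
                    pair = (a, b)
                    break
            if pair:
                break
        a, b = pair
        y = h[0] * D[:, a] + h[1] * D[:, b] + rng.normal(0, 1, 500)
        return g, y, (g.variants["id"].iloc[a], g.variants["id"].iloc[b])

    def test_single_significant_variant_selected(self):
        rng = np.random.default_rng(2)
        dosages = rng.binomial(2, 0.5, size=(400, 50)).astype(float)
        g = _gset(dosages)
        y = 0.6 * dosages[:, 7] + rng.normal(0, 1, 400)
        stats = _ols_scan(g, y)
        res = cojo_select(stats, g, mode="threshold", p_threshold=5e-8)
        assert res.selected == ["v7"]
        marginal_b = stats.set_index("SNP").loc["v7", "b"]
        np.testing.assert_allclose(res.joint_b[0], marginal_b, rtol=1e-10)

    def test_no_variant_passes_gives_empty_result(self):
        rng = np.random.default_rng(3)
        g = _gset(rng.binomial(2, 0.5, size=(300, 40)).astype(float))
        y = rng.normal(size=300)
        res = cojo_select(_ols_scan(g, y), g, mode="threshold", p_threshold=1e-10)
        assert res.selected == []

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_joint_effects_match_individual_level_regression(self, seed):
        """Summary-statistic joint fit reproduces multiple regression when
        the LD reference is the discovery data itself."""
        g, y, causal = self._sim(seed)
        res = cojo_select(_ols_scan(g, y), g, mode="threshold", p_threshold=5e-3)
        assert len(res.selected) >= 2
        cols = g.column_index(np.array(res.selected, dtype=object))
        X = np.column_stack([np.ones(len(y)), g.dosages[:, cols]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        np.testing.assert_allclose(res.joint_b, beta, rtol=0.05, atol=1e-8)

    def test_uncorrelated_selection_keeps_marginal_effects(self):
        # near-orthogonal causal variants: joint ≈ marginal effects
        rng = np.random.default_rng(5)
        dosages = rng.binomial(2, 0.5, size=(4000, 60)).astype(float)
        g = _gset(dosages)
        y = 0.3 * dosages[:, 0] + 0.3 * dosages[:, 30] + rng.normal(0, 1, 4000)
        stats = _ols_scan(g, y)
        res = cojo_select(stats, g, mode="threshold", p_threshold=5e-6)
        marg = stats.set_index("SNP").loc[res.selected, "b"].to_numpy()
        np.testing.assert_allclose(res.joint_b, marg, rtol=0.05)

    def test_topn_size_bounded_and_contains_threshold_set(self):
        g, y, causal = self._sim(11)
        stats = _ols_scan(g, y)
        res_n = cojo_select(stats, g, mode="topN", top_n=3)
        assert len(res_n.selected) <= 3
        res_all = cojo_select(stats, g, mode="topN", top_n=50)
        res_thr = cojo_select(stats, g, mode="threshold", p_threshold=5e-3)
        assert len(res_all.selected) <= 50
        # every threshold-selected variant is in the exhaustive topN set, or
        # was displaced by a collinear (r² > cap) proxy chosen in its place
        leftovers = set(res_thr.selected) - set(res_all.selected)
        for snp in leftovers:
            r2 = ld_r2(g, [snp] + res_all.selected)[0, 1:]
            assert r2.max() > 0.9

    def test_per_chromosome_scope_concatenates(self):
        rng = np.random.default_rng(6)
        dosages = rng.binomial(2, 0.5, size=(500, 40)).astype(float)
        chrom = ["1"] * 20 + ["2"] * 20
        g = _gset(dosages, chrom)
        y = 0.5 * dosages[:, 2] + 0.5 * dosages[:, 25] + rng.normal(0, 1, 500)
        res = cojo_select(_ols_scan(g, y), g, mode="threshold",
                          scope="per_chromosome", p_threshold=5e-6)
        assert res.scope == "per_chromosome"
        assert {"v2", "v25"} <= set(res.selected)

    def test_collinear_candidates_never_added(self):
        rng = np.random.default_rng(7)
        x = rng.binomial(2, 0.5, 400).astype(float)
        noise = np.where(rng.random(400) < 0.02, 2 - x, x)  # r2 ~ 0.92
        others = rng.binomial(2, 0.5, size=(400, 10)).astype(float)
        g = _gset(np.column_stack([x, noise, others]))
        y = 0.8 * x + rng.normal(0, 1, 400)
        res = cojo_select(_ols_scan(g, y), g, mode="threshold", p_threshold=5e-3,
                          collinearity_cap=0.8)
        assert not ({"v0", "v1"} <= set(res.selected))

    def test_small_reference_errors(self):
        rng = np.random.default_rng(8)
        dosages = rng.binomial(2, 0.5, size=(4, 30)).astype(float)
        g = _gset(dosages)
        stats = _ols_scan(g, rng.normal(size=4))
        stats["p"] = 1e-9  # force many additions
        with pytest.raises(ValueError, match="reference too small"):
            cojo_select(stats, g, mode="topN", top_n=10)
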