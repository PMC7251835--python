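"""File-format round trips and validation for the I/O layer."""

import numpy as np
import pandas as pd
import pytest

from seqgp.grm import GRM
from seqgp.iofmt import (FormatError, GenotypeSet, RunConfig, design_matrix,
                         make_variant_table, read_grm, read_ma, read_plink,
                         write_grm, write_ma, write_plink)

from conftest import make_ma


class TestPlink:
    def test_round_trip_identity(self, random_genotypes, tmp_path):
        prefix = tmp_path / "geno"
        write_plink(random_genotypes, prefix)
        back = read_plink(prefix)
        np.testing.assert_array_equal(back.dosages, random_genotypes.dosages)
        assert back.individual_ids == random_genotypes.individual_ids
        assert list(back.variant_ids) == list(random_genotypes.variant_ids)

    def test_bad_magic_rejected(self, random_genotypes, tmp_path):
        prefix = tmp_path / "geno"
        write_plink(random_genotypes, prefix)
        raw = bytearray((tmp_path / "geno.bed").read_bytes())
        raw[2] = 0x00  # individual-major flag: unsupported
        (tmp_path / "geno.bed").write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_plink(prefix)
        raw[0] = 0x55
        raw[2] = 0x01
        (tmp_path / "geno.bed").write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_plink(prefix)

    def test_payload_size_checked(self, random_genotypes, tmp_path):
        prefix = tmp_path / "geno"
        write_plink(random_genotypes, prefix)
        raw = (tmp_path / "geno.bed").read_bytes()
        (tmp_path / "geno.bed").write_bytes(raw + b"\x00\x00")
        with pytest.raises(FormatError, match="payload"):
            read_plink(prefix)

    def test_missing_imputed_to_column_mean(self, tmp_path):
        # one column with dosages {missing, 0, 2, 2} -> imputed value 4/3
        variants = make_variant_table(["v0"], ["1"], [100], ["A"], ["B"])
        gset = GenotypeSet([f"i{k}" for k in range(4)], ["b"] * 4,
                           np.array([[2.0], [0.0], [2.0], [2.0]]), variants)
        prefix = tmp_path / "m"
        write_plink(gset, prefix)
        raw = bytearray((tmp_path / "m.bed").read_bytes())
        # first individual's 2-bit field (low bits of byte 3) -> 01 = missing
        raw[3] = (raw[3] & 0b11111100) | 0b01
        (tmp_path / "m.bed").write_bytes(bytes(raw))
        back = read_plink(prefix)
        assert back.n_imputed == 1
        np.testing.assert_allclose(back.dosages[0, 0], 4.0 / 3.0)
        np.testing.assert_array_equal(back.dosages[1:, 0], [0.0, 2.0, 2.0])

    def test_soft_calls_rejected_on_write(self, random_genotypes, tmp_path):
        random_genotypes.dosages[0, 0] = 0.5
        with pytest.raises(ValueError, match="hard genotype"):
            write_plink(random_genotypes, tmp_path / "x")


class TestMa:
    def test_round_trip(self, tmp_path):
        stats = make_ma(100)
        write_ma(stats, tmp_path / "s.ma")
        back = read_ma(tmp_path / "s.ma")
        for col in ("freq", "b", "se", "p"):
            np.testing.assert_allclose(back[col], stats[col], rtol=1e-12)
        assert (back["N"] == 868).all()

    @pytest.mark.parametrize("col,value", [("p", 0.0), ("p", 1.5), ("freq", -0.1)])
    def test_invalid_fields_rejected(self, tmp_path, col, value):
        stats = make_ma(3)
        stats.loc[1, col] = value
        with pytest.raises(ValueError):
            write_ma(stats, tmp_path / "bad.ma")

    def test_missing_column_is_format_error(self, tmp_path):
        make_ma(3).drop(columns=["se"]).to_csv(tmp_path / "x.ma", sep="\t", index=False)
        with pytest.raises(FormatError, match="se"):
            read_ma(tmp_path / "x.ma")


class TestGrmIO:
    def _grm(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n, 2 * n))
        vals = A @ A.T / (2 * n)
        return GRM([f"i{k}" for k in range(n)], vals,
                   [f"v{k}" for k in range(5)], np.full(5, 0.5))

    def test_round_trip(self, tmp_path):
        grm = self._grm()
        write_grm(grm, tmp_path / "g")
        back = read_grm(tmp_path / "g")
        assert np.abs(back.values - grm.values).max() < 1e-6
        assert back.individual_ids == grm.individual_ids
        assert back.variant_ids_used == grm.variant_ids_used

    def test_asymmetric_rejected(self, tmp_path):
        grm = self._grm()
        grm.values[0, 1] += 0.5
        with pytest.raises(ValueError, match="symmetric"):
            write_grm(grm, tmp_path / "g")

    def test_empty_id_list_rejected(self, tmp_path):
        grm = self._grm()
        grm.individual_ids = []
        grm.values = np.zeros((0, 0))
        with pytest.raises(FormatError):
            write_grm(grm, tmp_path / "g")


class TestVariantTable:
    def test_panel_nesting_enforced(self):
        with pytest.raises(ValueError, match="nested"):
            make_variant_table(["a", "b"], ["1", "1"], [1, 2], ["A", "A"], ["B", "B"],
                               p6k=[True, False], p50k=[False, False],
                               p800k=[True, True])

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(ids=["a", "a"], pos=[1, 2]), "duplicate"),
        (dict(ids=["a", "b"], pos=[0, 2]), "positive"),
    ])
    def test_id_and_position_validation(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_variant_table(kwargs["ids"], ["1", "1"], kwargs["pos"],
                               ["A", "A"], ["B", "B"])


class TestDesignAndConfig:
    def test_design_matrix_full_rank_dummies(self):
        df = pd.DataFrame({"age": [1.0, 2, 3, 4], "cg": ["a", "a", "b", "b"]})
        X = design_matrix(df, continuous=("age",), categorical=("cg",))
        assert X.shape == (4, 3)
        assert np.linalg.matrix_rank(X) == 3

    def test_single_level_factor_absorbed(self):
        df = pd.DataFrame({"cg": ["a", "a", "a"]})
        X = design_matrix(df, categorical=("cg",))
        assert X.shape == (3, 1)

    def test_mgrm_control_is_rejected(self):
        with pytest.raises(ValueError, match="MGRM"):
            RunConfig(strategy="CONTROL", method="MGRM")
        RunConfig(strategy="CONTROL", method="SGRM")  # fine
        RunConfig(strategy="TOP_META", method="MGRM")  # fine

    def test_runconfig_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(panel_density="50K", strategy="TOP_META", method="BAYESR", seed=7)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert RunConfig.from_yaml(tmp_path / "c.yaml") == cfg
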