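"""Readers/writers for the standard formats the pipeline touches.

Genotypes travel as PLINK 1 ``.bed/.bim/.fam`` trios (SNP-major, 2-bit codes),
GWAS/meta summaries as whitespace-delimited COJO ``.ma`` tables
(``SNP A1 A2 freq b se p N``), and genomic relationship matrices as GCTA-style
text trios.  The in-memory containers defined here (:class:`GenotypeSet`,
phenotype tables as plain :class:`pandas.DataFrame`) are what every other
module consumes.

Conventions: coordinates are 1-based (``.bim`` convention); the dosage counts
copies of the A1 (effect) allele; missing genotypes are mean-imputed at load
and the imputation count is kept on the returned object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grm import GRM

logger = logging.getLogger(__name__)

PANELS = ("6K", "50K", "800K")
#: variant-table column holding membership of each commercial panel
PANEL_COLUMNS = {"6K": "p6k", "50K": "p50k", "800K": "p800k"}

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: 2-bit PLINK code -> dosage of A1 (NaN = missing, imputed at load)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "p6k", "p50k", "p800k"]


def make_variant_table(ids, chrom, pos, a1, a2, p6k=None, p50k=None, p800k=None) -> pd.DataFrame:
    """Assemble and validate a variant map (one row per WGS variant).

    Panel flags must be nested: every 6K variant is on the 50K panel and every
    50K variant is on the 800K panel; all variants belong to the WGS set.
    """
    n = len(ids)
    z = np.zeros(n, dtype=bool)
    df = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=object).astype(str),
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": np.asarray(a1, dtype=object),
            "a2": np.asarray(a2, dtype=object),
            "p6k": z if p6k is None else np.asarray(p6k, dtype=bool),
            "p50k": z if p50k is None else np.asarray(p50k, dtype=bool),
            "p800k": z if p800k is None else np.asarray(p800k, dtype=bool),
        }
    )
    if df["id"].duplicated().any():
        raise ValueError("duplicate variant ids")
    if (df["pos"] <= 0).any():
        raise ValueError("positions must be positive (1-based)")
    if (df["a1"] == df["a2"]).any():
        raise ValueError("effect and other allele must differ")
    if (df["p6k"] & ~df["p50k"]).any() or (df["p50k"] & ~df["p800k"]).any():
        raise ValueError("panel flags must be nested: 6K ⊆ 50K ⊆ 800K")
    return df


@dataclass
class GenotypeSet:
    """Individuals × variants dosage matrix with its variant map.

    ``dosages[i, j]`` is the (possibly mean-imputed) count of the A1 allele of
    variant ``j`` carried by individual ``i``; values lie in ``[0, 2]``.
    """

    individual_ids: list[str]
    breed_labels: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame
    n_imputed: int = 0

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.breed_labels) != n:
            raise ValueError("breed_labels length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")
        if np.isnan(self.dosages).any():
            raise ValueError("dosages contain missing values after load")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def panel_ids(self, density: str) -> np.ndarray:
        """Variant ids on a commercial panel ('6K', '50K', '800K') or 'WGS'."""
        if density == "WGS":
            return self.variant_ids
        return self.variants.loc[self.variants[PANEL_COLUMNS[density]], "id"].to_numpy()

    def column_index(self, ids) -> np.ndarray:
        """Column positions of the given variant ids (order preserved)."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0][:5]
            raise KeyError(f"variant ids not in genotype set: {list(missing)} ...")
        return idx

    def subset_individuals(self, rows) -> "GenotypeSet":
        rows = np.asarray(rows)
        return GenotypeSet(
            [self.individual_ids[i] for i in rows],
            [self.breed_labels[i] for i in rows],
            self.dosages[rows],
            self.variants.reset_index(drop=True),
        )

    @staticmethod
    def concatenate(sets: list["GenotypeSet"]) -> "GenotypeSet":
        """Stack individuals from sets sharing an identical variant map."""
        first = sets[0]
        for s in sets[1:]:
            if not first.variants["id"].equals(s.variants["id"]):
                raise ValueError("genotype sets have different variant maps")
        return GenotypeSet(
            sum((s.individual_ids for s in sets), []),
            sum((s.breed_labels for s in sets), []),
            np.vstack([s.dosages for s in sets]),
            first.variants.reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------


def read_plink(prefix) -> GenotypeSet:
    """Read a PLINK 1 ``.bed/.bim/.fam`` trio (SNP-major only).

    Missing genotypes are imputed to the column mean; the number of imputed
    calls is logged and stored on the returned set.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={0: str, 1: str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={0: str, 1: str, 4: str, 5: str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise FormatError("not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise FormatError("only SNP-major .bed files are supported (third magic byte != 0x01)")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise FormatError(
            f".bed payload is {payload.size} bytes; expected {bytes_per_variant * m} "
            f"for {n} individuals x {m} variants"
        )
    codes = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, individual index runs along the low bits first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    geno = ((codes[:, :, None] >> shifts[None, None, :]) & 0b11).reshape(m, -1)[:, :n]
    dosages = _BED_DECODE[geno].T.copy()  # (n, m)

    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        col_means = np.nanmean(dosages, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = col_means[idx[1]]
        logger.info("read_plink(%s): imputed %d missing genotypes to column means", prefix, n_missing)

    variants = make_variant_table(bim["id"], bim["chrom"], bim["pos"], bim["a1"], bim["a2"])
    return GenotypeSet(
        fam["iid"].astype(str).tolist(), fam["fid"].astype(str).tolist(),
        dosages, variants, n_imputed=n_missing,
    )


def write_plink(gset: GenotypeSet, prefix) -> None:
    """Write a GenotypeSet as a PLINK 1 trio; dosages must be integral."""
    prefix = Path(prefix)
    d = np.asarray(gset.dosages)
    rounded = np.rint(d)
    if np.max(np.abs(d - rounded)) > 1e-6:
        raise ValueError("write_plink requires hard genotype calls (dosages in {0,1,2})")
    fam = pd.DataFrame(
        {
            "fid": gset.breed_labels, "iid": gset.individual_ids,
            "father": 0, "mother": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    v = gset.variants
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"], "a1": v["a1"], "a2": v["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = rounded.shape
    codes = np.empty((m, n), dtype=np.uint8)
    g = rounded.T.astype(np.int64)
    codes[g == 2] = 0b00
    codes[g == 1] = 0b10
    codes[g == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.full((m, pad), 0b01, dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# COJO .ma summary statistics
# ---------------------------------------------------------------------------


def validate_ma(stats: pd.DataFrame) -> pd.DataFrame:
    stats = stats[MA_COLUMNS].copy()
    p = stats["p"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    f = stats["freq"].to_numpy(dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return stats


def read_ma(path) -> pd.DataFrame:
    """Read a COJO ``.ma`` summary table (SNP A1 A2 freq b se p N)."""
    stats = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str, "A1": str, "A2": str})
    missing = set(MA_COLUMNS) - set(stats.columns)
    if missing:
        raise FormatError(f".ma file missing columns: {sorted(missing)}")
    return validate_ma(stats)


def write_ma(stats: pd.DataFrame, path) -> None:
    validate_ma(stats).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# GCTA-style GRM text trio
# ---------------------------------------------------------------------------


def write_grm(grm: GRM, prefix) -> None:
    """Write a GRM as GCTA-style text: lower triangle + id list + variant list.

    ``<prefix>.grm.txt`` holds ``i j m G_ij`` rows (1-based, lower triangle),
    ``<prefix>.grm.id`` the family/individual ids, ``<prefix>.grm.snps`` the
    variant ids and allele frequencies used to build the matrix.
    """
    prefix = Path(prefix)
    vals = np.asarray(grm.values)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("GRM must be symmetric")
    n = vals.shape[0]
    if len(grm.individual_ids) != n:
        raise FormatError("id list length does not match GRM dimension")
    if n == 0:
        raise FormatError("empty id list")
    m = len(grm.variant_ids_used)
    i, j = np.tril_indices(n)
    table = pd.DataFrame({"i": i + 1, "j": j + 1, "m": m, "g": vals[i, j]})
    table.to_csv(prefix.with_name(prefix.name + ".grm.txt"), sep="\t", header=False,
                 index=False, float_format="%.10g")
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        prefix.with_name(prefix.name + ".grm.id"), sep="\t", header=False, index=False
    )
    pd.DataFrame({"id": grm.variant_ids_used, "freq": grm.allele_freqs_used}).to_csv(
        prefix.with_name(prefix.name + ".grm.snps"), sep="\t", header=False, index=False,
        float_format="%.10g",
    )


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(prefix.with_name(prefix.name + ".grm.id"), sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    tri = pd.read_csv(prefix.with_name(prefix.name + ".grm.txt"), sep=r"\s+", header=None,
                      names=["i", "j", "m", "g"])
    n = len(ids)
    if tri["i"].max() != n or len(tri) != n * (n + 1) // 2:
        raise FormatError("GRM triangle does not match id-list length")
    vals = np.zeros((n, n))
    vals[tri["i"] - 1, tri["j"] - 1] = tri["g"]
    vals = vals + np.tril(vals, -1).T
    snps = pd.read_csv(prefix.with_name(prefix.name + ".grm.snps"), sep=r"\s+", header=None,
                       names=["id", "freq"], dtype={0: str})
    return GRM(ids["iid"].tolist(), vals, snps["id"].tolist(), snps["freq"].to_numpy())


# ---------------------------------------------------------------------------
# design matrices and run configuration
# ---------------------------------------------------------------------------


def design_matrix(pheno: pd.DataFrame, continuous=(), categorical=()) -> np.ndarray:
    """Full-rank fixed-effects design: intercept + covariates + dummy codes.

    Categorical factors are dummy-coded dropping the first level; a factor
    with a single observed level is absorbed by the intercept (and logged).
    """
    cols = [np.ones(len(pheno))]
    for c in continuous:
        cols.append(pheno[c].to_numpy(dtype=float))
    for c in categorical:
        dummies = pd.get_dummies(pheno[c].astype("category"), drop_first=True)
        if dummies.shape[1] == 0:
            logger.info("design_matrix: factor %r has a single level; absorbed in intercept", c)
            continue
        cols.append(dummies.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    return X


@dataclass
class RunConfig:
    """One prediction scenario: panel density × pre-selection strategy × method."""

    panel_density: str = "800K"
    strategy: str = "CONTROL"
    method: str = "SGRM"
    seed: int = 0
    chain_length: int = 50_000
    burn_in: int = 20_000
    thinning: int = 10
    reml_max_iter: int = 200
    reml_tol: float = 1e-8

    def __post_init__(self):
        from .preselect import STRATEGY_LABELS

        if self.panel_density not in PANELS:
            raise ValueError(f"panel_density must be one of {PANELS}")
        if self.strategy not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.method not in ("SGRM", "MGRM", "BAYESR"):
            raise ValueError("method must be SGRM, MGRM or BAYESR")
        # the MGRM CONTROL model is the SGRM CONTROL model (no WGS component)
        if self.method == "MGRM" and self.strategy == "CONTROL":
            raise ValueError("MGRM requires a non-CONTROL strategy (MGRM CONTROL ≡ SGRM CONTROL)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)
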