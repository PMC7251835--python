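"""Metal-style meta-analysis of GWAS summary statistics.

Two schemes are provided, matching the classic Metal options:

* **standard-error scheme** (`meta_se`): inverse-variance weighting of
  per-study effects, used after the effects have been standardised by the
  study trait mean with the reconstructed standard error ``se = b / z`` where

      z = −0.862 + √(0.743 − 2.404·ln P).

  The natural logarithm makes this the Altman–Bland approximation to the
  two-sided normal quantile (z(0.05) = 1.9566 ≈ 1.96); a base-10 logarithm
  would give z(0.05) = 3.15, unusable as a z-score.

* **sample-size scheme** (`meta_pvalue`): Stouffer combination of signed
  z-scores with √N weights; only p-values, effect signs and sample sizes
  enter.

Effect alleles are harmonised across studies before combining: when a study
reports the alleles swapped relative to the first study carrying the variant,
its effect sign is flipped and its frequency complemented; irreconcilable
allele pairs are dropped with a log message.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

META_COLUMNS = ["SNP", "A1", "A2", "freq", "b_meta", "se_meta", "z_meta",
                "p_meta", "n_total", "n_studies", "direction"]


def p_to_z(p):
    """Approximate |z| from a two-sided p-value (natural log; z ≥ 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    z = -0.862 + np.sqrt(0.743 - 2.404 * np.log(p))
    z = np.maximum(z, 0.0)
    return float(z) if z.ndim == 0 else z


def two_sided_p_from_z(z):
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    return np.clip(p, 1e-300, 1.0)


def standardize_effects(stats: pd.DataFrame, trait_mean: float) -> pd.DataFrame:
    """Standardise effects by the trait mean and rebuild se from the p-value.

    b' = b / trait_mean (sign preserved); se' = |b'| / z(p); p is unchanged.
    Records with p = 1 and b ≠ 0 get an infinite se and are flagged for
    exclusion from the standard-error meta-analysis.
    """
    if trait_mean == 0:
        raise ValueError("trait_mean must be nonzero")
    out = stats.copy()
    b = out["b"].to_numpy(dtype=float) / trait_mean
    z = p_to_z(out["p"].to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(z > 0, np.abs(b) / z, np.inf)
    se = np.where(b == 0.0, 0.0, se)  # a true-zero effect carries no se information
    n_inf = int(np.isinf(se).sum())
    if n_inf:
        logger.info("standardize_effects: %d records with p=1, b≠0 flagged (infinite se)", n_inf)
    out["b"] = b
    out["se"] = se
    return out


def _harmonize(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack studies on shared ids with effect alleles aligned to first seen."""
    frames = []
    for k, st in enumerate(studies):
        f = st.copy()
        f["study"] = k
        frames.append(f)
    stacked = pd.concat(frames, ignore_index=True)
    ref = stacked.drop_duplicates("SNP").set_index("SNP")[["A1", "A2"]]
    a1 = stacked["SNP"].map(ref["A1"])
    a2 = stacked["SNP"].map(ref["A2"])
    same = (stacked["A1"] == a1) & (stacked["A2"] == a2)
    flipped = (stacked["A1"] == a2) & (stacked["A2"] == a1)
    bad = ~(same | flipped)
    if bad.any():
        logger.warning("meta: dropping %d records with irreconcilable alleles", int(bad.sum()))
        stacked = stacked[~bad].copy()
        same, flipped = same[~bad], flipped[~bad]
    stacked.loc[flipped, "b"] = -stacked.loc[flipped, "b"]
    stacked.loc[flipped, "freq"] = 1.0 - stacked.loc[flipped, "freq"]
    stacked["A1"] = stacked["SNP"].map(ref["A1"])
    stacked["A2"] = stacked["SNP"].map(ref["A2"])
    return stacked


def _direction(signs: pd.Series, n_studies: int) -> str:
    marks = {1.0: "+", -1.0: "-", 0.0: "0"}
    got = ["?"] * n_studies
    for k, s in signs.items():
        got[k] = marks.get(np.sign(s), "?")
    return "".join(got)


def meta_se(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance (standard-error scheme) meta-analysis per variant."""
    n_studies = len(studies)
    stacked = _harmonize(studies)
    stacked = stacked[np.isfinite(stacked["se"]) & (stacked["se"] > 0)]
    rows = []
    for snp, grp in stacked.groupby("SNP", sort=False):
        w = 1.0 / grp["se"].to_numpy() ** 2
        b = float(np.sum(w * grp["b"].to_numpy()) / w.sum())
        se = float(1.0 / np.sqrt(w.sum()))
        z = b / se
        rows.append(
            {
                "SNP": snp, "A1": grp["A1"].iloc[0], "A2": grp["A2"].iloc[0],
                "freq": float(np.average(grp["freq"], weights=grp["N"])),
                "b_meta": b, "se_meta": se, "z_meta": z,
                "p_meta": float(two_sided_p_from_z(z)),
                "n_total": int(grp["N"].sum()), "n_studies": len(grp),
                "direction": _direction(grp.set_index("study")["b"], n_studies),
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)


def meta_pvalue(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size (Stouffer √N-weighted) meta-analysis per variant."""
    n_studies = len(studies)
    stacked = _harmonize(studies)
    missing_n = ~np.isfinite(stacked["N"].to_numpy(dtype=float))
    if missing_n.any():
        logger.warning("meta_pvalue: dropping %d records with missing N", int(missing_n.sum()))
        stacked = stacked[~missing_n]
    rows = []
    for snp, grp in stacked.groupby("SNP", sort=False):
        nvec = grp["N"].to_numpy(dtype=float)
        zvec = np.sign(grp["b"].to_numpy()) * p_to_z(grp["p"].to_numpy(dtype=float))
        z = float(np.sum(np.sqrt(nvec) * zvec) / np.sqrt(nvec.sum()))
        rows.append(
            {
                "SNP": snp, "A1": grp["A1"].iloc[0], "A2": grp["A2"].iloc[0],
                "freq": float(np.average(grp["freq"], weights=nvec)),
                "b_meta": np.nan, "se_meta": np.nan, "z_meta": z,
                "p_meta": float(two_sided_p_from_z(z)),
                "n_total": int(nvec.sum()), "n_studies": len(grp),
                "direction": _direction(grp.set_index("study")["b"], n_studies),
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)


def meta_to_ma(meta: pd.DataFrame) -> pd.DataFrame:
    """Convert a standard-error-scheme meta table to COJO ``.ma`` layout."""
    if meta["b_meta"].isna().any():
        raise ValueError("sample-size-scheme results carry no effect sizes; "
                         "run the standard-error scheme for COJO input")
    return pd.DataFrame(
        {
            "SNP": meta["SNP"], "A1": meta["A1"], "A2": meta["A2"],
            "freq": meta["freq"], "b": meta["b_meta"], "se": meta["se_meta"],
            "p": meta["p_meta"], "N": meta["n_total"],
        }
    )
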