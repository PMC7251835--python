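"""Mixed-linear-model association scan (EMMAX / P3D style).

The polygenic background is captured by a GRM fitted once under the null
model ``y = Xb + a + e`` (REML via :mod:`seqgp.gblup`); each variant is then
tested by generalised least squares with the covariance matrix
``V = σ̂g² G + σ̂e² I`` held fixed at the null estimates.  Per-variant effects,
standard errors and two-sided normal p-values are returned as a COJO-ready
summary table.

A leave-one-chromosome-out analysis is obtained by fitting one null model per
chromosome GRM and scanning each chromosome's variants against its own null
fit; by default the tested variant stays in the GRM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special

from .gblup import VarianceComponents, reml
from .grm import GRM
from .iofmt import MA_COLUMNS, GenotypeSet

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class NullModelFit:
    """Variance components of the covariate-only mixed model."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    varcomp: VarianceComponents
    grm_values: np.ndarray

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def fit_null_mlm(y, X, grm) -> NullModelFit:
    """REML fit of phenotype on covariates with a GRM random effect."""
    G = grm.values if isinstance(grm, GRM) else np.asarray(grm, float)
    vc = reml(np.asarray(y, float), X, [G], labels=["animal"])
    if not vc.converged:
        raise RuntimeError(
            f"null-model REML did not converge in {vc.iterations} iterations "
            f"(last loglik {vc.loglik:.6f})"
        )
    return NullModelFit(vc.component("animal"), vc.ve, vc.loglik, vc, G)


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, floored away from zero so p ∈ (0, 1]."""
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    return np.clip(p, _P_FLOOR, 1.0)


def mlma_scan(genotypes: GenotypeSet, y, X, null_fit: NullModelFit,
              variant_ids=None, chunk_size=4096) -> pd.DataFrame:
    """GLS scan of each variant with the null covariance held fixed.

    Returns a summary table with columns ``SNP A1 A2 freq b se p N``.
    Variants monomorphic in the tested set get ``b=0, se=inf, p=1``.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    if variant_ids is None:
        variant_ids = genotypes.variant_ids
    variant_ids = np.asarray(variant_ids)
    cols = genotypes.column_index(variant_ids)

    V = null_fit.sigma_g2 * null_fit.grm_values + null_fit.sigma_e2 * np.eye(n)
    L = linalg.cholesky(V, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    Q, _ = np.linalg.qr(Xt)
    y_res = yt - Q @ (Q.T @ yt)

    m = cols.size
    b = np.zeros(m)
    se = np.full(m, np.inf)
    freq = np.zeros(m)
    for start in range(0, m, chunk_size):
        sl = slice(start, min(start + chunk_size, m))
        W = genotypes.dosages[:, cols[sl]]
        freq[sl] = W.mean(axis=0) / 2.0
        Wt = linalg.solve_triangular(L, W, lower=True)
        W_res = Wt - Q @ (Q.T @ Wt)
        d = np.einsum("ij,ij->j", W_res, W_res)
        ok = d > 1e-10
        b_chunk = np.zeros(d.size)
        b_chunk[ok] = (W_res[:, ok].T @ y_res) / d[ok]
        se_chunk = np.full(d.size, np.inf)
        se_chunk[ok] = 1.0 / np.sqrt(d[ok])
        b[sl], se[sl] = b_chunk, se_chunk

    n_mono = int(np.isinf(se).sum())
    if n_mono:
        logger.info("mlma_scan: %d variants monomorphic in tested set (b=0, se=inf, p=1)", n_mono)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isfinite(se), b / se, 0.0)
    p = two_sided_p(z)

    v = genotypes.variants.iloc[cols]
    return pd.DataFrame(
        {
            "SNP": variant_ids,
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "freq": freq,
            "b": b,
            "se": se,
            "p": p,
            "N": n,
        }
    )[MA_COLUMNS]
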