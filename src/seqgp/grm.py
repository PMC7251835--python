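"""Genomic relationship matrices (VanRaden/GCTA method 1).

G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)), centred with
allele frequencies of the whole analysed population.  Monomorphic variants are
dropped (their per-variant scaling divides by zero), mirroring GCTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Symmetric genomic relationship matrix plus the inputs that made it."""

    individual_ids: list
    values: np.ndarray
    variant_ids_used: list
    allele_freqs_used: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM values must be a square matrix")
        if v.shape[0] != len(self.individual_ids):
            raise ValueError("GRM dimension does not match individual ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if len(self.variant_ids_used) == 0:
            raise ValueError("GRM built from an empty variant list")


def allele_frequencies(genotypes, variant_ids) -> np.ndarray:
    """A1 allele frequencies p_i = mean(dosage)/2 over all individuals.

    Monomorphic variants (p = 0 or 1) are flagged with a log message; callers
    building a GRM or standardised genotype matrix must drop them.
    """
    variant_ids = np.asarray(variant_ids)
    if variant_ids.size == 0:
        raise ValueError("empty variant subset")
    cols = genotypes.column_index(variant_ids)
    p = genotypes.dosages[:, cols].mean(axis=0) / 2.0
    n_mono = int(((p <= 0) | (p >= 1)).sum())
    if n_mono:
        logger.info("allele_frequencies: %d monomorphic variants flagged", n_mono)
    return p


def build_grm(genotypes, variant_ids, freqs=None) -> GRM:
    """Build the GRM over ``variant_ids`` with given (or computed) frequencies.

    ``freqs`` must correspond to the A1 alleles of ``variant_ids`` in order;
    pass frequencies computed on the full population when the matrix is used
    inside a cross-validation split.
    """
    variant_ids = np.asarray(variant_ids)
    if freqs is None:
        freqs = allele_frequencies(genotypes, variant_ids)
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.all():
        logger.warning("build_grm: dropping %d monomorphic variants", int((~poly).sum()))
    variant_ids, freqs = variant_ids[poly], freqs[poly]
    if variant_ids.size == 0:
        raise ValueError("no polymorphic variants left for GRM")
    cols = genotypes.column_index(variant_ids)
    W = (genotypes.dosages[:, cols] - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    values = (W @ W.T) / variant_ids.size
    return GRM(list(genotypes.individual_ids), values, list(variant_ids), freqs)
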