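"""Conditional-or-joint (COJO) selection from GWAS summary statistics.

Greedy stepwise selection of approximately independent associated variants:
marginal effects come from the summary table (``b``, ``se``, ``freq``,
``p``, ``N``) and the between-variant correlations from a genotyped LD
reference.  Joint and conditional least-squares coefficients are
reconstructed from those pieces exactly as in summary-statistic conditional
analysis: with D_j = 2 p_j (1 − p_j) N_j playing the role of x_j'x_j,

    X'X ≈ √D_i √D_j r_ij,      X'y ≈ D_j b_j,

and the phenotypic variance inferred per variant from (b, se, freq, N) with
the median taken across variants.  Two modes: ``threshold`` (add while the
best conditional p passes, with back-elimination of selected variants whose
joint p rises above the threshold) and ``topN`` (run until N variants are
selected or no candidate clears the collinearity cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iofmt import GenotypeSet
from .meta import two_sided_p_from_z

logger = logging.getLogger(__name__)


@dataclass
class CojoResult:
    selected: list
    joint_b: np.ndarray
    joint_se: np.ndarray
    joint_p: np.ndarray
    mode: str
    scope: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.selected, "joint_b": self.joint_b,
                             "joint_se": self.joint_se, "joint_p": self.joint_p})

    @staticmethod
    def concatenate(parts: list["CojoResult"], mode, scope) -> "CojoResult":
        return CojoResult(
            sum((p.selected for p in parts), []),
            np.concatenate([p.joint_b for p in parts]) if parts else np.empty(0),
            np.concatenate([p.joint_se for p in parts]) if parts else np.empty(0),
            np.concatenate([p.joint_p for p in parts]) if parts else np.empty(0),
            mode, scope,
        )


def ld_r2(reference: GenotypeSet, ids) -> np.ndarray:
    """Squared Pearson correlation between dosage columns of the reference."""
    cols = reference.column_index(np.asarray(ids))
    W = reference.dosages[:, cols]
    sd = W.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in LD computation")
    return np.corrcoef(W, rowvar=False).reshape(len(cols), len(cols)) ** 2


class _CojoEngine:
    """Stepwise machinery over one (stats, reference) pair."""

    def __init__(self, stats: pd.DataFrame, reference: GenotypeSet, collinearity_cap: float):
        keep = np.isfinite(stats["se"]) & (stats["se"] > 0) & \
            (stats["freq"] > 0) & (stats["freq"] < 1)
        stats = stats[keep]
        ref_ids = set(reference.variant_ids)
        stats = stats[stats["SNP"].isin(ref_ids)].reset_index(drop=True)
        self.stats = stats
        self.cap = collinearity_cap
        self.n_ref = reference.n_individuals

        cols = reference.column_index(stats["SNP"].to_numpy())
        W = reference.dosages[:, cols]
        Wc = W - W.mean(axis=0)
        sd = Wc.std(axis=0)
        sd[sd == 0] = np.nan
        self._Z = Wc / sd  # standardised reference columns; corr = Z'Z / n

        self.b = stats["b"].to_numpy(dtype=float)
        self.se = stats["se"].to_numpy(dtype=float)
        self.p = stats["p"].to_numpy(dtype=float)
        self.N = stats["N"].to_numpy(dtype=float)
        self.freq = stats["freq"].to_numpy(dtype=float)
        # x_j'x_j (centred) reconstructed from the realised reference variance;
        # exact when the reference is the discovery data itself, and closer to
        # the truth than the 2p(1-p) Hardy–Weinberg value under inbreeding
        self.D = Wc.var(axis=0) * self.N
        # per-variant phenotypic variance implied by (b, se, freq, N)
        with np.errstate(over="ignore"):
            vary = (self.D * self.se ** 2 * (self.N - 2) + self.D * self.b ** 2) / (self.N - 1)
        self.s2y = float(np.nanmedian(vary))
        self.n = float(np.median(self.N))
        self.yty = self.s2y * (self.n - 1.0)

    def corr(self, idx_a, idx_b) -> np.ndarray:
        return (self._Z[:, idx_a].T @ self._Z[:, idx_b]) / self.n_ref

    def joint(self, S: list[int]):
        """Joint coefficients, ses and p for the selected index set."""
        k = len(S)
        Ds = self.D[S]
        R = self.corr(S, S)
        B = np.sqrt(np.outer(Ds, Ds)) * R
        rhs = Ds * self.b[S]
        Binv = np.linalg.pinv(B) if np.linalg.cond(B) > 1e12 else np.linalg.inv(B)
        bj = Binv @ rhs
        rss = max(self.yty - float(bj @ rhs), 1e-8 * self.yty)
        df = max(self.n - k - 1.0, 1.0)
        s2 = rss / df
        sej = np.sqrt(np.maximum(np.diag(Binv), 0.0) * s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sej > 0, bj / sej, 0.0)
        return bj, sej, two_sided_p_from_z(z), Binv, s2

    def conditional(self, S: list[int], candidates: np.ndarray):
        """Conditional b, se, p for each candidate given the selected set."""
        if not S:
            return self.b[candidates], self.se[candidates], self.p[candidates]
        bj, _, _, Binv, s2 = self.joint(S)
        Dc = self.D[candidates]
        r_cS = self.corr(candidates, S)
        V = np.sqrt(Dc)[:, None] * np.sqrt(self.D[S])[None, :] * r_cS
        num = Dc * self.b[candidates] - V @ bj
        den = Dc - np.einsum("ij,ij->i", V @ Binv, V)
        bad = den <= 1e-8 * Dc
        den = np.where(bad, np.nan, den)
        b_cond = num / den
        se_cond = np.sqrt(s2 / den)
        p_cond = np.where(np.isnan(b_cond), 1.0, two_sided_p_from_z(b_cond / se_cond))
        return b_cond, se_cond, p_cond


def cojo_select(stats: pd.DataFrame, reference: GenotypeSet, mode="threshold",
                scope="genomewide", p_threshold=5e-8, top_n=None,
                collinearity_cap=0.9) -> CojoResult:
    """Stepwise conditional-or-joint selection.

    ``mode='threshold'`` keeps adding the best conditionally significant
    variant (p ≤ ``p_threshold``) and back-eliminates selected variants whose
    joint p rises above the threshold; ``mode='topN'`` runs until ``top_n``
    variants are selected regardless of significance.  ``scope``
    ``'per_chromosome'`` runs the procedure independently within each
    chromosome of the reference map and concatenates the selections.
    """
    if mode not in ("threshold", "topN"):
        raise ValueError("mode must be 'threshold' or 'topN'")
    if mode == "topN" and not top_n:
        raise ValueError("topN mode requires top_n")
    if scope == "per_chromosome":
        vmap = reference.variants.set_index("id")["chrom"]
        chrom_of = stats["SNP"].map(vmap)
        parts = []
        for _, sub in stats.groupby(chrom_of, sort=True):
            parts.append(cojo_select(sub, reference, mode=mode, scope="genomewide",
                                     p_threshold=p_threshold, top_n=top_n,
                                     collinearity_cap=collinearity_cap))
        return CojoResult.concatenate(parts, mode, "per_chromosome")

    eng = _CojoEngine(stats, reference, collinearity_cap)
    m = len(eng.stats)
    empty = CojoResult([], np.empty(0), np.empty(0), np.empty(0), mode, scope)
    if m == 0:
        return empty

    S: list[int] = []
    available = np.ones(m, dtype=bool)
    target = top_n if mode == "topN" else m
    while len(S) < target:
        if eng.n_ref < len(S) + 2:
            raise ValueError(
                f"LD reference too small ({eng.n_ref} individuals) for {len(S)} selected variants")
        cand = np.where(available)[0]
        if cand.size == 0:
            break
        if S:
            # collinearity screen against the already-selected set
            r2 = eng.corr(cand, S) ** 2
            ok = r2.max(axis=1) <= eng.cap
            cand = cand[ok]
            if cand.size == 0:
                break
        _, _, p_cond = eng.conditional(S, cand)
        best = int(np.nanargmin(p_cond))
        if mode == "threshold" and not (p_cond[best] <= p_threshold):
            break
        chosen = int(cand[best])
        S.append(chosen)
        available[chosen] = False

        if mode == "threshold" and len(S) > 1:
            # back-elimination: drop selected variants losing joint significance
            while len(S) > 1:
                _, _, pj, _, _ = eng.joint(S)
                worst = int(np.argmax(pj))
                if pj[worst] <= p_threshold:
                    break
                dropped = S.pop(worst)
                logger.info("cojo_select: back-eliminated %s", eng.stats["SNP"].iloc[dropped])
                if dropped == chosen:
                    break
            if chosen not in S:
                break

    if not S:
        return empty
    bj, sej, pj, _, _ = eng.joint(S)
    return CojoResult(eng.stats["SNP"].iloc[S].tolist(), bj, sej, pj, mode, scope)
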