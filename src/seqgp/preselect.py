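"""The nine sequence-variant pre-selection strategies.

Each strategy turns discovery GWAS output into a list of whole-genome
sequence variants to add to a marker-panel prediction analysis:

====================  ========================================================
CONTROL               marker panel only, no added sequence variants
TOP_GWAS              all variants with p ≤ 5e−6 in either discovery cohort
COJO_GWAS_100 / 250   stepwise COJO per cohort, 100 / 250 most significant
GWAS_COJO_CHR         per-chromosome COJO per cohort at p ≤ 5e−3
TOP_META              all variants with p ≤ 5e−6 in the sample-size meta
META_COJO_100 / 250   COJO of the standard-error meta, 100 / 250 variants
META_COJO_CHR         per-chromosome COJO of the standard-error meta, p ≤ 5e−3
====================  ========================================================

Thresholded strategies walk an ordered ladder of thresholds (genome-wide
5e−8 first) until at least one variant is found.  After selection, variants
with minor allele frequency below 0.01 and variants already on the target
marker panel are removed (panel members keep being analysed as panel SNPs).
GWAS-based strategies take the de-duplicated union over the two cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cojo import cojo_select
from .grm import allele_frequencies

logger = logging.getLogger(__name__)

LADDER_TOP = (5e-8, 5e-6)
LADDER_CHR = (5e-8, 5e-6, 5e-3)


@dataclass(frozen=True)
class StrategySpec:
    label: str
    kind: str                  # 'control' | 'top' | 'cojo'
    source: str                # 'gwas' | 'meta'
    mode: str | None = None    # cojo mode
    scope: str = "genomewide"
    ladder: tuple = ()
    top_n: int | None = None


STRATEGIES = {
    "CONTROL": StrategySpec("CONTROL", "control", "none"),
    "TOP_GWAS": StrategySpec("TOP_GWAS", "top", "gwas", ladder=LADDER_TOP),
    "COJO_GWAS_100": StrategySpec("COJO_GWAS_100", "cojo", "gwas", mode="topN", top_n=100),
    "COJO_GWAS_250": StrategySpec("COJO_GWAS_250", "cojo", "gwas", mode="topN", top_n=250),
    "GWAS_COJO_CHR": StrategySpec("GWAS_COJO_CHR", "cojo", "gwas", mode="threshold",
                                  scope="per_chromosome", ladder=LADDER_CHR),
    "TOP_META": StrategySpec("TOP_META", "top", "meta", ladder=LADDER_TOP),
    "META_COJO_100": StrategySpec("META_COJO_100", "cojo", "meta", mode="topN", top_n=100),
    "META_COJO_250": StrategySpec("META_COJO_250", "cojo", "meta", mode="topN", top_n=250),
    "META_COJO_CHR": StrategySpec("META_COJO_CHR", "cojo", "meta", mode="threshold",
                                  scope="per_chromosome", ladder=LADDER_CHR),
}
STRATEGY_LABELS = tuple(STRATEGIES)


@dataclass
class PreselectedSet:
    variant_ids: list
    source: StrategySpec
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def _ladder_top(tables: list[pd.DataFrame], pcol: str, ladder) -> pd.DataFrame:
    """First ladder threshold yielding ≥1 hit; union over tables, p order."""
    for t in ladder:
        hits = [tb[tb[pcol] <= t] for tb in tables]
        combined = pd.concat(hits, ignore_index=True) if hits else pd.DataFrame()
        if len(combined):
            combined = combined.sort_values(pcol).drop_duplicates("SNP")
            combined["threshold"] = t
            return combined
    return pd.DataFrame(columns=["SNP", pcol])


def _cojo_with_ladder(stats, reference, spec: StrategySpec, cap: float):
    if spec.mode == "topN":
        return cojo_select(stats, reference, mode="topN", scope=spec.scope,
                           top_n=spec.top_n, collinearity_cap=cap)
    for t in spec.ladder:
        res = cojo_select(stats, reference, mode="threshold", scope=spec.scope,
                          p_threshold=t, collinearity_cap=cap)
        if res.selected:
            return res
    return cojo_select(stats, reference, mode="threshold", scope=spec.scope,
                       p_threshold=spec.ladder[-1], collinearity_cap=cap)


def apply_strategy(spec: StrategySpec | str, *, gwas_summaries=None, gwas_references=None,
                   meta_se_ma=None, meta_pvalue_table=None, meta_reference=None,
                   target_panel_ids=(), maf_genotypes=None, maf_threshold=0.01,
                   collinearity_cap=0.9) -> PreselectedSet:
    """Run one pre-selection strategy and apply the MAF and panel filters.

    ``gwas_summaries`` maps cohort name to its ``.ma`` scan and
    ``gwas_references`` to the matching LD-reference genotypes;
    ``meta_se_ma`` is the standardised inverse-variance meta in ``.ma``
    layout, ``meta_pvalue_table`` the sample-size-scheme meta table and
    ``meta_reference`` the combined discovery genotypes.  MAF is computed on
    ``maf_genotypes`` (typically the prediction herd, where the selected
    variants will be used).
    """
    if isinstance(spec, str):
        spec = STRATEGIES[spec]
    if spec.kind == "control":
        return PreselectedSet([], spec, pd.DataFrame(columns=["SNP", "source", "p", "b"]))

    rows = []
    if spec.kind == "top":
        if spec.source == "gwas":
            if not gwas_summaries:
                raise ValueError(f"{spec.label} needs the cohort GWAS summaries")
            hits = _ladder_top(list(gwas_summaries.values()), "p", spec.ladder)
            rows = [(s, "gwas", p, b) for s, p, b in
                    zip(hits.get("SNP", []), hits.get("p", []), hits.get("b", []))]
        else:
            if meta_pvalue_table is None:
                raise ValueError(f"{spec.label} needs the sample-size meta table")
            hits = _ladder_top([meta_pvalue_table], "p_meta", spec.ladder)
            rows = [(s, "meta_pvalue", p, np.nan) for s, p in
                    zip(hits.get("SNP", []), hits.get("p_meta", []))]
    elif spec.kind == "cojo":
        if spec.source == "gwas":
            if not (gwas_summaries and gwas_references):
                raise ValueError(f"{spec.label} needs cohort summaries and LD references")
            for name, stats in gwas_summaries.items():
                res = _cojo_with_ladder(stats, gwas_references[name], spec, collinearity_cap)
                rows += [(s, f"gwas:{name}", p, b) for s, b, p in
                         zip(res.selected, res.joint_b, res.joint_p)]
        else:
            if meta_se_ma is None or meta_reference is None:
                raise ValueError(f"{spec.label} needs the standard-error meta and a reference")
            res = _cojo_with_ladder(meta_se_ma, meta_reference, spec, collinearity_cap)
            rows = [(s, "meta_se", p, b) for s, b, p in
                    zip(res.selected, res.joint_b, res.joint_p)]
    else:
        raise ValueError(f"unknown strategy kind {spec.kind!r}")

    prov = pd.DataFrame(rows, columns=["SNP", "source", "p", "b"])
    prov = prov.drop_duplicates("SNP")  # de-duplicating union across cohorts

    if maf_genotypes is not None and len(prov):
        freqs = allele_frequencies(maf_genotypes, prov["SNP"].to_numpy())
        maf = np.minimum(freqs, 1.0 - freqs)
        dropped = int((maf < maf_threshold).sum())
        if dropped:
            logger.info("%s: %d variants below MAF %.3g removed", spec.label, dropped, maf_threshold)
        prov = prov[maf >= maf_threshold]

    on_panel = prov["SNP"].isin(set(target_panel_ids))
    if on_panel.any():
        logger.info("%s: %d pre-selected variants already on the target panel "
                    "kept as panel SNPs only", spec.label, int(on_panel.sum()))
    prov = prov[~on_panel].reset_index(drop=True)
    return PreselectedSet(prov["SNP"].tolist(), spec, prov)
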