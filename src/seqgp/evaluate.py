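"""Cross-validated prediction accuracy and bias over the scenario grid.

Accuracy of a scenario is the mean, over five random validation folds, of
the Pearson correlation between predicted GEBV and phenotypes adjusted for
fixed effects, divided by √h² — with h² taken from the single-GRM 800K
CONTROL REML fit so that every scenario is scaled by the same reference
heritability.  Bias is the slope of the regression of adjusted phenotype on
GEBV (1 = neither inflated nor deflated), pooled over folds.

``run_grid`` drives the whole study on a simulated (or user-assembled)
dataset: discovery GWAS per cohort, the two meta-analyses, each
pre-selection strategy, and cross-validated prediction for every
(panel, strategy, method) cell, with the multi-GRM model skipped for
CONTROL (it would be identical to the single-GRM CONTROL).  The fold
assignment is drawn once and reused across every scenario.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import fit_null_mlm, mlma_scan
from .bayesr import BayesRPrior, bayesr_gibbs, standardize_genotypes
from .gblup import blup_gebv, reml
from .grm import allele_frequencies, build_grm
from .iofmt import GenotypeSet, design_matrix
from .meta import meta_pvalue, meta_se, meta_to_ma, standardize_effects
from .preselect import STRATEGIES, apply_strategy
from .simdata import SimulatedStudy

logger = logging.getLogger(__name__)

ALL_PANELS = ("6K", "50K", "800K")
ALL_METHODS = ("SGRM", "MGRM", "BAYESR")


def make_folds(ids, k=5, seed=0) -> pd.Series:
    """Random k-way partition (sizes differing by ≤ 1), breed-agnostic."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    if len(ids) < k:
        raise ValueError("fewer individuals than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(order, k), start=1):
        fold[chunk] = f
    return pd.Series(fold, index=ids, name="fold")


def adjust_phenotypes(pheno: pd.DataFrame, continuous=("age",),
                      categorical=("contemporary_group",)) -> np.ndarray:
    """OLS residuals of the trait on the fixed effects only (no GRM)."""
    continuous = [c for c in continuous if c in pheno.columns]
    categorical = [c for c in categorical if c in pheno.columns]
    X = design_matrix(pheno, continuous=continuous, categorical=categorical)
    y = pheno["trait"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class EvalMetrics:
    per_fold_correlation: list
    mean_correlation: float
    accuracy: float
    bias_slope: float
    per_fold_slopes: list
    h2_reference: float


def accuracy_and_bias(gebv_folds, adjusted_folds, h2_reference) -> EvalMetrics:
    """Fold correlations, accuracy = mean r/√h², pooled bias slope.

    ``gebv_folds`` and ``adjusted_folds`` are parallel lists of per-fold
    validation vectors.
    """
    rs, slopes = [], []
    for g, a in zip(gebv_folds, adjusted_folds):
        g = np.asarray(g, float)
        a = np.asarray(a, float)
        if g.size < 3:
            raise ValueError("need at least 3 validation animals per fold")
        if np.var(g) == 0:
            raise ValueError("zero-variance GEBV; correlation undefined")
        rs.append(float(np.corrcoef(g, a)[0, 1]))
        slopes.append(float(np.polyfit(g, a, 1)[0]))
    g_all = np.concatenate([np.asarray(g, float) for g in gebv_folds])
    a_all = np.concatenate([np.asarray(a, float) for a in adjusted_folds])
    bias = float(np.polyfit(g_all, a_all, 1)[0])
    mean_r = float(np.mean(rs))
    return EvalMetrics(rs, mean_r, mean_r / np.sqrt(h2_reference), bias, slopes, h2_reference)


# ---------------------------------------------------------------------------
# grid orchestration
# ---------------------------------------------------------------------------


def _all_strategies():
    return tuple(STRATEGIES)


@dataclass
class GridConfig:
    panels: tuple = ALL_PANELS
    strategies: tuple = field(default_factory=_all_strategies)
    methods: tuple = ALL_METHODS
    k_folds: int = 5
    seed: int = 0
    chain_length: int = 5000
    burn_in: int = 2000
    thinning: int = 10
    gwas_grm_panel: str = "800K"
    maf_threshold: float = 0.01
    collinearity_cap: float = 0.9


def discovery_design(ptable: pd.DataFrame) -> np.ndarray:
    cont = [c for c in ("bos_indicus_fraction",) if c in ptable.columns]
    return design_matrix(ptable, continuous=cont,
                         categorical=("contemporary_group", "dam_age"))


def prediction_design(ptable: pd.DataFrame) -> np.ndarray:
    return design_matrix(ptable, continuous=("age",), categorical=("contemporary_group",))


def run_discovery_gwas(study: SimulatedStudy, config: GridConfig):
    """Per-cohort mixed-model scans of all WGS variants."""
    summaries, trait_means = {}, {}
    for name, (gset, ptable) in study.discovery.items():
        X = discovery_design(ptable)
        y = ptable["trait"].to_numpy(dtype=float)
        grm = build_grm(gset, gset.panel_ids(config.gwas_grm_panel))
        null = fit_null_mlm(y, X, grm)
        logger.info("GWAS %s: null h² = %.3f", name, null.h2)
        summaries[name] = mlma_scan(gset, y, X, null)
        trait_means[name] = float(y.mean())
    return summaries, trait_means


def run_meta(summaries: dict, trait_means: dict):
    """Standard-error-scheme meta (standardised) and sample-size-scheme meta."""
    std = [standardize_effects(tab, trait_means[name]) for name, tab in summaries.items()]
    se_ma = meta_to_ma(meta_se(std))
    pvalue_table = meta_pvalue(list(summaries.values()))
    return se_ma, pvalue_table


def preselect_all(study: SimulatedStudy, summaries, se_ma, pvalue_table, config: GridConfig):
    """Run every requested strategy once (panel exclusion applied later)."""
    prediction, _ = study.prediction
    meta_reference = GenotypeSet.concatenate([g for g, _ in study.discovery.values()])
    sets = {}
    for label in config.strategies:
        try:
            sets[label] = apply_strategy(
                STRATEGIES[label], gwas_summaries=summaries,
                gwas_references={n: g for n, (g, _) in study.discovery.items()},
                meta_se_ma=se_ma, meta_pvalue_table=pvalue_table,
                meta_reference=meta_reference, target_panel_ids=(),
                maf_genotypes=prediction, maf_threshold=config.maf_threshold,
                collinearity_cap=config.collinearity_cap,
            )
            logger.info("strategy %s: %d variants pre-selected",
                        label, len(sets[label].variant_ids))
        except Exception as exc:  # a failed strategy marks its cells, not the run
            logger.warning("strategy %s failed: %s", label, exc)
            sets[label] = exc
    return sets


def _cell_seed(seed, panel, strategy, method, fold) -> int:
    return zlib.crc32(f"{seed}|{panel}|{strategy}|{method}|{fold}".encode()) % (2 ** 31)


def _evaluate_cell(prediction, y, X, adjusted, folds, panel_ids, wgs_ids,
                   method, h2_ref, config) -> EvalMetrics:
    fold_vals = folds.to_numpy()
    n = prediction.n_individuals
    if method == "SGRM":
        ids = np.concatenate([panel_ids, wgs_ids]) if len(wgs_ids) else panel_ids
        grms = [build_grm(prediction, ids).values]
    elif method == "MGRM":
        if len(wgs_ids) == 0:
            raise ValueError("MGRM needs a non-empty pre-selected variant set")
        grms = [build_grm(prediction, panel_ids).values,
                build_grm(prediction, wgs_ids).values]
    elif method == "BAYESR":
        ids = np.concatenate([panel_ids, wgs_ids]) if len(wgs_ids) else panel_ids
        freqs = allele_frequencies(prediction, ids)
        W, _, _ = standardize_genotypes(prediction, ids, freqs)
    else:
        raise ValueError(f"unknown method {method}")

    gebv_folds, adj_folds = [], []
    for f in range(1, config.k_folds + 1):
        val = np.where(fold_vals == f)[0]
        train = np.where(fold_vals != f)[0]
        if method in ("SGRM", "MGRM"):
            vc = reml(y[train], X[train], [G[np.ix_(train, train)] for G in grms])
            fit = blup_gebv(vc, grms, y[train], X[train], train)
            gebv_val = fit.total_gebv[val]
        else:
            prior = BayesRPrior(chain_length=config.chain_length, burn_in=config.burn_in,
                                thinning=config.thinning)
            seed = _cell_seed(config.seed, "", "", "BAYESR", f)
            post = bayesr_gibbs(y[train], X[train], W[train], prior, seed=seed)
            gebv_val = W[val] @ post.g_hat
        gebv_folds.append(gebv_val)
        adj_folds.append(adjusted[val])
    return accuracy_and_bias(gebv_folds, adj_folds, h2_ref)


def reference_h2(prediction, y, X, config: GridConfig, folds=None) -> float:
    """Reference h²: the single-GRM 800K CONTROL estimate.

    When a fold assignment is given, the REML estimates are averaged over the
    five training (reference) populations, mirroring how the study reports
    its variance components; otherwise a single full-herd fit is used.
    """
    G = build_grm(prediction, prediction.panel_ids("800K")).values
    if folds is None:
        return reml(y, X, [G]).h2_total
    fold_vals = folds.to_numpy()
    h2s = []
    for f in np.unique(fold_vals):
        tr = np.where(fold_vals != f)[0]
        h2s.append(reml(y[tr], X[tr], [G[np.ix_(tr, tr)]]).h2_total)
    return float(np.mean(h2s))


def benchmark_configs(seed: int, full_grid: bool = False):
    """The canonical desk-scale benchmark study and grid configuration.

    One simulated study of 800 discovery + 1000 prediction animals over 6000
    sequence variants (panels 600/1500/3000) with the default genetic
    architecture, evaluated either on the focused CONTROL/META_COJO_CHR
    sub-grid or (``full_grid=True``) on all nine strategies.
    """
    from .simdata import SimConfig

    sim = SimConfig(
        n_discovery={"Brahman": 400, "TropicalComposite": 400},
        n_prediction={"Brahman": 270, "SantaGertrudis": 460, "Droughtmaster": 270},
        n_variants_wgs=6000, panel_sizes={"6K": 600, "50K": 1500, "800K": 3000},
        n_chromosomes=10, seed=seed,
    )
    grid = GridConfig(
        seed=seed,
        strategies=tuple(STRATEGIES) if full_grid else ("CONTROL", "META_COJO_CHR"),
        chain_length=1500, burn_in=500, thinning=5,
    )
    return sim, grid


def run_grid(study: SimulatedStudy, config: GridConfig | None = None) -> pd.DataFrame:
    """One EvalResult row per (panel, strategy, method), MGRM×CONTROL skipped."""
    if config is None:
        config = GridConfig()
    prediction, ptable = study.prediction
    y = ptable["trait"].to_numpy(dtype=float)
    X = prediction_design(ptable)
    adjusted = adjust_phenotypes(ptable)
    folds = make_folds(prediction.individual_ids, config.k_folds, config.seed)

    summaries, trait_means = run_discovery_gwas(study, config)
    se_ma, pvalue_table = run_meta(summaries, trait_means)
    selections = preselect_all(study, summaries, se_ma, pvalue_table, config)
    h2_ref = reference_h2(prediction, y, X, config, folds)
    logger.info("reference h² (SGRM 800K CONTROL) = %.3f", h2_ref)

    rows = []
    for panel in config.panels:
        panel_ids = prediction.panel_ids(panel)
        panel_set = set(panel_ids)
        for strategy in config.strategies:
            selection = selections[strategy]
            if isinstance(selection, Exception):
                for method in config.methods:
                    if method == "MGRM" and strategy == "CONTROL":
                        continue
                    rows.append({"panel": panel, "strategy": strategy, "method": method,
                                 "n_wgs_selected": 0, "h2_reference": h2_ref,
                                 "mean_correlation": np.nan, "accuracy": np.nan,
                                 "bias_slope": np.nan, "status": "failed",
                                 "error": str(selection)})
                continue
            wgs_ids = np.array(
                [v for v in selection.variant_ids if v not in panel_set],
                dtype=object)
            for method in config.methods:
                if method == "MGRM" and strategy == "CONTROL":
                    continue  # confounded: MGRM CONTROL ≡ SGRM CONTROL
                row = {"panel": panel, "strategy": strategy, "method": method,
                       "n_wgs_selected": len(wgs_ids), "h2_reference": h2_ref,
                       "status": "ok", "error": ""}
                try:
                    m = _evaluate_cell(prediction, y, X, adjusted, folds, panel_ids,
                                       wgs_ids, method, h2_ref, config)
                    row.update(
                        mean_correlation=m.mean_correlation, accuracy=m.accuracy,
                        bias_slope=m.bias_slope,
                        **{f"r_fold{i+1}": r for i, r in enumerate(m.per_fold_correlation)},
                    )
                except Exception as exc:  # scenario failure must not stop the grid
                    logger.warning("scenario (%s, %s, %s) failed: %s", panel, strategy,
                                   method, exc)
                    row.update(mean_correlation=np.nan, accuracy=np.nan,
                               bias_slope=np.nan, status="failed", error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
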