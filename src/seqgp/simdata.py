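"""Synthetic multi-breed genotypes and two-trait phenotypes.

The generator emulates the study design the pipeline targets: two discovery
herds recorded for a continuous age-at-puberty trait (AGECL, moderately
heritable), and a three-breed prediction herd recorded for a single-visit
puberty proxy score (RMS, lowly heritable), with the two traits sharing QTL
whose effects are strongly negatively correlated (default r_g = −0.83).

Genotypes come from a Balding–Nichols model: each breed's allele frequency is
drawn from Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst) around an ancestral frequency
p ~ U(0.05, 0.95), and haplotypes follow a first-order Markov copying process
so that LD between adjacent variants decays exponentially with distance.
Nested marker panels (6K ⊂ 50K ⊂ 800K ⊂ WGS) are flagged on the variant map;
causal variants live in the WGS set and a configurable fraction (plus the one
optional large-effect QTL) is kept off every commercial panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iofmt import GenotypeSet, make_variant_table


def _default_discovery():
    return {"Brahman": 400, "TropicalComposite": 400}


def _default_prediction():
    return {"Brahman": 270, "SantaGertrudis": 480, "Droughtmaster": 250}


def _default_panels():
    return {"6K": 1000, "50K": 4000, "800K": 12000}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are desk scale."""

    n_discovery: dict = field(default_factory=_default_discovery)
    n_prediction: dict = field(default_factory=_default_prediction)
    n_variants_wgs: int = 20_000
    panel_sizes: dict = field(default_factory=_default_panels)
    n_chromosomes: int = 10
    chromosome_length_bp: int = 100_000_000
    fst: float = 0.1
    ld_decay_bp: float = 1_000_000.0
    n_qtl: int = 40
    large_qtl: bool = True
    large_qtl_share: float = 0.20
    qtl_offpanel_fraction: float = 0.0
    qtl_variance_profile: list | None = None
    h2_discovery: float = 0.55
    h2_prediction: float = 0.20
    genetic_correlation: float = -0.83
    trait_mean_discovery: float = 600.0
    vp_discovery: float = 2500.0
    trait_mean_prediction: float = 2.27
    vp_prediction: float = 1.11
    n_contemporary_groups: int = 8
    n_dam_age_levels: int = 5
    cg_effect_sd: float = 0.15   # relative to the trait's phenotypic SD
    age_effect_sd: float = 0.10  # idem; prediction trait only
    round_prediction_trait: bool = False
    seed: int = 0

    def __post_init__(self):
        sizes = [self.panel_sizes[k] for k in ("6K", "50K", "800K")]
        if not (sizes[0] <= sizes[1] <= sizes[2] <= self.n_variants_wgs):
            raise ValueError("panel sizes must be nested and ≤ n_variants_wgs")
        for h2 in (self.h2_discovery, self.h2_prediction):
            if not 0.0 <= h2 < 1.0:
                raise ValueError("heritabilities must lie in [0, 1)")
        if abs(self.genetic_correlation) > 1.0:
            raise ValueError("|genetic_correlation| must be ≤ 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_qtl > self.n_variants_wgs:
            raise ValueError("n_qtl exceeds the WGS variant count")
        if self.n_qtl == 0 and (self.h2_discovery > 0 or self.h2_prediction > 0):
            raise ValueError("requested h² > 0 is unreachable with 0 QTL")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimConfig":
        """Herd sizes of the real study (868 + 960 discovery; 979/1802/914)."""
        kw = dict(
            n_discovery={"Brahman": 868, "TropicalComposite": 960},
            n_prediction={"Brahman": 979, "SantaGertrudis": 1802, "Droughtmaster": 914},
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimulatedStudy:
    """Genotypes, phenotypes, and ground truth for one simulated study."""

    discovery: dict            # population -> (GenotypeSet, phenotype DataFrame)
    prediction: tuple          # (GenotypeSet, phenotype DataFrame)
    qtl: pd.DataFrame          # id, chrom, pos, freq, effect_discovery, effect_prediction, on_* flags
    tbv: pd.DataFrame          # individual_id, population, tbv_discovery, tbv_prediction
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _variant_map(config: SimConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    m = config.n_variants_wgs
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.chromosome_length_bp, size=k, replace=False)) + 1
        chroms.append(np.full(k, str(c), dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    ids = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)

    # nested panels: 6K ⊂ 50K ⊂ 800K ⊂ WGS
    idx800 = np.sort(rng.choice(m, size=config.panel_sizes["800K"], replace=False))
    idx50 = np.sort(rng.choice(idx800, size=config.panel_sizes["50K"], replace=False))
    idx6 = np.sort(rng.choice(idx50, size=config.panel_sizes["6K"], replace=False))
    p800k = np.zeros(m, dtype=bool); p800k[idx800] = True
    p50k = np.zeros(m, dtype=bool); p50k[idx50] = True
    p6k = np.zeros(m, dtype=bool); p6k[idx6] = True

    variants = make_variant_table(ids, chrom, pos, ["A"] * m, ["B"] * m, p6k, p50k, p800k)
    ancestral = rng.uniform(0.05, 0.95, size=m)
    return variants, ancestral


def _breed_frequencies(ancestral, fst, rng) -> np.ndarray:
    if fst == 0.0:
        return ancestral.copy()
    a = ancestral * (1.0 - fst) / fst
    b = (1.0 - ancestral) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def _sample_haplotypes(freqs, variants: pd.DataFrame, n_hap: int, ld_decay: float, rng):
    """Markov copying chain: adjacent-variant correlation exp(−distance/decay)."""
    m = len(freqs)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    dist = np.empty(m)
    dist[1:] = pos[1:] - pos[:-1]
    r_adj = np.where(new_chrom, 0.0, np.exp(-np.abs(dist) / ld_decay))
    r_adj[0] = 0.0

    H = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    sd = np.sqrt(freqs * (1.0 - freqs))
    prev = (u[:, 0] < freqs[0]).astype(np.int8)
    H[:, 0] = prev
    for j in range(1, m):
        if r_adj[j] == 0.0:
            pj = freqs[j]
            prev = (u[:, j] < pj).astype(np.int8)
        else:
            pj = freqs[j] + r_adj[j] * sd[j] / sd[j - 1] * (prev - freqs[j - 1])
            np.clip(pj, 0.0, 1.0, out=pj)
            prev = (u[:, j] < pj).astype(np.int8)
        H[:, j] = prev
    return H


def simulate_genotypes(config: SimConfig, rng=None):
    """Generate per-population GenotypeSets with nested panel flags.

    Returns ``(discovery_sets, prediction_set, ancestral_freqs)`` where
    ``discovery_sets`` maps population name to its GenotypeSet and the
    prediction set stacks all prediction breeds over a shared variant map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants, ancestral = _variant_map(config, rng)

    breeds = list(dict.fromkeys(list(config.n_discovery) + list(config.n_prediction)))
    breed_freqs = {b: _breed_frequencies(ancestral, config.fst, rng) for b in breeds}

    def draw_population(breed, n, prefix):
        H = _sample_haplotypes(breed_freqs[breed], variants, 2 * n, config.ld_decay_bp, rng)
        dosages = (H[0::2] + H[1::2]).astype(np.float64)
        ids = [f"{prefix}_{breed}_{i:05d}" for i in range(n)]
        return GenotypeSet(ids, [breed] * n, dosages, variants.copy())

    discovery = {b: draw_population(b, n, "disc") for b, n in config.n_discovery.items()}
    pred_sets = [draw_population(b, n, "pred") for b, n in config.n_prediction.items()]
    prediction = GenotypeSet.concatenate(pred_sets)
    return discovery, prediction, ancestral


# ---------------------------------------------------------------------------
# QTL architecture and phenotypes
# ---------------------------------------------------------------------------


def _draw_qtl(config: SimConfig, variants: pd.DataFrame, ancestral, rng) -> pd.DataFrame:
    m = config.n_variants_wgs
    off_panel = ~variants["p800k"].to_numpy()
    candidates_off = np.where(off_panel & (ancestral > 0.25) & (ancestral < 0.75))[0]

    n_off = min(int(round(config.qtl_offpanel_fraction * config.n_qtl)), candidates_off.size)
    if config.large_qtl and config.n_qtl > 1:
        n_off = max(n_off, 1)  # the dominant QTL always sits off the panels
    chosen_off = rng.choice(candidates_off, size=n_off, replace=False)
    remaining = np.setdiff1d(np.arange(m), chosen_off)
    chosen_any = rng.choice(remaining, size=config.n_qtl - n_off, replace=False)
    qtl_idx = np.sort(np.concatenate([chosen_off, chosen_any]))

    # per-QTL share of the genetic variance
    if config.qtl_variance_profile is not None:
        weights = np.zeros(config.n_qtl)
        start = 0
        for frac, share in config.qtl_variance_profile:
            k = int(round(frac * config.n_qtl))
            if k:
                weights[start:start + k] = share / k
                start += k
        weights[start:] = max(0.0, 1.0 - weights.sum()) / max(1, config.n_qtl - start)
    else:
        weights = np.full(config.n_qtl, 1.0 / max(config.n_qtl, 1))
        if config.large_qtl and config.n_qtl > 1:
            # one large off-panel QTL dominating the signal (a PLAG1-like region)
            off_mask = off_panel[qtl_idx]
            large = int(rng.choice(np.where(off_mask)[0])) if off_mask.any() else 0
            weights[:] = (1.0 - config.large_qtl_share) / (config.n_qtl - 1)
            weights[large] = config.large_qtl_share

    rg = config.genetic_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rg], [rg, 1.0]], size=config.n_qtl)
    p = ancestral[qtl_idx]
    scale = np.sqrt(weights / (2.0 * p * (1.0 - p)))
    qtl = variants.iloc[qtl_idx][["id", "chrom", "pos", "p6k", "p50k", "p800k"]].copy()
    qtl["freq_ancestral"] = p
    qtl["effect_discovery"] = z[:, 0] * scale
    qtl["effect_prediction"] = z[:, 1] * scale
    return qtl.reset_index(drop=True)


def _true_breeding_values(gsets: list[GenotypeSet], qtl: pd.DataFrame, effect_col: str):
    """Per-animal TBV = centred QTL dosages × effects, per genotype set."""
    out = []
    for g in gsets:
        cols = g.column_index(qtl["id"].to_numpy())
        X = g.dosages[:, cols]
        Xc = X - X.mean(axis=0)
        out.append(Xc @ qtl[effect_col].to_numpy(dtype=float))
    return out


def _scale_to_h2(tbvs: list[np.ndarray], h2: float, vp: float):
    """Scale factor making pooled Var(TBV) equal h²·vp (0 when TBV is null)."""
    pooled = np.concatenate(tbvs)
    v = pooled.var()
    if v == 0.0:
        return 0.0
    return np.sqrt(h2 * vp / v)


def simulate_phenotypes(config: SimConfig, discovery, prediction, qtl: pd.DataFrame, rng):
    """Build phenotype tables and true breeding values for every population.

    Discovery populations get the age-at-puberty trait with contemporary-group
    and dam-age fixed effects (plus a Bos indicus fraction covariate for the
    composite population); the prediction herd gets the proxy score with age
    and contemporary-group effects, centred on ``trait_mean_prediction``.
    """
    disc_sets = list(discovery.values())
    tbv_disc_raw = _true_breeding_values(disc_sets, qtl, "effect_discovery")
    tbv_pred_raw = _true_breeding_values(disc_sets + [prediction], qtl, "effect_prediction")

    s_disc = _scale_to_h2(tbv_disc_raw, config.h2_discovery, config.vp_discovery)
    s_pred = _scale_to_h2([tbv_pred_raw[-1]], config.h2_prediction, config.vp_prediction)

    sd_disc = np.sqrt(config.vp_discovery)
    sd_pred = np.sqrt(config.vp_prediction)
    cg_levels = [f"cg{k}" for k in range(config.n_contemporary_groups)]

    tbv_rows = []
    disc_tables = {}
    for (name, gset), tbv_a in zip(discovery.items(), tbv_disc_raw):
        n = gset.n_individuals
        tbv = s_disc * tbv_a
        cg = rng.integers(config.n_contemporary_groups, size=n)
        cg_eff = rng.normal(0.0, config.cg_effect_sd * sd_disc, size=config.n_contemporary_groups)
        cg_eff -= cg_eff.mean()  # contrasts; the trait mean carries the level
        dam = rng.integers(config.n_dam_age_levels, size=n)
        dam_eff = rng.normal(0.0, 0.05 * sd_disc, size=config.n_dam_age_levels)
        dam_eff -= dam_eff.mean()
        e = rng.normal(0.0, np.sqrt((1.0 - config.h2_discovery) * config.vp_discovery), size=n)
        y = config.trait_mean_discovery + tbv + cg_eff[cg] + dam_eff[dam] + e
        table = pd.DataFrame(
            {
                "individual_id": gset.individual_ids,
                "trait": y,
                "contemporary_group": [cg_levels[k] for k in cg],
                "dam_age": [f"dam{k}" for k in dam],
            }
        )
        if name == "TropicalComposite":
            bi = rng.uniform(0.2, 0.8, size=n)
            y += 0.2 * sd_disc * (bi - bi.mean())
            table["trait"] = y
            table["bos_indicus_fraction"] = bi
        disc_tables[name] = table
        tbv_rows.append(pd.DataFrame(
            {"individual_id": gset.individual_ids, "population": name,
             "tbv_discovery": tbv, "tbv_prediction": np.nan}))

    # prediction herd
    n = prediction.n_individuals
    tbv_p = s_pred * tbv_pred_raw[-1]
    age = rng.normal(600.0, 30.0, size=n)
    age_slope = config.age_effect_sd * sd_pred / 30.0
    cg = rng.integers(config.n_contemporary_groups, size=n)
    cg_eff = rng.normal(0.0, config.cg_effect_sd * sd_pred, size=config.n_contemporary_groups)
    cg_eff -= cg_eff.mean()
    e = rng.normal(0.0, np.sqrt((1.0 - config.h2_prediction) * config.vp_prediction), size=n)
    y = config.trait_mean_prediction + tbv_p + age_slope * (age - age.mean()) + cg_eff[cg] + e
    if config.round_prediction_trait:
        y = np.clip(np.rint(y), 0, 5)
    pred_table = pd.DataFrame(
        {
            "individual_id": prediction.individual_ids,
            "trait": y,
            "age": age,
            "contemporary_group": [cg_levels[k] for k in cg],
        }
    )
    tbv_rows.append(pd.DataFrame(
        {"individual_id": prediction.individual_ids, "population": "prediction",
         "tbv_discovery": np.nan, "tbv_prediction": tbv_p}))

    # record TBV for discovery animals on the prediction trait too (truth table)
    for rows, tbv_b in zip(tbv_rows[:-1], tbv_pred_raw[:-1]):
        rows["tbv_prediction"] = s_pred * tbv_b

    qtl_out = qtl.copy()
    qtl_out["effect_discovery"] *= s_disc
    qtl_out["effect_prediction"] *= s_pred
    return disc_tables, pred_table, qtl_out, pd.concat(tbv_rows, ignore_index=True)


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Full study: genotypes, QTL architecture, phenotypes, ground truth."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    discovery, prediction, ancestral = simulate_genotypes(config, rng)
    some = next(iter(discovery.values())) if discovery else prediction
    if config.n_qtl > 0:
        qtl = _draw_qtl(config, some.variants, ancestral, rng)
    else:
        qtl = pd.DataFrame(columns=["id", "chrom", "pos", "p6k", "p50k", "p800k",
                                    "freq_ancestral", "effect_discovery", "effect_prediction"])
    disc_tables, pred_table, qtl, tbv = simulate_phenotypes(config, discovery, prediction, qtl, rng)
    disc = {name: (discovery[name], disc_tables[name]) for name in discovery}
    return SimulatedStudy(disc, (prediction, pred_table), qtl, tbv, config)
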