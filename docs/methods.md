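# Methods

`seqgp` re-implements, at desk scale, a complete genomic-prediction study
design for age-at-puberty proxy traits in multi-breed tropical beef cattle:
discovery GWAS in two research herds, meta-analysis of the two summary sets,
conditional-or-joint (COJO) pre-selection of whole-genome sequence variants,
and cross-validated prediction in a separate multi-breed herd with GBLUP
(one or two genomic relationship matrices) and BayesR. Because the real herd
data are proprietary, the package ships a synthetic-data generator that
emulates the study's statistical structure, and every analysis stage is
exercised against that generator.

## The synthetic study

**Genotypes.** Breeds diverge from a common ancestral population under a
Balding–Nichols model: for ancestral frequency p ~ U(0.05, 0.95) and
divergence Fst = f, each breed's frequency is drawn from
Beta(p(1−f)/f, (1−p)(1−f)/f), so that Hudson's Fst on realised genotypes
recovers f (checked in the tests). Haplotypes are sampled by a first-order
Markov copying process along each chromosome: the correlation between
adjacent variants is exp(−d/λ) for distance d, giving exponentially decaying
LD with genetic distance. The decay scale λ defaults to 1 Mb. That value is
chosen so that, at desk-scale marker spacing, the three nested panels
reproduce the tagging regime of real bovine arrays — beef cattle LD is
long-range, dense panels (50K/800K equivalents) tag most common variants
well, and the sparse 6K-equivalent panel tags weakly. Nested panel
membership (6K ⊂ 50K ⊂ 800K ⊂ WGS) is drawn once on the shared variant map.

**Trait architecture.** Two traits share the same QTL with per-QTL effects
drawn from a bivariate normal with correlation r_g = −0.83 (the reported
genetic correlation between the direct age-at-puberty measure and the
single-visit proxy score). Defaults: 40 QTL; one "large" QTL carrying 20% of
the genetic variance, always placed off every commercial panel at common
ancestral frequency (0.25–0.75) — this emulates the PLAG1-region signal that
dominated the real study's meta-analysis selections and is the mechanism by
which pre-selected sequence variants can help a sparse panel. The remaining
QTL are drawn uniformly over the sequence-variant set, so roughly half sit
on the 800K panel and the rest are well tagged; this matches the real
study's variance components, where the marker panels already capture
essentially all of the trait's additive variance and added sequence variants
contribute only a small extra component. Effects are rescaled once per trait
so that the realised variance of true breeding values equals h²·Vp exactly
(defaults h² = 0.55 for the discovery trait and 0.20, Vp = 1.11, mean 2.27
for the prediction trait). Contemporary-group, dam-age (discovery), Bos
indicus fraction (composite discovery herd) and age-at-measurement
(prediction herd) fixed effects are added as centred draws of modest size
(≈ 0.05–0.15 phenotypic SD), so the realised Var(TBV)/Var(y) stays within a
few percent of the nominal h². The prediction trait is kept continuous by
default (the study analysed the 0–5 score as approximately normal); integer
rounding to the 0–5 scale is available.

**Desk scale.** Default herd sizes are 400+400 discovery and 1000 prediction
animals over 20 000 sequence variants (panels 1 000/4 000/12 000); the
benchmark grid used by the acceptance checks runs 6 000 variants with panels
600/1 500/3 000, and `SimConfig.paper_scale()` carries the real herd sizes
(868/960 discovery; 979/1802/914 prediction). Everything is driven by one
integer seed and is byte-reproducible.

What the generator does **not** emulate: coalescent-exact LD and allele
spectra, pedigree/family structure within herds, breed-specific LD phase
differences, imputation error, and genotype missingness. Passing tests
therefore demonstrate the machinery and its statistical behaviour under this
idealised architecture, not performance on real cattle data.

## Discovery GWAS

Each cohort is scanned with a mixed linear model: variance components of the
covariate-only null model (`y = Xb + a + e`, `a ~ N(0, G σg²)`) are
estimated once by REML and held fixed for every variant test (the
P3D/EMMAX approximation, matching standard MLMA practice). Each variant's
effect is then a generalised-least-squares coefficient with covariance
σ̂g²G + σ̂e²I, with a two-sided normal p-value — the large-sample convention
consumed by COJO and Metal-style meta-analysis. The GRM uses the 800K-
equivalent panel by default and the tested variant is not removed from it;
leave-one-chromosome-out can be had by passing per-chromosome null fits.
Monomorphic variants yield records with b = 0, se = ∞, p = 1.

## Meta-analysis

Two Metal-style schemes. The *sample-size* scheme combines signed z-scores
with √N weights (Stouffer). The *standard-error* (inverse-variance) scheme
is applied to effects standardised by each cohort's trait mean, with the
standard error reconstructed from the p-value via

    z = −0.862 + √(0.743 − 2.404·ln P),      se = |b| / z.

The logarithm is natural: that makes this the Altman–Bland approximation to
the normal quantile (z(0.05) = 1.9566 ≈ 1.96); a base-10 reading would give
z(0.05) = 3.15, unusable as a z-score. The approximation is excellent in the
tail (0.2% relative error at p = 0.05, 2% at p = 10⁻⁶) but degrades in
relative terms as p → 1; it is used exactly as published. Effect alleles are
harmonised by id before combining (swapped alleles flip the effect sign and
complement the frequency); irreconcilable allele pairs are dropped.

## COJO pre-selection

Greedy stepwise selection from summary statistics with a genotyped LD
reference. Joint and conditional coefficients are reconstructed from
(b, se, freq, N) and the reference correlations; the per-variant x'x is
taken as N times the *realised* reference dosage variance (exact when the
reference is the discovery sample itself, and closer to the truth than the
2p(1−p) Hardy–Weinberg value otherwise), and the phenotypic variance is the
median across variants of the value implied by each variant's (b, se, freq,
N). Threshold mode adds the best conditionally significant variant and
back-eliminates selected variants whose joint p rises above the threshold;
topN mode runs until N variants are selected. Candidates with r² > 0.9
against the selected set are never added. Per-chromosome scope runs the
procedure independently within chromosomes. Thresholded strategies walk the
published ladder (5e−8, then 5e−6, then 5e−3 for the per-chromosome
strategies) until at least one variant is found.

The nine strategies (marker-panel CONTROL; TOP / COJO-100 / COJO-250 /
per-chromosome COJO, each from the single-cohort GWAS union or from the
meta-analysis) then pass a MAF ≥ 0.01 filter (computed on the prediction
herd, where the variants will be used) and lose any variant already on the
target marker panel (those keep being analysed as panel SNPs).

## GBLUP

Average-information REML with three expectation-maximisation warm-up steps;
variances start at vp/(2·c) per genetic component and vp/2 for the
residual, are clamped at ≥ 10⁻⁸·vp, and convergence is declared at
|Δ log L| < 10⁻⁸ (≤ 200 iterations). Because the restricted likelihood can
be multimodal on small data, the optimiser re-starts from the near-null
boundary whenever a post-convergence probe finds a higher likelihood there.
A numerically non-positive-definite GRM gets one 10⁻⁶ diagonal jitter.
GEBVs are conditional expectations: â_c = σ̂_c²·G_c[all, train]·V⁻¹(y−Xb̂),
so validation animals are predicted through their relationship rows alone;
in the two-matrix model the component GEBVs are summed. GRMs are VanRaden/
GCTA method 1, centred with allele frequencies of the entire analysed
population; monomorphic variants are dropped.

## BayesR

Single-site Gibbs sampling of the four-component mixture
{0, 0.0001, 0.001, 0.01}·σg² on column-standardised genotypes, with
Dirichlet(1,1,1,1) mixture proportions, fixed effects sampled inside the
chain (flat priors), σe² from its scaled inverse-χ² full conditional, and
the mixture scale σg² sampled from its full conditional given the current
effects (weakly informative scaled inverse-χ², ν₀ = 4, scale vp/2) —
a fixed-σg² mode is available and is the supported configuration when the
zero component is pinned shut (e.g. the ridge limit used for validation),
where a sampled scale mixes pathologically once every SNP is active and
m ≫ n. Component indicators are sampled by exact enumeration of the four
marginal likelihoods. Chain defaults are 50 000 iterations with 20 000
burn-in (thinning 10); the test suite and benchmark use shorter chains
(≈1 500–5 000) after checking that posterior summaries are stable at those
lengths for the sizes involved. The reported genetic variance is the
posterior mean of Var(Wg) — the genetic variance realised in the sample,
comparable to a REML additive variance. Candidate GEBVs are W_cands·ĝ with
candidates standardised using the *training-population* allele frequencies.

Two properties of this posterior are worth knowing. On a truly null trait,
a null SNP cannot distinguish the point-mass class from the 0.0001·σg²
class (their marginal likelihoods agree to first order), so the reported
zero-class proportion plateaus near 0.5 rather than 1; and per-draw Var(Wg)
contains posterior-uncertainty noise, so it does not shrink to zero on null
data even though the posterior-mean effects predict nothing. The tests
assert the identifiable statements (Var(W·ĝ) ≈ 0; the largest-effect class
stays empty).

## Cross-validated evaluation

Animals of the prediction herd are randomly partitioned into five folds
(breed-agnostic, sizes within one, fixed across all scenarios of a run).
Phenotypes are adjusted once for fixed effects by OLS on the full herd.
Per fold, models are trained on the other four folds and validation GEBVs
are correlated with the adjusted phenotypes; accuracy is the mean fold
correlation divided by √h², with h² taken from the single-GRM 800K CONTROL
REML fit averaged over the five training sets. Bias is the slope of
adjusted phenotype (response) on GEBV (predictor), pooled over validation
folds (per-fold slopes are also reported). The full grid is 3 panels × 9
strategies × 3 methods minus the three confounded MGRM-CONTROL cells = 78
scenario rows; a failing scenario is recorded as a failed row and the grid
continues.

## Numerical and design choices

- Ties at p-value thresholds are inclusive (p ≤ t).
- GWAS strategies take the de-duplicated union of the two cohorts'
  selections.
- The per-variant phenotypic-variance reconstruction in COJO floors the
  joint residual variance at 10⁻⁸·s²y.
- BayesR seeds are derived per fold with CRC32 so that a rerun of the same
  grid is bit-identical.
- `RunConfig` rejects the MGRM × CONTROL combination outright (it is the
  SGRM CONTROL model).
- The GRM centring population is the dataset being analysed; a different
  frequency vector can be passed explicitly (e.g. whole-population
  frequencies inside a CV split, which is what `run_grid` does).

## Known limitations

- The Markov-copying LD model has a single global decay scale and fully
  consistent LD phase across breeds; across-breed LD decay of *phase* — one
  of the hypothesised mechanisms behind BayesR's advantage on real
  multi-breed data — is not modelled. The BayesR edge reproduced here comes
  from the sparse, large-QTL architecture instead.
- Marker-captured heritability at desk scale has a large sampling variance;
  single-seed accuracy comparisons between methods are noisy, which is why
  the benchmark reports means over five replicate studies.
- COJO's summary-statistic algebra assumes the LD reference matches the
  discovery sample; with an external reference its joint effects are
  approximations, as in the original method.
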