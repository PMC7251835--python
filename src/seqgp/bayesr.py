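"""BayesR: SNP effects from a four-component normal mixture, by Gibbs sampling.

Model: ``y = Xb + Wg + e`` with ``W`` the column-standardised genotype matrix
and each SNP effect drawn from one of four normals with variances
``{0, 0.0001, 0.001, 0.01} × σg²``.  The mixture proportions have a
Dirichlet(1,1,1,1) prior, the component indicator of each SNP is sampled by
exact enumeration of the four marginal likelihoods (single-site Gibbs with
residual updating), fixed effects are sampled from their flat-prior full
conditionals inside the chain, σe² from its scaled inverse-χ² full
conditional, and the mixture scale σg² from its full conditional given the
current effects (weakly informative scaled inverse-χ², ν₀ = 4, scale vp/2).

The *reported* genetic variance (``sigma_g2_hat``) is the posterior mean of
Var(Wg) — the variance of the genetic values actually realised in the sample,
which is the quantity comparable to a REML additive variance — rather than
the mixture scale hyperparameter.

Breeding values for unphenotyped candidates are ``GEBV = W_cands · ĝ`` with
``W_cands`` standardised with the *training* allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

MULTIPLIERS = (0.0, 0.0001, 0.001, 0.01)


@dataclass
class BayesRPrior:
    component_variance_multipliers: tuple = MULTIPLIERS
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    chain_length: int = 50_000
    burn_in: int = 20_000
    thinning: int = 10
    fixed_proportions: tuple | None = None  # e.g. (0,0,0,1) collapses to ridge
    sample_scale: bool = True               # sample σg²; False keeps it fixed
    sigma_g2_value: float | None = None     # explicit σg² (used when not sampling)
    scale_df: float = 4.0

    def __post_init__(self):
        if tuple(self.component_variance_multipliers) != MULTIPLIERS:
            raise ValueError(f"component variance multipliers are fixed at {MULTIPLIERS}")
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be ≥ 1")


@dataclass
class BayesRPosterior:
    g_hat: np.ndarray            # posterior-mean SNP effects (standardised scale)
    pr_hat: np.ndarray           # posterior-mean mixture proportions
    sigma_g2_hat: float          # posterior mean Var(Wg)
    sigma_e2_hat: float
    fixed_solutions: np.ndarray
    inclusion_prob: np.ndarray   # per-SNP 1 − P(zero component)
    va_samples: np.ndarray       # kept Var(Wg) draws, for chain diagnostics
    n_samples: int

    @property
    def h2(self) -> float:
        return self.sigma_g2_hat / (self.sigma_g2_hat + self.sigma_e2_hat)

    def ess_sigma_g2(self) -> float:
        return effective_sample_size(self.va_samples)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or x.var() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    s = 0.0
    for t in range(1, n // 2):
        pair = acf[2 * t - 1] + acf[2 * t] if 2 * t < n else acf[2 * t - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def standardize_genotypes(genotypes, variant_ids, freqs=None):
    """Standardised genotype columns (dos − 2p)/√(2p(1−p)); monomorphic dropped.

    Returns ``(W, kept_ids, kept_freqs)``.  Pass the training-population
    frequencies when standardising candidate animals.
    """
    variant_ids = np.asarray(variant_ids)
    cols = genotypes.column_index(variant_ids)
    X = genotypes.dosages[:, cols]
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.all():
        logger.warning("standardize_genotypes: dropping %d monomorphic variants",
                       int((~poly).sum()))
    X, freqs, variant_ids = X[:, poly], freqs[poly], variant_ids[poly]
    W = (X - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    return np.asfortranarray(W), variant_ids, freqs


@njit(fastmath=False)
def _gibbs_kernel(y, X, W, gammas, alpha, n_iter, burn_in, thin, seed,
                  pr_fixed, pr_init, sample_scale, scale_df, scale_s0, sigma_g_init):
    np.random.seed(seed)
    n, m = W.shape
    pfix = X.shape[1]
    wtw = np.empty(m)
    for j in range(m):
        wtw[j] = np.dot(W[:, j], W[:, j])
    xtx = np.empty(pfix)
    for j in range(pfix):
        xtx[j] = np.dot(X[:, j], X[:, j])

    beta = np.zeros(pfix)
    g = np.zeros(m)
    r = y.copy()
    vy = np.var(y)
    sigma_e2 = 0.5 * vy
    sigma_g2 = sigma_g_init  # mixture scale
    pr = pr_init.copy()

    g_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    pr_sum = np.zeros(4)
    beta_sum = np.zeros(pfix)
    ve_sum = 0.0
    n_keep = (n_iter - burn_in + thin - 1) // thin
    va_samples = np.zeros(n_keep)
    kept = 0

    logp = np.empty(4)
    for it in range(n_iter):
        # fixed effects, flat prior
        for j in range(pfix):
            old = beta[j]
            rhs = np.dot(X[:, j], r) + xtx[j] * old
            mean = rhs / xtx[j]
            beta[j] = np.random.normal(mean, np.sqrt(sigma_e2 / xtx[j]))
            diff = old - beta[j]
            for i in range(n):
                r[i] += X[i, j] * diff

        # SNP effects: enumerate the four component likelihoods
        counts = np.zeros(4)
        ssq = 0.0
        nnz = 0
        for j in range(m):
            gj = g[j]
            if gj != 0.0:
                for i in range(n):
                    r[i] += W[i, j] * gj
            rhs = np.dot(W[:, j], r)
            logp[0] = np.log(pr[0]) if pr[0] > 0 else -1e30
            for k in range(1, 4):
                if pr[k] <= 0:
                    logp[k] = -1e30
                    continue
                v = gammas[k] * sigma_g2
                c = v * wtw[j] + sigma_e2
                logp[k] = (np.log(pr[k]) - 0.5 * np.log(c / sigma_e2)
                           + 0.5 * rhs * rhs * v / (sigma_e2 * c))
            mx = logp[0]
            for k in range(1, 4):
                if logp[k] > mx:
                    mx = logp[k]
            tot = 0.0
            for k in range(4):
                logp[k] = np.exp(logp[k] - mx)
                tot += logp[k]
            u = np.random.random() * tot
            acc = 0.0
            comp = 3
            for k in range(4):
                acc += logp[k]
                if u <= acc:
                    comp = k
                    break
            if comp == 0:
                g[j] = 0.0
            else:
                v = gammas[comp] * sigma_g2
                lhs = wtw[j] + sigma_e2 / v
                gj = np.random.normal(rhs / lhs, np.sqrt(sigma_e2 / lhs))
                g[j] = gj
                for i in range(n):
                    r[i] -= W[i, j] * gj
                ssq += gj * gj / gammas[comp]
                nnz += 1
            counts[comp] += 1.0

        if not pr_fixed:
            tot = 0.0
            for k in range(4):
                pr[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
                tot += pr[k]
            for k in range(4):
                pr[k] /= tot

        sse = np.dot(r, r)
        sigma_e2 = sse / np.random.chisquare(n - 2.0)
        if sample_scale:
            sigma_g2 = (ssq + scale_df * scale_s0) / np.random.chisquare(nnz + scale_df)

        if it >= burn_in and (it - burn_in) % thin == 0:
            g_sum += g
            for j in range(m):
                if g[j] != 0.0:
                    incl_sum[j] += 1.0
            pr_sum += counts / m
            beta_sum += beta
            ve_sum += sigma_e2
            # genetic variance realised in the sample: Var(Wg), Wg = y − Xb − r
            mu = 0.0
            for i in range(n):
                xb = 0.0
                for j in range(pfix):
                    xb += X[i, j] * beta[j]
                u = y[i] - xb - r[i]
                va_samples[kept] += u * u
                mu += u
            mu /= n
            va_samples[kept] = va_samples[kept] / (n - 1) - mu * mu * n / (n - 1)
            kept += 1

    return (g_sum / kept, incl_sum / kept, pr_sum / kept, beta_sum / kept,
            ve_sum / kept, va_samples[:kept])


def bayesr_gibbs(y, X, W, prior: BayesRPrior | None = None, seed: int = 0) -> BayesRPosterior:
    """Run the BayesR Gibbs chain; reproducible given ``seed``."""
    if prior is None:
        prior = BayesRPrior()
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.asfortranarray(np.atleast_2d(np.asarray(X, dtype=np.float64)))
    W = np.asfortranarray(np.asarray(W, dtype=np.float64))
    if not (y.size == X.shape[0] == W.shape[0]):
        raise ValueError("y, X and W must have aligned rows")
    pr_fixed = prior.fixed_proportions is not None
    pr_init = (np.asarray(prior.fixed_proportions, float) if pr_fixed
               else np.full(4, 0.25))
    if pr_fixed and not np.isclose(pr_init.sum(), 1.0):
        raise ValueError("fixed_proportions must sum to 1")
    vy = float(np.var(y))
    scale_s0 = 0.5 * vy
    # start the mixture scale where the implied genic variance ≈ vy/2; with the
    # zero component pinned shut this avoids a long burn-in out of an overfit
    # state when m ≫ n
    expected_mult = float(np.asarray(MULTIPLIERS) @ pr_init)
    if prior.sigma_g2_value is not None:
        sigma_g_init = float(prior.sigma_g2_value)
    elif pr_fixed and expected_mult > 0:
        sigma_g_init = 0.5 * vy / (W.shape[1] * expected_mult)
    else:
        sigma_g_init = 0.5 * vy
    g_hat, incl, pr_hat, beta, ve, va_samples = _gibbs_kernel(
        y, X, W, np.asarray(MULTIPLIERS), np.asarray(prior.dirichlet_alpha, float),
        prior.chain_length, prior.burn_in, prior.thinning, seed,
        pr_fixed, pr_init, prior.sample_scale, prior.scale_df, scale_s0, sigma_g_init,
    )
    if not np.isfinite(va_samples).all():
        raise RuntimeError("non-finite residual sum encountered during the chain")
    return BayesRPosterior(
        g_hat=g_hat, pr_hat=pr_hat, sigma_g2_hat=float(va_samples.mean()),
        sigma_e2_hat=float(ve), fixed_solutions=beta, inclusion_prob=incl,
        va_samples=va_samples, n_samples=va_samples.size,
    )


def gebv_candidates(W_cands, g_hat) -> np.ndarray:
    """GEBV = W_cands · ĝ (fixed effects excluded)."""
    W_cands = np.asarray(W_cands, float)
    g_hat = np.asarray(g_hat, float)
    if W_cands.shape[1] != g_hat.size:
        raise ValueError(
            f"candidate matrix has {W_cands.shape[1]} columns but ĝ has {g_hat.size}")
    return W_cands @ g_hat


class BayesRRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style BayesR on raw dosage matrices.

    ``fit(X, y)`` standardises the dosage columns with training allele
    frequencies, runs the Gibbs chain and stores the posterior summaries;
    ``predict(X_new)`` standardises the new animals with the *training*
    frequencies and returns intercept + GEBV.
    """

    def __init__(self, n_iter=50_000, burn_in=20_000, thin=10,
                 fixed_proportions=None, random_state=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.fixed_proportions = fixed_proportions
        self.random_state = random_state

    def _standardize(self, X):
        X = np.asarray(X, float)
        W = (X[:, self._poly_] - 2.0 * self.freqs_) / np.sqrt(
            2.0 * self.freqs_ * (1.0 - self.freqs_))
        return np.asfortranarray(W)

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        p = X.mean(axis=0) / 2.0
        self._poly_ = (p > 0) & (p < 1)
        self.freqs_ = p[self._poly_]
        W = self._standardize(X)
        n = y.size
        design = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), np.asarray(covariates, float)])
        prior = BayesRPrior(chain_length=self.n_iter, burn_in=self.burn_in,
                            thinning=self.thin, fixed_proportions=self.fixed_proportions)
        self.posterior_ = bayesr_gibbs(y, design, W, prior, seed=self.random_state)
        self.g_hat_ = self.posterior_.g_hat
        self.intercept_ = float(self.posterior_.fixed_solutions[0])
        return self

    def predict(self, X):
        return self.intercept_ + gebv_candidates(self._standardize(X), self.g_hat_)
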