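"""GBLUP: REML variance components and genomic breeding values.

The mixed model is ``y = Xb + Σ_c Z a_c + e`` with ``a_c ~ N(0, G_c σ_c²)``
for one (SGRM) or two (MGRM) genomic relationship matrices and
``e ~ N(0, I σ_e²)``.  Variance components are estimated by average-
information REML with a few expectation-maximisation warm-up steps; breeding
values are the conditional expectations

    â_c = σ̂_c² · G_c[all, train] · V⁻¹ (y − X b̂),   V = Σ_c σ̂_c² G_c + σ̂_e² I,

so unphenotyped (validation) animals get predictions through their
relationship rows alone.  In the multi-matrix model the per-component GEBVs
are summed to give the total GEBV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .grm import GRM

logger = logging.getLogger(__name__)

_CLAMP = 1e-8  # relative floor for variance components at the boundary


@dataclass
class VarianceComponents:
    vp: float
    components: list          # [(label, variance), ...] genetic terms only
    ve: float
    h2_per_component: list
    h2_total: float
    loglik: float
    converged: bool
    iterations: int

    def component(self, label: str) -> float:
        return dict(self.components)[label]


@dataclass
class GblupFit:
    varcomp: VarianceComponents
    fixed_solutions: np.ndarray
    individual_ids: list
    gebv: dict                # label -> GEBV vector over all individuals
    total_gebv: np.ndarray


def _as_matrix(g) -> np.ndarray:
    return g.values if isinstance(g, GRM) else np.asarray(g, dtype=float)


def restricted_loglik(y, X, grms, variances) -> float:
    """Restricted log-likelihood at the given component values.

    ``variances`` lists the genetic components in ``grms`` order followed by
    the residual variance.  Exposed mainly for diagnostics and validation.
    """
    y = np.asarray(y, float)
    n = y.size
    Ks = [_as_matrix(g) for g in grms] + [np.eye(n)]
    V = sum(s * K for s, K in zip(variances, Ks))
    c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vinv_X = linalg.cho_solve((c, low), X)
    Vinv_y = linalg.cho_solve((c, low), y)
    XtVX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    r = y - X @ beta
    quad = r @ linalg.cho_solve((c, low), r)
    return -0.5 * (logdet_v + logdet_x + quad)


def reml(y, X, grms, labels=None, max_iter=200, tol=1e-8, n_em=3) -> VarianceComponents:
    """AI-REML for 1–2 GRMs plus a residual; variances clamped at ≥ 0.

    Starts each genetic component at vp/(2·c) and the residual at vp/2,
    runs ``n_em`` expectation-maximisation fixed-point steps, then switches
    to average-information updates with step halving.  Convergence is
    declared when the restricted log-likelihood moves by less than ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("y and X have different numbers of rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design X is rank deficient")
    mats = [_as_matrix(g) for g in grms]
    if not 1 <= len(mats) <= 2:
        raise ValueError("reml supports one or two GRMs")
    if labels is None:
        labels = [f"g{i+1}" for i in range(len(mats))]

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    vp = float(np.var(y - X @ beta_ols, ddof=X.shape[1]))
    if vp <= 0:
        raise ValueError("phenotype has no residual variance")
    c = len(mats)
    s = np.array([vp / (2 * c)] * c + [vp / 2.0])
    Ks = mats + [np.eye(n)]
    floor = _CLAMP * vp

    def evaluate(svec):
        V = sum(si * K for si, K in zip(svec, Ks))
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return None
        Vinv = linalg.cho_solve(cf, np.eye(n))
        VinvX = Vinv @ X
        XtVX = X.T @ VinvX
        C = np.linalg.inv(XtVX)
        P = Vinv - VinvX @ C @ VinvX.T
        Py = P @ y
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        _, logdet_x = np.linalg.slogdet(XtVX)
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        return ll, P, Py

    state = evaluate(s)
    if state is None:
        # numerically non-PSD relationship matrix: jitter the diagonal once
        logger.warning("reml: V not positive definite at start; adding 1e-6 jitter to GRMs")
        Ks = [K + 1e-6 * np.eye(n) for K in mats] + [np.eye(n)]
        state = evaluate(s)
    if state is None:
        raise ValueError("non-finite likelihood at starting values")

    def optimize(s, state):
        ll, P, Py = state
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            q = [K @ Py for K in Ks]
            trPK = np.array([np.sum(P * K) for K in Ks])
            ytPKPy = np.array([Py @ qi for qi in q])
            dL = -0.5 * (trPK - ytPKPy)

            if it <= n_em:
                s_new = np.maximum(s * ytPKPy / np.maximum(trPK, 1e-12), floor)
            else:
                AI = 0.5 * np.array([[qi @ P @ qj for qj in q] for qi in q])
                if np.linalg.cond(AI) > 1e10:
                    logger.warning("reml: average-information matrix singular; "
                                   "variance components not separately identifiable")
                    delta = np.linalg.pinv(AI) @ dL
                else:
                    delta = np.linalg.solve(AI, dL)
                s_new = np.maximum(s + delta, floor)

            new_state = evaluate(s_new)
            halvings = 0
            while (new_state is None or new_state[0] < ll - 1e-10) and halvings < 12:
                s_new = np.maximum(s + 0.5 ** (halvings + 1) * (s_new - s), floor)
                new_state = evaluate(s_new)
                halvings += 1
            if new_state is None:
                raise ValueError(f"non-finite likelihood at iteration {it}; trace: s={s}")
            ll_new, P, Py = new_state
            delta_ll = ll_new - ll
            s, ll = s_new, ll_new
            if it > n_em and abs(delta_ll) < tol:
                converged = True
                break
        return s, ll, it, converged

    s, ll, it, converged = optimize(s, state)

    # the restricted likelihood can be multimodal on small data: if the
    # near-null boundary beats the converged interior point, restart there
    s_null = np.array([floor] * c + [vp])
    null_state = evaluate(s_null)
    if null_state is not None and null_state[0] > ll + 1e-6:
        s2, ll2, it2, conv2 = optimize(s_null, null_state)
        if ll2 > ll:
            s, ll, it, converged = s2, ll2, it + it2, conv2

    comps = list(zip(labels, [float(v) for v in s[:-1]]))
    ve = float(s[-1])
    total = float(s.sum())
    h2 = [v / total for _, v in comps]
    return VarianceComponents(
        vp=total, components=comps, ve=ve, h2_per_component=h2,
        h2_total=float(sum(h2)), loglik=float(ll), converged=converged, iterations=it,
    )


def blup_gebv(varcomp: VarianceComponents, grms, y, X, train_idx, individual_ids=None) -> GblupFit:
    """BLUP breeding values for all animals from a fitted variance model.

    ``train_idx`` indexes the phenotyped rows within the GRM ordering; ``y``
    and ``X`` cover the training animals only (in ``train_idx`` order).
    """
    mats = [_as_matrix(g) for g in grms]
    n_all = mats[0].shape[0]
    train_idx = np.asarray(train_idx)
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    svec = [v for _, v in varcomp.components]

    V = sum(s * K[np.ix_(train_idx, train_idx)] for s, K in zip(svec, mats))
    V = V + varcomp.ve * np.eye(train_idx.size)
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        logger.warning("blup_gebv: V singular; retrying with 1e-6·vp jitter")
        V = V + 1e-6 * varcomp.vp * np.eye(train_idx.size)
        cf = linalg.cho_factor(V, lower=True)

    VinvX = linalg.cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ VinvX, X.T @ linalg.cho_solve(cf, y))
    alpha = linalg.cho_solve(cf, y - X @ beta)

    gebv = {}
    for (label, s), K in zip(varcomp.components, mats):
        gebv[label] = s * (K[:, train_idx] @ alpha)
    total = np.sum(list(gebv.values()), axis=0)
    if individual_ids is None:
        individual_ids = list(range(n_all))
    return GblupFit(varcomp, beta, list(individual_ids), gebv, total)


class GBLUPRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style GBLUP on precomputed genomic relationship kernels.

    ``fit(K, y)`` takes the training-by-training kernel (one matrix, or a
    list of matrices for the multi-GRM model) and ``predict(K_new)`` the
    new-by-training kernel(s).  Fixed effects beyond the intercept are passed
    as ``covariates=`` to ``fit``; predictions are GEBVs plus the intercept.
    """

    def __init__(self, max_iter=200, tol=1e-8):
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _klist(K):
        return [np.asarray(k, float) for k in (K if isinstance(K, (list, tuple)) else [K])]

    def fit(self, K, y, covariates=None):
        mats = self._klist(K)
        y = np.asarray(y, float)
        n = y.size
        X = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), np.asarray(covariates, float)])
        self.varcomp_ = reml(y, X, mats, max_iter=self.max_iter, tol=self.tol)
        fit = blup_gebv(self.varcomp_, mats, y, X, np.arange(n))
        self.alpha_ = linalg.cho_solve(
            linalg.cho_factor(
                sum(s * m for (_, s), m in zip(self.varcomp_.components, mats))
                + self.varcomp_.ve * np.eye(n), lower=True),
            y - X @ fit.fixed_solutions)
        self.beta_ = fit.fixed_solutions
        self.train_gebv_ = fit.total_gebv
        self.n_train_ = n
        return self

    def predict(self, K_new):
        mats = self._klist(K_new)
        gebv = np.zeros(mats[0].shape[0])
        for (label, s), K in zip(self.varcomp_.components, mats):
            gebv += s * (K @ self.alpha_)
        return self.beta_[0] + gebv
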