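"""Weighted GLM on pseudo-values with log(-log) link.

The response stacks the n direct 0->2 pseudo-values (weight 1, group
indicator 0) and the m composite 0->1->2 pseudo-values (IPCW weight gamma_i,
group indicator 1); a subject with an observed transition therefore
contributes one row to each group.  The mean model is

    E[V] = exp(-exp(beta0 + beta1 * x)),

i.e. linear on the cloglog scale g(S) = log(-log S), so exp(beta1) is the
ratio of cumulative hazards at t* between the two groups (cHR < 1 means
higher survival with a donor).  The working model is a homoscedastic normal
response; all inference uses the sandwich (HC0) covariance with the analysis
weights treated as fixed frequency-type weights.  On this saturated design
the estimating equations are solved exactly by the weighted group means:
beta0 = g(V0_bar), beta1 = g(V1_bar) - g(V0_bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .ipcw import WeightTable, compute_weights, fit_observability_curve
from .pseudo import (
    composite012_pseudo_values,
    conditional12_pseudo_values,
    direct02_pseudo_values,
    impute_composite012,
)

__all__ = ["GLMFit", "FitResult", "assemble_design", "fit_cloglog_glm",
           "analyze", "cloglog"]

IRLS_TOL = 1e-8
IRLS_MAXIT = 100


def cloglog(s):
    """g(S) = log(-log S), the link mapping survival to log cumulative hazard."""
    return np.log(-np.log(s))


@dataclass
class GLMFit:
    """Solution of the weighted estimating equations plus sandwich covariance."""

    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class FitResult:
    """Two-group analysis result on the cloglog scale and derived quantities."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    s0_hat: float
    s1_hat: float
    chr: float
    ci_chr: tuple
    wald_p: float
    n_response: int
    converged: bool
    n_iter: int
    grouping: str = "exact-waiting-time"
    imputations: int = 0
    v0_bar: float = np.nan
    v1_bar: float = np.nan
    se_uncorrected: tuple = field(default=(np.nan, np.nan))

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0, "beta1": self.beta1,
            "se_beta0": self.se_beta0, "se_beta1": self.se_beta1,
            "s0_hat": self.s0_hat, "s1_hat": self.s1_hat,
            "chr": self.chr, "ci_chr_lower": self.ci_chr[0],
            "ci_chr_upper": self.ci_chr[1], "wald_p": self.wald_p,
            "n_response": self.n_response, "converged": self.converged,
            "grouping": self.grouping, "imputations": self.imputations,
        }


def assemble_design(direct02: pd.DataFrame, composite: pd.DataFrame,
                    weights: WeightTable | None):
    """Stack the (n+m)-row response, group indicator and weight vectors.

    Returns ``(y, X, w)`` with X = [1, x1], x1 = 0 for the n direct rows and
    1 for the m composite rows; direct-row weights are 1, composite-row
    weights are gamma_i.  With no transition subjects the design degenerates
    to intercept-only.
    """
    y0 = direct02["value"].to_numpy(dtype=float)
    n = len(y0)
    if composite is None or len(composite) == 0:
        y = y0
        X = np.ones((n, 1))
        w = np.ones(n)
        return y, X, w
    y1 = composite["value"].to_numpy(dtype=float)
    m = len(y1)
    if weights is not None:
        if weights.m != m:
            raise ValueError("weight table and composite table length mismatch")
        gam = weights.gamma
    else:
        gam = np.ones(m)
    y = np.concatenate([y0, y1])
    X = np.column_stack([np.ones(n + m),
                         np.concatenate([np.zeros(n), np.ones(m)])])
    w = np.concatenate([np.ones(n), gam])
    return y, X, w


def fit_cloglog_glm(y, X, w=None) -> GLMFit:
    """IRLS for the weighted estimating equations sum w_i (y_i - mu_i) mu'_i x_i = 0.

    mu = exp(-exp(eta)), identity working variance.  The covariance is the
    HC0 sandwich B^{-1} M B^{-1} with B = X' diag(w mu'^2) X and
    M = X' diag(w^2 mu'^2 (y-mu)^2) X, weights fixed.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)

    # initial values: common intercept at the cloglog of the clipped overall
    # weighted mean (clipping is for initialisation only, never for the fit)
    ybar = np.clip(np.sum(w * y) / np.sum(w), 1e-6, 1 - 1e-6)
    beta = np.zeros(p)
    beta[0] = cloglog(ybar)

    def _score(b):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            eeta = np.exp(X @ b)
            mu = np.exp(-eeta)
            dmu = np.where(np.isfinite(eeta), -eeta * mu, 0.0)  # d mu / d eta
            return mu, dmu, X.T @ (w * dmu * (y - mu))

    converged = False
    it = 0
    mu, dmu, U = _score(beta)
    for it in range(1, IRLS_MAXIT + 1):
        B = X.T @ (X * (w * dmu**2)[:, None])
        try:
            step = np.linalg.solve(B, U)
        except np.linalg.LinAlgError:
            return GLMFit(beta, np.full((p, p), np.nan), False, it,
                          "singular information matrix "
                          "(group mean outside (0,1)?)")
        if not np.all(np.isfinite(step)):
            return GLMFit(beta, np.full((p, p), np.nan), False, it,
                          "non-finite IRLS step (group mean outside (0,1)?)")
        # damped Newton: halve the step until the estimating function shrinks
        unorm = np.linalg.norm(U)
        for _ in range(30):
            cand = beta + step
            mu_c, dmu_c, U_c = _score(cand)
            if np.all(np.isfinite(U_c)) and np.linalg.norm(U_c) <= unorm:
                break
            step = step / 2
        else:
            return GLMFit(beta, np.full((p, p), np.nan), False, it,
                          "IRLS step halving failed (group mean outside (0,1)?)")
        beta, mu, dmu, U = cand, mu_c, dmu_c, U_c
        if np.max(np.abs(step)) < IRLS_TOL:
            converged = True
            break

    eta = X @ beta
    mu = np.exp(-np.exp(eta))
    dmu = -np.exp(eta) * mu
    B = X.T @ (X * (w * dmu**2)[:, None])
    resid = w * dmu * (y - mu)   # resid^2 = w^2 dmu^2 (y-mu)^2, the HC0 meat
    M = (X * resid[:, None]).T @ (X * resid[:, None])
    try:
        Binv = np.linalg.inv(B)
        cov = Binv @ M @ Binv
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    msg = "" if converged else "IRLS did not converge"
    return GLMFit(beta, cov, converged, it, msg)


def analyze(df: pd.DataFrame, config: AnalysisConfig) -> FitResult:
    """Full single-dataset pipeline: pseudo-values -> IPCW -> weighted GLM.

    Point estimates come from the non-imputed fit; standard errors are the
    mean sandwich SEs over ``config.imputations`` refits in which the shared
    Kaplan-Meier factor S0_hat(w_i) is replaced by Bernoulli draws.
    """
    from .io import validate_subjects

    df = validate_subjects(df, t_search=config.t_search)
    t_star = config.t_star

    direct_tab, direct_curve = direct02_pseudo_values(df, t_star)
    cond = conditional12_pseudo_values(df, t_star, grouping=config.grouping)
    m = len(cond)

    if m == 0:
        y, X, w = assemble_design(direct_tab, None, None)
        fit = fit_cloglog_glm(y, X, w)
        b0 = float(fit.beta[0])
        return FitResult(
            beta0=b0, beta1=np.nan, se_beta0=float(fit.se[0]),
            se_beta1=np.nan, s0_hat=float(np.exp(-np.exp(b0))),
            s1_hat=np.nan, chr=np.nan, ci_chr=(np.nan, np.nan),
            wald_p=np.nan, n_response=len(y), converged=fit.converged,
            n_iter=fit.n_iter, grouping=config.grouping, imputations=0,
            v0_bar=float(np.mean(y)),
        )

    comp = composite012_pseudo_values(direct_curve, cond)
    g_curve = fit_observability_curve(df)
    weights = compute_weights(g_curve, df)

    y, X, w = assemble_design(direct_tab, comp, weights)
    fit = fit_cloglog_glm(y, X, w)
    se0, se1 = float(fit.se[0]), float(fit.se[1])
    se0_unc, se1_unc = se0, se1

    if config.imputations >= 1:
        rng = np.random.default_rng(config.seed)
        ses = []
        for _ in range(config.imputations):
            comp_imp = impute_composite012(direct_curve, cond, rng)
            yi, Xi, wi = assemble_design(direct_tab, comp_imp, weights)
            fit_i = fit_cloglog_glm(yi, Xi, wi)
            if fit_i.converged:
                ses.append(fit_i.se)
        if ses:
            se0, se1 = np.mean(ses, axis=0)

    b0, b1 = float(fit.beta[0]), float(fit.beta[1])
    z = stats.norm.ppf(0.5 + config.level / 2)
    ci = (float(np.exp(b1 - z * se1)), float(np.exp(b1 + z * se1)))
    wald_p = float(2 * stats.norm.sf(abs(b1) / se1)) if se1 > 0 else np.nan
    n = len(direct_tab)
    v0_bar = float(np.mean(y[:n]))
    v1_bar = float(np.mean(w[n:] * y[n:]))
    return FitResult(
        beta0=b0, beta1=b1, se_beta0=float(se0), se_beta1=float(se1),
        s0_hat=float(np.exp(-np.exp(b0))),
        s1_hat=float(np.exp(-np.exp(b0 + b1))),
        chr=float(np.exp(b1)), ci_chr=ci, wald_p=wald_p,
        n_response=len(y), converged=fit.converged, n_iter=fit.n_iter,
        grouping=config.grouping, imputations=config.imputations,
        v0_bar=v0_bar, v1_bar=v1_bar,
        se_uncorrected=(se0_unc, se1_unc),
    )
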