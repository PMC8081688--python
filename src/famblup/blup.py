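"""REML variance components and BLUP over an arbitrary relationship kernel.

The core model is ``y = X b + g + e`` with ``g ~ N(0, K sigma2_g)`` for a
relationship matrix K (pedigree A, genomic G, blended G_mod or single-step
H) and ``e ~ N(0, I sigma2_e)``.  The single-residual REML profiles the
likelihood over the variance ratio ``lambda = sigma2_e / sigma2_g`` using
one eigendecomposition of the observed kernel block -- a robust,
derivative-free scheme that is exact for this model class.  The two-group
extension with heterogeneous residual variances is fitted by Nelder-Mead on
log-variances with a dense-Cholesky restricted likelihood.

Random effects for lines without phenotypes are obtained by the conditional
expectation ``g_u = K_uo (K_oo + lambda I)^-1 (y - X b)``, which is
algebraically identical to solving the mixed-model equations with the
missing rows included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship import RelationshipMatrix

__all__ = [
    "BlupFit",
    "fit_single_kernel",
    "fit_trait_assisted",
    "fit_group_model",
    "heritability_from_fit",
    "gebv",
]

_VAR_FLOOR_REL = 1e-10
_LOGLAM_LO, _LOGLAM_HI = -8.0, 8.0


@dataclass
class BlupFit:
    """Fitted variance components, fixed effects and predicted line effects."""

    sigma2_g: float
    sigma2_e: float | dict
    mu: float
    g: pd.Series  # predicted random effect for every kernel id
    loglik: float
    gamma: float | None = None
    group_effects: dict | None = None
    converged: bool = True
    degenerate: bool = False

    @property
    def lam(self) -> float:
        """Residual-to-genetic variance ratio (homogeneous residual only)."""
        if isinstance(self.sigma2_e, dict):
            raise ValueError("lambda undefined for heterogeneous residuals")
        return self.sigma2_e / self.sigma2_g


def _check_kernel(k: np.ndarray) -> np.ndarray:
    """Eigendecompose and validate a kernel; negative eigenvalues beyond
    numerical noise mean the kernel is indefinite."""
    d, u = np.linalg.eigh((k + k.T) / 2.0)
    tol = 1e-6 * max(abs(d[-1]), 1.0)
    if d[0] < -tol:
        raise ValueError(
            "kernel is not positive (semi)definite; blend it with the "
            "identity (e.g. 0.5*K + 0.5*I) before fitting"
        )
    return np.clip(d, 0.0, None), u


def _profile_reml(y: np.ndarray, x: np.ndarray, k: np.ndarray):
    """Profile REML over log(lambda) using the eigenbasis of the kernel.

    Returns (sigma2_g, sigma2_e, beta, loglik, solve) where ``solve(v)``
    applies (K + lambda*I)^-1 at the optimum.
    """
    n, p = x.shape
    if n - p < 1:
        raise ValueError("not enough observations for the fixed effects")
    d, u = _check_kernel(k)
    yt = u.T @ y
    xt = u.T @ x

    def crit(loglam: float):
        w = d + 10.0 ** loglam
        xw = xt / w[:, None]
        xtwx = xt.T @ xw
        beta = np.linalg.solve(xtwx, xw.T @ yt)
        r = yt - xt @ beta
        quad = float(r @ (r / w))
        quad = max(quad, 1e-300)
        s2g = quad / (n - p)
        ll = -0.5 * (
            (n - p) * (np.log(s2g) + 1.0)
            + float(np.sum(np.log(w)))
            + float(np.linalg.slogdet(xtwx)[1])
        )
        return ll, s2g, beta

    grid = np.linspace(_LOGLAM_LO, _LOGLAM_HI, 65)
    lls = np.array([crit(g)[0] for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -crit(t)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    loglam = float(res.x)
    ll, s2g, beta = crit(loglam)
    lam = 10.0 ** loglam
    floor = _VAR_FLOOR_REL * max(float(np.var(y)), 1e-12)
    s2g = max(s2g, floor)
    s2e = lam * s2g

    def solve(v: np.ndarray) -> np.ndarray:
        return u @ ((u.T @ v) / (d + lam))

    return s2g, s2e, beta, float(ll), lam, solve


def _align(y: pd.Series, kernel: RelationshipMatrix):
    y = pd.Series(y, dtype=float)
    ids = list(y.index)
    missing = [i for i in ids if i not in set(kernel.ids)]
    if missing:
        raise ValueError(f"response ids absent from kernel: {missing[:5]}")
    return y, ids


def fit_single_kernel(y: pd.Series, kernel: RelationshipMatrix) -> BlupFit:
    """Fit ``y = mu + g + e`` with ``g ~ N(0, K sigma2_g)`` by REML.

    ``y`` is indexed by line id; predictions ``g`` are returned for every id
    in the kernel, observed or not.
    """
    y, obs = _align(y, kernel)
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    yv = y.to_numpy()
    x = np.ones((len(obs), 1))
    k_oo = kernel.loc(obs, obs)
    degenerate = float(np.var(yv)) < 1e-12 * max(1.0, abs(float(np.mean(yv))))
    s2g, s2e, beta, ll, lam, solve = _profile_reml(yv, x, k_oo)
    mu = float(beta[0])
    resid = yv - mu
    alpha = solve(resid)  # (K_oo + lambda I)^-1 (y - mu)
    g_all = kernel.loc(kernel.ids, obs) @ alpha
    return BlupFit(
        sigma2_g=s2g,
        sigma2_e=s2e,
        mu=mu,
        g=pd.Series(g_all, index=kernel.ids),
        loglik=ll,
        degenerate=degenerate,
    )


def fit_trait_assisted(
    y: pd.Series, covariate_x: pd.Series, kernel: RelationshipMatrix
) -> BlupFit:
    """Fit ``y = mu + gamma*x + g + e``: a secondary trait (or a
    pre-existing record of the trait itself) enters as a fixed regression."""
    y, obs = _align(y, kernel)
    x_obs = pd.Series(covariate_x, dtype=float).reindex(obs)
    if x_obs.isna().any():
        missing = x_obs.index[x_obs.isna()][0]
        raise ValueError(f"covariate missing for observed id {missing!r}")
    if float(x_obs.var(ddof=1)) < 1e-14:
        raise ValueError("constant covariate: regression coefficient inestimable")
    if len(obs) < 4:
        raise ValueError("need at least 4 observations")
    yv = y.to_numpy()
    x = np.column_stack([np.ones(len(obs)), x_obs.to_numpy()])
    k_oo = kernel.loc(obs, obs)
    s2g, s2e, beta, ll, lam, solve = _profile_reml(yv, x, k_oo)
    resid = yv - x @ beta
    alpha = solve(resid)
    g_all = kernel.loc(kernel.ids, obs) @ alpha
    return BlupFit(
        sigma2_g=s2g,
        sigma2_e=s2e,
        mu=float(beta[0]),
        gamma=float(beta[1]),
        g=pd.Series(g_all, index=kernel.ids),
        loglik=ll,
    )


def _dense_reml(y, x, v):
    """Restricted log-likelihood, GLS fixed effects and V^-1 r for a dense
    covariance V."""
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi_y = np.linalg.solve(c.T, np.linalg.solve(c, y))
    vi_x = np.linalg.solve(c.T, np.linalg.solve(c, x))
    xtvx = x.T @ vi_x
    beta = np.linalg.solve(xtvx, x.T @ vi_y)
    r = y - x @ beta
    vi_r = np.linalg.solve(c.T, np.linalg.solve(c, r))
    ll = -0.5 * (
        logdet_v + float(np.linalg.slogdet(xtvx)[1]) + float(r @ vi_r)
    )
    return ll, beta, vi_r


def fit_group_model(
    y: pd.Series,
    groups: pd.Series,
    kernel: RelationshipMatrix,
    heterogeneous: bool = True,
) -> BlupFit:
    """Fit ``y = mu + s_h + g + e`` with a fixed two-level group contrast.

    Used to pool training records with pre-existing records of selection
    candidates: the group effect absorbs the level difference between the
    two data sources, and with ``heterogeneous=True`` each group gets its
    own residual variance to reflect its phenotyping quality.
    """
    y, obs = _align(y, kernel)
    grp = pd.Series(groups).reindex(obs)
    if grp.isna().any():
        raise ValueError("group label missing for an observed id")
    levels = list(pd.unique(grp))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    counts = grp.value_counts()
    if heterogeneous and counts.min() < 2:
        raise ValueError("heterogeneous residuals need >= 2 records per group")
    yv = y.to_numpy()
    ind2 = (grp == levels[1]).to_numpy().astype(float)
    x = np.column_stack([np.ones(len(obs)), ind2])
    k_oo = kernel.loc(obs, obs)
    _check_kernel(k_oo)

    if not heterogeneous:
        s2g, s2e, beta, ll, lam, solve = _profile_reml(yv, x, k_oo)
        resid = yv - x @ beta
        alpha = solve(resid)
        g_all = kernel.loc(kernel.ids, obs) @ alpha
        return BlupFit(
            sigma2_g=s2g, sigma2_e=s2e, mu=float(beta[0]),
            g=pd.Series(g_all, index=kernel.ids), loglik=ll,
            group_effects={levels[0]: 0.0, levels[1]: float(beta[1])},
        )

    # initialize from the homogeneous fit
    s2g0, s2e0, *_ = _profile_reml(yv, x, k_oo)
    v_y = max(float(np.var(yv)), 1e-8)
    x0 = np.log(np.maximum([s2g0, s2e0, s2e0], 1e-8 * v_y))
    masks = [(grp == lv).to_numpy() for lv in levels]

    def negll(theta):
        s2g, se1, se2 = np.exp(theta)
        v = s2g * k_oo + np.diag(se1 * masks[0] + se2 * masks[1])
        out = _dense_reml(yv, x, v)
        if out is None:
            return 1e12
        return -out[0]

    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000},
    )
    s2g, se1, se2 = np.exp(res.x)
    v = s2g * k_oo + np.diag(se1 * masks[0] + se2 * masks[1])
    ll, beta, vi_r = _dense_reml(yv, x, v)
    g_all = s2g * (kernel.loc(kernel.ids, obs) @ vi_r)
    return BlupFit(
        sigma2_g=float(s2g),
        sigma2_e={levels[0]: float(se1), levels[1]: float(se2)},
        mu=float(beta[0]),
        g=pd.Series(g_all, index=kernel.ids),
        loglik=float(ll),
        group_effects={levels[0]: 0.0, levels[1]: float(beta[1])},
        converged=bool(res.success),
    )


def heritability_from_fit(fit: BlupFit, phenotypes: pd.Series) -> float:
    """Entry-mean heritability ``(sigma2_P - sigma2_e) / sigma2_P`` where
    sigma2_P is the unbiased sample variance of the phenotypes."""
    if isinstance(fit.sigma2_e, dict):
        raise ValueError("heritability needs a homogeneous-residual fit")
    s2p = float(pd.Series(phenotypes, dtype=float).var(ddof=1))
    if not np.isfinite(s2p) or s2p <= 0:
        raise ValueError("zero phenotypic variance")
    h2 = (s2p - fit.sigma2_e) / s2p
    if h2 < 0 or h2 > 1:
        warnings.warn(f"heritability {h2:.3f} outside [0, 1]; clipping")
    return float(np.clip(h2, 0.0, 1.0))


def gebv(fit: BlupFit, x: pd.Series | None = None, ids=None) -> pd.Series:
    """Estimated breeding values ``mu + gamma*x + g`` for the requested ids
    (default: all kernel ids).  ``x`` is required when the fit includes a
    covariate and must cover every requested id."""
    ids = list(ids) if ids is not None else list(fit.g.index)
    out = fit.mu + fit.g.reindex(ids)
    if fit.gamma is not None:
        if x is None:
            raise ValueError("fit has a covariate: supply x")
        xs = pd.Series(x, dtype=float).reindex(ids)
        if xs.isna().any():
            raise ValueError("covariate missing for a requested id")
        out = out + fit.gamma * xs
    return out
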