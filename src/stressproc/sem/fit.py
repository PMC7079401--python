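"""Maximum-likelihood estimation of a RAM model.

The fitter minimizes the normal-theory discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

by quasi-Newton (BFGS) iteration with an analytic gradient, from
documented start values (free loadings 0.5, structural paths 0, variances
at half the sample variances, free exogenous covariances at half the
sample covariances).  Standard errors come from the inverse of the
numerically differentiated information matrix of (n-1)/2 * F_ML; the test
of exact fit is chi2_ML = (n-1) * F_ML at the optimum.

Heywood cases (negative estimated residual variances) are reported via
``SemFit.heywood``, not constrained away; ``fit_ml(..., bounded=True)``
retries with non-negativity bounds on variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spec import SemSpec, implied_covariance_full

__all__ = ["SemFit", "ml_discrepancy", "fit_ml", "standardize", "delta_matrix"]

_CONV_F_TOL = 1e-9
_CONV_G_TOL = 1e-6


def ml_discrepancy(s_sample: np.ndarray, sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between two SPD matrices.

    Non-negative, zero iff the matrices coincide.  Raises when either
    matrix is not symmetric positive-definite.
    """
    s = np.asarray(s_sample, dtype=float)
    g = np.asarray(sigma, dtype=float)
    if s.shape != g.shape or s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("matrices must be square and of equal order")
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    sign_g, logdet_g = np.linalg.slogdet(g)
    if sign_s <= 0 or sign_g <= 0:
        raise ValueError("matrices must be positive-definite")
    return float(logdet_g + np.trace(np.linalg.solve(g, s)) - logdet_s - p)


def _discrepancy_and_grad(
    spec: SemSpec, theta: np.ndarray, s_sample: np.ndarray, logdet_s: float
) -> tuple[float, np.ndarray]:
    """F_ML and its analytic gradient at theta (inf for inadmissible Sigma)."""
    a, s = spec.matrices(theta)
    m = a.shape[0]
    p = spec.n_observed
    try:
        minv = np.linalg.inv(np.eye(m) - a)
    except np.linalg.LinAlgError:
        return math.inf, np.zeros(spec.n_free)
    v = minv @ s @ minv.T
    sigma = (v[:p, :p] + v[:p, :p].T) / 2.0
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return math.inf, np.zeros(spec.n_free)
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + float((sigma_inv * s_sample).sum()) - logdet_s - p
    # G = d F / d Sigma (observed block), embedded in the full ordering
    g_obs = sigma_inv - sigma_inv @ s_sample @ sigma_inv
    grad = np.zeros(spec.n_free)
    # path parameters: dV = M E_ij V + (M E_ij V)^T with M E_ij V = outer(M[:,i], V[j,:])
    gv = g_obs  # p x p
    for i, j, k in spec.a_free:
        u = minv[:p, i]
        w = v[j, :p]
        grad[k] += 2.0 * float(u @ gv @ w)
    # (co)variance parameters: dV = outer(M[:,i], M[:,j]) (+ transpose if i != j)
    for i, j, k in spec.s_free:
        u = minv[:p, i]
        w = minv[:p, j]
        val = float(u @ gv @ w)
        grad[k] += 2.0 * val if i != j else val
    return f, grad


def _start_values(spec: SemSpec, s_sample: np.ndarray) -> np.ndarray:
    theta = np.zeros(spec.n_free)
    p = spec.n_observed
    var = np.diag(s_sample)
    # latent scale proxies: sample variance of each latent's first indicator
    first_ind: dict[int, float] = {}
    for lat in spec.latents:
        li = spec.index(lat)
        col = spec.a_fixed[:, li]
        rows = [i for i in np.nonzero(col)[0] if i < p]
        rows += [i for i, j, _ in spec.a_free if j == li and i < p]
        first_ind[li] = var[min(rows)] if rows else 1.0
    for i, j, k in spec.a_free:
        label = spec.parameter_labels[k]
        theta[k] = 0.5 if "=~" in label else 0.0
    for i, j, k in spec.s_free:
        if i == j:
            base = var[i] if i < p else first_ind.get(i, 1.0)
            theta[k] = 0.5 * base
        else:
            si = s_sample[i, j] if (i < p and j < p) else 0.0
            theta[k] = 0.5 * si
    return theta


@dataclass
class SemFit:
    """A fitted covariance-structure model."""

    spec: SemSpec
    n: int
    s_sample: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    cov_theta: np.ndarray
    sigma: np.ndarray
    f_ml: float
    chi2_ml: float
    df: int
    converged: bool
    heywood: tuple[str, ...] = ()
    chi2_sb: float | None = None
    scaling_c: float | None = None
    indices: dict[str, float] = field(default_factory=dict)
    data: pd.DataFrame | None = None

    @property
    def p_value_ml(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2_ml, self.df))

    @property
    def p_value_sb(self) -> float | None:
        if self.chi2_sb is None or self.df == 0:
            return None
        return float(stats.chi2.sf(self.chi2_sb, self.df))

    def estimates(self) -> pd.DataFrame:
        z = np.divide(self.theta, self.se, out=np.full_like(self.theta, np.nan),
                      where=self.se > 0)
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=list(self.spec.parameter_labels),
        )

    def standardized(self) -> pd.Series:
        return standardize(self)

    def r2(self) -> pd.Series:
        """Proportion of variance explained per endogenous variable."""
        from .spec import implied_covariance_full

        v = implied_covariance_full(self.spec, self.theta)
        a, s = self.spec.matrices(self.theta)
        out = {}
        endo = {i for i, _, _ in self.spec.a_free} | {
            int(i) for i, j in zip(*np.nonzero(self.spec.a_fixed))
        }
        for i in sorted(endo):
            if v[i, i] > 0:
                out[self.spec.variables[i]] = 1.0 - s[i, i] / v[i, i]
        return pd.Series(out, dtype=float)


def _sample_cov(data: pd.DataFrame, spec: SemSpec) -> tuple[np.ndarray, int]:
    missing = [v for v in spec.observed if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks observed variables {missing}")
    x = data[list(spec.observed)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values: complete-case data required")
    n = x.shape[0]
    if n <= spec.n_observed:
        raise ValueError("need n > number of observed variables")
    return np.cov(x, rowvar=False, ddof=1), n


def fit_ml(
    spec: SemSpec,
    data: pd.DataFrame | None = None,
    *,
    s_sample: np.ndarray | None = None,
    n: int | None = None,
    theta0: np.ndarray | None = None,
    bounded: bool = False,
    compute_se: bool = True,
) -> SemFit:
    """Fit a RAM model by maximum likelihood.

    Either a complete-case ``data`` table covering all observed variables
    or a sample covariance ``s_sample`` with sample size ``n`` must be
    given.  ``bounded=True`` constrains free variances to be non-negative
    (a retry facility for Heywood cases).
    """
    if data is not None:
        s_samp, n_obs = _sample_cov(data, spec)
    else:
        if s_sample is None or n is None:
            raise ValueError("need data or (s_sample, n)")
        s_samp, n_obs = np.asarray(s_sample, dtype=float), int(n)
    spec.validate()
    sign, logdet_s = np.linalg.slogdet(s_samp)
    if sign <= 0:
        raise ValueError("sample covariance is not positive-definite")
    theta0 = _start_values(spec, s_samp) if theta0 is None else np.asarray(theta0, float)

    fun = lambda t: _discrepancy_and_grad(spec, t, s_samp, logdet_s)
    if bounded:
        bounds = [(None, None)] * spec.n_free
        for i, j, k in spec.s_free:
            if i == j:
                bounds[k] = (0.0, None)
        res = optimize.minimize(
            fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": _CONV_F_TOL, "gtol": _CONV_G_TOL},
        )
    else:
        res = optimize.minimize(
            fun, theta0, jac=True, method="BFGS",
            options={"maxiter": 2000, "gtol": _CONV_G_TOL},
        )
        if not res.success:  # polish from the BFGS point
            res2 = optimize.minimize(
                fun, res.x, jac=True, method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": _CONV_F_TOL, "gtol": _CONV_G_TOL},
            )
            if res2.fun <= res.fun:
                res = res2
    theta = res.x
    f_val = float(res.fun)
    grad_norm = float(np.linalg.norm(fun(theta)[1], ord=np.inf))
    converged = bool(np.isfinite(f_val)) and grad_norm < 1e-3
    chi2 = max((n_obs - 1) * f_val, 0.0)
    a, s = spec.matrices(theta)
    heywood = tuple(
        spec.variables[i]
        for i, j, k in spec.s_free
        if i == j and theta[k] < 0
    )
    p = spec.n_observed
    sigma = implied_covariance_full(spec, theta)[:p, :p]

    if compute_se:
        cov_theta = _theta_covariance(spec, theta, s_samp, logdet_s, n_obs)
        se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    else:
        cov_theta = np.full((spec.n_free, spec.n_free), np.nan)
        se = np.full(spec.n_free, np.nan)

    return SemFit(
        spec=spec,
        n=n_obs,
        s_sample=s_samp,
        theta=theta,
        se=se,
        cov_theta=cov_theta,
        sigma=sigma,
        f_ml=f_val,
        chi2_ml=chi2,
        df=spec.df,
        converged=converged,
        heywood=heywood,
        data=data,
    )


def _theta_covariance(
    spec: SemSpec, theta: np.ndarray, s_samp: np.ndarray, logdet_s: float, n: int
) -> np.ndarray:
    """Inverse observed information of (n-1)/2 * F_ML, by central differences
    of the analytic gradient (step 1e-5 on each parameter's own scale)."""
    q = spec.n_free
    hess = np.zeros((q, q))
    for k in range(q):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        gp = _discrepancy_and_grad(spec, tp, s_samp, logdet_s)[1]
        gm = _discrepancy_and_grad(spec, tm, s_samp, logdet_s)[1]
        hess[:, k] = (gp - gm) / (2 * h)
    hess = (hess + hess.T) / 2.0 * ((n - 1) / 2.0)
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hess)


def delta_matrix(spec: SemSpec, theta: np.ndarray) -> np.ndarray:
    """Jacobian of vech(Sigma) with respect to theta (analytic).

    vech stacks the lower triangle column-wise by row-major lower indexing
    ((0,0), (1,0), (1,1), ...), matching :func:`stressproc.sem.robust.vech`.
    """
    a, s = spec.matrices(theta)
    m = a.shape[0]
    p = spec.n_observed
    minv = np.linalg.inv(np.eye(m) - a)
    v = minv @ s @ minv.T
    rows = [(i, j) for i in range(p) for j in range(i + 1)]
    delta = np.zeros((len(rows), spec.n_free))
    for i, j, k in spec.a_free:
        d = np.outer(minv[:p, i], v[j, :p])
        d = d + d.T
        delta[:, k] += np.array([d[r, c] for r, c in rows])
    for i, j, k in spec.s_free:
        d = np.outer(minv[:p, i], minv[:p, j])
        if i != j:
            d = d + d.T
        else:
            d = (d + d.T) / 2.0
        delta[:, k] += np.array([d[r, c] for r, c in rows])
    return delta


def standardize(fit: SemFit) -> pd.Series:
    """Standardized solution: every path/loading in SD units, covariances
    as correlations.

    A coefficient of ``source -> target`` is multiplied by the implied SD
    of the source and divided by the implied SD of the target; S entries
    are divided by both SDs.  Invariant to linear rescaling of any
    observed variable.
    """
    v = implied_covariance_full(fit.spec, fit.theta)
    sd = np.sqrt(np.clip(np.diag(v), 0.0, None))
    if (sd <= 0).any():
        bad = [fit.spec.variables[i] for i in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero implied variance for {bad}")
    out: dict[str, float] = {}
    for i, j, k in fit.spec.a_free:
        out[fit.spec.parameter_labels[k]] = fit.theta[k] * sd[j] / sd[i]
    for i, j, k in fit.spec.s_free:
        out[fit.spec.parameter_labels[k]] = fit.theta[k] / (sd[i] * sd[j])
    return pd.Series(out, dtype=float)


def standardized_a(spec: SemSpec, theta: np.ndarray) -> np.ndarray:
    """The full A matrix rescaled to the standardized metric."""
    a, _ = spec.matrices(theta)
    v = implied_covariance_full(spec, theta)
    sd = np.sqrt(np.clip(np.diag(v), 1e-300, None))
    return a * (sd[None, :] / sd[:, None])
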