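"""Variable screening with random-intercept linear models.

The survey design clusters participants within kebeles (urban districts),
so candidate predictors of the EPDS score are screened with a linear
random-intercept model: first one bivariate model per candidate, then one
multivariable model on the candidates that reached p < 0.05, retaining
those still at p < 0.05.

Estimation is maximum likelihood (not REML, since fixed effects are being
compared across models) by direct optimization of the profiled
log-likelihood: for a given variance ratio ``lam = tau2/sigma2`` the GLS
fixed effects and the residual variance have closed forms, leaving a
one-dimensional concave-in-practice profile over ``lam`` that is optimized
by bounded scalar search.  Wald (normal) p-values are reported for the
fixed effects; no small-sample degrees-of-freedom correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MixedModelFit", "fit_random_intercept", "screen_variables"]


@dataclass(frozen=True)
class MixedModelFit:
    """ML fit of a linear random-intercept model."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    random_intercept_variance: float
    residual_variance: float
    log_likelihood: float
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p": self.p_values}, index=self.names
        )


def _profile_negloglik(lam, y_groups, x_groups, n, p):
    """-2 profiled log-likelihood (up to const) and GLS pieces at lam >= 0."""
    xtv_x = np.zeros((p, p))
    xtv_y = np.zeros(p)
    logdet = 0.0
    for y_g, x_g in zip(y_groups, x_groups):
        m = len(y_g)
        w = lam / (1.0 + lam * m)  # (I + lam J)^-1 = I - w J
        logdet += math.log1p(lam * m)
        xs, ys = x_g.sum(axis=0), y_g.sum()
        xtv_x += x_g.T @ x_g - w * np.outer(xs, xs)
        xtv_y += x_g.T @ y_g - w * xs * ys
    beta = np.linalg.solve(xtv_x, xtv_y)
    rss = 0.0
    for y_g, x_g in zip(y_groups, x_groups):
        m = len(y_g)
        w = lam / (1.0 + lam * m)
        r = y_g - x_g @ beta
        rss += r @ r - w * r.sum() ** 2
    sigma2 = rss / n
    # -2 log L = n log(2 pi sigma2) + logdet + n
    m2ll = n * math.log(2 * math.pi * sigma2) + logdet + n
    return m2ll, beta, sigma2, xtv_x


def fit_random_intercept(
    outcome: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    cluster: np.ndarray,
    add_intercept: bool = True,
) -> MixedModelFit:
    """ML fit of ``y = X b + u[cluster] + e`` with a scalar random intercept.

    With the between-cluster variance profiled out at zero (one cluster, or
    no between-cluster signal) the fit reproduces ordinary least squares.
    Raises on a rank-deficient design.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(design, dtype=float))
        if x.shape[0] != y.size:
            x = x.T
        names = [f"x{j}" for j in range(x.shape[1])]
    if add_intercept:
        x = np.column_stack([np.ones_like(y), x])
        names = ["intercept", *names]
    n, p = x.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("singular design matrix")
    cluster = np.asarray(cluster)
    codes = pd.factorize(cluster)[0]
    y_groups = [y[codes == g] for g in range(codes.max() + 1)]
    x_groups = [x[codes == g] for g in range(codes.max() + 1)]

    def objective(log_lam: float) -> float:
        return _profile_negloglik(math.exp(log_lam), y_groups, x_groups, n, p)[0]

    # profile over log(lam) on a generous bracket, plus the lam = 0 boundary
    res = optimize.minimize_scalar(
        objective, bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    at_zero = _profile_negloglik(0.0, y_groups, x_groups, n, p)
    lam = math.exp(res.x)
    best = _profile_negloglik(lam, y_groups, x_groups, n, p)
    if at_zero[0] <= best[0] + 1e-10:
        lam, best = 0.0, at_zero
    m2ll, beta, sigma2, xtv_x = best
    cov = sigma2 * np.linalg.inv(xtv_x)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return MixedModelFit(
        names=tuple(names),
        coef=beta,
        se=se,
        p_values=pvals,
        random_intercept_variance=lam * sigma2,
        residual_variance=sigma2,
        log_likelihood=-0.5 * m2ll,
        converged=bool(res.success or lam == 0.0),
    )


def screen_variables(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    cluster: str,
    alpha: float = 0.05,
) -> dict:
    """Two-stage screening of candidate predictors of a numeric outcome.

    Stage 1 fits one bivariate random-intercept model per candidate and
    keeps those with Wald p < ``alpha``.  Stage 2 fits a single
    multivariable model on the retained set and returns the candidates
    still at p < ``alpha``.  Deterministic given the input.  Multi-column
    candidates (e.g. dummy blocks) may be passed as ``name`` mapping to a
    list of columns via a ``"block:"`` prefix convention: a candidate whose
    name contains ``"+"`` is split on it and its columns enter jointly; the
    block is retained when its smallest per-column p is below ``alpha``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    y = data[outcome].to_numpy(dtype=float)
    cl = data[cluster].to_numpy()

    def columns_of(cand: str) -> list[str]:
        return cand.split("+") if "+" in cand else [cand]

    bivariate: dict[str, float] = {}
    for cand in candidates:
        fit = fit_random_intercept(y, data[columns_of(cand)], cl)
        bivariate[cand] = float(fit.p_values[1:].min())
    retained = [c for c in candidates if bivariate[c] < alpha]
    selected: list[str] = []
    multivariable: dict[str, float] = {}
    if retained:
        cols = [col for c in retained for col in columns_of(c)]
        fit = fit_random_intercept(y, data[cols], cl)
        pos = 1  # skip intercept
        for cand in retained:
            ncol = len(columns_of(cand))
            multivariable[cand] = float(fit.p_values[pos : pos + ncol].min())
            pos += ncol
        selected = [c for c in retained if multivariable[c] < alpha]
    return {
        "bivariate_p": bivariate,
        "retained": retained,
        "multivariable_p": multivariable,
        "selected": selected,
    }
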