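"""Satorra-Bentler scaled chi-square.

The normal-theory chi-square over-rejects under excess kurtosis.  The
scaled statistic divides it by a correction factor built from the
fourth-order sample moments:

    Gamma_hat = sample covariance of d_i = vech((x_i - xbar)(x_i - xbar)^T)
    W         = 1/2 D^T (Sigma_hat^-1 kron Sigma_hat^-1) D
    U         = W - W Delta (Delta^T W Delta)^-1 Delta^T W
    c         = tr(U Gamma_hat) / df,   chi2_SB = chi2_ML / c

with D the duplication matrix and Delta the Jacobian of vech(Sigma) in
the free parameters.  Under multivariate normality c converges to 1 and
the scaled and unscaled statistics coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import SemFit, delta_matrix

__all__ = ["satorra_bentler", "vech", "duplication_matrix", "gamma_adf"]


def vech(mat: np.ndarray) -> np.ndarray:
    """Stack the lower triangle row by row: (0,0), (1,0), (1,1), ..."""
    p = mat.shape[0]
    return np.concatenate([mat[i, : i + 1] for i in range(p)])


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric p x p M (vech as above)."""
    pairs = [(i, j) for i in range(p) for j in range(i + 1)]
    d = np.zeros((p * p, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        d[i * p + j, col] = 1.0
        if i != j:
            d[j * p + i, col] = 1.0
    return d


def gamma_adf(x: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of sqrt(n) vech(S): the fourth-moment matrix
    ``mean of (d_i - dbar)(d_i - dbar)^T`` with d_i the centered
    second-moment vectors."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0)
    rows = [(i, j) for i in range(p) for j in range(i + 1)]
    d = np.empty((n, len(rows)))
    for col, (i, j) in enumerate(rows):
        d[:, col] = xc[:, i] * xc[:, j]
    dc = d - d.mean(axis=0)
    return dc.T @ dc / n


def satorra_bentler(fit: SemFit, data: pd.DataFrame | None = None) -> tuple[float, float]:
    """Scaled chi-square and scaling factor for a converged fit.

    ``data`` defaults to the table the model was fitted on; the raw
    observations are required because the correction uses fourth-order
    moments.  Returns ``(chi2_sb, scaling_c)`` and records both on the
    fit.  Raises when the model has zero degrees of freedom or a
    rank-deficient Jacobian.
    """
    if data is None:
        data = fit.data
    if data is None:
        raise ValueError("raw data required for the Satorra-Bentler correction")
    if fit.df == 0:
        raise ValueError("scaling undefined for a saturated (df = 0) model")
    x = data[list(fit.spec.observed)].to_numpy(dtype=float)
    p = fit.spec.n_observed
    sigma_inv = np.linalg.inv(fit.sigma)
    dup = duplication_matrix(p)
    w = 0.5 * dup.T @ np.kron(sigma_inv, sigma_inv) @ dup
    delta = delta_matrix(fit.spec, fit.theta)
    if np.linalg.matrix_rank(delta) < delta.shape[1]:
        raise ValueError("rank-deficient parameter Jacobian")
    wd = w @ delta
    u = w - wd @ np.linalg.solve(delta.T @ wd, wd.T)
    gamma = gamma_adf(x)
    c = float(np.trace(u @ gamma)) / fit.df
    if c <= 0:
        raise ValueError(f"non-positive scaling factor {c}")
    chi2_sb = fit.chi2_ml / c
    fit.chi2_sb, fit.scaling_c = chi2_sb, c
    return chi2_sb, c
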