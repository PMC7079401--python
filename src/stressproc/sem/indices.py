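"""Fit-index battery: RMSEA, CFI, TLI, SRMR, CD.

The incremental indices compare the fitted model with the independence
baseline (all covariances fixed to zero, variances free) fitted to the
same sample.  Every chi-square-based index is emitted in both its ML and,
when scaled statistics are available on both fits, Satorra-Bentler scaled
variants (suffix ``_sb``).  Chi-squares use the (n-1) convention
throughout, so RMSEA's denominator is df * (n-1).
"""

from __future__ import annotations

import math

import numpy as np

from .fit import SemFit

__all__ = ["fit_indices"]


def _rmsea(chi2: float, df: int, n: int) -> float:
    if df == 0:
        return 0.0
    return math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))


def _cfi(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    return 1.0 - num / den if den > 0 else 1.0


def _tli(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    if df == 0 or df_b == 0:
        return 1.0
    ratio_b = chi2_b / df_b
    if ratio_b <= 1.0:
        return 1.0
    return (ratio_b - chi2 / df) / (ratio_b - 1.0)


def _srmr(s: np.ndarray, sigma: np.ndarray) -> float:
    """Root mean squared residual in the correlation metric, including the
    diagonal, over the p(p+1)/2 unique moments."""
    sd = np.sqrt(np.diag(s))
    scale = np.outer(sd, sd)
    resid = (s - sigma) / scale
    p = s.shape[0]
    total = 0.0
    for i in range(p):
        for j in range(i + 1):
            total += resid[i, j] ** 2
    return math.sqrt(total / (p * (p + 1) / 2))


def _cd(fit: SemFit) -> float:
    """Determinant-based coefficient of determination over the endogenous
    observed variables: 1 - |residual cov| / |implied cov|."""
    spec = fit.spec
    a, s = spec.matrices(fit.theta)
    p = spec.n_observed
    endo = sorted(
        {i for i, _, k in spec.a_free if i < p}
        | {int(i) for i, j in zip(*np.nonzero(spec.a_fixed)) if i < p}
    )
    if not endo:
        return 0.0
    resid = s[np.ix_(endo, endo)]
    implied = fit.sigma[np.ix_(endo, endo)]
    det_r = np.linalg.det(resid)
    det_i = np.linalg.det(implied)
    if det_i <= 0:
        return math.nan
    return 1.0 - det_r / det_i


def fit_indices(fit: SemFit, baseline: SemFit) -> dict[str, float]:
    """Compute the index battery against an independence baseline.

    The baseline must be fitted on the same data (same n and observed
    variables).  Results are recorded on ``fit.indices`` and returned.
    """
    if baseline.n != fit.n or baseline.spec.n_observed != fit.spec.n_observed:
        raise ValueError("baseline must be fitted to the same sample")
    chi2, df, n = fit.chi2_ml, fit.df, fit.n
    chi2_b, df_b = baseline.chi2_ml, baseline.df
    out = {
        "chi2": chi2,
        "df": float(df),
        "chi2_baseline": chi2_b,
        "df_baseline": float(df_b),
        "rmsea": _rmsea(chi2, df, n),
        "cfi": _cfi(chi2, df, chi2_b, df_b),
        "tli": _tli(chi2, df, chi2_b, df_b),
        "srmr": _srmr(fit.s_sample, fit.sigma),
        "cd": _cd(fit),
    }
    if fit.chi2_sb is not None and baseline.chi2_sb is not None:
        out.update(
            chi2_sb=fit.chi2_sb,
            scaling_c=fit.scaling_c,
            rmsea_sb=_rmsea(fit.chi2_sb, df, n),
            cfi_sb=_cfi(fit.chi2_sb, df, baseline.chi2_sb, df_b),
            tli_sb=_tli(fit.chi2_sb, df, baseline.chi2_sb, df_b),
        )
    fit.indices = out
    return out
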