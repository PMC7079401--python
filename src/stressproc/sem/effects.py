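"""Direct, indirect and total effect decomposition.

For a recursive structural coefficient matrix ``B`` (entry [target,
source]) the total-effect matrix is ``T = (I - B)^-1 - I``, equal to the
sum over all directed paths of products of path coefficients (finite
because B is nilpotent under a causal ordering).  For a chosen outcome,
the direct effect of each predictor is the corresponding entry of ``B``,
the indirect effect is ``T - B``, and total = direct + indirect holds as
an identity.

Decomposition is evaluated on the standardized solution; standard errors
come from the first-order delta method, propagating the estimate
covariance through a numerically differentiated effect map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import SemFit, standardized_a
from .spec import SemSpec

__all__ = ["EffectTable", "total_effect_matrix", "decompose_effects"]


def total_effect_matrix(b: np.ndarray) -> np.ndarray:
    """(I - B)^-1 - I for a recursive (permutation-triangular) B."""
    b = np.asarray(b, dtype=float)
    m = b.shape[0]
    power = np.eye(m)
    total = np.zeros_like(b)
    for _ in range(m):  # B is nilpotent: the series terminates
        power = b @ power
        if not power.any():
            break
        total += power
    else:
        raise ValueError("structural matrix is not recursive (cycle detected)")
    return total


@dataclass
class EffectTable:
    """Per-predictor standardized effect decomposition on one outcome."""

    outcome: str
    table: pd.DataFrame  # index: source; columns direct/indirect/total (+ se, p)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EffectTable(outcome={self.outcome!r})\n{self.table.round(3)}"

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _structural_effects(
    spec: SemSpec, theta: np.ndarray, outcome: str
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(direct, indirect) standardized effect vectors on the outcome."""
    a_std = standardized_a(spec, theta)
    names = spec.structural_variables()
    idx = [spec.index(v) for v in names]
    b = a_std[np.ix_(idx, idx)]
    t = total_effect_matrix(b)
    k = names.index(outcome)
    return b[k, :], t[k, :] - b[k, :], names


def decompose_effects(fit: SemFit, outcome: str) -> EffectTable:
    """Standardized direct/indirect/total effects of every structural
    variable on ``outcome``, with delta-method SEs and normal p-values."""
    spec = fit.spec
    if outcome not in spec.structural_variables():
        raise ValueError(f"{outcome!r} is not a structural variable")
    direct, indirect, names = _structural_effects(spec, fit.theta, outcome)
    total = direct + indirect

    # delta method: Jacobian of (direct, indirect) stacked, by central
    # differences on the free parameters
    q = spec.n_free
    m = len(names)
    jac = np.zeros((2 * m, q))
    have_cov = np.all(np.isfinite(fit.cov_theta))
    if have_cov:
        for kparam in range(q):
            h = 1e-5 * max(1.0, abs(fit.theta[kparam]))
            tp, tm = fit.theta.copy(), fit.theta.copy()
            tp[kparam] += h
            tm[kparam] -= h
            dp, ip_, _ = _structural_effects(spec, tp, outcome)
            dm, im, _ = _structural_effects(spec, tm, outcome)
            jac[:m, kparam] = (dp - dm) / (2 * h)
            jac[m:, kparam] = (ip_ - im) / (2 * h)
        cov = jac @ fit.cov_theta @ jac.T
        var_d = np.clip(np.diag(cov[:m, :m]), 0.0, None)
        var_i = np.clip(np.diag(cov[m:, m:]), 0.0, None)
        cov_di = np.diag(cov[:m, m:])
        var_t = np.clip(var_d + var_i + 2 * cov_di, 0.0, None)
        se_d, se_i, se_t = np.sqrt(var_d), np.sqrt(var_i), np.sqrt(var_t)
    else:
        se_d = se_i = se_t = np.full(m, np.nan)

    def pvals(est: np.ndarray, se: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.nan)
        return 2 * stats.norm.sf(np.abs(z))

    frame = pd.DataFrame(
        {
            "direct": direct,
            "se_direct": se_d,
            "p_direct": pvals(direct, se_d),
            "indirect": indirect,
            "se_indirect": se_i,
            "p_indirect": pvals(indirect, se_i),
            "total": total,
            "se_total": se_t,
            "p_total": pvals(total, se_t),
        },
        index=list(names),
    )
    frame = frame.drop(index=outcome)
    keep = (frame["direct"] != 0) | (frame["indirect"] != 0)
    frame = frame[keep | frame.index.isin([])]
    return EffectTable(outcome=outcome, table=frame)
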