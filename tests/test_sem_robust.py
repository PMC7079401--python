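"""Satorra-Bentler scaling and the fit-index battery."""

import numpy as np
import pandas as pd
import pytest

from stressproc.sem import (
    build_spec,
    fit_indices,
    fit_ml,
    independence_spec,
    satorra_bentler,
)
from stressproc.sem.fit import delta_matrix
from stressproc.sem.indices import _cfi, _rmsea, _srmr, _tli
from stressproc.sem.robust import duplication_matrix, gamma_adf, vech


def factor_data(rng, n, loadings=(1.0, 0.9, 0.7, 0.6), resid=0.5, nonnormal=False):
    f = rng.normal(size=n)
    eps = rng.normal(size=(n, len(loadings)))
    if nonnormal:
        f = (np.exp(f) - np.exp(0.5)) / np.sqrt(np.exp(2) - np.exp(1))  # skewed
        eps = eps * rng.exponential(1.0, size=(n, 1))  # heavy tails
    x = np.outer(f, loadings) + eps * np.sqrt(resid)
    return pd.DataFrame(x, columns=[f"y{i+1}" for i in range(len(loadings))])


def factor_spec(p=4):
    return build_spec({"eta": [f"y{i+1}" for i in range(p)]}, [], [])


class TestSatorraBentler:
    def test_normal_limit_scaling_near_one(self, rng):
        data = factor_data(rng, n=5000)
        fit = fit_ml(factor_spec(), data)
        _, c = satorra_bentler(fit)
        assert c == pytest.approx(1.0, abs=0.05)

    def test_scaled_statistic_is_chi2_over_c(self, rng):
        data = factor_data(rng, n=1000, nonnormal=True)
        fit = fit_ml(factor_spec(), data)
        chi2_sb, c = satorra_bentler(fit)
        assert chi2_sb * c == pytest.approx(fit.chi2_ml, rel=1e-12)

    def test_nonnormal_data_inflates_scaling(self, rng):
        data = factor_data(rng, n=4000, nonnormal=True)
        fit = fit_ml(factor_spec(), data)
        _, c = satorra_bentler(fit)
        assert c > 1.1  # excess kurtosis must push the correction above 1

    def test_saturated_model_rejected(self, rng):
        from stressproc.sem import saturated_spec

        data = factor_data(rng, n=300)
        fit = fit_ml(saturated_spec(list(data.columns)), data)
        with pytest.raises(ValueError, match="saturated"):
            satorra_bentler(fit, data)

    def test_closed_form_two_variable_independence_model(self, rng):
        """df = 1 zero-covariance model: the scaling factor has an explicit
        small-matrix form computed here from first principles."""
        n = 2000
        x = rng.normal(size=(n, 2)) * [1.0, 2.0]
        data = pd.DataFrame(x, columns=["a", "b"])
        fit = fit_ml(independence_spec(["a", "b"]), data)
        _, c = satorra_bentler(fit, data)

        # independent computation, vech order (aa, ba, bb)
        s = fit.sigma
        si = np.linalg.inv(s)
        d = np.zeros((4, 3))
        d[0, 0] = d[3, 2] = 1.0
        d[1, 1] = d[2, 1] = 1.0
        w = 0.5 * d.T @ np.kron(si, si) @ d
        delta = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])  # d sigma/d(va, vb)
        wd = w @ delta
        u = w - wd @ np.linalg.inv(delta.T @ w @ delta) @ wd.T
        xc = x - x.mean(0)
        moments = np.stack([xc[:, 0] ** 2, xc[:, 0] * xc[:, 1], xc[:, 1] ** 2], axis=1)
        mc = moments - moments.mean(0)
        gamma = mc.T @ mc / n
        c_expected = float(np.trace(u @ gamma)) / 1.0
        assert c == pytest.approx(c_expected, rel=1e-10)

    def test_delta_matrix_matches_finite_differences(self, rng):
        from stressproc.sem import implied_covariance

        spec = factor_spec()
        data = factor_data(rng, n=500)
        fit = fit_ml(spec, data)
        delta = delta_matrix(spec, fit.theta)
        h = 1e-6
        for k in range(spec.n_free):
            tp, tm = fit.theta.copy(), fit.theta.copy()
            tp[k] += h
            tm[k] -= h
            num = (
                vech(implied_covariance(spec, tp)) - vech(implied_covariance(spec, tm))
            ) / (2 * h)
            np.testing.assert_allclose(delta[:, k], num, atol=1e-5)

    def test_duplication_matrix_roundtrip(self, rng):
        m = rng.normal(size=(4, 4))
        m = m + m.T
        d = duplication_matrix(4)
        np.testing.assert_allclose(d @ vech(m), m.flatten())

    def test_gamma_normal_theory_limit(self, rng):
        # under normality Gamma -> 2 Dplus (Sigma kron Sigma) Dplus'
        x = rng.normal(size=(200_000, 2))
        g = gamma_adf(x)
        sigma = np.cov(x, rowvar=False, ddof=0)
        d = duplication_matrix(2)
        dplus = np.linalg.pinv(d)
        expected = 2 * dplus @ np.kron(sigma, sigma) @ dplus.T
        np.testing.assert_allclose(g, expected, atol=0.05)


class TestFitIndices:
    def test_perfect_fit(self, config, frame):
        from stressproc.model import default_sem_spec
        from stressproc.sem import implied_covariance

        spec = default_sem_spec()
        fit = fit_ml(spec, frame)
        # refit the model to its own implied covariance: exact fit
        refit = fit_ml(spec, s_sample=fit.sigma, n=916)
        baseline = fit_ml(independence_spec(spec.observed), s_sample=fit.sigma, n=916)
        idx = fit_indices(refit, baseline)
        assert idx["rmsea"] == pytest.approx(0.0, abs=1e-6)
        assert idx["cfi"] == pytest.approx(1.0, abs=1e-6)
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-5)

    def test_arithmetic_oracle(self):
        # chi2 50 on 25 df, n 916, baseline 1000 on 45 df
        assert _rmsea(50.0, 25, 916) == pytest.approx(np.sqrt(25 / (25 * 915)))
        assert _cfi(50.0, 25, 1000.0, 45) == pytest.approx(1 - 25 / 955)
        ratio_b = 1000.0 / 45
        assert _tli(50.0, 25, 1000.0, 45) == pytest.approx(
            (ratio_b - 2.0) / (ratio_b - 1.0)
        )

    def test_srmr_hand_computation(self):
        s = np.array([[1.0, 0.3], [0.3, 4.0]])
        sigma = np.array([[1.0, 0.5], [0.5, 4.0]])
        # residual correlation: (0.3 - 0.5) / 2 = -0.1; diagonal residuals 0
        expected = np.sqrt((0.1**2) / 3)
        assert _srmr(s, sigma) == pytest.approx(expected)

    def test_chi2_degradation_orders_indices(self, rng, frame):
        from stressproc.model import default_sem_spec

        spec = default_sem_spec()
        fit = fit_ml(spec, frame)
        satorra_bentler(fit, frame)
        baseline = fit_ml(independence_spec(spec.observed), frame)
        satorra_bentler(baseline, frame)
        idx = fit_indices(fit, baseline)
        assert 0.0 <= idx["rmsea"] <= 0.08
        assert idx["cfi"] >= 0.9 and idx["tli"] >= 0.9
        assert idx["srmr"] < 0.05
        assert "cfi_sb" in idx and idx["scaling_c"] > 0
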