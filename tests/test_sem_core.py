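"""RAM specification, implied covariance and ML fitting."""

import numpy as np
import pandas as pd
import pytest

from stressproc.model import default_sem_spec
from stressproc.sem import (
    build_spec,
    fit_ml,
    implied_covariance,
    ml_discrepancy,
    saturated_spec,
    standardize,
)


def triad_spec():
    return build_spec({"eta": ["y1", "y2", "y3"]}, [], [])


def triad_data(rng, n=2000, loadings=(1.0, 0.8, 0.6), resid=0.5):
    f = rng.normal(size=n)
    x = np.outer(f, loadings) + rng.normal(size=(n, 3)) * np.sqrt(resid)
    return pd.DataFrame(x, columns=["y1", "y2", "y3"])


class TestSpec:
    def test_triad_is_just_identified(self):
        spec = triad_spec()
        assert spec.n_free == 6  # 2 loadings, 3 residuals, 1 latent variance
        assert spec.n_observed == 3
        assert spec.df == 0

    def test_default_model_shape(self):
        spec = default_sem_spec()
        assert spec.n_observed == 10
        assert spec.latents == ("depression",)
        # 2 loadings + 14 paths + 11 variances + 6 stressor covariances
        assert spec.n_free == 33
        assert spec.df == 22
        spec.validate()

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            build_spec({"eta": ["y1", "y2", "y3"]}, [("a", "b"), ("b", "a")])

    def test_underidentified_rejected(self):
        # a lone two-indicator factor has more free parameters than moments
        with pytest.raises(ValueError, match="degrees of freedom"):
            build_spec({"eta": ["y1", "y2"]}, [], [])

    def test_latent_variance_identification(self):
        spec = build_spec(
            {"eta": ["y1", "y2", "y3"]}, [], [],
            identification="latent_variance_fixed_1",
        )
        assert "eta=~y1" in spec.parameter_labels  # all loadings free
        assert spec.df == 0


class TestImpliedCovariance:
    def test_no_paths_passes_s_through(self):
        spec = saturated_spec(["a", "b"])
        theta = np.array([2.0, 0.3, 1.0])  # a~~a, b~~a, b~~b
        sigma = implied_covariance(spec, theta)
        np.testing.assert_allclose(sigma, [[2.0, 0.3], [0.3, 1.0]])

    def test_single_factor_oracle(self):
        # independent evaluation: Sigma = lam phi lam' + diag(theta)
        spec = triad_spec()
        theta = dict(zip(spec.parameter_labels, [0.8, 0.6, 0.5, 0.5, 0.5, 1.0]))
        sigma = implied_covariance(spec, list(theta.values()))
        lam = np.array([1.0, 0.8, 0.6])
        expected = np.outer(lam, lam) * 1.0 + np.diag([0.5, 0.5, 0.5])
        np.testing.assert_allclose(sigma, expected, atol=1e-12)

    def test_homogeneity_in_s(self):
        spec = triad_spec()
        theta = np.array([0.8, 0.6, 0.5, 0.4, 0.3, 1.0])
        scaled = theta.copy()
        scaled[2:] *= 3.0  # all S entries
        np.testing.assert_allclose(
            implied_covariance(spec, scaled), 3.0 * implied_covariance(spec, theta)
        )

    def test_wrong_theta_length(self):
        with pytest.raises(ValueError):
            implied_covariance(triad_spec(), [1.0, 2.0])


class TestDiscrepancy:
    def test_zero_at_equality(self, rng):
        a = rng.normal(size=(4, 4))
        s = a @ a.T + 4 * np.eye(4)
        assert ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        assert ml_discrepancy(np.eye(2), 2 * np.eye(2)) == pytest.approx(
            2 * np.log(2.0) + 1 - 2
        )

    def test_nonnegative_on_random_spd_pairs(self, rng):
        for _ in range(25):
            a = rng.normal(size=(3, 3))
            b = rng.normal(size=(3, 3))
            s = a @ a.T + np.eye(3)
            g = b @ b.T + np.eye(3)
            assert ml_discrepancy(s, g) >= -1e-12

    def test_rejects_indefinite(self):
        with pytest.raises(ValueError):
            ml_discrepancy(np.diag([1.0, -1.0]), np.eye(2))


class TestFitMl:
    def test_triad_matches_closed_form(self, rng):
        data = triad_data(rng)
        fit = fit_ml(triad_spec(), data)
        assert fit.converged
        assert fit.f_ml == pytest.approx(0.0, abs=1e-9)
        s = fit.s_sample
        phi = s[0, 1] * s[0, 2] / s[1, 2]
        est = dict(zip(fit.spec.parameter_labels, fit.theta))
        assert est["eta~~eta"] == pytest.approx(phi, rel=1e-4)
        assert est["eta=~y2"] == pytest.approx(s[0, 1] / phi, rel=1e-4)
        assert est["eta=~y3"] == pytest.approx(s[0, 2] / phi, rel=1e-4)

    def test_saturated_model_chi2_zero(self, rng):
        data = triad_data(rng)
        fit = fit_ml(saturated_spec(["y1", "y2", "y3"]), data)
        assert fit.df == 0
        assert fit.chi2_ml == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_default_model(self, frame, config):
        fit = fit_ml(default_sem_spec(), frame)
        assert fit.converged and not fit.heywood
        # one cohort at n = 916: allow ~3 SE of sampling noise per path
        # (the 100-replicate recovery check lives in the acceptance suite)
        std = standardize(fit)
        for (src, dst), target in config.structural_paths.items():
            assert std[f"{dst}~{src}"] == pytest.approx(target, abs=0.13)

    def test_deterministic_restart(self, rng):
        data = triad_data(rng)
        f1 = fit_ml(triad_spec(), data)
        f2 = fit_ml(triad_spec(), data)
        np.testing.assert_array_equal(f1.theta, f2.theta)

    def test_needs_data_or_covariance(self):
        with pytest.raises(ValueError):
            fit_ml(triad_spec())


class TestStandardize:
    def test_rescaling_invariance(self, rng):
        data = triad_data(rng)
        fit = fit_ml(triad_spec(), data)
        rescaled = data.copy()
        rescaled["y2"] = rescaled["y2"] * 10.0
        fit2 = fit_ml(triad_spec(), rescaled)
        pd.testing.assert_series_equal(
            standardize(fit), standardize(fit2), atol=1e-6, rtol=1e-4
        )

    def test_single_path_standardization(self):
        # X -> Y with var(X) = 4, b = .25 -> standardized .5
        spec = build_spec({}, [("x", "y")], [])
        s = np.array([[4.0, 1.0], [1.0, 1.0]])
        fit = fit_ml(spec, s_sample=s, n=500)
        est = dict(zip(spec.parameter_labels, fit.theta))
        assert est["y~x"] == pytest.approx(0.25, abs=1e-6)
        assert standardize(fit)["y~x"] == pytest.approx(0.5, abs=1e-6)

    def test_standardized_data_leaves_estimates_alone(self, rng):
        data = triad_data(rng, n=5000)
        z = (data - data.mean()) / data.std(ddof=1)
        fit = fit_ml(triad_spec(), z)
        std = standardize(fit)
        est = dict(zip(fit.spec.parameter_labels, fit.theta))
        for lab in ("eta=~y2", "eta=~y3"):
            # loadings multiplied by latent sd ~ the standardized loading;
            # with unit indicator variances raw and standardized are close
            assert std[lab] == pytest.approx(
                est[lab] * np.sqrt(est["eta~~eta"]), rel=1e-6
            )
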