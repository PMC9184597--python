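"""OLS fitting, diagnostics, and prediction intervals."""

import numpy as np
import pandas as pd
import pytest

from gelrsm import fitting, rsm, synthetic
from gelrsm.exceptions import FitError, InputError
from oracle_utils import ols_normal_equations


def _noiseless_data(model, replicates=1):
    cfg = synthetic.SimulationConfig(seed=0, noise_sd_modulus=0.0,
                                     replicates=replicates)
    return synthetic.generate_doe_dataset(model, cfg)


@pytest.fixture(scope="module")
def positive_ref(refined):
    """Reference model raised clear of the 0 kPa floor (+70 kPa intercept).

    The reference quadratic extrapolates negative in one corner of the design
    box, where the generator's physical floor censors it; calibration checks
    of the *estimator* use this shifted twin so censoring never engages."""
    return rsm.QuadraticModel(
        form="actual", intercept=refined.intercept + 70.0,
        linear=dict(refined.linear), interaction=dict(refined.interaction),
        quadratic=dict(refined.quadratic), space=refined.space,
    )


@pytest.fixture(scope="module")
def noisy_fit(refined):
    data = synthetic.generate_doe_dataset(
        refined, synthetic.SimulationConfig(seed=11))
    return fitting.fit_quadratic(data, form="actual"), data


class TestDesignMatrix:
    def test_single_row_single_term(self, space):
        frame = pd.DataFrame(
            [[4.0, 2.0, 10.0, 1.5, 30.0]],
            columns=["gelma", "time", "hase", "hama", "modulus"],
        )
        X, y, cols = fitting.build_design_matrix(
            fitting.DoEDataset(frame), ("gelma",), space, form="actual")
        np.testing.assert_allclose(X, [[1.0, 4.0]])
        assert cols == ["intercept", "gelma"]
        np.testing.assert_allclose(y, [30.0])

    def test_reference_sweep_dimensions(self, refined):
        data = _noiseless_data(refined)
        X, _, _ = fitting.build_design_matrix(data)
        assert X.shape == (3 * 2 * 6 * 7, 12)

    def test_coded_row_at_midpoints_is_intercept_only(self, space):
        frame = pd.DataFrame(
            [[5.0, 12.0, 500.0, 2.25, 10.0]],
            columns=["gelma", "time", "hase", "hama", "modulus"],
        )
        X, _, _ = fitting.build_design_matrix(fitting.DoEDataset(frame))
        np.testing.assert_allclose(X[0], [1.0] + [0.0] * 11, atol=1e-14)


class TestFit:
    def test_noiseless_recovery_is_exact(self, positive_ref):
        fit = fitting.fit_quadratic(_noiseless_data(positive_ref), form="actual")
        want = rsm.to_coded(positive_ref)
        got = fit.coded_model
        assert got.intercept == pytest.approx(want.intercept, rel=1e-8)
        for n, v in want.linear.items():
            assert got.linear[n] == pytest.approx(v, rel=1e-8, abs=1e-8)
        for p, v in want.interaction.items():
            assert got.interaction[p] == pytest.approx(v, rel=1e-8, abs=1e-8)
        for n, v in want.quadratic.items():
            assert got.quadratic[n] == pytest.approx(v, rel=1e-8, abs=1e-8)
        assert fit.diagnostics.r2 == pytest.approx(1.0, abs=1e-10)
        # σ̂ is pure roundoff: signal-to-noise is effectively infinite
        assert fit.diagnostics.adequate_precision > 1e6

    def test_noisy_fit_is_adequate(self, noisy_fit):
        fit, _ = noisy_fit
        assert fit.diagnostics.r2 >= 0.9
        assert fit.diagnostics.adj_r2 <= fit.diagnostics.r2
        assert fit.diagnostics.adequate_precision > 4.0
        assert fit.diagnostics.dof == fit.n_rows - 12

    def test_constant_response_errors(self, space):
        frame = pd.DataFrame(
            {"gelma": np.linspace(2.5, 7.5, 20),
             "time": np.linspace(0, 24, 20),
             "hase": np.linspace(0, 1000, 20),
             "hama": np.linspace(1.5, 3.0, 20),
             "modulus": 7.0})
        with pytest.raises(FitError, match="zero variance"):
            fitting.fit_quadratic(fitting.DoEDataset(frame), ("gelma",), space)

    def test_rank_deficiency_names_collinear_terms(self, refined):
        data = _noiseless_data(refined)
        frame = data.frame.copy()
        frame["hama"] = 1.5  # constant factor: hama column aliases intercept
        with pytest.raises(FitError, match="hama"):
            fitting.fit_quadratic(fitting.DoEDataset(frame))

    def test_too_few_rows_rejected(self, refined, space):
        frame = _noiseless_data(refined).frame.head(5)
        with pytest.raises(InputError, match="rows"):
            fitting.fit_quadratic(fitting.DoEDataset(frame))

    def test_matches_normal_equations_oracle(self, refined):
        data = synthetic.generate_doe_dataset(
            refined, synthetic.SimulationConfig(seed=5, replicates=1))
        fit = fitting.fit_quadratic(data)
        X, y, cols = fitting.build_design_matrix(data)
        beta = ols_normal_equations(X, y)
        got = [fit.coded_model.intercept] + [
            _coded_coef(fit.coded_model, t) for t in cols[1:]
        ]
        np.testing.assert_allclose(got, beta, rtol=1e-9)

    def test_r2_invariant_under_reparameterization(self, refined):
        data = synthetic.generate_doe_dataset(
            refined, synthetic.SimulationConfig(seed=21, replicates=1))
        r2_coded = fitting.fit_quadratic(data, form="coded").diagnostics.r2
        # actual-units design matrix spans the same column space
        X, y, _ = fitting.build_design_matrix(data, form="actual")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        r2_actual = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2_coded == pytest.approx(r2_actual, abs=1e-10)

    def test_anova_flags_absent_effects(self, space):
        # response built from gelma only; hama terms should be insignificant
        rng = np.random.default_rng(3)
        n = 120
        frame = pd.DataFrame({
            "gelma": rng.uniform(2.5, 7.5, n),
            "time": rng.uniform(0, 24, n),
            "hase": rng.uniform(0, 1000, n),
            "hama": rng.uniform(1.5, 3.0, n),
        })
        frame["modulus"] = 10 + 8 * frame["gelma"] + rng.normal(0, 1, n)
        fit = fitting.fit_quadratic(
            fitting.DoEDataset(frame), ("gelma", "hama"), space)
        anova = fit.diagnostics.anova.set_index("term")
        assert anova.loc["gelma", "significant"]
        assert not anova.loc["hama", "significant"]

    def test_coefficient_bias_and_rmse_over_replicated_fits(self, positive_ref):
        """Estimator calibration on the study grid at the study noise level:
        200 simulated sweeps -> per-coefficient |bias| < 0.5 kPa and
        RMSE < 1.5 kPa in coded units."""
        want = rsm.to_coded(positive_ref)
        terms = fitting.REFERENCE_TERM_SET
        truth = np.array([want.intercept] + [_coded_coef(want, t) for t in terms])
        estimates = []
        for seed in range(200):
            data = synthetic.generate_doe_dataset(
                positive_ref, synthetic.SimulationConfig(seed=seed))
            X, y, _ = fitting.build_design_matrix(data)
            estimates.append(ols_normal_equations(X, y))
        estimates = np.array(estimates)
        bias = estimates.mean(axis=0) - truth
        rmse = np.sqrt(((estimates - truth) ** 2).mean(axis=0))
        assert np.abs(bias).max() < 0.5
        assert rmse.max() < 1.5


class TestAdequatePrecision:
    def test_hand_computable_example(self):
        ap = fitting.adequate_precision_from_predictions(
            np.array([0.0, 1.0, 2.0]), n_params=2, sigma2=1.0, n=3)
        assert ap == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), rel=1e-12)

    def test_constant_predictions_give_zero(self):
        ap = fitting.adequate_precision_from_predictions(
            np.full(10, 5.0), n_params=3, sigma2=2.0)
        assert ap == 0.0

    def test_zero_variance_is_error(self):
        with pytest.raises(FitError):
            fitting.adequate_precision_from_predictions(
                np.array([0.0, 1.0]), n_params=2, sigma2=0.0)

    def test_rows_and_distinct_modes_differ_by_replication(self, noisy_fit):
        fit, data = noisy_fit
        ap_rows = fitting.adequate_precision(fit, data, n_mode="rows")
        ap_distinct = fitting.adequate_precision(fit, data, n_mode="distinct")
        # triplicates: n drops by 3, AP by sqrt(3)
        assert ap_rows / ap_distinct == pytest.approx(np.sqrt(3.0), rel=1e-9)
        assert ap_rows == pytest.approx(fit.diagnostics.adequate_precision)


class TestPredictionInterval:
    def test_noiseless_interval_degenerates_to_point(self, positive_ref):
        fit = fitting.fit_quadratic(_noiseless_data(positive_ref))
        pi = fitting.predict_with_interval(
            fit, dict(gelma=5, time=12, hase=500, hama=2.25))
        assert pi.upper - pi.lower == pytest.approx(0.0, abs=1e-6)
        assert pi.lower <= pi.point <= pi.upper

    def test_higher_level_is_strictly_wider(self, noisy_fit):
        fit, _ = noisy_fit
        point = dict(gelma=5, time=12, hase=500, hama=2.25)
        w95 = fitting.predict_with_interval(fit, point, level=0.95).width
        w99 = fitting.predict_with_interval(fit, point, level=0.99).width
        assert w99 > w95

    def test_mean_of_replicates_narrows_interval(self, noisy_fit):
        fit, _ = noisy_fit
        point = dict(gelma=5, time=12, hase=500, hama=2.25)
        w1 = fitting.predict_with_interval(fit, point, n_new=1).width
        w3 = fitting.predict_with_interval(fit, point, n_new=3).width
        assert w3 < w1

    def test_width_grows_with_leverage_along_a_ray(self, noisy_fit):
        fit, _ = noisy_fit
        widths = []
        for s in (0.0, 0.4, 0.8, 1.0):
            point = {f.name: f.center + s * f.half_range
                     for f in fit.space.factors}
            widths.append(fitting.predict_with_interval(fit, point).width)
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_outside_space_warns(self, noisy_fit):
        fit, _ = noisy_fit
        with pytest.warns(UserWarning, match="outside"):
            fitting.predict_with_interval(
                fit, dict(gelma=9.0, time=12, hase=500, hama=2.25))

    def test_monte_carlo_coverage_of_new_observations(self, refined, noisy_fit):
        """~95% of new noisy observations at random in-space points fall in
        their 95% PIs (PI from the fitted model, truth from the generator)."""
        fit, _ = noisy_fit
        rng = np.random.default_rng(2718)
        n = 1000
        pts = {f.name: rng.uniform(f.low, f.high, n) for f in fit.space.factors}
        obs = np.asarray(rsm.evaluate_model(refined, pts)) + rng.normal(0, 8.0, n)
        inside = sum(
            fitting.predict_with_interval(
                fit, {k: v[i] for k, v in pts.items()}).contains(obs[i])
            for i in range(n)
        )
        assert 0.93 <= inside / n <= 0.97


def _coded_coef(model, term):
    if term.endswith("^2"):
        return model.quadratic[term[:-2]]
    if "*" in term:
        a, b = term.split("*")
        return model.interaction[(a, b)]
    return model.linear[term]
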