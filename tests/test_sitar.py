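import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pubsitar.basis import NaturalCubicSpline
from pubsitar.exceptions import ConfigError, DataError, FitError, LandmarkError
from pubsitar.simulate import SimConfig, simulate_cohort
from pubsitar.sitar import (SitarFit, SitarSpec, age_at_level,
                            age_at_peak_velocity, fit_sitar,
                            individual_pubertal_age, predict_curves,
                            remove_outliers, select_model)

from .oracles import random_intercept_ml_loglik


def _toy_random_intercept(n_ind=20, n_obs=5, tau=2.0, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ind):
        ages = rng.uniform(7, 17, n_obs)
        u = tau * rng.standard_normal()
        y = 100 + 2.0 * ages + u + sigma * rng.standard_normal(n_obs)
        rows.append(pd.DataFrame({"id": f"P{i:03d}", "age_y": ages, "value": y}))
    return pd.concat(rows, ignore_index=True)


class TestLinearMixedModelReduction:
    """With only the size effect, SITAR is a random-intercept linear mixed
    model; the marginal likelihood must match closed-form GLS."""

    def test_loglik_matches_closed_form_oracle(self):
        data = _toy_random_intercept()
        spec = SitarSpec(random_effects=("size",), n_knots=2, tol=1e-12,
                         max_iter=100)
        fit = fit_sitar(data, spec)
        spline = NaturalCubicSpline(fit.knots)
        X = np.column_stack([np.ones(len(data)),
                             spline.design(data["age_y"].to_numpy())])
        oracle = random_intercept_ml_loglik(X, data["value"].to_numpy(),
                                            data["id"].to_numpy())
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)

    def test_loglik_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        data = _toy_random_intercept(seed=3)
        spec = SitarSpec(random_effects=("size",), n_knots=2, tol=1e-12,
                         max_iter=100)
        fit = fit_sitar(data, spec)
        spline = NaturalCubicSpline(fit.knots)
        B = spline.design(data["age_y"].to_numpy())
        df = data.assign(**{f"b{j}": B[:, j] for j in range(B.shape[1])})
        formula = "value ~ " + " + ".join(f"b{j}" for j in range(B.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, df, groups=df["id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-3)

    def test_intercept_blups_match_shrinkage_formula(self):
        data = _toy_random_intercept(seed=5)
        spec = SitarSpec(random_effects=("size",), n_knots=2, tol=1e-12,
                         max_iter=100)
        fit = fit_sitar(data, spec)
        spline = NaturalCubicSpline(fit.knots)
        X = np.column_stack([np.ones(len(data)),
                             spline.design(data["age_y"].to_numpy())])
        resid = data["value"].to_numpy() - X @ fit.coef
        psi = fit.omega[0, 0] / fit.sigma**2
        for pid, grp in data.groupby("id"):
            idx = data.index.get_indexer(grp.index)
            ni = len(idx)
            expected = psi / (1 + ni * psi) * resid[idx].sum()
            assert fit.blups.loc[pid, "size"] == pytest.approx(expected,
                                                               abs=1e-5)


class TestFitRecovery:
    def test_noiseless_zero_effect_data_recovers_mean_curve(self):
        cfg = SimConfig(n_per_sex=40, missingness_clinic=0.0).with_measures(
            ["height"])
        m = replace(cfg.measures["height"], timing_sd=1e-9, size_sd=1e-9,
                    intensity_sd=1e-9, residual_sd=0.01)
        cfg = SimConfig(n_per_sex=40, missingness_clinic=0.0,
                        measures={"height": m})
        cohort = simulate_cohort(cfg, seed=1)
        data = cohort.measurements[cohort.measurements["sex"] == "F"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_sitar(data, SitarSpec(outcome="height", n_knots=4))
        grid = np.linspace(8, 17, 50)
        true = cfg.measures["height"].curve_by_sex["F"].value(grid)
        assert np.max(np.abs(fit.distance(grid) - true)) < 0.05
        assert np.sqrt(fit.omega[1, 1]) < 0.05  # timing SD ~ 0

    def test_random_effect_recovery_on_generator_data(self, height_fit_f):
        cfg, cohort, fit = height_fit_f
        pm = cohort.true_effects.per_measure
        truth = pm[(pm["measure"] == "height")
                   & (pm["sex"] == "F")].set_index("id")
        joined = fit.blups.join(truth)
        for est, true in (("size", "alpha"), ("timing", "beta"),
                          ("intensity", "gamma")):
            r = np.corrcoef(joined[est], joined[true])[0, 1]
            assert r >= 0.85, f"{est} recovery r={r:.3f}"
        sd_hat = np.sqrt(fit.omega[1, 1])
        assert abs(sd_hat - 1.0) < 0.15

    def test_predicted_effects_are_shrunken_with_near_zero_mean(self,
                                                                height_fit_f):
        _, _, fit = height_fit_f
        n = len(fit.blups)
        for j, eff in enumerate(fit.effects):
            assert fit.blups[eff].var(ddof=1) <= fit.omega[j, j] * (1 + 1e-9)
            # mean is zero up to sampling noise (the penalty centres the
            # effects; the fixed-knot spline absorbs the remainder only
            # approximately)
            assert abs(fit.blups[eff].mean()) < 3.0 * fit.blups[eff].std() / np.sqrt(n)

    def test_loglik_never_decreases_when_adding_an_effect(self, height_cohort):
        cfg, cohort = height_cohort
        data = cohort.measurements[cohort.measurements["sex"] == "M"]
        lls = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for effects in (("size",), ("size", "timing"),
                            ("size", "timing", "intensity")):
                lls[effects] = fit_sitar(
                    data, SitarSpec(outcome="height", random_effects=effects,
                                    n_knots=4)).loglik
        assert lls[("size", "timing")] >= lls[("size",)] - 1e-3
        assert (lls[("size", "timing", "intensity")]
                >= lls[("size", "timing")] - 1e-3)

    def test_omega_is_symmetric_positive_semidefinite(self, height_fit_f):
        _, _, fit = height_fit_f
        assert np.allclose(fit.omega, fit.omega.T)
        assert np.linalg.eigvalsh(fit.omega).min() >= -1e-10


class TestTranslationEquivariance:
    def test_shifting_ages_shifts_apv_and_preserves_variances(self,
                                                              height_cohort):
        cfg, cohort = height_cohort
        data = cohort.measurements[cohort.measurements["sex"] == "F"]
        shifted = data.assign(age_months=data["age_months"] + 12.0)
        spec = SitarSpec(outcome="height", n_knots=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit0 = fit_sitar(data, spec)
            fit1 = fit_sitar(shifted, spec)
        assert (age_at_peak_velocity(fit1) - age_at_peak_velocity(fit0)
                == pytest.approx(1.0, abs=0.02))
        assert np.allclose(fit1.omega, fit0.omega,
                           atol=1e-3 * (1 + np.abs(fit0.omega)).max())
        assert fit1.sigma == pytest.approx(fit0.sigma, abs=1e-3)


class TestSelectModel:
    def test_single_candidate_returned_with_one_row_table(self, height_cohort):
        _, cohort = height_cohort
        data = cohort.measurements[cohort.measurements["sex"] == "F"]
        best, table = select_model(data, SitarSpec(outcome="height"), (4,))
        assert best.spec.n_knots == 4
        assert len(table) == 1

    def test_candidate_table_has_one_row_per_knot_count(self, height_cohort):
        _, cohort = height_cohort
        data = cohort.measurements[cohort.measurements["sex"] == "F"]
        best, table = select_model(data, SitarSpec(outcome="height"),
                                   (2, 3, 4, 5))
        assert list(table["n_knots"]) == [2, 3, 4, 5]
        converged = table[table["converged"]]
        assert best.bic == pytest.approx(converged["bic"].min())


class TestLandmarks:
    def test_velocity_integrates_to_distance_difference(self, height_fit_f):
        from scipy.integrate import quad
        _, _, fit = height_fit_f
        a, b = 9.0, 15.0
        integral, _ = quad(lambda t: float(fit.velocity(t)), a, b,
                           limit=200, epsabs=1e-10)
        assert integral == pytest.approx(
            float(fit.distance(b) - fit.distance(a)), abs=1e-6)

    def test_velocity_constant_beyond_boundary_knots(self, height_fit_f):
        _, _, fit = height_fit_f
        lo, hi = fit.knots[0], fit.knots[-1]
        v_lo = fit.velocity(np.array([lo - 3.0, lo - 1.0]))
        v_hi = fit.velocity(np.array([hi + 1.0, hi + 3.0]))
        assert v_lo[0] == pytest.approx(v_lo[1], abs=1e-10)
        assert v_hi[0] == pytest.approx(v_hi[1], abs=1e-10)

    def test_predict_curves_wrapper(self, height_fit_f):
        _, _, fit = height_fit_f
        ages = np.linspace(9, 15, 20)
        d, v = predict_curves(fit, ages)
        assert np.array_equal(d, fit.distance(ages))
        assert np.array_equal(v, fit.velocity(ages))

    def test_monotone_linear_curve_has_no_interior_peak(self, height_fit_f):
        _, _, fit = height_fit_f
        linear = SitarFit(spec=fit.spec, knots=fit.knots,
                          coef=np.array([100.0, 2.0] + [0.0] * (len(fit.coef) - 2)),
                          omega=fit.omega, sigma=fit.sigma, blups=fit.blups,
                          loglik=0.0, bic=0.0, converged=True,
                          n_individuals=1, n_observations=1)
        with pytest.raises(LandmarkError):
            age_at_peak_velocity(linear)

    def test_age_at_level_finds_smallest_crossing(self, height_fit_f):
        _, _, fit = height_fit_f
        level = float(fit.distance(12.0))
        age = age_at_level(fit, level)
        assert abs(float(fit.distance(age)) - level) < 1e-5
        grid = np.linspace(fit.knots[0], age - 1e-3, 500)
        assert (fit.distance(grid) < level).all()

    def test_age_at_level_flags_unreachable_level(self, height_fit_f):
        _, _, fit = height_fit_f
        with pytest.raises(LandmarkError):
            age_at_level(fit, 1e6)

    def test_individual_pubertal_age_is_landmark_plus_timing(self,
                                                             height_fit_f):
        _, _, fit = height_fit_f
        ages = individual_pubertal_age(fit, 11.7)
        assert np.allclose(ages.to_numpy(),
                           11.7 + fit.blups["timing"].to_numpy())
        assert ages.mean() == pytest.approx(11.7, abs=0.05)

    def test_individual_pubertal_age_requires_timing_effect(self):
        data = _toy_random_intercept()
        spec = SitarSpec(random_effects=("size",), n_knots=2)
        fit = fit_sitar(data, spec)
        with pytest.raises(FitError):
            individual_pubertal_age(fit, 12.0)


class TestRemoveOutliers:
    @staticmethod
    def _frame(values, sex="F", occasion=0):
        return pd.DataFrame({"id": [f"P{i}" for i in range(len(values))],
                             "sex": sex, "occasion": occasion,
                             "measure": "height", "value": values})

    def test_clean_data_untouched(self):
        rng = np.random.default_rng(0)
        data = self._frame(np.clip(rng.standard_normal(500), -4, 4))
        filtered, report = remove_outliers(data)
        assert report.n_removed == 0
        assert len(filtered) == 500

    def test_single_extreme_point_removed(self):
        rng = np.random.default_rng(1)
        vals = np.clip(rng.standard_normal(999), -4, 4).tolist() + [8.0]
        filtered, report = remove_outliers(self._frame(vals))
        assert report.n_removed == 1
        assert 8.0 not in filtered["value"].to_numpy()

    def test_report_percentage_arithmetic(self):
        from pubsitar.sitar import OutlierReport
        assert OutlierReport(4, 1000).pct_removed == pytest.approx(0.4)

    def test_grouping_is_per_sex_and_occasion(self):
        # a value extreme for occasion 0 but typical for occasion 1 is kept
        rng = np.random.default_rng(2)
        a = self._frame(np.clip(rng.standard_normal(300), -4, 4), occasion=0)
        b = self._frame(100 + np.clip(rng.standard_normal(300), -4, 4),
                        occasion=1)
        data = pd.concat([a, b], ignore_index=True)
        _, report = remove_outliers(data)
        assert report.n_removed == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigError):
            remove_outliers(self._frame([1.0, 2.0]), threshold=0)


class TestSpecValidation:
    def test_knot_range_enforced(self):
        with pytest.raises(ConfigError):
            SitarSpec(n_knots=6)

    def test_effects_must_be_known_and_nonempty(self):
        with pytest.raises(ConfigError):
            SitarSpec(random_effects=())
        with pytest.raises(ConfigError):
            SitarSpec(random_effects=("size", "speed"))

    def test_effects_canonicalized(self):
        spec = SitarSpec(random_effects=("intensity", "size", "timing"))
        assert spec.random_effects == ("size", "timing", "intensity")

    def test_all_missing_outcome_rejected(self):
        data = pd.DataFrame({"id": ["a", "b"], "age_y": [8.0, 9.0],
                             "value": [np.nan, np.nan]})
        with pytest.raises(DataError):
            fit_sitar(data, SitarSpec(n_knots=2))
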