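"""Least-squares fitting: timecourse and macro recovery, uncertainty
quantification, weighting, and population summaries."""

import numpy as np
import pytest

from iggkin.datasets import pooled_macro_estimates, subject_timecourse_estimates
from iggkin.estimation import (FitResult, fit_macro_fixed, fit_macro_joint,
                               fit_timecourse, summarize_population)
from iggkin.kinetics import DEFAULT_PARAMETERS
from iggkin.macro import MacroDataset, fcr, half_life
from iggkin.synthetic import (NoiseModel, PopulationSpec, generate_subject,
                              generate_population_macro)


def make_macro_dataset(params, x_values, noise_fcr=0.0, noise_th=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.asarray(x_values, dtype=float)
    f = np.array([fcr(params, xi) for xi in x])
    t = np.array([half_life(params, xi) for xi in x])
    if noise_fcr:
        f = f * (1 + noise_fcr * rng.standard_normal(f.size))
    if noise_th:
        t = t * (1 + noise_th * rng.standard_normal(t.size))
    return MacroDataset(x1E=x, fcr_per_day=np.abs(f), thalf_days=np.abs(t))


class TestTimecourseFit:
    def test_noise_free_exact_recovery(self, params):
        data = generate_subject(params, 200.0, noise=NoiseModel(scale=0.0))
        result = fit_timecourse(data)
        truth = [fcr(params, 200.0), params.k12, params.k21]
        assert result.estimates == pytest.approx(truth, rel=1e-6)
        assert result.rmse < 1e-9

    def test_noisy_recovery_and_sensible_ses(self, params):
        data = generate_subject(params, 200.0, noise=NoiseModel(scale=0.03, seed=11))
        result = fit_timecourse(data)
        truth = np.array([fcr(params, 200.0), params.k12, params.k21])
        assert np.all(np.abs(result.estimates - truth) / truth < 0.10)
        # standard errors are small relative to estimates, as for the
        # historical subjects
        assert np.all(result.standard_errors < 0.25 * result.estimates)

    def test_correlation_matrix_contract(self, params):
        data = generate_subject(params, 200.0, noise=NoiseModel(scale=0.03, seed=3))
        result = fit_timecourse(data)
        C = result.correlation_matrix
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert np.all((C >= -1.0) & (C <= 1.0))
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)

    def test_confidence_interval_definition(self, params):
        data = generate_subject(params, 200.0, noise=NoiseModel(scale=0.03, seed=5))
        result = fit_timecourse(data)
        half_width = (result.confidence_intervals[:, 1]
                      - result.confidence_intervals[:, 0]) / 2
        from scipy import stats
        tq = stats.t.ppf(0.975, result.degrees_of_freedom)
        assert half_width == pytest.approx(tq * result.standard_errors, rel=1e-9)

    def test_ses_shrink_with_sample_size(self, params):
        from iggkin.kinetics import TracerDesign
        times_n = np.linspace(0.25, 30.0, 30)
        times_4n = np.linspace(0.25, 30.0, 120)
        results = []
        for times in (times_n, times_4n):
            design = TracerDesign(dose_D=0.005, sample_times=times,
                                  endogenous_production_IE=15.0)
            data = generate_subject(params, 200.0, design=design,
                                    noise=NoiseModel(scale=0.03, seed=21))
            results.append(fit_timecourse(data))
        ratio = results[0].se("FCR") / results[1].se("FCR")
        assert 1.3 < ratio < 3.2  # ~sqrt(4) = 2

    def test_too_few_observations_rejected(self, params):
        from iggkin.macro import TimecourseDataset
        data = TimecourseDataset("tiny", np.array([1.0, 2.0]),
                                 np.array([0.9, 0.8]), np.array([0.95, 0.9]))
        with pytest.raises(ValueError):
            fit_timecourse(data)


class TestMacroFit:
    def test_noise_free_joint_recovery(self):
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40))
        result = fit_macro_joint(data, seed=0)
        for name in ("k31", "Vmax", "KM"):
            assert abs(result[name] - getattr(truth, name)) \
                / getattr(truth, name) < 0.01
        # the exchange rates are recovered but barely determined, with
        # near-total mutual correlation
        assert abs(result.correlation("k12", "k21")) > 0.9

    def test_elimination_correlation_structure(self):
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40),
                                  noise_fcr=0.05, noise_th=0.05, seed=4)
        result = fit_macro_joint(data, seed=0)
        pairs = {(a, b): abs(result.correlation(a, b))
                 for a, b in (("k31", "Vmax"), ("k31", "KM"), ("Vmax", "KM"))}
        assert max(pairs, key=pairs.get) == ("Vmax", "KM")

    def test_weight_rule_variance_ratio(self):
        # with typical means (T½ ~ 30 d, FCR ~ 0.09/d) the implied T½
        # residual variance is ~1e5 times the FCR residual variance
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40))
        result = fit_macro_joint(data, seed=0)
        ratio = result.weights["implied_variance_ratio"]
        assert 0.5e5 < ratio < 2.2e5
        assert result.weights["w_thalf"] == pytest.approx(1.0 / ratio, rel=1e-12)

    def test_literal_reciprocal_rule_available(self):
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40))
        result = fit_macro_joint(data, weight_rule="literal_reciprocal", seed=0)
        assert result.weights["w_thalf"] > 1.0  # transposed convention

    def test_fixed_fit_excludes_frozen_parameters(self):
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40))
        result = fit_macro_fixed(data, {"k12": truth.k12, "k21": truth.k21},
                                 seed=0)
        assert result.parameter_names == ["k31", "Vmax", "KM"]
        assert result.correlation_matrix.shape == (3, 3)
        for name in ("k31", "Vmax", "KM"):
            assert abs(result[name] - getattr(truth, name)) \
                / getattr(truth, name) < 1e-4

    def test_fixing_wrong_values_biases_elimination_parameters(self):
        truth = pooled_macro_estimates()
        data = make_macro_dataset(truth, np.geomspace(30, 2000, 40))
        biased = fit_macro_fixed(data, {"k12": 5 * truth.k12,
                                        "k21": 5 * truth.k21}, seed=0)
        deviation = max(abs(biased[n] - getattr(truth, n)) / getattr(truth, n)
                        for n in ("k31", "Vmax", "KM"))
        assert deviation > 0.01

    def test_round_trip_from_generator(self):
        spec = PopulationSpec(n_subjects=40, exchange_cv=0.0)
        data = generate_population_macro(spec, NoiseModel(scale=0.0),
                                         NoiseModel(scale=0.0), seed=2)
        result = fit_macro_joint(data, seed=0)
        assert result["k31"] == pytest.approx(spec.k31, rel=0.01)
        assert result["Vmax"] == pytest.approx(spec.Vmax, rel=0.02)
        assert result["KM"] == pytest.approx(spec.KM, rel=0.02)

    def test_insufficient_data_rejected(self):
        truth = pooled_macro_estimates()
        with pytest.raises(ValueError):
            fit_macro_joint(make_macro_dataset(truth, [100.0, 200.0, 300.0,
                                                       400.0]))
        with pytest.raises(ValueError):
            fit_macro_joint(make_macro_dataset(truth,
                                               np.linspace(100, 400, 8)))


class TestPopulationSummary:
    def _results_from_table(self):
        table = subject_timecourse_estimates()
        results = []
        for _, row in table.iterrows():
            est = np.array([row.fcr, row.k12, row.k21])
            results.append(FitResult(
                parameter_names=["FCR", "k12", "k21"], estimates=est,
                standard_errors=np.array([row.fcr_se, row.k12_se, row.k21_se]),
                confidence_intervals=np.zeros((3, 2)),
                correlation_matrix=np.eye(3), rmse=row.rmse,
                residual_variance=0.0, n_observations=0,
                degrees_of_freedom=0))
        return results

    def test_reference_means_and_medians(self):
        summary = summarize_population(self._results_from_table())
        assert summary.mean["FCR"] == pytest.approx(0.0950, abs=5e-4)
        assert summary.median["FCR"] == pytest.approx(0.0761, abs=5e-5)
        assert summary.mean["k12"] == pytest.approx(0.383, abs=5e-4)
        assert summary.median["k12"] == pytest.approx(0.381, abs=5e-4)
        assert summary.mean["k21"] == pytest.approx(0.423, abs=5e-4)
        assert summary.median["k21"] == pytest.approx(0.378, abs=5e-4)

    def test_single_result(self):
        one = self._results_from_table()[:1]
        summary = summarize_population(one)
        assert summary.mean == summary.median
        assert summary.n_subjects == 1

    def test_inconsistent_parameter_sets_rejected(self):
        results = self._results_from_table()
        results[1].parameter_names = ["a", "b", "c"]
        with pytest.raises(ValueError):
            summarize_population(results)
        with pytest.raises(ValueError):
            summarize_population([])
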