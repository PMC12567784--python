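import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanopbtk as npk
from nanopbtk.evaluate import ObservedDataset

positive_list = st.lists(st.floats(min_value=1e-3, max_value=1e6),
                         min_size=1, max_size=20)


class TestAafe:
    @pytest.mark.parametrize("sim,meas,expected", [
        ([1.0, 5.0, 10.0], [1.0, 5.0, 10.0], 1.0),
        ([2.0, 10.0], [1.0, 5.0], 2.0),
        ([10.0, 1000.0], [100.0, 100.0], 10.0),
    ])
    def test_known_values(self, sim, meas, expected):
        assert npk.aafe(sim, meas) == pytest.approx(expected)

    def test_symmetry(self):
        sim, meas = [3.0, 7.0, 0.2], [1.0, 10.0, 0.5]
        assert npk.aafe(sim, meas) == pytest.approx(npk.aafe(meas, sim))

    def test_non_positive_is_an_error(self):
        with pytest.raises(ValueError):
            npk.aafe([1.0, 0.0], [1.0, 1.0])

    @given(values=positive_list, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_multiplicative_invariance(self, values, c):
        meas = np.asarray(values)
        sim = meas * 1.7
        assert npk.aafe(c * sim, c * meas) == pytest.approx(
            npk.aafe(sim, meas), rel=1e-9)

    def test_at_least_one(self):
        assert npk.aafe([0.3], [2.7]) >= 1.0


class TestRelativeError:
    @pytest.mark.parametrize("sim,meas,expected",
                             [(158, 158, 0.0), (120, 100, 20.0), (50, 100, 50.0)])
    def test_known_values(self, sim, meas, expected):
        assert npk.relative_error(sim, meas) == pytest.approx(expected)

    def test_zero_measurement_is_an_error(self):
        with pytest.raises(ValueError):
            npk.relative_error(1.0, 0.0)


class TestRSquared:
    def test_identity_is_perfect(self):
        values = [1.0, 10.0, 100.0, 55.0]
        assert npk.r_squared(values, values) == pytest.approx(1.0)

    def test_affine_is_perfect_in_linear_space(self):
        meas = np.array([1.0, 2.0, 5.0, 9.0])
        assert npk.r_squared(3 * meas + 1, meas, space="linear") == \
            pytest.approx(1.0)

    def test_square_kills_sign(self):
        meas = np.array([1.0, 2.0, 5.0, 9.0])
        anti = meas[::-1]
        assert npk.r_squared(anti, meas, space="linear") == pytest.approx(
            npk.r_squared(meas, anti, space="linear"))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            npk.r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFoldBand:
    def test_identity_inside(self):
        assert npk.fold_band_fraction([5.0, 7.0], [5.0, 7.0]) == 1.0

    def test_threefold_outside(self):
        assert npk.fold_band_fraction([3.0, 30.0], [1.0, 10.0]) == 0.0

    def test_mixed_ratios(self):
        meas = np.array([1.0, 1.0, 1.0, 1.0])
        sim = np.array([0.4, 1.0, 1.9, 2.5])
        assert npk.fold_band_fraction(sim, meas) == 0.5


class TestHalfLife:
    def test_pure_exponential(self):
        t = np.linspace(0, 700, 701)
        series = pd.Series(8.0 * np.exp(-np.log(2) / 100.0 * t), index=t)
        assert npk.half_life(series) == pytest.approx(100.0, rel=1e-9)

    def test_scale_invariance(self, kreyling_observables):
        series = kreyling_observables["liver"]
        assert npk.half_life(37.0 * series) == pytest.approx(
            npk.half_life(series), rel=1e-12)

    def test_constant_series_reports_no_elimination(self):
        t = np.linspace(1, 100, 100)
        assert npk.half_life(pd.Series(np.ones_like(t), index=t)) is None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            npk.half_life(pd.Series([1.0], index=[5.0]))


class TestLocalSensitivity:
    @staticmethod
    def _double(response):
        """Wrap a closed-form response theta -> y(times) as a simulator."""
        def simulator(params, scenario, times, observables, rtol, atol):
            theta = params.get("chemical.liver.P")
            return {"y": response(theta, np.asarray(times))}
        return simulator

    def test_power_law_response(self, params, kreyling):
        res = npk.local_sensitivity(
            params, kreyling.scenario, "chemical.liver.P", "y", [1.0, 5.0],
            simulator=self._double(lambda th, t: th**2 * np.ones_like(t)))
        np.testing.assert_allclose(res.coefficients, 2.0, atol=1e-10)
        assert res.aggregate == pytest.approx(2.0)

    def test_independent_output_has_zero_sensitivity(self, params, kreyling):
        res = npk.local_sensitivity(
            params, kreyling.scenario, "chemical.liver.P", "y", [1.0],
            simulator=self._double(lambda th, t: 42.0 * np.ones_like(t)))
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_finite_difference_matches_analytic_decay(self, params, kreyling):
        """One-compartment decay y = exp(-k t): d ln y / d ln k = -k t."""
        k0 = params.get("chemical.liver.P")  # reuse a positive registry slot
        times = np.array([0.5, 1.5, 2.5]) / k0  # keep k*t small and smooth
        res = npk.local_sensitivity(
            params, kreyling.scenario, "chemical.liver.P", "y", times,
            simulator=self._double(lambda th, t: np.exp(-th * t)))
        np.testing.assert_allclose(res.coefficients, -k0 * times, atol=1e-4)

    def test_step_size_robustness_on_pbtk(self, params, kreyling):
        """Halving h barely moves S: the model response is smooth in theta."""
        times = [24.0, 168.0]
        a = npk.local_sensitivity(params, kreyling.scenario, "P_lu", "liver",
                                  times, h=0.01)
        b = npk.local_sensitivity(params, kreyling.scenario, "P_lu", "liver",
                                  times, h=0.005)
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-2)

    def test_non_positive_theta_rejected(self, params, kreyling):
        p = params.with_overrides({"chemical.liver.K_max": 0.0})
        with pytest.raises(ValueError):
            npk.local_sensitivity(p, kreyling.scenario, "chemical.liver.K_max",
                                  "liver", [1.0])


class TestPerturbationStudy:
    def test_unit_factor_is_identity(self, params, kreyling):
        study = npk.perturbation_study(params, kreyling.scenario, "P_lu",
                                       factors=(1.0,), outputs=("liver",),
                                       t_end=48.0)
        pd.testing.assert_frame_equal(study.perturbed[1.0], study.baseline)

    def test_inert_parameter_changes_nothing(self, params, kreyling):
        # no upper-airway deposit in this scenario, so its clearance is idle
        study = npk.perturbation_study(params, kreyling.scenario,
                                       "respiratory.K_upp_feces",
                                       factors=(2.0,), outputs=("lung",),
                                       t_end=48.0)
        pd.testing.assert_frame_equal(study.perturbed[2.0], study.baseline)

    def test_alveolar_interstitial_transfer_direction(self, params, kreyling):
        """Faster alveolar-to-interstitium transfer must deplete the alveolar
        surface and load the lung interstitium, at every positive time."""
        study = npk.perturbation_study(params, kreyling.scenario,
                                       "K_alv_inter",
                                       outputs=("alveolar", "lung"),
                                       t_end=100.0)
        up, down = study.perturbed[2.0], study.perturbed[0.5]
        positive = up.index > 0
        assert np.all(up.loc[positive, "alveolar"]
                      < down.loc[positive, "alveolar"])
        assert np.all(up.loc[positive, "lung"] > down.loc[positive, "lung"])

    def test_invalid_factor(self, params, kreyling):
        with pytest.raises(ValueError):
            npk.perturbation_study(params, kreyling.scenario, "P_lu",
                                   factors=(0.0,))


class TestFitParameters:
    def test_empty_free_list_returns_input(self, params, kreyling):
        dataset = npk.generate_observed(params, kreyling, noise_cv=0.0,
                                        replicates=1, seed=0)
        fit = npk.fit_parameters(params, kreyling.scenario, dataset, free=[])
        assert fit.params == params
        assert fit.objective == pytest.approx(0.0, abs=1e-10)

    def test_truth_start_stays_at_truth(self, params, kreyling):
        dataset = npk.generate_observed(params, kreyling, noise_cv=0.0,
                                        replicates=1, seed=0)
        fit = npk.fit_parameters(params, kreyling.scenario, dataset,
                                 free=["P_lu"])
        assert fit.objective == pytest.approx(0.0, abs=1e-8)
        assert fit.params.get("P_lu") == pytest.approx(30359.0, rel=1e-3)

    def test_empty_dataset_is_an_error(self, params, kreyling):
        empty = ObservedDataset(pd.DataFrame(
            columns=["observable", "time_h", "mean_ng", "sd_ng"]))
        with pytest.raises(ValueError):
            npk.fit_parameters(params, kreyling.scenario, empty, free=["P_lu"])


class TestObservedDataset:
    def test_csv_round_trip(self, tmp_path):
        ds = ObservedDataset.from_records(
            [("liver", 4.0, 3.2, 0.4), ("lung", 24.0, 500.0, 20.0)])
        path = tmp_path / "observed.csv"
        ds.to_csv(path)
        back = ObservedDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.records, ds.records)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ObservedDataset(pd.DataFrame({"organ": ["liver"]}))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ObservedDataset.from_records([("liver", -1.0, 3.0, 0.1)])
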