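"""Descriptive kinetics, scaling-factor fitting and prediction-error metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from e2pbk import (
    KINETIC_SETS,
    TABLE4_PRINTED_SF,
    FitError,
    ObservedSeries,
    ParameterError,
    TimeCourse,
    TransportKinetics,
    catalytic_efficiency,
    fit_scaling_factor,
    fold_deviation,
    fold_range,
    hepatocellularity_scaling_factor,
    summarize_scaling_factors,
)
from e2pbk.synthetic import StudyDesign, generate_observed


class TestCatalyticEfficiency:
    @pytest.mark.parametrize(
        "label, expected",
        [("brouwer", 32.8), ("ishizuka", 72.3), ("kouzuki", 100.775), ("brock_vore", 35.6)],
    )
    def test_published_hepatocyte_sets(self, label, expected):
        assert catalytic_efficiency(KINETIC_SETS[label]) == pytest.approx(expected, abs=0.1)

    def test_identity(self):
        assert catalytic_efficiency(TransportKinetics(km=1.0, vmax_invitro=1.0)) == 1.0


class TestFoldRange:
    def test_km_spread_across_hepatocyte_studies(self):
        kms = [k.km for k in KINETIC_SETS.values()]
        assert fold_range(kms) == pytest.approx(45.5 / 4.54, rel=1e-12)
        assert fold_range(kms) <= 11.0

    def test_catalytic_efficiency_spread_is_much_tighter(self):
        ces = [catalytic_efficiency(k) for k in KINETIC_SETS.values()]
        assert fold_range(ces) == pytest.approx(3.07, abs=0.01)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20))
    def test_at_least_one_and_scale_invariant(self, values):
        r = fold_range(values)
        assert r >= 1.0
        assert fold_range([v * 7.3 for v in values]) == pytest.approx(r, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_range([])
        with pytest.raises(ValueError):
            fold_range([1.0, 0.0])


def test_hepatocellularity_cross_check_brackets_the_calibrated_range():
    lo = hepatocellularity_scaling_factor(117e6, 0.985)
    hi = hepatocellularity_scaling_factor(135e6, 0.985)
    assert round(lo) == 115
    assert 115 <= lo < hi <= 133


class TestSummarize:
    def test_published_per_pair_values(self):
        s = summarize_scaling_factors(TABLE4_PRINTED_SF)
        assert s.n == 24
        assert s.mean == pytest.approx(125.125, abs=1e-9)
        assert s.sem == pytest.approx(23.4233, abs=1e-3)

    def test_single_and_constant_inputs_have_zero_sem(self):
        assert summarize_scaling_factors([100.0]).sem == 0.0
        s = summarize_scaling_factors([100.0, 100.0, 100.0])
        assert s.mean == 100.0 and s.sem == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_scaling_factors([])


class TestFitScalingFactor:
    @pytest.mark.parametrize("endpoint", ["blood", "bile"])
    def test_noiseless_round_trip_recovers_truth(self, brouwer, endpoint):
        design = StudyDesign(endpoint, 81.0, 1.0 if endpoint == "blood" else 2.0, 8,
                             "round_trip")
        obs = generate_observed(design, 129.0, brouwer)
        fit = fit_scaling_factor(obs, brouwer)
        assert fit.converged
        assert fit.sf == pytest.approx(129.0, rel=0.01)
        assert 5.0 <= fit.sf <= 500.0

    def test_lower_bound_recovery(self, brouwer):
        design = StudyDesign("blood", 81.0, 1.0, 8, "boundary")
        obs = generate_observed(design, 5.0, brouwer)
        fit = fit_scaling_factor(obs, brouwer)
        assert fit.sf == pytest.approx(5.0, abs=1.0)

    def test_returned_objective_beats_every_grid_point(self, brouwer):
        from e2pbk.calibration import _objective
        from e2pbk import PartitionCoefficients, PhysiologyParams

        design = StudyDesign("bile", 48.0, 1.5, 9, "grid_check")
        obs = generate_observed(design, 200.0, brouwer)
        fit = fit_scaling_factor(obs, brouwer)
        phys, pc = PhysiologyParams(), PartitionCoefficients()
        for sf in np.arange(5.0, 501.0, 25.0):
            assert fit.objective <= _objective(sf, obs, brouwer, phys, pc, False) + 1e-12

    def test_across_kinetic_sets_fitted_sf_spread_stays_bounded(self, kouzuki, brouwer):
        # one observed series, all four hepatocyte data sets: the fitted
        # scaling factors may differ but not wildly (CE spread is ~3-fold)
        design = StudyDesign("blood", 81.0, 1.0, 8, "spread")
        obs = generate_observed(design, 129.0, brouwer)
        sfs = [fit_scaling_factor(obs, k).sf for k in KINETIC_SETS.values()]
        assert fold_range(sfs) <= 20.0

    def test_degenerate_observations_rejected(self, brouwer):
        with pytest.raises(FitError):
            fit_scaling_factor(
                ObservedSeries("blood", [0.5, 1.0], [0.0, 0.0], dose=81.0), brouwer
            )
        with pytest.raises(FitError):
            fit_scaling_factor(
                ObservedSeries("blood", [0.5], [1.0], dose=81.0), brouwer
            )

    def test_bad_bounds_rejected(self, brouwer):
        obs = ObservedSeries("blood", [0.5, 1.0], [1e-4, 5e-5], dose=81.0)
        with pytest.raises(ParameterError):
            fit_scaling_factor(obs, brouwer, bounds=(0.0, 500.0))


class TestFoldDeviation:
    def _tc(self, times, values):
        return TimeCourse(np.asarray(times, float), np.asarray(values, float),
                          np.zeros(len(times)))

    def test_identical_series_fold_one(self):
        obs = ObservedSeries("blood", [0.5, 1.0], [2.0, 1.0], dose=81.0)
        tc = self._tc([0.0, 0.5, 1.0], [4.0, 2.0, 1.0])
        folds, gmean, excluded = fold_deviation(tc, obs)
        assert np.allclose(folds, 1.0) and gmean == pytest.approx(1.0)
        assert excluded == 0

    def test_uniform_twofold_overprediction(self):
        obs = ObservedSeries("blood", [0.5, 1.0], [1.0, 2.0], dose=81.0)
        tc = self._tc([0.0, 0.5, 1.0], [4.0, 2.0, 4.0])
        _, gmean, _ = fold_deviation(tc, obs)
        assert gmean == pytest.approx(2.0)

    def test_fold_is_direction_symmetric(self):
        # 2× over at one point, 2× under at the other -> geometric mean 2
        obs = ObservedSeries("blood", [0.5, 1.0], [1.0, 2.0], dose=81.0)
        tc = self._tc([0.0, 0.5, 1.0], [3.0, 2.0, 1.0])
        _, gmean, _ = fold_deviation(tc, obs)
        assert gmean == pytest.approx(2.0)
        # swapping prediction and observation leaves the folds unchanged
        obs_swapped = ObservedSeries("blood", [0.5, 1.0], [2.0, 1.0], dose=81.0)
        tc_swapped = self._tc([0.0, 0.5, 1.0], [0.0, 1.0, 2.0])
        _, gmean_swapped, _ = fold_deviation(tc_swapped, obs_swapped)
        assert gmean_swapped == pytest.approx(gmean)

    def test_zero_pairs_excluded_and_counted(self):
        obs = ObservedSeries("bile", [0.0, 0.5, 1.0], [0.0, 10.0, 20.0], dose=81.0)
        tc = TimeCourse(np.array([0.0, 0.5, 1.0]), np.zeros(3),
                        np.array([0.0, 10.0, 20.0]))
        folds, gmean, excluded = fold_deviation(tc, obs)
        assert excluded == 1 and folds.size == 2

    def test_all_zero_pairs_is_an_error(self):
        obs = ObservedSeries("bile", [0.0, 0.5], [0.0, 0.0], dose=81.0)
        tc = TimeCourse(np.array([0.0, 0.5]), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            fold_deviation(tc, obs)


class TestObservedSeriesValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ParameterError):
            ObservedSeries("blood", [1.0, 0.5], [1.0, 2.0], dose=81.0)

    def test_bile_above_100_percent_rejected(self):
        with pytest.raises(ParameterError):
            ObservedSeries("bile", [0.5, 1.0], [50.0, 101.0], dose=81.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ParameterError):
            ObservedSeries("blood", [0.5, 1.0], [1.0, -0.1], dose=81.0)
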