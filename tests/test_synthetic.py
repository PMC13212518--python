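"""Synthetic cohort generator: schedules, noise model, cohorts, rendering."""

import numpy as np
import pytest

from caulipheno.calibration import calibrate_from_ruler
from caulipheno.models import evaluate_model, fit_model
from caulipheno.synthetic import (AcquisitionSchedule, DEFAULT_ARCHETYPES,
                                  PlantTruth, render_label_mask,
                                  simulate_cohort, simulate_curd_series,
                                  simulate_leaf_series,
                                  sine_params_from_landmarks)

from conftest import RICHARDS_TRUTH, SINE_TRUTH, make_truth


class TestSchedule:
    def test_three_day_cadence_then_daily(self):
        sched = AcquisitionSchedule(base_interval=3)
        days = sched.sampling_days(end_day=75, first_curd_day=70)
        assert days[0] == 1 and np.all(np.diff(days[days < 70]) == 3)
        dense = days[days >= 70]
        np.testing.assert_allclose(dense, np.arange(70, 76))

    def test_no_densification_without_curd(self):
        sched = AcquisitionSchedule()
        days = sched.sampling_days(end_day=30)
        np.testing.assert_allclose(days, np.arange(1, 31, 3))

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule(base_interval=1, dense_interval=3)

    def test_camera_height_switch(self):
        sched = AcquisitionSchedule()
        assert sched.camera_height(70) == 1.5
        assert sched.camera_height(71) == 2.2


class TestLeafSimulation:
    def test_zero_noise_identity(self, clean_leaf_series):
        expected = evaluate_model("richards", RICHARDS_TRUTH, clean_leaf_series.days)
        np.testing.assert_allclose(clean_leaf_series.values, expected)

    def test_noise_cv_monte_carlo(self, schedule):
        """1000 replicate draws at day 55 have sample CV in [0.017, 0.023]."""
        truth = make_truth(noise_cv=0.02)
        idx = None
        vals = []
        for seed in range(1000):
            s = simulate_leaf_series(truth, schedule, seed=seed)
            if idx is None:
                idx = int(np.nonzero(s.days == 55.0)[0][0])
            vals.append(s.values[idx])
        vals = np.array(vals)
        cv = vals.std(ddof=1) / vals.mean()
        assert 0.017 <= cv <= 0.023

    def test_deterministic_for_fixed_seed(self, schedule):
        truth = make_truth(noise_cv=0.05)
        a = simulate_leaf_series(truth, schedule, seed=9)
        b = simulate_leaf_series(truth, schedule, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlantTruth("p", "g", 1,
                       {"a": float("inf"), "k": 0.1, "tc": 50, "d": 1.5},
                       dict(SINE_TRUTH), 70, 85)


class TestCurdSimulation:
    def test_series_starts_at_appearance(self, clean_curd_series):
        assert clean_curd_series.days[0] >= 70.0

    def test_zero_noise_sine_values(self, clean_curd_series):
        expected = evaluate_model("sine", SINE_TRUTH, clean_curd_series.days)
        np.testing.assert_allclose(clean_curd_series.values, expected)

    def test_harvest_beyond_half_period_rejected(self, schedule):
        truth = make_truth(harvest=130.0)  # past tc + w/2 = 115
        with pytest.raises(ValueError):
            simulate_curd_series(truth, schedule)

    def test_landmark_construction_passes_through_anchors(self):
        params = sine_params_from_landmarks(70.0, 85.0, 8.0, 350.0, -0.3)
        assert evaluate_model("sine", params, 70.0) == pytest.approx(8.0)
        assert evaluate_model("sine", params, 85.0) == pytest.approx(350.0)
        # whole observed arc inside the monotone-increasing half period
        assert params["tc"] - params["w"] / 2 <= 70.0
        assert 85.0 <= params["tc"] + params["w"] / 2


class TestCohort:
    def test_default_cohort_size(self, cohort_bundle):
        cohort = cohort_bundle["cohort"]
        assert len(cohort.plant_ids) == 141
        assert cohort.truth["germplasm_id"].nunique() == 47

    def test_small_cohort(self):
        import dataclasses

        archetypes = tuple(dataclasses.replace(a, n_germplasms=1)
                           for a in DEFAULT_ARCHETYPES[:2])
        c = simulate_cohort(archetypes, replicates=1, seed=0)
        assert len(c.plant_ids) == 2 and len(c.truth) == 2

    def test_truth_table_byte_identical_across_runs(self):
        import dataclasses

        archetypes = tuple(dataclasses.replace(a, n_germplasms=2)
                           for a in DEFAULT_ARCHETYPES)
        a = simulate_cohort(archetypes, replicates=2, seed=3)
        b = simulate_cohort(archetypes, replicates=2, seed=3)
        assert a.truth.to_csv(index=False) == b.truth.to_csv(index=False)

    def test_series_days_strictly_increasing(self, cohort_bundle):
        cohort = cohort_bundle["cohort"]
        for store in (cohort.leaf_series, cohort.curd_series):
            for s in store.values():
                assert np.all(np.diff(s.days) > 0)

    def test_archetype_size_ordering(self, cohort_bundle):
        """The large high-yield archetype has the largest final leaf areas."""
        cohort = cohort_bundle["cohort"]
        finals = {}
        truth = cohort.truth.set_index("plant_id")
        for pid, s in cohort.leaf_series.items():
            finals.setdefault(truth.loc[pid, "archetype"], []).append(s.final_value)
        means = {k: np.mean(v) for k, v in finals.items()}
        assert max(means, key=means.get) == "large_highyield"
        assert min(means, key=means.get) == "midmaturity_compact"

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(replicates=0)

    def test_zero_noise_cohort_identifiable(self):
        """Noise-free generation refits to the generating parameters."""
        import dataclasses

        arch = dataclasses.replace(
            DEFAULT_ARCHETYPES[0], n_germplasms=2,
            params={**DEFAULT_ARCHETYPES[0].params, "noise_cv": (0.0, 0.0)},
        )
        c = simulate_cohort((arch,), replicates=1, seed=4)
        truth = c.truth.set_index("plant_id")
        for pid in c.plant_ids:
            lf = fit_model(c.leaf_series[pid], "richards")
            sf = fit_model(c.curd_series[pid], "sine")
            for p in ("a", "k", "tc", "d"):
                assert lf.params[p] == pytest.approx(truth.loc[pid, f"leaf_{p}"],
                                                     rel=1e-3)
            for p in ("y0", "A", "tc", "w"):
                assert sf.params[p] == pytest.approx(truth.loc[pid, f"curd_{p}"],
                                                     rel=1e-3)


class TestRenderMask:
    PROFILE = calibrate_from_ruler(30.0, 600.0, 1.5)  # 0.0025 cm^2/px

    def test_zero_curd_has_no_code_two(self):
        mask, boxes = render_label_mask(25.0, 0.0, self.PROFILE, seed=0)
        assert not np.any(mask == 2)
        assert boxes["curd"] is None

    def test_pixel_count_within_two_percent(self):
        mask, _ = render_label_mask(25.0, 0.0, self.PROFILE, canvas=(300, 300),
                                    seed=1)
        count = int(np.sum(mask == 1))
        assert count == pytest.approx(25.0 / self.PROFILE.pixel_to_area, rel=0.02)

    def test_curd_nested_inside_plant(self):
        mask, boxes = render_label_mask(100.0, 20.0, self.PROFILE,
                                        canvas=(500, 500), seed=2)
        curd, plant = boxes["curd"], boxes["plant"]
        assert curd.x >= plant.x and curd.y >= plant.y
        assert curd.x + curd.width <= plant.x + plant.width
        # both classes hit their requested pixel budgets
        for code, area in ((1, 100.0), (2, 20.0)):
            assert int(np.sum(mask == code)) == pytest.approx(
                area / self.PROFILE.pixel_to_area, rel=0.02)

    def test_oversized_area_rejected(self):
        with pytest.raises(ValueError):
            render_label_mask(10000.0, 0.0, self.PROFILE, canvas=(100, 100))

    def test_curd_larger_than_plant_rejected(self):
        with pytest.raises(ValueError):
            render_label_mask(10.0, 20.0, self.PROFILE)
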