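"""Sensitivity framework: signal/error SD composition, Theta, relative
sensitivity, equivalent sampling intensity, trend, time-to-detect."""

import math

import numpy as np
import pytest

from bcsense.records import weekly_animal_means
from bcsense.reference import load_reference_components, load_reference_rates
from bcsense.sensitivity import (
    BETWEEN_ANIMALS,
    CHANGE_OVER_TIME,
    SamplingDesign,
    actual_sd,
    contrast_spec,
    equivalent_samplers,
    error_sd,
    rate_of_change,
    relative_sensitivity,
    sensitivity,
    summary_from_components,
    time_to_detect,
)
from bcsense.simulate import GenerativeModel, HerdDesign, simulate_herd


@pytest.fixture(scope="module")
def ref():
    return load_reference_components()


class TestDivisors:
    def test_camera_change_divisors_match_sampling_structure(self):
        spec = contrast_spec("camera", CHANGE_OVER_TIME)
        assert spec.divisors == {
            "WD": 7, "WC": 2, "WDM": 14, "WDA": 7, "WDC": 14, "WAC": 2,
            "WDMA": 14, "WDMC": 14, "WDAC": 14, "WDMAC": 14, "eps": 14,
        }

    def test_camera_between_divisors(self):
        spec = contrast_spec("camera", BETWEEN_ANIMALS)
        assert spec.divisors == {
            "AC": 2, "WDA": 7, "WAC": 2, "WDMA": 14, "WDAC": 14,
            "WDMAC": 14, "eps": 14,
        }

    def test_visual_divisors_are_the_scorer_count(self):
        for kind in (CHANGE_OVER_TIME, BETWEEN_ANIMALS):
            spec = contrast_spec("visual", kind)
            assert set(spec.divisors.values()) == {3}

    def test_device_main_effects_are_excluded_from_error(self):
        for method, kind in (("camera", CHANGE_OVER_TIME), ("visual", BETWEEN_ANIMALS)):
            spec = contrast_spec(method, kind)
            assert "C" not in spec.divisors and "S" not in spec.divisors

    def test_error_sd_monotone_in_divisors(self, ref):
        comps = ref["refined_camera"]
        base = contrast_spec("camera", CHANGE_OVER_TIME)
        bigger = contrast_spec(
            "camera", CHANGE_OVER_TIME,
            SamplingDesign(n_days=14, n_milkings=4, n_cameras=4),
        )
        assert error_sd(comps, bigger) < error_sd(comps, base)


class TestReferenceArithmetic:
    """Exact composition of the published variance components."""

    def test_actual_sds(self, ref):
        assert actual_sd(ref["visual"], CHANGE_OVER_TIME) == pytest.approx(0.139, abs=5e-4)
        assert actual_sd(ref["refined_camera"], BETWEEN_ANIMALS) == pytest.approx(0.232, abs=5e-4)

    def test_error_sds(self, ref):
        sm = error_sd(ref["refined_camera"], contrast_spec("camera", CHANGE_OVER_TIME))
        assert sm == pytest.approx(0.026, abs=5e-4)
        sm = error_sd(ref["visual"], contrast_spec("visual", BETWEEN_ANIMALS))
        assert sm == pytest.approx(0.090, abs=5e-4)

    def test_sensitivity_ratio(self, ref):
        sa = actual_sd(ref["refined_camera"], CHANGE_OVER_TIME)
        sm = error_sd(ref["refined_camera"], contrast_spec("camera", CHANGE_OVER_TIME))
        assert sensitivity(sa, sm) == pytest.approx(6.2, abs=0.1)

    def test_relative_sensitivity_and_equivalent_scorers(self, ref):
        theta = {}
        for name, model in (("refined_camera", "camera"), ("raw_camera", "camera"), ("visual", "visual")):
            sa = actual_sd(ref[name], CHANGE_OVER_TIME)
            sm = error_sd(ref[name], contrast_spec(model, CHANGE_OVER_TIME))
            theta[name] = sensitivity(sa, sm)
        rs_refined = relative_sensitivity(theta["refined_camera"], theta["visual"])
        rs_raw = relative_sensitivity(theta["raw_camera"], theta["visual"])
        assert rs_refined == pytest.approx(3.7, abs=0.1)
        assert equivalent_samplers(rs_refined, 3) == 41
        assert equivalent_samplers(rs_raw, 3) == 14

    def test_detect_days_from_printed_values(self):
        assert time_to_detect(0.083, -0.17) == pytest.approx(44, abs=1)
        assert time_to_detect(0.026, -0.19) == pytest.approx(12, abs=1)


class TestProperties:
    def test_all_zero_components_give_zero_sds(self):
        zeros = {t: 0.0 for t in ("W", "A", "WA", "WS", "AS", "S", "eps")}
        assert actual_sd(zeros, CHANGE_OVER_TIME) == 0.0
        assert error_sd(zeros, contrast_spec("visual", CHANGE_OVER_TIME)) == 0.0

    def test_theta_scale_invariance(self):
        assert sensitivity(0.3, 0.1) == pytest.approx(sensitivity(0.6, 0.2))
        assert sensitivity(1.0, 1.0) == 1.0

    def test_theta_undefined_for_zero_error(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity(0.3, 0.0)

    def test_rs_reciprocity(self):
        assert relative_sensitivity(3.0, 2.0) * relative_sensitivity(2.0, 3.0) == pytest.approx(1.0)
        assert relative_sensitivity(2.0, 2.0) == 1.0

    def test_equivalent_samplers_identity(self):
        assert equivalent_samplers(1.0, 3) == 3

    def test_missing_term_is_reported_by_name(self):
        with pytest.raises(KeyError, match="WA"):
            actual_sd({"W": 0.01, "A": 0.02}, CHANGE_OVER_TIME)
        with pytest.raises(KeyError, match="eps"):
            error_sd({"WS": 0.01}, contrast_spec("visual", CHANGE_OVER_TIME))


class TestRateOfChange:
    def test_flat_series_has_zero_slope(self):
        means = weekly_animal_means(_constant_frame())
        assert rate_of_change(means) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        import pandas as pd

        weeks = np.arange(1, 9)
        t_months = (weeks - 1) * 7 / 30.44
        means = pd.DataFrame({
            "animal_id": "cow001", "week": weeks, "method": "camera",
            "mean_value": 5.0 - 0.2 * t_months, "n_contributing": 14,
        })
        assert rate_of_change(means) == pytest.approx(-0.2, abs=1e-10)

    def test_single_week_is_degenerate(self):
        import pandas as pd

        means = pd.DataFrame({
            "animal_id": ["a", "b"], "week": [1, 1], "method": "camera",
            "mean_value": [4.0, 5.0], "n_contributing": [3, 3],
        })
        with pytest.raises(ValueError):
            rate_of_change(means)

    def test_simulated_trend_recovered(self):
        model = GenerativeModel()
        slopes = [
            rate_of_change(weekly_animal_means(simulate_herd(HerdDesign(), model, seed=s)[0]))
            for s in range(6)
        ]
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - model.trend_slope) < 2 * mc_se


def _constant_frame():
    from conftest import make_records

    return make_records(
        [4.0] * 6, week=[1, 1, 2, 2, 3, 3], day=[1, 2] * 3,
        milking=["AM", "PM"] * 3,
    )


class TestTimeToDetect:
    def test_zero_slope_is_infinite(self):
        assert math.isinf(time_to_detect(0.05, 0.0))

    def test_zero_error_is_instant(self):
        assert time_to_detect(0.0, -0.2) == 0.0
        assert time_to_detect(0.0, 0.0) == 0.0

    def test_sign_of_slope_is_irrelevant(self):
        assert time_to_detect(0.05, -0.2) == time_to_detect(0.05, 0.2)


class TestErrorVarianceOracle:
    def test_empirical_cow_week_mean_error_matches_composition(self):
        """Simulate pure measurement error with a few nonzero components and
        check the SD of cow-week means against the divisor composition."""
        meas = {t: 0.0 for t in (
            "C", "WD", "WC", "AC", "WDM", "WDA", "WDC", "WAC",
            "WDMA", "WDMC", "WDAC", "WDMAC", "eps")}
        meas.update({"WD": 0.01, "WDM": 0.01, "eps": 0.05})
        model = GenerativeModel(
            trend_slope=0.0,
            biological={"W": 0.0, "A": 0.0, "WA": 0.0},
            camera_measurement=meas,
        )
        design = HerdDesign(n_animals=100, n_weeks=25)
        variances = []
        for seed in range(5):
            cam, _ = simulate_herd(design, model, seed=seed)
            means = weekly_animal_means(cam)["mean_value"]
            variances.append(means.var(ddof=1))
        expected = error_sd(model.camera_measurement, contrast_spec("camera", CHANGE_OVER_TIME)) ** 2
        assert np.mean(variances) == pytest.approx(expected, rel=0.10)


def test_summary_table_shape_and_reference_anchor():
    comps = load_reference_components()
    rates = load_reference_rates()
    table = summary_from_components(
        comps, betas=rates["beta_per_month"].to_dict(),
        reference_method="visual",
        camera_like=("raw_camera", "refined_camera"),
    )
    assert len(table) == 6
    assert set(table["contrast"]) == {CHANGE_OVER_TIME, BETWEEN_ANIMALS}
    vis_change = table[(table["method"] == "visual") & (table["contrast"] == CHANGE_OVER_TIME)]
    assert vis_change["detect_days"].iloc[0] == pytest.approx(44, abs=1)


def test_summary_with_zero_components_surfaces_division_error():
    zeros = {
        m: {t: 0.0 for t in comps}
        for m, comps in load_reference_components().items()
    }
    with pytest.raises(ZeroDivisionError):
        summary_from_components(
            zeros, reference_method="visual",
            camera_like=("raw_camera", "refined_camera"),
        )
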