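"""REML variance components: model terms, aliasing, closed-form oracles,
cross-checks and optimizer contracts."""

import numpy as np
import pandas as pd
import pytest

from bcsense.simulate import GenerativeModel, HerdDesign, simulate_herd
from bcsense.varcomp import (
    ConvergenceError,
    ModelTerm,
    SingularModelError,
    build_model_terms,
    check_aliasing,
    reml_variance_components,
)

from conftest import make_records, one_way_anova_components, two_way_anova_components


def one_way_frame(groups=20, reps=5, sigma_a2=0.5, sigma_e2=1.0, seed=7):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(sigma_a2), groups)
    y = (a[:, None] + rng.normal(0, np.sqrt(sigma_e2), (groups, reps))).ravel()
    return make_records(
        y,
        animal=[f"g{i:02d}" for i in range(groups) for _ in range(reps)],
        day=[r % 7 + 1 for i in range(groups) for r in range(reps)],
        method="visual",
        milking=None,
        device="s1",
    ), y


class TestModelTerms:
    def test_camera_model_has_sixteen_terms(self):
        terms = build_model_terms("camera")
        assert len(terms) == 16
        assert terms[-1].name == "eps"
        names = {t.name for t in terms}
        assert {"W", "A", "C", "WD", "WA", "WC", "AC", "WDM", "WDA", "WDC",
                "WAC", "WDMA", "WDMC", "WDAC", "WDMAC", "eps"} == names

    def test_visual_model_has_seven_terms(self):
        terms = build_model_terms("visual")
        assert len(terms) == 7
        assert {t.name for t in terms} == {"W", "A", "S", "WA", "WS", "AS", "eps"}

    def test_factor_sets_are_within_each_methods_universe(self):
        for t in build_model_terms("camera"):
            assert set(t.factors) <= {"W", "D", "M", "A", "C"}
        for t in build_model_terms("visual"):
            assert set(t.factors) <= {"W", "A", "S"}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            build_model_terms("ultrasound")


class TestAliasing:
    def test_one_observation_per_cell_aliases_top_interactions(self):
        cam, _ = simulate_herd(HerdDesign(n_animals=4, n_weeks=2), GenerativeModel(), seed=0)
        report = check_aliasing(build_model_terms("camera"), cam)
        assert "WDMAC" in report.aliased_with_residual
        assert "WDMA" in report.aliased_with_residual  # one camera pass per milking

    def test_duplicate_measurements_remove_wdma_aliasing(self):
        cam, _ = simulate_herd(HerdDesign(n_animals=4, n_weeks=2), GenerativeModel(), seed=0)
        dup = cam.copy()
        dup["device_id"] = np.where(dup["device_id"] == "cam1", "cam2", "cam1")
        both = pd.concat([cam, dup], ignore_index=True)  # two cameras per milking
        report = check_aliasing(build_model_terms("camera"), both)
        assert "WDMA" not in report.aliased_with_residual
        assert "WDMAC" in report.aliased_with_residual

    def test_visual_design_has_no_aliasing(self):
        _, vis = simulate_herd(HerdDesign(n_animals=6, n_weeks=3), GenerativeModel(), seed=0)
        report = check_aliasing(build_model_terms("visual"), vis)
        assert report.constrained == ()

    def test_requesting_aliased_terms_without_dropping_raises(self):
        cam, _ = simulate_herd(HerdDesign(n_animals=4, n_weeks=2), GenerativeModel(), seed=0)
        with pytest.raises(SingularModelError, match="WDMA"):
            reml_variance_components(cam, drop_aliased=False)


class TestClosedFormOracles:
    def test_balanced_one_way_matches_anova_estimators(self):
        df, y = one_way_frame()
        terms = [ModelTerm.from_name("A"), ModelTerm.from_name("eps")]
        comp = reml_variance_components(df, terms=terms, method="visual")
        sa, se = one_way_anova_components(y, 20, 5)
        assert comp.estimates["A"] == pytest.approx(sa, rel=1e-4)
        assert comp.estimates["eps"] == pytest.approx(se, rel=1e-4)

    def test_balanced_two_way_crossed_matches_ems_estimators(self):
        rng = np.random.default_rng(13)
        A, B, R = 10, 8, 2
        ai = rng.normal(0, 0.8, A)
        bj = rng.normal(0, 0.6, B)
        cij = rng.normal(0, 0.4, (A, B))
        y = (
            ai[:, None, None] + bj[None, :, None] + cij[:, :, None]
            + rng.normal(0, 1.0, (A, B, R))
        ).ravel()
        df = make_records(
            y,
            animal=[f"a{i}" for i in range(A) for _ in range(B * R)],
            week=[b + 1 for _ in range(A) for b in range(B) for _ in range(R)],
            day=[r + 1 for _ in range(A * B) for r in range(R)],
            method="visual",
            milking=None,
            device="s1",
        )
        terms = [ModelTerm.from_name(n) for n in ("A", "W", "WA", "eps")]
        comp = reml_variance_components(df, terms=terms, method="visual")
        sa, sb, sab, se = two_way_anova_components(y, A, B, R)
        assert comp.estimates["A"] == pytest.approx(sa, rel=1e-4)
        assert comp.estimates["W"] == pytest.approx(sb, rel=1e-4)
        assert comp.estimates["WA"] == pytest.approx(sab, rel=1e-4)
        assert comp.estimates["eps"] == pytest.approx(se, rel=1e-4)

    def test_one_way_matches_statsmodels_reml(self):
        import statsmodels.formula.api as smf

        df, y = one_way_frame(seed=29)
        terms = [ModelTerm.from_name("A"), ModelTerm.from_name("eps")]
        comp = reml_variance_components(df, terms=terms, method="visual")
        d2 = pd.DataFrame({"y": y, "g": np.repeat(np.arange(20), 5)})
        fit = smf.mixedlm("y ~ 1", d2, groups=d2["g"]).fit(reml=True)
        assert comp.estimates["A"] == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-5)
        assert comp.estimates["eps"] == pytest.approx(float(fit.scale), rel=1e-5)


class TestOptimizerContracts:
    def test_residual_only_simulation_yields_near_zero_components(self):
        """Visual-model data that is pure residual noise: every non-residual
        component collapses toward zero and the residual recovers 1.0."""
        rng = np.random.default_rng(5)
        design = HerdDesign(n_animals=50, n_weeks=20, days_per_week=1,
                            milkings_per_day=1, n_scorers=3)
        model = GenerativeModel(
            trend_slope=0.0,
            biological={"W": 0.0, "A": 0.0, "WA": 0.0},
            visual_measurement={"S": 0.0, "WS": 0.0, "AS": 0.0, "eps": 1.0},
        )
        _, vis = simulate_herd(design, model, seed=5)
        assert len(vis) == 3000
        comp = reml_variance_components(vis)
        for term, est in comp.estimates.items():
            if term != "eps":
                assert est < 0.02, (term, est)
        assert 0.9 < comp.estimates["eps"] < 1.1

    def test_restricted_loglik_never_decreases(self):
        cam, vis = simulate_herd(HerdDesign(n_animals=8, n_weeks=4), GenerativeModel(), seed=8)
        for df in (vis, cam):
            comp = reml_variance_components(df)
            assert np.all(np.diff(comp.loglik_trace) >= -1e-8)

    def test_estimates_invariant_to_relabeling(self):
        _, vis = simulate_herd(HerdDesign(n_animals=8, n_weeks=4), GenerativeModel(), seed=9)
        comp = reml_variance_components(vis)
        shuffled = vis.copy()
        mapping = {f"cow{i+1:03d}": f"zz{(i * 7) % 8:02d}" for i in range(8)}
        shuffled["animal_id"] = shuffled["animal_id"].map(mapping)
        shuffled = shuffled.sample(frac=1, random_state=1).reset_index(drop=True)
        comp2 = reml_variance_components(shuffled)
        for term, est in comp.estimates.items():
            assert comp2.estimates[term] == pytest.approx(est, abs=1e-6)

    def test_components_sum_close_to_total_variance(self):
        _, vis = simulate_herd(HerdDesign(n_animals=12, n_weeks=6), GenerativeModel(), seed=10)
        comp = reml_variance_components(vis, fixed_trend=True)
        total = sum(comp.estimates.values())
        detrended = vis.copy()
        t = (detrended["week"] - 1).to_numpy(dtype=float)
        slope, icpt = np.polyfit(t, detrended["value"], 1)
        resid_var = np.var(detrended["value"] - slope * t - icpt, ddof=1)
        assert abs(total - resid_var) / resid_var < 0.15

    def test_constant_response_returns_all_zero(self):
        df = make_records([4.0] * 20, day=[i % 7 + 1 for i in range(20)],
                          week=[i // 7 + 1 for i in range(20)],
                          method="visual", milking=None, device="s1")
        terms = [ModelTerm.from_name("W"), ModelTerm.from_name("eps")]
        comp = reml_variance_components(df, terms=terms, method="visual")
        assert all(v == 0.0 for v in comp.estimates.values())
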