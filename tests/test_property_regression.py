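"""Pedotransfer regressions: ratios, screening, selection, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bgrsom as b


def props(bgr="X", dm=7.0, dm_org=30.0, ph=7.8, ct=40.0, nh4n=3.0, nt=6.5):
    return b.BGRProperties(bgr, dm, dm_org, ph, ct, nh4n, nt)


class TestDeriveRatios:
    def test_high_ammonium_digestate(self):
        p = b.derive_ratios(props(nt=6.3, nh4n=2.9, ct=38.4))
        assert p.norg == pytest.approx(3.4)
        assert p.ct_norg == pytest.approx(38.4 / 3.4, abs=0.05)
        assert p.ct_norg == pytest.approx(11.3, abs=0.05)

    def test_pure_maize_digestate(self):
        p61 = b.derive_ratios(props(nt=8.2, nh4n=5.5, ct=42.0))
        assert p61.norg == pytest.approx(2.7)
        assert p61.ct_norg == pytest.approx(15.6, abs=0.05)

    def test_no_ammonium_makes_ratios_equal(self):
        p = b.derive_ratios(props(nh4n=0.0))
        assert p.ct_norg == pytest.approx(p.ct_nt)

    def test_ammonium_exceeding_total_n_rejected(self):
        with pytest.raises(ValueError, match="N_t"):
            b.derive_ratios(props(nt=3.0, nh4n=3.5))


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = b.fit_simple_regression(x, 2 * x + 1, "x")
        assert r.slope == pytest.approx(2.0, abs=1e-12)
        assert r.intercept == pytest.approx(1.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        r = b.fit_simple_regression(x, y, "x")
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.slope == pytest.approx(slope, abs=1e-10)
        assert r.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            b.fit_simple_regression(np.ones(5), np.arange(5.0), "c")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        a=st.floats(0.1, 5.0), c=st.floats(-3.0, 3.0),
        d=st.floats(0.1, 5.0), e=st.floats(-3.0, 3.0),
    )
    def test_r_squared_affine_invariant(self, a, c, d, e):
        rng = np.random.default_rng(17)
        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(size=25)
        base = b.fit_simple_regression(x, y, "x").r_squared
        rescaled = b.fit_simple_regression(a * x + c, d * y + e, "x").r_squared
        assert rescaled == pytest.approx(base, abs=1e-9)


class TestHeadlineRegressions:
    def test_k_from_ph(self, reference_properties, reference_tables):
        _, _, params = reference_tables
        ph = [p.ph for p in reference_properties]
        r = b.fit_simple_regression(ph, params["k"], "ph")
        assert r.slope == pytest.approx(-0.710, abs=0.002)
        assert r.intercept == pytest.approx(5.996, abs=0.005)
        assert r.r_squared == pytest.approx(0.863, abs=0.003)
        assert r.p_value < 0.05

    def test_eta_from_ct_norg(self, reference_properties, reference_tables):
        _, _, params = reference_tables
        ratio = [p.ct_norg for p in reference_properties]
        r = b.fit_simple_regression(ratio, params["eta"], "ct_norg")
        assert r.slope == pytest.approx(-0.013, abs=0.001)
        assert r.intercept == pytest.approx(1.016, abs=0.005)
        assert r.r_squared == pytest.approx(0.696, abs=0.003)
        assert r.p_value < 0.05


class TestScreening:
    def test_top_predictors_on_reference_digestates(
        self, reference_properties, reference_tables
    ):
        _, _, params = reference_tables
        screen = b.screen_predictors(reference_properties, params[["k", "eta"]])
        best_k = screen[screen["parameter"] == "k"].iloc[0]
        best_eta = screen[screen["parameter"] == "eta"].iloc[0]
        assert best_k["property"] == "ph"
        assert best_eta["property"] == "ct_norg"

    def test_noise_response_matches_columnwise_ols_oracle(self, reference_properties):
        rng = np.random.default_rng(42)
        import pandas as pd

        noise = pd.DataFrame(
            {"k": rng.normal(size=6), "eta": rng.normal(size=6)},
            index=[p.bgr_id for p in reference_properties],
        )
        screen = b.screen_predictors(reference_properties, noise)
        for _, row in screen.iterrows():
            x = np.array([getattr(p, row["property"]) for p in reference_properties])
            y = noise.loc[[p.bgr_id for p in reference_properties], row["parameter"]]
            r_oracle = np.corrcoef(x, y)[0, 1] ** 2
            assert row["r_squared"] == pytest.approx(r_oracle, abs=1e-10)

    def test_schema_mismatch_rejected(self, reference_properties, reference_tables):
        _, _, params = reference_tables
        with pytest.raises(ValueError):
            b.screen_predictors(reference_properties[:-1], params[["k", "eta"]])


class TestModelSelection:
    def test_multiple_regression_refused_on_reference_fixture(
        self, reference_properties, reference_tables
    ):
        _, _, params = reference_tables
        screen = b.screen_predictors(reference_properties, params[["k", "eta"]])
        sel = b.select_model(screen, reference_properties)
        assert not sel.multiple_allowed
        blocked = {(a, b_): r for a, b_, r in sel.blocking_correlations}
        assert ("ct_norg", "ph") in blocked
        assert blocked[("ct_norg", "ph")] == pytest.approx(0.43, abs=0.01)
        assert ("norg", "ph") in blocked
        assert abs(blocked[("norg", "ph")]) == pytest.approx(0.55, abs=0.01)

    def test_orthogonal_predictors_permit_multiple_regression(self):
        # two exactly uncorrelated synthetic predictors
        import pandas as pd

        ph = np.array([7.0, 7.0, 8.0, 8.0, 9.0, 9.0])
        ratio = np.array([10.0, 14.0, 10.0, 14.0, 10.0, 14.0])
        panel = [
            b.derive_ratios(
                b.BGRProperties(f"S{i}", 7.0, 30.0, ph[i], 40.0, 0.0, 40.0 / ratio[i])
            )
            for i in range(6)
        ]
        params = pd.DataFrame(
            {"k": 5.996 - 0.710 * ph, "eta": 1.016 - 0.013 * ratio},
            index=[p.bgr_id for p in panel],
        )
        screen = b.screen_predictors(panel, params)
        sel = b.select_model(screen, panel)
        blocked_pairs = {frozenset((a, b_)) for a, b_, _ in sel.blocking_correlations}
        assert frozenset(("ct_norg", "ph")) not in blocked_pairs


class TestPrediction:
    def _models(self, reference_properties, reference_tables):
        _, _, params = reference_tables
        screen = b.screen_predictors(reference_properties, params[["k", "eta"]])
        sel = b.select_model(screen, reference_properties)
        return sel.k_model, sel.eta_model

    def test_printed_equations_evaluated(self, reference_properties, reference_tables):
        k_model, eta_model = self._models(reference_properties, reference_tables)
        p = b.derive_ratios(props(ph=7.7, ct=40.0, nt=7.0, nh4n=3.0))
        pred, _ = b.predict_parameters(p, k_model, eta_model)
        assert pred.k == pytest.approx(5.996 - 0.710 * 7.7, abs=0.01)
        p10 = b.derive_ratios(props(ph=7.8, ct=40.0, nt=7.0, nh4n=3.0))
        assert p10.ct_norg == pytest.approx(10.0)
        pred10, _ = b.predict_parameters(p10, k_model, eta_model)
        assert pred10.eta == pytest.approx(1.016 - 0.013 * 10.0, abs=0.005)

    def test_extrapolation_flagged_not_rejected(
        self, reference_properties, reference_tables
    ):
        k_model, eta_model = self._models(reference_properties, reference_tables)
        outside = b.derive_ratios(props(ph=9.2))
        pred, warnings = b.predict_parameters(outside, k_model, eta_model)
        assert warnings and "extrapolation" in warnings[0]
        assert pred.k >= 0.01  # floored, never negative

    def test_prediction_se_minimal_at_calibration_mean(
        self, reference_properties, reference_tables
    ):
        k_model, _ = self._models(reference_properties, reference_tables)
        grid = np.linspace(k_model.x_min, k_model.x_max, 21)
        ses = [k_model.prediction_se(x) for x in grid]
        assert grid[np.argmin(ses)] == pytest.approx(k_model.x_mean, abs=0.05)

    def test_round_trip_recovery_through_inverted_models(
        self, reference_properties, reference_tables
    ):
        """Properties generated by inverting the fitted models reproduce
        the parameters exactly when no noise is added."""
        k_model, eta_model = self._models(reference_properties, reference_tables)
        for k_true, eta_true in [(0.35, 0.85), (0.50, 0.87)]:
            ph = (k_true - k_model.intercept) / k_model.slope
            ratio = (eta_true - eta_model.intercept) / eta_model.slope
            nt = 3.0 + 40.0 / ratio
            p = b.derive_ratios(props(ph=ph, ct=40.0, nt=nt, nh4n=3.0))
            pred, _ = b.predict_parameters(p, k_model, eta_model)
            assert pred.k == pytest.approx(k_true, abs=1e-9)
            assert pred.eta == pytest.approx(eta_true, abs=1e-9)


class TestRangeCoverage:
    def test_study_vs_literature_range(self, reference_properties):
        cov = b.range_coverage(
            [p.ct_norg for p in reference_properties], *b.LITERATURE_CT_NORG
        )
        assert round(cov) == 27

    def test_full_span_is_hundred_percent(self):
        assert b.range_coverage([5.9, 26.4], 5.9, 26.4) == pytest.approx(100.0)

    def test_single_value_is_zero(self):
        assert b.range_coverage([12.0], 5.9, 26.4) == 0.0

    def test_zero_reference_range_rejected(self):
        with pytest.raises(ValueError):
            b.range_coverage([1.0, 2.0], 5.0, 5.0)
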