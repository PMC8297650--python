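import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uvcanopy.response import (
    AssayAbsorbance,
    FluorescenceRecord,
    HyperbolicYield,
    fit_hyperbolic,
    fit_linear_yield,
    fv_fm,
    fv_fm_is_normal,
    increase_rate,
    rsa,
    yield_report,
    YieldFit,
    Eq2Fit,
)


class TestRSA:
    @pytest.mark.parametrize(
        "ac,asample,expected", [(0.5, 0.5, 0.0), (0.5, 0.0, 100.0), (0.8, 0.2, 75.0)]
    )
    def test_hand_arithmetic(self, ac, asample, expected):
        assert rsa(AssayAbsorbance(ac, asample)) == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        ac=st.floats(0.1, 2.0), ratio=st.floats(0.0, 1.0), c=st.floats(0.1, 10.0)
    )
    def test_invariant_under_common_rescaling(self, ac, ratio, c):
        base = rsa(AssayAbsorbance(ac, ac * ratio))
        scaled = rsa(AssayAbsorbance(c * ac, c * ac * ratio))
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            AssayAbsorbance(0.0, 0.1)


class TestFvFm:
    def test_hand_arithmetic(self):
        assert fv_fm(FluorescenceRecord(300, 1500)) == pytest.approx(0.80)
        assert fv_fm(FluorescenceRecord(0, 1200)) == 1.0

    def test_healthy_range_flagging(self):
        # unstressed plants sit at 0.82-0.83 across treatments
        assert fv_fm_is_normal(0.82) and fv_fm_is_normal(0.83)
        assert not fv_fm_is_normal(0.60)

    def test_f0_above_fm_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceRecord(1600, 1500)


class TestIncreaseRate:
    def test_sign_conventions(self):
        assert increase_rate(5.0, 5.0) == 0.0
        assert increase_rate(10.0, 5.0) == pytest.approx(100.0)
        assert increase_rate(4.0, 5.0) == pytest.approx(-20.0)

    def test_scale_invariance(self):
        assert increase_rate(12.0, 8.0) == pytest.approx(increase_rate(120.0, 80.0))


class TestLinearYield:
    def test_noiseless_line_recovered(self):
        x = np.linspace(0, 130, 20)
        fit = fit_linear_yield(x, 2 * x + 5)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(5.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_zero_slope_zero_r2(self):
        x = np.linspace(0, 100, 10)
        fit = fit_linear_yield(x, np.full_like(x, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 130, 50)
        y = 0.05 * x + 8 + rng.normal(0, 0.5, 50)
        fit = fit_linear_yield(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(r2_oracle, rel=1e-9)

    def test_noisy_slope_within_three_standard_errors(self):
        g, n = 0.05, 100
        rng = np.random.default_rng(7)
        x = rng.uniform(5, 130, n)
        y = g * x + 8 + rng.normal(0, 0.4, n)
        fit = fit_linear_yield(x, y)
        assert abs(fit.slope - g) < 3 * fit.slope_se

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_yield([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_linear_yield([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestHyperbolicFits:
    def test_noiseless_f2_recovery_to_machine_precision(self):
        x = np.linspace(5, 130, 30)
        y = HyperbolicYield(60, 20, "F2").percent_increase(x)
        fit = fit_hyperbolic(x, y, "F2")
        assert fit.a == pytest.approx(60.0, rel=1e-6)
        assert fit.b == pytest.approx(20.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    @pytest.mark.parametrize("form,a,b", [("F1", 200.0, 15.0), ("F3", 150.0, 3.0)])
    def test_noiseless_alternative_forms_recovered(self, form, a, b):
        x = np.linspace(5, 130, 30)
        y = HyperbolicYield(a, b, form).percent_increase(x)
        fit = fit_hyperbolic(x, y, form)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)

    def test_wrong_form_fits_strictly_worse(self):
        x = np.linspace(5, 130, 30)
        y = HyperbolicYield(200, 15, "F1").percent_increase(x)
        right = fit_hyperbolic(x, y, "F1")
        wrong = fit_hyperbolic(x, y, "F2")
        assert right.r2 > wrong.r2

    def test_stochastic_recovery_median_over_three_seeds(self):
        a, b = 60.0, 20.0
        est = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            x = rng.uniform(5, 130, 60)
            y = HyperbolicYield(a, b, "F2").percent_increase(x)
            y = y * (1 + rng.normal(0, 0.05, 60))  # 5% noise
            fit = fit_hyperbolic(x, y, "F2", seed=seed)
            est.append((fit.a, fit.b))
        assert np.median([e[0] for e in est]) == pytest.approx(a, rel=0.10)
        assert np.median([e[1] for e in est]) == pytest.approx(b, rel=0.10)

    def test_recovery_error_decreases_with_sample_size(self):
        a, b = 60.0, 20.0

        def mean_abs_err(n, reps=8):
            errs = []
            for seed in range(reps):
                rng = np.random.default_rng(1000 + seed)
                x = rng.uniform(5, 130, n)
                y = HyperbolicYield(a, b, "F2").percent_increase(x)
                y = y * (1 + rng.normal(0, 0.05, n))
                fit = fit_hyperbolic(x, y, "F2", seed=seed)
                errs.append(abs(fit.a - a) / a)
            return np.mean(errs)

        assert mean_abs_err(300) < mean_abs_err(30)

    def test_positive_duv_required_for_singular_forms(self):
        x = np.array([0.0, 10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            fit_hyperbolic(x, x, "F3")

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperbolic([1, 2, 3], [1, 2, 3], "F9")


class TestYieldReport:
    def _fits(self):
        linear, nonlinear = [], []
        for stage in ("14DAT", "28DAT"):
            for pos in ("upper", "middle", "lower"):
                for comp in ("tfc_mg_ce_g", "tpc_mg_gae_g"):
                    linear.append(
                        YieldFit(1, 0, 0.1, 1.0, 10, position_class=pos, stage=stage,
                                 compound=comp)
                    )
                    nonlinear.append(
                        Eq2Fit(60, 20, "F2", 1.0, 10, True, position_class=pos,
                               stage=stage, compound=comp)
                    )
        return linear, nonlinear

    def test_two_stages_three_positions_six_rows(self):
        linear, nonlinear = self._fits()
        table = yield_report(linear, nonlinear)
        assert len(table) == 6
        assert list(table["Leaf position"][:3]) == ["upper", "middle", "lower"]

    def test_perfect_fits_report_unity_r2(self):
        linear, nonlinear = self._fits()
        table = yield_report(linear, nonlinear)
        r2_cols = [c for c in table.columns if c.endswith("R2")]
        assert len(r2_cols) == 4
        assert (table[r2_cols] == 1.0).all().all()

    def test_column_names_distinguish_regression_kinds(self):
        linear, nonlinear = self._fits()
        cols = yield_report(linear, nonlinear).columns
        assert any("Linear regression" in c for c in cols)
        assert any("Nonlinear regression" in c for c in cols)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            yield_report([])
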