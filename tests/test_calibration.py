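import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from spotval import calibration as cal
from spotval import simulate as sim


def _levels_xy(truth, base_cv, seed, reps_per_level=9, **config_kw):
    curves = max(reps_per_level // 3, 1)
    t = sim.AnalyteTruth(
        order=truth.order, a2=truth.a2, a1=truth.a1, a0=truth.a0,
        variance_power=truth.variance_power, base_cv=base_cv,
    )
    config = sim.SyntheticConfig(truth={"A": t}, curves_per_day=curves, seed=seed, **config_kw)
    frame = sim.generate_calibration(config)
    return cal.ratio_data(frame, 20.0)


class TestAssessVariance:
    def test_quadratic_variance_growth_selects_1_over_x2(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.05, variance_power=2.0, base_cv=0.1)
        x, y = _levels_xy(truth, 0.1, seed=1, reps_per_level=999)
        va = cal.assess_variance(x, y)
        assert va.heteroscedastic
        assert va.chosen_weighting == "1/x2"
        assert va.variance_power_estimate == pytest.approx(2.0, abs=0.25)

    def test_linear_variance_growth_selects_1_over_x(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.05, variance_power=1.0, base_cv=0.1)
        x, y = _levels_xy(truth, 0.1, seed=2, reps_per_level=999)
        va = cal.assess_variance(x, y)
        assert va.chosen_weighting == "1/x"
        assert va.variance_power_estimate == pytest.approx(1.0, abs=0.25)

    def test_constant_variance_homoscedastic(self):
        rng = np.random.default_rng(3)
        x = np.repeat([0.1, 0.25, 0.5, 1.0, 2.5, 5.0], 50)
        y = 1.0 * x + 0.05 + rng.normal(0, 0.02, x.size)
        va = cal.assess_variance(x, y)
        assert not va.heteroscedastic
        assert va.chosen_weighting == "none"

    def test_weighting_none_iff_homoscedastic(self):
        for seed in range(5):
            truth = sim.AnalyteTruth(a1=1.0, a0=0.05, variance_power=2.0, base_cv=0.08)
            x, y = _levels_xy(truth, 0.08, seed=seed)
            va = cal.assess_variance(x, y)
            assert (va.chosen_weighting == "none") == (not va.heteroscedastic)

    def test_zero_variance_everywhere_warns(self, clean_linear_frame):
        x, y = cal.ratio_data(clean_linear_frame, 20.0)
        with pytest.warns(UserWarning, match="zero variance"):
            va = cal.assess_variance(x, y)
        assert not va.heteroscedastic
        assert va.chosen_weighting == "none"

    def test_single_replicate_level_rejected(self):
        x = np.array([0.1, 0.1, 0.5, 0.5, 1.0])
        y = x.copy()
        with pytest.raises(cal.CalibrationError, match="replicates"):
            cal.assess_variance(x, y)


class TestFitCalibration:
    def test_noise_free_reference_equation_recovered(self):
        # y = 0.8092 x + 0.0579 from the packaged reference fixture
        x = np.repeat([0.1, 0.25, 0.5, 1.0, 2.5, 5.0], 3)
        y = 0.8092 * x + 0.0579
        for weighting in cal.WEIGHTINGS:
            model = cal.fit_calibration(x, y, weighting, "linear")
            assert model.a1 == pytest.approx(0.8092, abs=1e-12)
            assert model.a0 == pytest.approx(0.0579, abs=1e-12)
            assert model.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self, wls_oracle):
        rng = np.random.default_rng(7)
        for trial in range(20):
            x = rng.uniform(0.05, 5.0, size=12)
            y = rng.uniform(0.1, 10.0, size=12)
            weighting = cal.WEIGHTINGS[trial % 3]
            order = ("linear", "quadratic")[trial % 2]
            degree = 1 if order == "linear" else 2
            w = {"none": np.ones_like(x), "1/x": 1 / x, "1/x2": 1 / x**2}[weighting]
            expected = wls_oracle(x, y, w, degree)
            model = cal.fit_calibration(x, y, weighting, order)
            got = [model.a0, model.a1] + ([model.a2] if degree == 2 else [])
            assert np.allclose(got, expected, rtol=1e-8)

    def test_weight_mass_invariance(self, noisy_frame):
        x, y = cal.ratio_data(noisy_frame, 20.0)
        m1 = cal.fit_calibration(x, y, "1/x2", "linear")
        m2 = cal.fit_calibration(np.tile(x, 2), np.tile(y, 2), "1/x2", "linear")
        assert m2.a1 == pytest.approx(m1.a1, rel=1e-12)
        assert m2.a0 == pytest.approx(m1.a0, abs=1e-12)

    def test_weighted_residual_orthogonality(self, noisy_frame):
        # normal-equation identity: weighted residuals orthogonal to design columns
        x, y = cal.ratio_data(noisy_frame, 20.0)
        model = cal.fit_calibration(x, y, "1/x2", "quadratic")
        resid = y - model.predict(x)
        w = 1 / x**2
        for column in (np.ones_like(x), x, x**2):
            assert np.sum(w * resid * column) == pytest.approx(0.0, abs=1e-8)

    def test_singular_design_rejected(self):
        x = np.full(6, 1.0)
        with pytest.raises(cal.CalibrationError):
            cal.fit_calibration(x, x, "none", "linear")


class TestOrderSelection:
    def test_noise_free_linear(self):
        x = np.repeat([0.1, 0.25, 0.5, 1.0, 2.5, 5.0], 3)
        y = 0.9 * x + 0.01
        sel = cal.select_model_order(x, y, "none")
        assert sel.order == "linear"
        assert sel.mandel_f == pytest.approx(0.0, abs=1e-6)

    def test_saturating_quadratic_detected(self):
        # reference saturating response: y = -0.0538 x^2 + 5.5136 x + 0.0339
        truth = sim.AnalyteTruth(
            order="quadratic", a2=-0.0538, a1=5.5136, a0=0.0339, base_cv=0.0
        )
        x, y = _levels_xy(truth, 0.01, seed=4)
        sel = cal.select_model_order(x, y, "1/x2")
        assert sel.order == "quadratic"
        assert sel.mandel_significant

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_quadratic_never_increases_wrss(self, seed):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.1, 0.25, 0.5, 1.0, 2.5, 5.0], 3)
        y = rng.uniform(0.1, 5.0) * x + rng.normal(0, 0.1, x.size)
        w = 1 / x**2
        _, sse1 = cal._wls(x, y, w, 1)
        _, sse2 = cal._wls(x, y, w, 2)
        assert sse2 <= sse1 + 1e-10

    def test_no_replication_warns_and_uses_mandel(self):
        x = np.array([0.1, 0.25, 0.5, 1.0, 2.5, 5.0])
        y = 0.9 * x + 0.01
        with pytest.warns(UserWarning, match="Mandel"):
            sel = cal.select_model_order(x, y, "none")
        assert sel.order == "linear"
        assert sel.lof_p_linear is None


class TestBackCalculate:
    def test_reference_linear_inversion(self):
        model = cal.CalibrationModel(
            analyte_id="PFBA", order="linear", weighting="1/x2",
            a2=0.0, a1=0.8092, a0=0.0579, residual_sd=0.0, n=54,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        assert cal.back_calculate(model, 0.4625) == pytest.approx(10.0, rel=1e-9)

    def test_quadratic_monotone_branch(self):
        model = cal.CalibrationModel(
            analyte_id="L-PFHxS", order="quadratic", weighting="1/x2",
            a2=-0.0538, a1=5.5136, a0=0.0339, residual_sd=0.0, n=54,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        y = model.predict(2.5)
        # mirror root sits near 2000 ng/mL; the ascending branch must win
        assert cal.back_calculate(model, float(y)) == pytest.approx(50.0, rel=1e-9)

    def test_intercept_maps_to_zero(self):
        model = cal.CalibrationModel(
            analyte_id="A", order="linear", weighting="none",
            a2=0.0, a1=1.0, a0=0.25, residual_sd=0.0, n=18,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        assert cal.back_calculate(model, 0.25) == 0.0

    def test_no_real_root_flagged(self):
        model = cal.CalibrationModel(
            analyte_id="A", order="quadratic", weighting="none",
            a2=-0.1, a1=1.0, a0=0.0, residual_sd=0.0, n=18,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        # vertex value is 2.5; y above it has no real root
        with pytest.raises(cal.NonQuantifiableError):
            cal.back_calculate(model, 5.0)

    def test_out_of_range_root_flagged(self):
        model = cal.CalibrationModel(
            analyte_id="A", order="linear", weighting="none",
            a2=0.0, a1=1.0, a0=0.0, residual_sd=0.0, n=18,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        with pytest.raises(cal.NonQuantifiableError):
            cal.back_calculate(model, 11.0)  # 220 ng/mL > 2x upper

    @given(
        x=st.floats(0.1, 5.0),
        a1=st.floats(0.1, 10.0),
        a0=st.floats(-0.05, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_round_trip(self, x, a1, a0):
        model = cal.CalibrationModel(
            analyte_id="A", order="linear", weighting="none",
            a2=0.0, a1=a1, a0=a0, residual_sd=0.0, n=18,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        assume(float(model.predict(x)) >= 0)
        assert cal.back_calculate(model, float(model.predict(x))) == pytest.approx(
            x * 20.0, rel=1e-9
        )

    @given(x=st.floats(0.1, 5.0), a2=st.floats(-0.05, -0.001))
    @settings(max_examples=50, deadline=None)
    def test_quadratic_round_trip(self, x, a2):
        model = cal.CalibrationModel(
            analyte_id="A", order="quadratic", weighting="none",
            a2=a2, a1=1.0, a0=0.02, residual_sd=0.0, n=18,
            is_concentration=20.0, range_ng_ml=(2.0, 100.0),
        )
        assert cal.back_calculate(model, float(model.predict(x))) == pytest.approx(
            x * 20.0, rel=1e-9
        )


class TestWeightingRecovery:
    def test_recovers_generating_power_at_paper_noise(self):
        # acceptance-grade property at reduced scale: >= 90% recovery
        hits = 0
        n_sims = 60
        rng = np.random.default_rng(0)
        for i in range(n_sims):
            base_cv = rng.uniform(0.05, 0.15)
            truth = sim.AnalyteTruth(a1=1.0, a0=0.05, variance_power=2.0, base_cv=base_cv)
            x, y = _levels_xy(truth, base_cv, seed=i)
            if cal.assess_variance(x, y).chosen_weighting == "1/x2":
                hits += 1
        assert hits >= 0.9 * n_sims
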