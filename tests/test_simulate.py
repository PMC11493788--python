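import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotval import simulate as sim
from spotval.doe import full_factorial
from spotval.limits import measure_sn


class TestCalibrationGeneration:
    def test_record_count_default_design(self, pfba_truth):
        config = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=0)
        frame = sim.generate_calibration(config)
        assert len(frame) == 54  # 6 levels x 3 curves x 3 days
        assert set(frame["role"]) == {"calibrator"}

    def test_noise_free_on_truth(self, clean_linear_frame):
        y = clean_linear_frame["area_analyte"] / clean_linear_frame["area_is"]
        x = clean_linear_frame["level_ng_ml"] / 20.0
        assert np.allclose(y, 0.9 * x)

    def test_variance_power_law_k2(self):
        # ~1000 replicates per level; log-log slope of per-level variance vs x
        truth = sim.AnalyteTruth(a1=1.0, a0=0.05, variance_power=2.0, base_cv=0.1)
        config = sim.SyntheticConfig(truth={"A": truth}, curves_per_day=334, days=3, seed=5)
        frame = sim.generate_calibration(config)
        x = frame["level_ng_ml"].to_numpy() / 20.0
        y = (frame["area_analyte"] / frame["area_is"]).to_numpy()
        levels = np.unique(x)
        s2 = np.array([np.var(y[x == lv], ddof=1) for lv in levels])
        slope = np.polyfit(np.log(levels), np.log(s2), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_seed_determinism(self, pfba_truth, tmp_path):
        config = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=42)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        sim.write_measurements(sim.generate_calibration(config), a)
        sim.write_measurements(sim.generate_calibration(config), b)
        assert a.read_bytes() == b.read_bytes()
        config2 = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=43)
        c = tmp_path / "c.csv"
        sim.write_measurements(sim.generate_calibration(config2), c)
        assert a.read_bytes() != c.read_bytes()

    @given(seed=st.integers(0, 10_000), base_cv=st.floats(0.01, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_responses_always_positive(self, seed, base_cv):
        truth = sim.AnalyteTruth(a1=0.8, a0=0.01, base_cv=base_cv)
        config = sim.SyntheticConfig(truth={"A": truth}, seed=seed, day_effect_sd=0.05)
        frame = sim.generate_calibration(config)
        assert (frame["area_analyte"] > 0).all()

    def test_invalid_levels_rejected(self):
        with pytest.raises(sim.SimulationError):
            sim.SyntheticConfig(levels=(5.0, 2.0))


class TestMeErSets:
    def test_noise_free_propagation(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.0, base_cv=0.0)
        config = sim.SyntheticConfig(
            truth={"A": truth}, me_multiplier=1.28, er_multiplier=0.93, seed=0
        )
        s1, s2, s3 = sim.generate_me_er_sets(config)
        r1 = (s1["area_analyte"] / s1["area_is"]).to_numpy()
        r2 = (s2["area_analyte"] / s2["area_is"]).to_numpy()
        r3 = (s3["area_analyte"] / s3["area_is"]).to_numpy()
        assert np.allclose(r1 / r2, 1.28)
        assert np.allclose(r3 / r1, 0.93)

    def test_unit_multipliers_same_expectation(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.0, base_cv=0.0)
        config = sim.SyntheticConfig(truth={"A": truth}, me_multiplier=1.0, er_multiplier=1.0)
        s1, s2, s3 = sim.generate_me_er_sets(config)
        assert np.allclose(s1["area_analyte"], s2["area_analyte"])
        assert np.allclose(s1["area_analyte"], s3["area_analyte"])

    def test_large_enhancement_monte_carlo(self):
        # mirrors the largest-enhancement scenario of the reference table
        truth = sim.AnalyteTruth(a1=1.0, a0=0.0, base_cv=0.1)
        config = sim.SyntheticConfig(truth={"A": truth}, me_multiplier=1.93, seed=3)
        s1, s2, _ = sim.generate_me_er_sets(config, replicates=1000)
        me = []
        for level in (2.0, 15.0, 75.0):
            r1 = (s1[s1["level_ng_ml"] == level]["area_analyte"]).mean()
            r2 = (s2[s2["level_ng_ml"] == level]["area_analyte"]).mean()
            me.append(100.0 * r1 / r2)
        assert np.mean(me) == pytest.approx(193.0, abs=2.0)


class TestStabilityGeneration:
    def test_default_grid_count(self, pfba_truth):
        config = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=0)
        frame = sim.generate_stability(config)
        assert len(frame) == 54  # 3 temps x 3 times x 2 concs x 3 reps

    def test_no_degradation_no_noise_constant(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.0, base_cv=0.0)
        config = sim.SyntheticConfig(truth={"A": truth})
        frame = sim.generate_stability(config, degradation_rate=0.0)
        for _, group in frame.groupby("level_ng_ml"):
            assert group["area_analyte"].nunique() == 1

    def test_temperature_specific_decay(self):
        truth = sim.AnalyteTruth(a1=1.0, a0=0.0, base_cv=0.05)
        config = sim.SyntheticConfig(truth={"A": truth}, seed=9)
        frame = sim.generate_stability(
            config, replicates=200, degradation_rate={25.0: 0.02}
        )
        room = frame[(frame["temp_c"] == 25.0) & (frame["level_ng_ml"] == 75.0)]
        d1 = room[room["time_d"] == 1.0]["area_analyte"].mean()
        d28 = room[room["time_d"] == 28.0]["area_analyte"].mean()
        assert d28 / d1 == pytest.approx(np.exp(-0.02 * 27), rel=0.03)
        frozen = frame[(frame["temp_c"] == -20.0) & (frame["level_ng_ml"] == 75.0)]
        f1 = frozen[frozen["time_d"] == 1.0]["area_analyte"].mean()
        f28 = frozen[frozen["time_d"] == 28.0]["area_analyte"].mean()
        assert f28 / f1 == pytest.approx(1.0, rel=0.03)


class TestDoeGeneration:
    def test_matrix_shape(self):
        design = full_factorial(seed=1)
        matrix = sim.generate_doe_responses(design, sim.DoeEffects(), seed=1)
        assert matrix.shape == (9, 25)

    def test_null_effects_constant(self):
        design = full_factorial()
        matrix = sim.generate_doe_responses(design, sim.DoeEffects(intercept=2.0), seed=0)
        assert np.allclose(matrix.to_numpy(), 2.0)

    def test_time_effect_monotone(self):
        design = full_factorial()
        effects = sim.DoeEffects(beta_time=0.5)
        matrix = sim.generate_doe_responses(design, effects, analyte_ids=["A"], seed=0)
        runs = design.runs.set_index("run_id")
        joined = runs.join(matrix.rename(columns={"A": "resp"}))
        for _, group in joined.groupby("volume"):
            ordered = group.sort_values("time")["resp"].to_numpy()
            assert np.all(np.diff(ordered) > 0)


class TestChromatograms:
    def test_blank_trace(self):
        cc = sim.ChromatogramConfig()
        chrom = sim.generate_chromatogram(cc, conc_ng_ml=0.0, seed=1)
        t = chrom.time
        peak_region = chrom.intensity[(t >= chrom.peak_window[0]) & (t <= chrom.peak_window[1])]
        assert np.abs(peak_region).max() < 6 * cc.baseline_noise_sd

    def test_noiseless_peak_height(self):
        cc = sim.ChromatogramConfig(baseline_noise_sd=0.0)
        chrom = sim.generate_chromatogram(cc, conc_ng_ml=10.0, seed=0)
        assert chrom.intensity.max() == pytest.approx(10.0 * cc.height_per_unit_conc, rel=1e-6)

    def test_constructed_sn_recovered(self):
        # height / noise_sd = 30 by construction; measured S/N within 15%
        cc = sim.ChromatogramConfig(height_per_unit_conc=750.0, baseline_noise_sd=25.0)
        sn = [measure_sn(sim.generate_chromatogram(cc, 1.0, seed=s)) for s in range(100)]
        assert np.mean(sn) == pytest.approx(30.0, rel=0.15)

    def test_sigma_coverage_validated(self):
        with pytest.raises(sim.SimulationError):
            sim.ChromatogramConfig(peak_center=0.1, peak_sigma=0.05, duration=13.0)


class TestIo:
    def test_measurements_round_trip(self, noisy_frame, tmp_path):
        path = tmp_path / "m.csv"
        sim.write_measurements(noisy_frame, path)
        again = sim.read_measurements(path)
        assert len(again) == len(noisy_frame)
        assert np.allclose(again["area_analyte"], noisy_frame["area_analyte"])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"analyte_id": ["A"]}).to_csv(path, index=False)
        with pytest.raises(sim.SimulationError, match="missing columns"):
            sim.read_measurements(path)

    def test_config_yaml_round_trip(self, pfba_truth, tmp_path):
        config = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=17, day_effect_sd=0.03)
        path = tmp_path / "config.yaml"
        sim.config_to_yaml(config, path)
        assert sim.config_from_yaml(path) == config
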