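"""Calibration, LOD/LOQ, recovery, matrix effect, CV, quantitation."""

import math

import numpy as np
import pytest

from conftest import make_scenario
from mxpquant.quant import (
    Calibration,
    InsufficientDataError,
    NOT_REACHED,
    compute_cv,
    compute_matrix_effect,
    compute_recovery,
    determine_lod_loq,
    fit_calibration,
    measure_sample,
    quantify_sample,
    rt_windows_from_scenario,
    validation_report,
)
from mxpquant.simulate import (
    simulate_calibration_series,
    simulate_replicate_set,
    simulate_sample,
    simulate_validation_set,
)

LABEL = "FA 18:2-OOMxP"


class TestDetermineLodLoq:
    def test_snaps_to_prepared_grid(self):
        snr = {0.01: [0.5, 0.6], 0.1: [3.5, 3.4], 1.0: [12.0, 11.0], 2.5: [30.0]}
        assert determine_lod_loq(snr) == (0.1, 1.0)

    def test_sentinel_when_nothing_detected(self):
        assert determine_lod_loq({0.01: [0.2], 0.1: [0.4]}) == (NOT_REACHED, NOT_REACHED)

    def test_noise_free_limits_collapse_to_lowest_level(self, registry):
        scn = make_scenario(seed=21, response_factor=44.0)
        series = simulate_calibration_series(scn, registry=registry)
        res = fit_calibration(series, LABEL, registry, rt_windows_from_scenario(scn))
        assert res.lod == res.loq == 0.01

    def test_empty_input(self):
        with pytest.raises(ValueError):
            determine_lod_loq({})


class TestCalibrationFit:
    def test_noise_free_slope_recovers_generative_ratio(self, registry):
        scn = make_scenario(seed=22, response_factor=44.0)
        series = simulate_calibration_series(scn, registry=registry)
        res = fit_calibration(series, LABEL, registry, rt_windows_from_scenario(scn))
        generative = series.ground_truth.expected_ratio_slope(LABEL)
        assert generative == pytest.approx(0.0022, rel=1e-12)
        assert res.slope == pytest.approx(generative, rel=1e-6)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_series_r_squared_stays_high(self, registry):
        """Moderate noise keeps R^2 > 0.97 across seeded runs."""
        ok = 0
        for seed in range(20):
            scn = make_scenario(seed=1000 + seed, noise_sd=100.0)
            series = simulate_calibration_series(scn, registry=registry)
            res = fit_calibration(series, LABEL, registry, rt_windows_from_scenario(scn))
            ok += 0.97 <= res.r_squared <= 1.0
        assert ok >= 19

    def test_too_few_levels(self):
        cal = Calibration(
            levels=[1.0, 10.0], areas=[10.0, 100.0], is_areas=[50.0, 50.0],
            snrs=[100.0, 1000.0], species=LABEL,
        )
        with pytest.raises(InsufficientDataError):
            cal.fit()

    def test_sub_loq_levels_excluded_from_line(self):
        # levels below LOQ distort nothing even with wild areas
        levels = [0.1, 1.0, 2.5, 5.0, 10.0, 25.0]
        snrs = [3.5, 30.0, 80.0, 150.0, 300.0, 800.0]
        areas = [999.0] + [10.0 * lv for lv in levels[1:]]
        cal = Calibration(levels=levels, areas=areas, snrs=snrs,
                          species=LABEL, response_mode="absolute_area")
        res = cal.fit()
        assert res.lod == 0.1 and res.loq == 1.0
        assert res.linear_range == (1.0, 25.0)
        assert res.slope == pytest.approx(10.0, rel=1e-12)

    def test_absolute_area_mode(self, registry):
        scn = make_scenario(seed=23, response_factor=44.0)
        series = simulate_calibration_series(scn, registry=registry)
        res = fit_calibration(series, LABEL, registry,
                              rt_windows_from_scenario(scn),
                              response_mode="absolute_area")
        # slope ~ RF * sigma * sqrt(2*pi) * 60 up to boundary truncation
        ideal = series.ground_truth.expected_area(LABEL, 1.0)
        assert res.slope == pytest.approx(ideal, rel=0.01)

    def test_summary_mentions_key_quantities(self, registry):
        scn = make_scenario(seed=24, response_factor=44.0)
        series = simulate_calibration_series(scn, registry=registry)
        res = fit_calibration(series, LABEL, registry, rt_windows_from_scenario(scn))
        text = res.summary()
        assert "R^2" in text and "LOD" in text and "LOQ" in text

    def test_lod_loq_monotone_in_noise(self, registry):
        """A 5-rung noise ladder never lowers LOD or LOQ (5 seeds per rung)."""
        rungs = [5.0, 20.0, 50.0, 150.0, 400.0]
        meds = []
        for noise in rungs:
            lods, loqs = [], []
            for seed in range(5):
                scn = make_scenario(seed=3000 + seed, noise_sd=noise, run_length=3.0,
                                    baseline_level=max(50.0, 5 * noise))
                series = simulate_calibration_series(scn, registry=registry)
                rtw = rt_windows_from_scenario(scn)
                snr_by_level = {}
                for sample, level in zip(series.samples, series.levels):
                    peak = measure_sample(sample, registry, rtw)[LABEL]
                    snr_by_level.setdefault(level, []).append(peak.snr)
                lod, loq = determine_lod_loq(snr_by_level)
                lods.append(lod)
                loqs.append(loq)
            meds.append((float(np.median(lods)), float(np.median(loqs))))
        assert all(b[0] >= a[0] and b[1] >= a[1] for a, b in zip(meds, meds[1:]))


class TestRatioEstimators:
    def test_recovery_from_simulated_validation_set(self, registry):
        scn = make_scenario(seed=25, matrix_multiplier=0.91,
                            recovery_fraction=0.70, replicate_cv=0.05)
        valset = simulate_validation_set(scn, replicates=5, registry=registry)
        rtw = rt_windows_from_scenario(scn)

        def areas(samples):
            return [measure_sample(s, registry, rtw)[LABEL].area for s in samples]

        rec = compute_recovery(areas(valset.spiked_sample), areas(valset.spiked_extract))
        assert rec.mean_pct == pytest.approx(70.0, abs=3 * 5.0 * math.sqrt(2 / 5))
        assert rec.n == 5 and rec.sd_pct > 0

    def test_recovery_trivial_cases(self):
        assert compute_recovery(100.0, 100.0).mean_pct == 100.0
        assert compute_recovery(0.0, 50.0).mean_pct == 0.0
        with pytest.raises(ValueError):
            compute_recovery(10.0, 0.0)

    @pytest.mark.parametrize(
        "multiplier, label",
        [(0.91, "ion suppression"), (1.02, "ion enhancement"), (1.20, "ion enhancement")],
    )
    def test_matrix_effect_recovers_generative_multiplier(self, registry, multiplier, label):
        scn = make_scenario(seed=26, matrix_multiplier=multiplier)
        valset = simulate_validation_set(scn, replicates=3, registry=registry)
        rtw = rt_windows_from_scenario(scn)
        extract = [measure_sample(s, registry, rtw)[LABEL].area for s in valset.spiked_extract]
        neat = [measure_sample(s, registry, rtw)[LABEL].area for s in valset.neat_standard]
        res = compute_matrix_effect(extract, neat)
        assert res.mean_pct == pytest.approx(100 * multiplier, rel=1e-6)
        assert res.classification == label

    def test_matrix_effect_identity(self):
        assert compute_matrix_effect(50.0, 50.0).classification == "none"


class TestComputeCv:
    def test_agrees_with_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(3.0, 0.2, size=50).tolist()
        # independent two-pass mean/sd computation
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        oracle = 100 * sd / mean
        assert compute_cv(values) == pytest.approx(oracle, rel=1e-12)

    def test_identical_values_zero(self):
        assert compute_cv([5.0, 5.0, 5.0]) == 0.0

    def test_interday_uses_daily_means(self):
        days = [[10.0, 10.0], [12.0, 12.0], [11.0, 11.0]]
        expected = 100 * np.std([10.0, 12.0, 11.0], ddof=1) / 11.0
        assert compute_cv(days, "interday") == pytest.approx(expected, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_cv([1.0, 2.0])
        with pytest.raises(ValueError):
            compute_cv([1.0, -1.0, 0.0])
        with pytest.raises(ValueError):
            compute_cv([[1.0] * 3] * 2, "interday")
        with pytest.raises(ValueError):
            compute_cv([1.0, 2.0, 3.0], "weekly")

    def test_generative_cv_recovered(self, registry):
        """n=100 replicates at generative CV 5% estimate within [4%, 6%]."""
        scn = make_scenario(seed=27, replicate_cv=0.05, run_length=3.0)
        samples = simulate_replicate_set(scn, n_replicates=100, registry=registry)
        rtw = rt_windows_from_scenario(scn)
        areas = [measure_sample(s, registry, rtw)[LABEL].area for s in samples]
        assert 4.0 <= compute_cv(areas) <= 6.0

    def test_species_cvs_mostly_below_15pct(self, registry):
        """Replicate CV 10%, n=6 injections: the large majority of
        per-species CV estimates stay under 15% (the n=6 CV estimator
        itself has a sampling sd of ~3 points at a 10-point CV)."""
        from mxpquant.simulate import default_scenario

        cvs = []
        for seed in range(10):
            scn = default_scenario(seed=4000 + seed, replicate_cv=0.10, noise_sd=20.0)
            samples = simulate_replicate_set(scn, n_replicates=6, registry=registry)
            rtw = rt_windows_from_scenario(scn)
            for settings in scn.species:
                areas = [
                    measure_sample(s, registry, rtw)[settings.label].area
                    for s in samples
                ]
                cvs.append(compute_cv(areas))
        below = sum(cv < 15.0 for cv in cvs)
        assert below / len(cvs) >= 0.90


class TestQuantifySample:
    def _calibrate(self, scn, registry):
        series = simulate_calibration_series(scn, registry=registry)
        rtw = rt_windows_from_scenario(scn)
        return {LABEL: fit_calibration(series, LABEL, registry, rtw)}, rtw

    def test_noise_free_inversion_recovers_spike(self, registry):
        scn = make_scenario(seed=28, response_factor=44.0)
        cals, rtw = self._calibrate(scn, registry)
        sample = simulate_sample(scn, "unk", stream=99, registry=registry)
        res = quantify_sample(sample, registry, cals, rtw)
        assert res.ok
        conc = res.table.set_index("species").loc["FA 18:2-OOH", "concentration"]
        assert conc == pytest.approx(50.0, rel=0.01)

    def test_absent_analyte_reported_nd(self, registry):
        scn = make_scenario(seed=29, noise_sd=30.0)
        cals, rtw = self._calibrate(scn, registry)
        sample = simulate_sample(scn, "blank", stream=100,
                                 concentrations={LABEL: 0.0}, registry=registry)
        res = quantify_sample(sample, registry, cals, rtw)
        row = res.table.set_index("species").loc["FA 18:2-OOH"]
        assert row["flags"] == "ND"
        assert math.isnan(row["concentration"])

    def test_missing_is_fails_sample_qc(self, registry):
        scn = make_scenario(seed=30, noise_sd=30.0)
        cals, rtw = self._calibrate(scn, registry)
        sample = simulate_sample(
            scn, "bad", stream=101,
            concentrations={LABEL: 50.0, "FA 19:1-OOMxP": 0.0},
            registry=registry,
        )
        res = quantify_sample(sample, registry, cals, rtw)
        assert not res.ok
        assert res.table.empty
        assert "internal standard" in res.qc_message

    def test_dilution_chain_back_calculation(self, registry):
        scn = make_scenario(seed=31, response_factor=44.0)
        cals, rtw = self._calibrate(scn, registry)
        sample = simulate_sample(scn, "unk", stream=102, registry=registry)
        extract = quantify_sample(sample, registry, cals, rtw)
        serum = quantify_sample(sample, registry, cals, rtw,
                                source_volume_ul=50.0, per_ml=True)
        c_extract = extract.table["concentration"].iloc[0]
        c_serum = serum.table["concentration"].iloc[0]
        # 100 uL final / 50 uL serum, per mL
        assert c_serum == pytest.approx(c_extract * 2.0 * 1000.0, rel=1e-12)
        assert serum.table["units"].iloc[0] == "pmol/mL source"

    def test_sub_loq_flagged(self, registry):
        scn = make_scenario(seed=32, noise_sd=50.0)
        cals, rtw = self._calibrate(scn, registry)
        low = simulate_sample(scn, "low", stream=103,
                              concentrations={LABEL: 0.3}, registry=registry)
        res = quantify_sample(low, registry, cals, rtw)
        flags = res.table["flags"].iloc[0]
        assert "ND" in flags or "<LOQ" in flags


class TestValidationReport:
    def test_full_report_structure_and_values(self, registry):
        scn = make_scenario(seed=33, matrix_multiplier=0.91,
                            recovery_fraction=0.70, replicate_cv=0.04,
                            noise_sd=20.0, run_length=3.0)
        report = validation_report(scn, registry, replicates=5, days=3)
        assert list(report.columns) == [
            "species", "recovery_pct", "recovery_sd", "matrix_effect_pct",
            "cv_standard_pct", "cv_intraday_pct", "cv_interday_pct",
        ]
        row = report.set_index("species").loc["FA 18:2-OOH"]
        assert row["recovery_pct"] == pytest.approx(70.0, abs=8.0)
        assert row["matrix_effect_pct"] == pytest.approx(91.0, abs=8.0)
        assert 0 <= row["cv_intraday_pct"] < 15.0
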