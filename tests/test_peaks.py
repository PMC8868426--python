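"""Peak detection, integration, S/N, smoothing, trace I/O."""

import math

import numpy as np
import pytest

from conftest import make_scenario
from mxpquant.mzml_io import read_mzml_traces, write_mzml_traces
from mxpquant.peaks import (
    ChromatogramTrace,
    extract_trace,
    find_peak,
    read_traces_csv,
    smooth,
    write_traces_csv,
)
from mxpquant.simulate import simulate_trace

LABEL = "FA 18:2-OOMxP"
WINDOW = (1.7, 2.3)


def gaussian_trace(amplitude=1e5, rt=2.0, sigma=0.05, baseline=50.0, noise=0.0,
                   drift=0.0, seed=0, run=4.0, rate=5.0):
    t = np.arange(int(run * 60 * rate) + 1) / (60 * rate)
    y = baseline + drift * t + amplitude * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return ChromatogramTrace(LABEL, t, np.clip(y, 0, None), sample_id="t")


class TestTraceInvariants:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="10 points"):
            ChromatogramTrace(LABEL, np.arange(5.0), np.ones(5))

    def test_non_increasing_times(self):
        t = np.arange(20.0)
        t[10] = t[9]
        with pytest.raises(ValueError, match="increasing"):
            ChromatogramTrace(LABEL, t, np.ones(20))

    def test_negative_intensities(self):
        with pytest.raises(ValueError, match="non-negative"):
            ChromatogramTrace(LABEL, np.arange(20.0), np.full(20, -1.0))


class TestSmooth:
    def test_constant_trace_unchanged(self):
        trace = ChromatogramTrace(LABEL, np.arange(50.0), np.full(50, 7.0))
        for method in ("moving_average", "savitzky_golay"):
            out = smooth(trace, 5, method)
            assert np.allclose(out.intensities, 7.0)

    @pytest.mark.parametrize("method", ["moving_average", "savitzky_golay"])
    def test_apex_shift_below_one_interval(self, method):
        trace = gaussian_trace(noise=2000.0, seed=3)
        sm = smooth(trace, 5, method)
        raw_apex_true = 2.0
        apex = sm.times[np.argmax(sm.intensities)]
        assert abs(apex - raw_apex_true) < 1.0 / 300 + 1e-12

    def test_window_validation(self):
        trace = ChromatogramTrace(LABEL, np.arange(20.0), np.ones(20))
        with pytest.raises(ValueError, match="odd"):
            smooth(trace, 4)
        with pytest.raises(ValueError):
            smooth(trace, 21)
        with pytest.raises(ValueError):
            smooth(trace, 1)


class TestFindPeak:
    def test_noise_free_gaussian_area_closed_form(self):
        amplitude, sigma = 2.0e5, 0.05
        trace = gaussian_trace(amplitude=amplitude, sigma=sigma)
        res = find_peak(trace, WINDOW)
        closed = amplitude * sigma * math.sqrt(2 * math.pi) * 60.0
        assert res.detected
        assert res.area == pytest.approx(closed, rel=0.01)
        assert res.height == pytest.approx(amplitude, rel=1e-3)
        assert res.snr == 1e6 and "zero_noise" in res.qc_flags

    def test_baseline_shift_invariance(self):
        a = find_peak(gaussian_trace(baseline=50.0, noise=500.0, seed=5), WINDOW)
        b = find_peak(gaussian_trace(baseline=5050.0, noise=500.0, seed=5), WINDOW)
        assert a.area == pytest.approx(b.area, rel=1e-9)
        assert a.height == pytest.approx(b.height, rel=1e-9)

    def test_linear_drift_removed(self):
        res = find_peak(gaussian_trace(drift=300.0), WINDOW)
        closed = 1e5 * 0.05 * math.sqrt(2 * math.pi) * 60.0
        assert res.area == pytest.approx(closed, rel=0.01)

    def test_area_linear_over_three_decades(self):
        areas = {
            a: find_peak(gaussian_trace(amplitude=a), WINDOW).area
            for a in (1e3, 1e4, 1e5, 1e6)
        }
        base = areas[1e3]
        for a, val in areas.items():
            assert val / base == pytest.approx(a / 1e3, rel=0.01)

    def test_snr_doubles_with_amplitude(self):
        """Monte-Carlo: height is linear in amplitude at fixed noise."""
        ratios = []
        for seed in range(100):
            lo = find_peak(gaussian_trace(amplitude=5e3, noise=100.0, seed=seed), WINDOW)
            hi = find_peak(gaussian_trace(amplitude=1e4, noise=100.0, seed=seed), WINDOW)
            ratios.append(hi.snr / lo.snr)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_snr_invariant_under_unit_rescaling(self):
        a = find_peak(gaussian_trace(noise=200.0, seed=7), WINDOW)
        big = gaussian_trace(amplitude=1e8, baseline=5e4, noise=2e5, seed=7)
        # same relative trace, intensities x1000
        b = find_peak(big, WINDOW)
        assert b.snr == pytest.approx(a.snr, rel=0.05)

    def test_snr_invariant_under_time_rescaling(self):
        trace = gaussian_trace(noise=200.0, seed=8)
        stretched = ChromatogramTrace(
            LABEL, trace.times * 2.0, trace.intensities, sample_id="t"
        )
        a = find_peak(trace, WINDOW)
        b = find_peak(stretched, (WINDOW[0] * 2, WINDOW[1] * 2))
        assert b.snr == pytest.approx(a.snr, rel=1e-9)
        assert b.height == pytest.approx(a.height, rel=1e-9)

    def test_flat_trace_not_detected(self):
        trace = gaussian_trace(amplitude=0.0, noise=50.0, seed=9)
        res = find_peak(trace, WINDOW)
        assert not res.detected
        assert res.area == 0.0 and res.height == 0.0
        assert "no_peak" in res.qc_flags

    def test_apex_matches_brute_force_oracle(self):
        """Exhaustive local-maximum scan agrees within 1 sampling interval."""
        dt = 1.0 / 300
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rt = float(rng.uniform(1.85, 2.15))
            trace = gaussian_trace(amplitude=5e4, rt=rt, noise=300.0, seed=seed + 1000)
            res = find_peak(trace, WINDOW)
            in_win = (trace.times >= WINDOW[0]) & (trace.times <= WINDOW[1])
            oracle_apex = trace.times[in_win][np.argmax(trace.intensities[in_win])]
            assert abs(res.apex_time - oracle_apex) <= dt + 1e-12

    def test_empty_window(self):
        with pytest.raises(ValueError, match="window"):
            find_peak(gaussian_trace(), (2.3, 1.7))
        with pytest.raises(ValueError, match="overlap"):
            find_peak(gaussian_trace(), (30.0, 31.0))

    def test_truncated_peak_flagged(self):
        # peak at the very start of the trace, window clipped at t=0
        trace = gaussian_trace(rt=0.02, sigma=0.05)
        res = find_peak(trace, (0.0, 0.3))
        assert "boundary_truncated" in res.qc_flags


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path):
        trace = gaussian_trace(noise=100.0, seed=11)
        path = tmp_path / "traces.csv"
        write_traces_csv([trace], path)
        (back,) = read_traces_csv(path)
        assert np.array_equal(back.times, trace.times)
        assert np.array_equal(back.intensities, trace.intensities)
        assert back.transition == LABEL

    def test_mzml_round_trip(self, tmp_path, registry):
        scn = make_scenario(seed=13, noise_sd=40.0)
        trace = simulate_trace(scn, LABEL, registry=registry)
        path = tmp_path / "sample.mzML"
        write_mzml_traces([trace], path)
        (back,) = read_mzml_traces(path)
        assert np.array_equal(back.times, trace.times)
        assert np.array_equal(back.intensities, trace.intensities)
        assert back.precursor_mz == 407.3 and back.product_mz == 335.3

    def test_extract_by_mz_from_mzml(self, tmp_path, registry):
        scn = make_scenario(seed=14, noise_sd=40.0)
        trace = simulate_trace(scn, LABEL, registry=registry)
        path = tmp_path / "sample.mzML"
        write_mzml_traces([trace], path)
        got = extract_trace(path, registry.get(LABEL))
        assert len(got) == len(trace)
        with pytest.raises(LookupError, match="no chromatogram"):
            extract_trace(path, registry.get("FA 18:3-OOMxP"), mz_tolerance=0.01)

    def test_ambiguous_mz_match_demands_tighter_tolerance(self, tmp_path):
        t = np.arange(20.0)
        a = ChromatogramTrace("a", t, np.ones(20), precursor_mz=407.3, product_mz=335.3)
        b = ChromatogramTrace("b", t, np.ones(20), precursor_mz=407.4, product_mz=335.3)
        path = tmp_path / "two.mzML"
        write_mzml_traces([a, b], path)

        from mxpquant.transitions import SRMTransition
        from mxpquant.chem import parse_species

        target = SRMTransition(parse_species("FA 18:2-OOMxP"), 407.35, 335.3, 13, 57)
        with pytest.raises(LookupError, match="tighten"):
            extract_trace(path, target, mz_tolerance=0.2)

    def test_extract_from_csv_by_label(self, tmp_path, registry):
        trace = gaussian_trace()
        path = tmp_path / "traces.csv"
        write_traces_csv([trace], path)
        got = extract_trace(path, registry.get(LABEL))
        assert np.array_equal(got.intensities, trace.intensities)
        with pytest.raises(LookupError, match="available"):
            extract_trace(path, registry.get("FA 18:3-OOMxP"))
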