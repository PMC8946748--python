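"""Two-step detector: filtering, event logic, segmentation, features."""

import numpy as np
import pytest

from clicktypes import (
    Bout,
    Calibration,
    DetectorConfig,
    SceneSpec,
    SonarPingTrain,
    bandpass,
    click_features,
    detect_clicks,
    detect_events,
    filter_candidates,
    get_template,
    make_click_template,
    segment_clicks,
    synth_scene,
)
from clicktypes.detector import _runs_of

FS = 200_000.0


def _tone(freq_hz, dur_s=0.05):
    t = np.arange(int(dur_s * FS)) / FS
    return np.sin(2 * np.pi * freq_hz * t)


def _pair_scene(gap_ms, rl=125.0, seed=3, cal=None):
    spec = SceneSpec(
        duration_s=1.0,
        bouts=(Bout("Gg", 0.4, 1, rl), Bout("Gg", 0.4 + gap_ms / 1000.0, 1, rl)),
        noise_floor_db=70.0,
        seed=seed,
    )
    x, _ = synth_scene(spec, cal)
    return bandpass(x, FS)


class TestBandpass:
    def test_passband_tone_unchanged(self):
        """A 50 kHz tone passes with amplitude change below 1 dB."""
        x = _tone(50_000.0)
        y = bandpass(x, FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        gain_db = 20 * np.log10(np.abs(y[mid]).max() / np.abs(x[mid]).max())
        assert abs(gain_db) < 1.0

    def test_stopband_tone_attenuated(self):
        """A 1 kHz tone is attenuated by more than 20 dB."""
        x = _tone(1_000.0)
        y = bandpass(x, FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        atten_db = 20 * np.log10(np.abs(x[mid]).max() / np.abs(y[mid]).max())
        assert atten_db > 20.0

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(1000), FS), 0.0)

    def test_band_edges_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, DetectorConfig(band_high_khz=150.0))
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 8_000.0)  # 5 kHz low edge >= 4 kHz Nyquist


class TestDetectEvents:
    def test_close_pair_merges_into_one_event(self, cal):
        """Clicks 2.0 ms apart fall within the 2.5 ms merge window."""
        assert len(detect_events(_pair_scene(2.0), FS, cal)) == 1

    def test_distant_pair_yields_two_events(self, cal):
        assert len(detect_events(_pair_scene(10.0), FS, cal)) == 2

    def test_subthreshold_click_not_detected(self, cal):
        """A click at 115 dB p2p stays below the 118 dB event threshold."""
        spec = SceneSpec(
            duration_s=1.0, bouts=(Bout("Gg", 0.5, 1, 115.0),), noise_floor_db=70.0, seed=2
        )
        x, _ = synth_scene(spec, cal)
        assert detect_events(bandpass(x, FS), FS, cal) == []

    def test_events_sorted_non_overlapping(self, cal):
        spec = SceneSpec(
            duration_s=3.0, bouts=(Bout("UD47", 0.3, 30, 124.0),), noise_floor_db=85.0, seed=4
        )
        x, _ = synth_scene(spec, cal)
        events = detect_events(bandpass(x, FS), FS, cal)
        assert len(events) > 1
        for a, b in zip(events, events[1:]):
            assert a.start_idx < a.end_idx <= b.start_idx


class TestSegmentClicks:
    def test_isolated_click_single_snippet(self, cal):
        spec = SceneSpec(
            duration_s=1.0, bouts=(Bout("Gg", 0.5, 1, 125.0),), noise_floor_db=80.0, seed=1
        )
        x, _ = synth_scene(spec, cal)
        xf = bandpass(x, FS)
        (ev,) = detect_events(xf, FS, cal)
        segs = segment_clicks(xf[ev.start_idx : ev.end_idx], FS, cal)
        assert len(segs) == 1
        s, e = segs[0]
        truth_idx = int(0.5 * FS) - ev.start_idx
        assert s <= truth_idx < e

    def test_click_pair_within_100us_merged(self, cal):
        xf = _pair_scene(0.05)  # 50 us apart
        (ev,) = detect_events(xf, FS, cal)
        assert len(segment_clicks(xf[ev.start_idx : ev.end_idx], FS, cal)) == 1

    def test_clipped_click_discarded(self, cal):
        """A click beyond full scale is segmented out entirely."""
        spec = SceneSpec(duration_s=1.0, noise_floor_db=70.0, seed=6)
        x, _ = synth_scene(spec, cal)
        click = make_click_template(get_template("Gg"), FS) * 1.2  # beyond clip level
        i = int(0.5 * FS)
        x[i : i + len(click)] += click
        np.clip(x, -1.0, 1.0, out=x)
        xf = bandpass(x, FS)
        (ev,) = detect_events(xf, FS, cal)
        assert segment_clicks(xf[ev.start_idx : ev.end_idx], FS, cal) == []

    def test_degenerate_event_no_clicks(self, cal):
        assert segment_clicks(np.zeros(500), FS, cal) == []

    def test_matches_brute_force_oracle(self, cal):
        """Segmentation agrees with a literal-rule brute-force scan on 100
        random tiny events (seed amplitude runs, contiguous envelope-energy
        expansion, <100 us merge, clip rejection applied sample by sample)."""
        from scipy.signal import hilbert

        cfg = DetectorConfig()
        rng = np.random.default_rng(0)
        amp_thr = cal.db_to_pp(cfg.pp_threshold_db - 0.01) / 2.0
        n_checked = 0
        for _ in range(100):
            n = rng.integers(80, 400)
            x = rng.normal(0, 0.001, n)
            for _ in range(rng.integers(0, 4)):
                i = int(rng.integers(5, n - 5))
                x[i] += rng.uniform(0.05, 0.9) * rng.choice([-1.0, 1.0])
            got = segment_clicks(x, FS, cal, cfg)

            env2 = np.abs(hilbert(x)) ** 2
            p = np.percentile(env2, cfg.energy_percentile)
            seeds = []
            run = []
            for i in range(n):  # literal scan for amplitude runs
                if abs(x[i]) >= amp_thr:
                    run.append(i)
                elif run:
                    seeds.append(max(run, key=lambda j: abs(x[j])))
                    run = []
            if run:
                seeds.append(max(run, key=lambda j: abs(x[j])))
            intervals = []
            for pk in seeds:
                s = pk
                while s > 0 and env2[s - 1] > p:
                    s -= 1
                e = pk
                while e < n - 1 and env2[e + 1] > p:
                    e += 1
                intervals.append([s, e + 1])
            intervals.sort()
            merged = []
            for s, e in intervals:
                if merged and s - merged[-1][1] < cfg.click_merge_us * 1e-6 * FS:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            expect = [
                (s, e) for s, e in merged if np.max(np.abs(x[s:e])) < cfg.clip_level
            ]
            assert got == expect
            n_checked += 1
        assert n_checked == 100


class TestClickFeatures:
    def test_spectral_resolution_is_500hz(self, cal):
        """fs 200 kHz with a 400-point FFT gives 0.5 kHz bin spacing."""
        rec = click_features(make_click_template(get_template("Gg"), FS), FS, cal)
        assert len(rec.spectrum_db) == 200
        # peak bin index * 0.5 kHz must reproduce the peak frequency
        assert rec.peak_freq_khz == np.argmax(rec.spectrum_db) * 0.5

    def test_pure_gabor_peak_frequency(self, cal):
        from clicktypes import TypeTemplate

        t = TypeTemplate(name="x", peak_freq_khz=40.0, bw3db_khz=5.0, modal_ici_s=0.1)
        rec = click_features(make_click_template(t, FS), FS, cal)
        assert rec.peak_freq_khz == pytest.approx(40.0, abs=0.25)

    def test_gg_bandwidth_median_over_detections(self, gg_records):
        """Median -3 dB bandwidth of detected Gg clicks near 4.5 kHz."""
        bw = np.median([r.bw3db_khz for r in gg_records])
        assert bw == pytest.approx(4.5, abs=1.0)

    def test_envelope_fixed_length(self, gg_records):
        assert all(len(r.envelope) == 200 for r in gg_records)


class TestFilterCandidates:
    def test_low_peak_frequency_discarded(self, cal, gg_records):
        rec = gg_records[0]
        low = type(rec)(**{**rec.__dict__, "peak_freq_khz": 4.0})
        keep, reason = filter_candidates(low)
        assert (keep, reason) == (False, "low_peak_freq")

    def test_target_click_kept(self, gg_records):
        keep, reason = filter_candidates(gg_records[0])
        assert keep and reason == "keep"

    def test_sonar_ping_discarded_by_duration(self, cal):
        """A 5 ms narrowband ping is rejected as a click candidate."""
        spec = SceneSpec(
            duration_s=4.0,
            confounders=(SonarPingTrain(start_s=0.5, ping_ms=5.0, n_pings=3),),
            noise_floor_db=85.0,
            seed=8,
        )
        x, _ = synth_scene(spec, cal)
        kept, discarded = detect_clicks(x, FS, cal, return_discarded=True)
        assert kept == []
        assert discarded and all(reason == "duration" for _, reason in discarded)


class TestPipelineProperties:
    def test_high_level_recall(self, cal):
        """>= 99% of truth clicks at >= 121 dB matched within 1 ms."""
        spec = SceneSpec(
            duration_s=32.0, bouts=(Bout("Gg", 0.5, 200, 123.0),), noise_floor_db=85.0, seed=13
        )
        x, truth = synth_scene(spec, cal)
        recs = detect_clicks(x, FS, cal)
        det = np.array([r.peak_time_s for r in recs])
        matched = sum(np.min(np.abs(det - t)) < 1e-3 for t in truth.click_time_s)
        assert matched / len(truth) >= 0.99

    def test_runs_of_helper(self):
        assert _runs_of(np.array([True, True, False, True])) == [(0, 2), (3, 4)]
        assert _runs_of(np.array([False, False])) == []
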