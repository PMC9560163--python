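"""Butterworth baseline: filter response, envelope, thresholds, veto."""

import numpy as np
import pytest
from scipy import signal as sp_signal

import ripplekit as rk
from ripplekit.spectral import FilterConfig, _runs


FS = 1250.0


def _sine(freq, dur=2.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_passes(self):
        out = rk.bandpass(_sine(150.0))
        assert np.abs(out[500:-500]).max() >= 0.9

    def test_low_frequency_tone_attenuated(self):
        out = rk.bandpass(_sine(10.0))
        assert np.abs(out[500:-500]).max() <= 0.1

    @pytest.mark.parametrize("freq,limit", [(50.0, 0.2), (600.0, 0.2)])
    def test_out_of_band_attenuation(self, freq, limit):
        out = rk.bandpass(_sine(freq))
        assert np.abs(out[500:-500]).max() <= limit

    def test_zero_input_zero_output(self):
        assert np.allclose(rk.bandpass(np.zeros(4000)), 0.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            rk.bandpass(np.zeros(10))


class TestEnvelope:
    def test_zero_input_zero_envelope(self):
        assert np.allclose(rk.envelope(np.zeros(4000)), 0.0)

    def test_tone_burst_peak_near_center(self):
        # vs the analytic (Hilbert) envelope of the same burst
        t = np.arange(int(2 * FS)) / FS
        center = 1.0
        burst = np.exp(-0.5 * ((t - center) / 0.02) ** 2) * np.sin(
            2 * np.pi * 150 * t)
        filt = rk.bandpass(burst)
        env = rk.envelope(filt)
        hilb = np.abs(sp_signal.hilbert(filt))
        assert abs(np.argmax(env) - np.argmax(hilb)) / FS < 0.005
        assert abs(np.argmax(env) / FS - center) < 0.005

    def test_gain_invariance_of_detection(self, rng):
        x = rng.standard_normal(int(30 * FS))
        x[10000:10100] += 10 * _sine(150.0, dur=100 / FS)
        base = rk.detect(rk.envelope(rk.bandpass(x)), 2.0, 5.0)
        cfg = FilterConfig(gain=7.5)
        scaled = rk.detect(rk.envelope(rk.bandpass(x), cfg=cfg), 2.0, 5.0)
        np.testing.assert_allclose(base.intervals, scaled.intervals, atol=1e-9)

    def test_envelope_non_negative(self, rng):
        assert rk.envelope(rng.standard_normal(5000)).min() >= 0


def _oracle_detect(z, thr1, thr2, fs, merge_gap):
    """Brute-force run scan over a centered envelope."""
    events = []
    i = 0
    while i < len(z):
        if z[i] >= thr1:
            j = i
            while j + 1 < len(z) and z[j + 1] >= thr1:
                j += 1
            if max(z[i:j + 1]) >= thr2:
                events.append([i / fs, (j + 1) / fs])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in events:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.array(merged).reshape(-1, 2)


class TestDetect:
    def test_white_noise_silent_at_ten_sd(self, rng):
        env = rk.envelope(rk.bandpass(rng.standard_normal(int(120 * FS))))
        assert len(rk.detect(env, 2.0, 10.0)) == 0

    def test_every_default_event_recalled(self, default_session):
        pyr = default_session.params.pyramidal_channel_index
        rec = rk.zscore(default_session.recording)
        env = rk.envelope(rk.bandpass(rec.data[:, pyr]))
        det = rk.detect(env, 2.0, 5.0)
        for s, e in default_session.ground_truth:
            assert np.any(det.overlaps(s, e))

    def test_nearby_bursts_merged(self):
        fs = FS
        x = np.zeros(int(2 * fs))
        for c in (1.0, 1.0 + 0.010 + 0.030):  # bursts ~10 ms apart edge-to-edge
            t = np.arange(int(0.03 * fs)) / fs
            i0 = int(c * fs)
            x[i0:i0 + t.size] += 5 * np.sin(2 * np.pi * 150 * t)
        env = rk.envelope(rk.bandpass(x + 0.01))
        det = rk.detect(env, 1.0, 2.0)
        assert len(det) == 1

    def test_matches_run_scan_oracle(self, rng):
        cfg = FilterConfig()
        for _ in range(1000):
            env = np.abs(rng.standard_normal(rng.integers(50, 200)))
            thr1 = rng.uniform(0.2, 1.0)
            thr2 = thr1 + rng.uniform(0.1, 1.5)
            got = rk.detect(env, thr1, thr2, fs=FS, cfg=cfg).intervals
            z = (env - env.mean()) / env.std()
            want = _oracle_detect(z, thr1, thr2, FS, cfg.merge_gap_s)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_monotonicity_in_thresholds(self, default_session):
        pyr = default_session.params.pyramidal_channel_index
        rec = rk.zscore(default_session.recording)
        env = rk.envelope(rk.bandpass(rec.data[:, pyr]))
        n_prev = np.inf
        for thr2 in (3.0, 5.0, 7.0, 9.0):
            n = len(rk.detect(env, 2.0, thr2))
            assert n <= n_prev
            n_prev = n
        # raising thr1 never lengthens any event
        wide = rk.detect(env, 1.0, 5.0)
        narrow = rk.detect(env, 2.5, 5.0)
        assert narrow.durations.sum() <= wide.durations.sum() + 1e-9

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            rk.detect(np.ones(100), 5.0, 2.0)


class TestGridSearch:
    def test_grid_has_sixty_combinations(self, default_session):
        cfg = FilterConfig()
        assert len(cfg.thr1_sd_candidates) * len(cfg.thr2_sd_candidates) == 60

    def test_best_pair_attains_table_maximum(self, default_session):
        pyr = default_session.params.pyramidal_channel_index
        rec = rk.zscore(default_session.recording)
        env = rk.envelope(rk.bandpass(rec.data[:, pyr]))
        (t1, t2), table = rk.grid_search(env, default_session.ground_truth,
                                         duration_s=rec.duration_s)
        assert len(table) == 60
        row = table[(table.thr1_sd == t1) & (table.thr2_sd == t2)]
        assert row.f1.iloc[0] == table.f1.max()

    def test_single_candidate_grid(self, default_session):
        pyr = default_session.params.pyramidal_channel_index
        rec = rk.zscore(default_session.recording)
        env = rk.envelope(rk.bandpass(rec.data[:, pyr]))
        cfg = FilterConfig(thr1_sd_candidates=(2.0,), thr2_sd_candidates=(5.0,))
        best, table = rk.grid_search(env, default_session.ground_truth,
                                     cfg=cfg, duration_s=rec.duration_s)
        assert best == (2.0, 5.0) and len(table) == 1

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            rk.grid_search(np.ones(100), rk.EventSet(np.empty((0, 2))))


class TestOnlineDetect:
    def _session_channels(self, session):
        rec = rk.zscore(session.recording)
        pyr = session.params.pyramidal_channel_index
        return rec.data[:, pyr], rec.data[:, -1]

    def test_identical_channels_veto_everything(self, rng):
        x = rng.standard_normal(int(90 * FS))
        x[80000:80100] += 8.0
        assert len(rk.online_detect(x, x, 4.0, calibration_s=30.0)) == 0

    def test_ripple_only_on_ripple_channel_retained(self, rng):
        base = rng.standard_normal(int(90 * FS))
        ripple = base.copy()
        i0 = int(80 * FS)
        t = np.arange(int(0.06 * FS)) / FS
        ripple[i0:i0 + t.size] += 8 * np.sin(2 * np.pi * 150 * t)
        det = rk.online_detect(ripple, base, 4.0, calibration_s=30.0)
        assert np.any(det.overlaps(80.0, 80.06))

    def test_broadband_artifact_on_both_channels_rejected(self, rng):
        base = rng.standard_normal(int(90 * FS))
        artifact = 10 * rng.standard_normal(int(0.05 * FS))
        a = base.copy()
        b = rng.standard_normal(int(90 * FS))
        i0 = int(80 * FS)
        a[i0:i0 + artifact.size] += artifact
        b[i0:i0 + artifact.size] += artifact
        det = rk.online_detect(a, b, 4.0, calibration_s=30.0)
        assert not np.any(det.overlaps(80.0, 80.05))

    def test_veto_reduces_false_positives_on_artifact_session(self):
        params = rk.GeneratorParams(duration_s=240.0, fs_raw=1250.0,
                                    artifact_rate_hz=0.2, seed=21)
        session = rk.generate_session(params)
        ripple_ch, veto_ch = self._session_channels(session)
        no_veto = rk.online_detect(ripple_ch, np.zeros_like(veto_ch), 4.0,
                                   calibration_s=60.0)
        veto = rk.online_detect(ripple_ch, veto_ch, 4.0, calibration_s=60.0)

        def n_fp(det):
            c = rk.match(det, session.ground_truth, window_s=0.032,
                         duration_s=240.0)
            return c.FP

        assert n_fp(veto) < n_fp(no_veto)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rk.online_detect(np.zeros(100), np.zeros(50), 4.0)


def test_run_finder_handles_edges():
    mask = np.array([1, 1, 0, 0, 1, 0, 1], dtype=bool)
    np.testing.assert_array_equal(_runs(mask), [[0, 2], [4, 5], [6, 7]])
    assert _runs(np.zeros(5, dtype=bool)).shape == (0, 2)
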