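"""Network arithmetic, loss, training, inference, event extraction."""

import numpy as np
import pytest

import ripplekit as rk
from ripplekit.cnn import extract_events


@pytest.fixture(scope="module")
def cnn32():
    return rk.build_model(rk.ArchitectureConfig.cnn32(), seed=0)


@pytest.fixture(scope="module")
def cnn12():
    return rk.build_model(rk.ArchitectureConfig.cnn12(), seed=0)


class TestArchitecture:
    def test_output_counts_on_full_chunk(self, cnn32, cnn12, rng):
        x = rng.standard_normal((1, 72000, 8))
        assert cnn32.forward(x).shape == (1, 1800, 1)
        assert cnn12.forward(x).shape == (1, 4500, 1)

    def test_stride_products_and_resolutions(self):
        c32, c12 = rk.ArchitectureConfig.cnn32(), rk.ArchitectureConfig.cnn12()
        assert c32.stride_product == 5 * 1 * 2 * 1 * 2 * 1 * 2 == 40
        assert c12.stride_product == 16
        assert c32.window_s == pytest.approx(0.032)
        assert c12.window_s == pytest.approx(0.0128)

    @pytest.mark.parametrize("length", [40, 77, 400, 1001])
    def test_fully_convolutional_output_length(self, cnn32, rng, length):
        x = rng.standard_normal((1, length, 8))
        assert cnn32.forward(x).shape[1] == length // 40

    def test_wrong_channel_count_rejected(self, cnn32, rng):
        with pytest.raises(ValueError, match="channels"):
            cnn32.forward(rng.standard_normal((1, 400, 7)))
        with pytest.raises(ValueError):
            rk.build_model(rk.ArchitectureConfig(n_input_channels=4))

    def test_default_hyperparameters(self):
        cfg = rk.ArchitectureConfig.cnn32()
        assert cfg.n_filters == (4, 2, 8, 4, 16, 8, 32)
        assert cfg.leaky_relu_alpha == 0.1
        assert cfg.l2_lambda == 0.0005
        tcfg = rk.TrainingConfig()
        assert (tcfg.learning_rate, tcfg.beta1, tcfg.beta2, tcfg.epsilon) == \
            (0.001, 0.9, 0.999, 1e-7)
        assert tcfg.batch_size == 16


class TestBceLoss:
    def test_perfect_hard_predictions_near_zero(self):
        assert rk.bce_loss([0, 1, 1], [0, 1, 1]) < 1e-5

    def test_single_uncertain_prediction(self):
        assert rk.bce_loss([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-4)

    def test_soft_label_value(self):
        # y=p=0.5 also evaluates to ln 2 under the soft-label formula
        assert rk.bce_loss([0.5], [0.5]) == pytest.approx(np.log(2), abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rk.bce_loss([1, 0], [0.5])


def _tiny_dataset(seed=0, n_chunks=4):
    params = rk.GeneratorParams(duration_s=n_chunks * 5.76 + 1.0,
                                fs_raw=1250.0, event_rate_hz=0.5, seed=seed)
    session = rk.generate_session(params)
    return rk.prepare_dataset(session.recording, session.ground_truth,
                              chunk_s=5.76)


class TestTraining:
    def test_zero_epochs_is_a_no_op(self):
        ds = _tiny_dataset()
        model = rk.build_model(rk.ArchitectureConfig.cnn32(), seed=1)
        w_before = model.blocks[0][0].params["W"].copy()
        model, history = rk.train(model, ds, rk.TrainingConfig(epochs=0, seed=0))
        np.testing.assert_array_equal(model.blocks[0][0].params["W"], w_before)
        assert history == {"train": [], "dev": []}

    def test_loss_decreases_on_tiny_set(self):
        ds = _tiny_dataset()
        model = rk.build_model(rk.ArchitectureConfig.cnn32(), seed=1)
        model, history = rk.train(model, ds,
                                  rk.TrainingConfig(epochs=200, seed=0))
        assert history["train"][-1] < history["train"][0]
        assert len(history["train"]) == len(history["dev"]) == 200

    def test_training_is_deterministic(self):
        ds = _tiny_dataset()
        outs = []
        for _ in range(2):
            model = rk.build_model(rk.ArchitectureConfig.cnn32(), seed=1)
            model, _ = rk.train(model, ds, rk.TrainingConfig(epochs=5, seed=0))
            outs.append(model.predict_proba(ds.X[:1].astype(np.float64)))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_window_count_mismatch_rejected(self):
        ds = _tiny_dataset()
        model = rk.build_model(rk.ArchitectureConfig.cnn12(), seed=1)
        with pytest.raises(ValueError, match="windows per chunk"):
            rk.train(model, ds, rk.TrainingConfig(epochs=1))


class TestPredict:
    def test_probabilities_in_unit_interval(self, cnn32, default_session):
        rec = rk.zscore(default_session.recording)
        trace = rk.predict(cnn32, rec)
        assert trace.p.min() >= 0 and trace.p.max() <= 1
        assert trace.p.size == rec.n_samples // 40

    def test_session_trace_equals_chunk_concatenation(self, cnn32, rng):
        x = rng.standard_normal((72000 * 2, 8))
        rec = rk.LfpRecording(x, fs=1250.0)
        full = rk.predict(cnn32, rec).p
        parts = [rk.predict(cnn32, rk.LfpRecording(x[i * 72000:(i + 1) * 72000],
                                                   fs=1250.0)).p
                 for i in range(2)]
        np.testing.assert_allclose(full, np.concatenate(parts), atol=1e-10)

    def test_trained_model_separates_events_from_background(
            self, trained_cnn32, heldout_session, heldout_trace):
        rec = heldout_session.recording
        y = rk.build_labels(1, heldout_session.ground_truth, 0.032,
                            chunk_s=rec.duration_s, fs=rec.fs).ravel()
        p = heldout_trace.p
        y = y[:p.size]
        assert p[y > 0.5].mean() > p[y == 0].mean() + 0.2


class TestStreamPredict:
    def test_hop_count_arithmetic(self, cnn12):
        n = 12_000
        rec = rk.LfpRecording(np.zeros((n, 8)), fs=1250.0)
        trace = rk.stream_predict(cnn12, rec, calibration_s=2.0)
        assert trace.p.size == (n - 16) // 8 + 1

    def test_causal_contract(self, cnn12, rng):
        x = rng.standard_normal((4000, 8))
        rec_a = rk.LfpRecording(x.copy(), fs=1250.0)
        x2 = x.copy()
        x2[2000:] += 100.0  # perturb the future only
        rec_b = rk.LfpRecording(x2, fs=1250.0)
        a = rk.stream_predict(cnn12, rec_a, calibration_s=1.0)
        b = rk.stream_predict(cnn12, rec_b, calibration_s=1.0)
        # windows ending at or before sample 2000 are unaffected
        n_safe = (2000 - 16) // 8 + 1
        np.testing.assert_array_equal(a.p[:n_safe], b.p[:n_safe])

    def test_streaming_matches_offline_on_stationary_input(self, cnn12, rng):
        x = rng.standard_normal((40_000, 8))
        rec = rk.LfpRecording(x, fs=1250.0)
        stream = rk.stream_predict(cnn12, rec, calibration_s=16.0)
        offline = rk.predict(cnn12, rk.zscore(rec))
        shared = stream.p[0::2][:offline.p.size]
        assert np.max(np.abs(shared - offline.p[:shared.size])) < 0.05

    def test_requires_cnn12_and_enough_calibration(self, cnn32, cnn12):
        rec = rk.LfpRecording(np.zeros((2000, 8)), fs=1250.0)
        with pytest.raises(ValueError, match="CNN12"):
            rk.stream_predict(cnn32, rec)
        with pytest.raises(ValueError, match="calibration"):
            rk.stream_predict(cnn12, rec, calibration_s=10.0)


def _brute_force_events(p, onset, confirm, window_s, t0=0.0):
    """Two-pass oracle: enumerate all maximal onset-runs, then filter."""
    events = []
    i = 0
    while i < len(p):
        if p[i] >= onset:
            j = i
            while j + 1 < len(p) and p[j + 1] >= onset:
                j += 1
            if any(p[k] >= confirm for k in range(i, j + 1)):
                events.append((t0 + i * window_s, t0 + (j + 1) * window_s))
            i = j + 1
        else:
            i += 1
    return events


class TestExtractEvents:
    def test_all_zero_trace_has_no_events(self):
        trace = rk.ProbabilityTrace(np.zeros(100), 0.032)
        assert len(extract_events(trace, 0.4, 0.7).events) == 0

    def test_stated_rule_enumeration(self):
        trace = rk.ProbabilityTrace([0.0, 0.45, 0.75, 0.8, 0.2], 0.032)
        det = extract_events(trace, 0.4, 0.7)
        np.testing.assert_allclose(det.events.intervals, [[0.032, 0.128]])
        assert det.peak_p[0] == pytest.approx(0.8)

    def test_equal_thresholds_degenerate_to_single_threshold(self, rng):
        p = rng.uniform(size=500)
        trace = rk.ProbabilityTrace(p, 0.032)
        det = extract_events(trace, 0.6, 0.6)
        oracle = _brute_force_events(p, 0.6, 0.6, 0.032)
        np.testing.assert_allclose(det.events.intervals,
                                   np.array(oracle).reshape(-1, 2))

    def test_matches_brute_force_scan_on_random_traces(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            onset = rng.uniform(0, 0.8)
            confirm = rng.uniform(onset, 1.0)
            trace = rk.ProbabilityTrace(p, 0.032)
            got = extract_events(trace, onset, confirm).events.intervals
            want = np.array(_brute_force_events(p, onset, confirm, 0.032)
                            ).reshape(-1, 2)
            np.testing.assert_allclose(got, want)

    def test_invalid_threshold_order_rejected(self):
        trace = rk.ProbabilityTrace(np.zeros(10), 0.032)
        with pytest.raises(ValueError):
            extract_events(trace, 0.8, 0.4)


class TestPersistence:
    def test_round_trip_predictions_identical(self, cnn32, tmp_path, rng):
        x = rng.standard_normal((1, 4000, 8))
        before = cnn32.predict_proba(x)
        rk.save_model(cnn32, tmp_path / "m")
        back = rk.load_model(tmp_path / "m")
        np.testing.assert_array_equal(back.predict_proba(x), before)

    def test_manifest_weight_mismatch_rejected(self, cnn32, cnn12, tmp_path):
        rk.save_model(cnn32, tmp_path / "m")
        import json
        manifest = json.loads((tmp_path / "m" / "manifest.json").read_text())
        manifest["variant"] = "CNN12"
        manifest["kernel_sizes"] = [2, 1, 2, 1, 2, 1, 2]
        (tmp_path / "m" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            rk.load_model(tmp_path / "m")
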