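"""Six-step cleaning chain: filters, ASR, wICA, segmentation, orchestrator."""

import numpy as np
import pytest
from scipy.signal import welch

import tinnerp as t
from tinnerp.eegsim import DEFAULT_CHANNEL_WEIGHTS
from tinnerp.exceptions import EmptyEpochsError

from conftest import multichannel_scale

FS = 256.0


def sine_recording(freq, duration=30.0, amplitude=10.0, n_ch=2):
    n = int(duration * FS)
    x = amplitude * np.sin(2 * np.pi * freq * np.arange(n) / FS)
    return t.EEGRecording(data=np.tile(x, (n_ch, 1)), fs=FS,
                          channels=tuple(t.MONTAGE_16[:n_ch]))


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# steps 1-3: baseline and filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_baseline_removal_zero_means(self):
        rec = t.EEGRecording(data=np.random.default_rng(0).normal(5.0, 1.0,
                                                                  (2, 1000)),
                             fs=FS, channels=("C3", "C4"))
        out = t.remove_baseline(rec)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_bandpass_preserves_mid_band(self):
        rec = sine_recording(10.0)
        out = t.bandpass(rec)
        assert rms(out.data) == pytest.approx(rms(rec.data), rel=0.02)

    def test_bandpass_removes_slow_drift(self):
        rec = sine_recording(0.01, duration=120.0)
        out = t.bandpass(rec)
        assert rms(out.data) < 0.1 * rms(rec.data)

    def test_bandpass_removes_high_frequency(self):
        rec = sine_recording(120.0)
        out = t.bandpass(rec)
        # compare away from the filtfilt edge transients
        n = rec.data.shape[1]
        sl = slice(n // 4, 3 * n // 4)
        assert rms(out.data[:, sl]) < 0.1 * rms(rec.data[:, sl])

    def test_bandpass_validates_nyquist(self):
        rec = sine_recording(10.0)
        with pytest.raises(ValueError):
            t.bandpass(rec, high=130.0)

    def test_notch_attenuates_60_hz(self):
        rec = sine_recording(60.0)
        out = t.notch60(rec)
        assert rms(out.data) < 0.05 * rms(rec.data)

    def test_notch_preserves_50_hz(self):
        rec = sine_recording(50.0)
        out = t.notch60(rec)
        assert rms(out.data) == pytest.approx(rms(rec.data), rel=0.1)

    def test_filters_are_zero_phase(self, tinnitus_template):
        # spec-level invariant: peak latency of a filtered template moves <= 1 sample
        n_rep = 40
        x = np.tile(tinnitus_template, n_rep)
        rec = t.EEGRecording(data=np.tile(x, (2, 1)), fs=FS,
                             channels=("C3", "C4"))
        for op in (t.bandpass, t.notch60):
            out = op(rec)
            # compare peaks inside a central repetition, away from edges
            lo, hi = 10 * 256, 11 * 256
            p_in = np.argmax(rec.data[0, lo:hi])
            p_out = np.argmax(out.data[0, lo:hi])
            assert abs(int(p_in) - int(p_out)) <= 1


# ---------------------------------------------------------------------------
# step 4: ASR
# ---------------------------------------------------------------------------

class TestASR:
    def test_clean_data_passes_through(self, small_session):
        rec, _ = small_session
        filt = t.notch60(t.bandpass(t.remove_baseline(rec)))
        out, report = t.asr_clean(filt)
        assert report.steps[0]["windows_altered"] == 0
        np.testing.assert_allclose(out.data, filt.data, atol=1e-9)

    def test_pop_artifact_removed(self, tinnitus_template, schedule):
        arts = {"pops": {"n": 1, "amplitude": 500.0, "channel": "T8"}}
        rec, truth = t.simulate_session(tinnitus_template, schedule,
                                        noise_sd=3.0, seed=7, artifacts=arts)
        filt = t.notch60(t.bandpass(t.remove_baseline(rec)))
        out, report = t.asr_clean(filt)
        assert report.steps[0]["windows_altered"] > 0
        pop = truth.artifacts[0]
        k = rec.channels.index(pop["channel"])
        i0 = int(pop["onset_s"] * FS)
        i1 = i0 + int(pop["duration_s"] * FS)
        # residual during the pop is on the order of the background, not 500 uV
        assert rms(out.data[k, i0:i1]) < 0.1 * rms(filt.data[k, i0:i1])

    def test_short_calibration_rejected(self, small_session):
        rec, _ = small_session
        with pytest.raises(ValueError):
            t.asr_clean(rec, calibration=rec.data[:, : int(10 * FS)])

    def test_report_window_bookkeeping(self, small_session):
        rec, _ = small_session
        _, report = t.asr_clean(rec)
        step = report.steps[0]
        assert step["step"] == "asr"
        assert step["windows_altered"] <= step["windows_total"]


# ---------------------------------------------------------------------------
# step 5: wICA
# ---------------------------------------------------------------------------

class TestWICA:
    def test_clean_data_nearly_unchanged(self, small_session):
        rec, _ = small_session
        filt = t.notch60(t.bandpass(t.remove_baseline(rec)))
        out, report = t.remove_stationary(filt, seed=0)
        change = rms(out.data - filt.data) / rms(filt.data)
        assert change < 0.05

    def test_blinks_reduce_frontal_low_frequency_power(self, tinnitus_template,
                                                       schedule):
        arts = {"ocular": {"n": 8, "amplitude": 150.0}}
        rec, _ = t.simulate_session(tinnitus_template, schedule, noise_sd=3.0,
                                    seed=11, artifacts=arts)
        filt = t.notch60(t.bandpass(t.remove_baseline(rec)))
        out, report = t.remove_stationary(filt, seed=0)
        assert report.steps[0]["components_flagged"] >= 1
        k = rec.channels.index("Fp1")
        f, p_in = welch(filt.data[k], fs=FS, nperseg=1024)
        _, p_out = welch(out.data[k], fs=FS, nperseg=1024)
        lf = f < 4.0
        assert p_out[lf].sum() < 0.5 * p_in[lf].sum()

    def test_occipital_alpha_preserved(self):
        rec, _ = t.simulate_resting(iaf=10.0, seed=5)
        out, _ = t.remove_stationary(rec, seed=0)
        k = rec.channels.index("O1")
        f, p_in = welch(rec.data[k], fs=FS, nperseg=2048)
        _, p_out = welch(out.data[k], fs=FS, nperseg=2048)
        band = (f >= 8) & (f <= 12)
        assert p_out[band].sum() == pytest.approx(p_in[band].sum(), rel=0.05)

    def test_too_few_channels_rejected(self):
        rec = t.EEGRecording(data=np.zeros((1, int(20 * FS))), fs=FS,
                             channels=("C3",))
        with pytest.raises(ValueError):
            t.remove_stationary(rec)

    def test_too_short_recording_rejected(self):
        rec = t.EEGRecording(data=np.zeros((2, int(5 * FS))), fs=FS,
                             channels=("C3", "C4"))
        with pytest.raises(ValueError):
            t.remove_stationary(rec)


# ---------------------------------------------------------------------------
# step 6: segmentation
# ---------------------------------------------------------------------------

class TestSegment:
    def test_epoch_shape(self, small_session):
        rec, _ = small_session
        ep = t.segment(rec)
        assert ep.data.shape == (50, 16, 256)
        assert ep.times.size == 256

    def test_baseline_correction_zeroes_prestimulus_mean(self, small_session):
        rec, _ = small_session
        ep = t.segment(rec, baseline_correct=True)
        pre = ep.data[:, :, ep.times < 0]
        np.testing.assert_allclose(pre.mean(axis=2), 0.0, atol=1e-9)

    def test_baseline_correction_can_be_disabled(self, small_session):
        rec, _ = small_session
        ep = t.segment(rec, baseline_correct=False)
        assert np.abs(ep.data[:, :, ep.times < 0].mean(axis=2)).max() > 0

    def test_partial_epochs_are_dropped_and_logged(self):
        n = int(10 * FS)
        rec = t.EEGRecording(data=np.zeros((2, n)), fs=FS,
                             channels=("C3", "C4"),
                             events=[(10, "stim"), (5 * 256, "stim"),
                                     (n - 10, "stim")])
        ep = t.segment(rec)
        assert ep.n_trials == 1
        assert ep.rejected == [0, 2]

    def test_no_events_raises(self):
        rec = t.EEGRecording(data=np.zeros((2, 1000)), fs=FS,
                             channels=("C3", "C4"))
        with pytest.raises(EmptyEpochsError):
            t.segment(rec)

    def test_epochset_validation(self):
        with pytest.raises(ValueError):
            t.EpochSet(data=np.zeros((5, 2, 100)), times=np.zeros(90), fs=FS,
                       channels=("C3", "C4"))


# ---------------------------------------------------------------------------
# orchestrator and the end-to-end recovery invariant
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_orchestrator_runs_all_steps_in_order(self, small_session):
        rec, _ = small_session
        epochs, report = t.preprocess_pipeline(rec)
        names = [s["step"] for s in report.steps]
        assert names == ["baseline_removal", "bandpass", "notch60", "asr",
                         "wica", "segment"]
        assert epochs.data.shape == (50, 16, 256)

    def test_artifacted_session_recovers_template(self, tinnitus_template,
                                                  schedule):
        """Steps 1-5 on an artifact-laden session leave the embedded template
        in the trial average within 20% amplitude error.

        The recovered scale is measured against the truth manifest by
        multichannel weighted least squares.  noise_sd is 3 uV so that the
        artifact-free estimator noise floor (50-trial protocol) stays well
        below the bound and a failure indicts the cleaning chain itself.
        """
        arts = {"ocular": {"n": 6, "amplitude": 150.0},
                "line": {"amplitude": 5.0},
                "pops": {"n": 1, "amplitude": 500.0}}
        for seed in (0, 1, 2):
            rec, truth = t.simulate_session(tinnitus_template, schedule,
                                            itc_level=1.0, noise_sd=3.0,
                                            seed=seed, artifacts=arts)
            epochs, _ = t.preprocess_pipeline(rec)
            scale = multichannel_scale(epochs, truth.template,
                                       truth.channel_weights)
            assert abs(scale - 1.0) <= 0.20
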