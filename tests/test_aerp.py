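"""AERP estimation: IAF, averaging, ITC, weighting, grand average, AUC, peaks."""

import numpy as np
import pytest

import tinnerp as t
from tinnerp.aerp import REFERENCE_IAF_HZ
from tinnerp.exceptions import (EmptyEpochsError, IncompatibleAxesError,
                                MissingChannelError)

FS = 256.0


def make_epochs(data, channels=("C3", "C4")):
    times = t.epoch_times(FS)
    return t.EpochSet(data=data, times=times, fs=FS, channels=channels)


def phase_locked_epochs(n_trials, freq, phase_sd=0.0, seed=0,
                        channels=("C3", "C4")):
    """Band oscillation with controlled phase scatter across trials."""
    rng = np.random.default_rng(seed)
    times = t.epoch_times(FS) / 1000.0
    data = np.empty((n_trials, len(channels), times.size))
    for i in range(n_trials):
        ph = rng.normal(0.0, phase_sd)
        data[i] = np.sin(2 * np.pi * freq * times + ph)
    return make_epochs(data, channels)


# ---------------------------------------------------------------------------
# IAF
# ---------------------------------------------------------------------------

class TestIAF:
    def test_recovery_on_synthetic_resting(self):
        rec, truth = t.simulate_resting(iaf=9.5, seed=0)
        assert t.estimate_iaf(rec) == pytest.approx(9.5, abs=0.25)

    def test_missing_occipital_channel(self):
        rec = t.EEGRecording(data=np.zeros((2, int(120 * FS))), fs=FS,
                             channels=("C3", "C4"))
        with pytest.raises(MissingChannelError):
            t.estimate_iaf(rec)

    def test_too_short_recording(self):
        rec = t.EEGRecording(data=np.zeros((16, int(30 * FS))), fs=FS)
        with pytest.raises(ValueError):
            t.estimate_iaf(rec)

    def test_low_prominence_warns(self):
        rec, _ = t.simulate_resting(iaf=10.0, alpha_snr=0.0, duration=120.0,
                                    seed=3)
        with pytest.warns(RuntimeWarning):
            t.estimate_iaf(rec)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

class TestAverage:
    def test_average_is_trial_mean(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(10, 2, 256)))
        np.testing.assert_allclose(t.average_epochs(ep), ep.data.mean(axis=0))

    def test_empty_epochs_raise(self):
        ep = make_epochs(np.empty((0, 2, 256)))
        with pytest.raises(EmptyEpochsError):
            t.average_epochs(ep)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

class TestITC:
    def test_identical_trials_give_unit_coherence(self):
        ep = phase_locked_epochs(20, 10.0, phase_sd=0.0)
        itc = t.compute_itc(ep, iaf=10.0)
        np.testing.assert_allclose(itc, 1.0, atol=1e-6)

    def test_bounds_for_random_phases(self):
        ep = phase_locked_epochs(30, 10.0, phase_sd=50.0, seed=1)
        itc = t.compute_itc(ep, iaf=10.0)
        assert np.all(itc >= 0.0) and np.all(itc <= 1.0)

    def test_phase_scatter_lowers_coherence(self):
        tight = t.compute_itc(phase_locked_epochs(40, 10.0, 0.2, seed=2), 10.0)
        loose = t.compute_itc(phase_locked_epochs(40, 10.0, 2.0, seed=2), 10.0)
        assert np.all(tight > loose)

    def test_random_phase_matches_resultant_null_oracle(self):
        # For N uniform phases the expected resultant length is ~ sqrt(pi/(4N));
        # Monte-Carlo oracle below, estimator compared within 20%.
        n_trials = 50
        rng = np.random.default_rng(7)
        oracle = np.mean([
            np.abs(np.mean(np.exp(1j * rng.uniform(0, 2 * np.pi, n_trials))))
            for _ in range(4000)])
        vals = []
        for seed in range(20):
            ep = phase_locked_epochs(n_trials, 10.0, phase_sd=100.0, seed=seed)
            vals.append(t.compute_itc(ep, 10.0).mean())
        assert np.mean(vals) == pytest.approx(oracle, rel=0.2)

    def test_single_trial_is_degenerate(self):
        ep = phase_locked_epochs(1, 10.0)
        with pytest.warns(RuntimeWarning):
            itc = t.compute_itc(ep, 10.0)
        np.testing.assert_allclose(itc, 1.0)

    def test_band_validation(self):
        ep = phase_locked_epochs(5, 10.0)
        with pytest.raises(ValueError):
            t.compute_itc(ep, iaf=1.0)          # lower edge <= 0
        with pytest.raises(ValueError):
            t.compute_itc(ep, iaf=127.0)        # upper edge >= Nyquist

    def test_unknown_method(self):
        ep = phase_locked_epochs(5, 10.0)
        with pytest.raises(ValueError):
            t.compute_itc(ep, 10.0, method="median")

    def test_peak_phase_variant_available(self):
        ep = phase_locked_epochs(20, 10.0, phase_sd=0.0)
        itc = t.compute_itc(ep, 10.0, method="peak-phase")
        np.testing.assert_allclose(itc, 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# weighting and grand averages
# ---------------------------------------------------------------------------

class TestWeighting:
    def test_weights_multiply_channels(self):
        times = t.epoch_times(FS)
        avg = np.vstack([np.ones(256), 2 * np.ones(256)])
        res = t.weight_aerp(avg, itc=[0.5, 1.0], iaf=8.0, times=times,
                            channels=("C3", "C4"))
        # weight = itc * (10 / 8)
        np.testing.assert_allclose(res.waveforms[0], 0.5 * 1.25)
        np.testing.assert_allclose(res.waveforms[1], 2.0 * 1.25)
        np.testing.assert_allclose(res.weights, [0.625, 1.25])

    def test_reference_iaf_gives_unit_factor(self):
        times = t.epoch_times(FS)
        avg = np.ones((1, 256))
        res = t.weight_aerp(avg, itc=[1.0], iaf=REFERENCE_IAF_HZ, times=times,
                            channels=("C3",))
        np.testing.assert_allclose(res.waveforms, avg)

    def test_itc_out_of_bounds_rejected(self):
        times = t.epoch_times(FS)
        with pytest.raises(ValueError):
            t.weight_aerp(np.ones((1, 256)), itc=[1.2], iaf=10.0, times=times,
                          channels=("C3",))

    def test_grand_average_is_mean(self):
        times = t.epoch_times(FS)
        res = [t.weight_aerp(np.full((1, 256), v), [1.0], 10.0, times, ("C3",))
               for v in (1.0, 3.0)]
        np.testing.assert_allclose(t.grand_average(res), 2.0)

    def test_grand_average_montage_mismatch(self):
        times = t.epoch_times(FS)
        a = t.weight_aerp(np.ones((1, 256)), [1.0], 10.0, times, ("C3",))
        b = t.weight_aerp(np.ones((1, 256)), [1.0], 10.0, times, ("C4",))
        with pytest.raises(IncompatibleAxesError):
            t.grand_average([a, b])

    def test_grand_average_needs_input(self):
        with pytest.raises(ValueError):
            t.grand_average([])


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAUC:
    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        times = t.epoch_times(FS)
        a, b = rng.normal(size=(2, 16, 256))
        fwd = t.auc_difference(a, b, times, t.MONTAGE_16)
        rev = t.auc_difference(b, a, times, t.MONTAGE_16)
        np.testing.assert_allclose(fwd.auc, -rev.auc)
        assert fwd.auc_max == pytest.approx(rev.auc_max)

    def test_half_sine_analytic_oracle(self):
        # difference = half sine of amplitude 1 uV over the 1000-ms window:
        # integral = 2 * A * T / pi = 2000/pi uV*ms
        times = t.epoch_times(FS)
        span = times[-1] - times[0]
        diff = np.sin(np.pi * (times - times[0]) / span)[None, :]
        res = t.auc_difference(diff, np.zeros_like(diff), times, ("C3",))
        assert res.auc[0] == pytest.approx(2.0 * span / np.pi, rel=1e-3)

    def test_max_channel_and_tie_break(self):
        times = t.epoch_times(FS)
        ga = np.zeros((3, 256))
        ga[1] = 1.0
        ga[2] = 1.0   # tie with channel index 1 -> first wins
        res = t.auc_difference(ga, np.zeros_like(ga), times,
                               ("C3", "C4", "T7"))
        assert res.auc_channel == "C4"
        assert res.auc_max == pytest.approx(abs(res.auc[1]))

    def test_shape_mismatch_rejected(self):
        times = t.epoch_times(FS)
        with pytest.raises(IncompatibleAxesError):
            t.auc_difference(np.zeros((2, 256)), np.zeros((3, 256)), times,
                             ("C3", "C4"))


# ---------------------------------------------------------------------------
# component peaks
# ---------------------------------------------------------------------------

class TestDetectComponents:
    WINDOWS = {"N1": (80.0, 220.0), "P2": (180.0, 320.0), "P3": (300.0, 500.0)}

    def test_negative_components_take_minimum(self):
        tpl = t.make_template(t.TINNITUS_COMPONENTS)
        times = t.epoch_times(FS)
        peaks = t.detect_components(tpl, times, self.WINDOWS).peaks
        assert peaks["N1"][0] == pytest.approx(-1.7, abs=0.05)
        assert peaks["P2"][0] == pytest.approx(2.4, abs=0.05)

    def test_latencies_on_grid(self):
        tpl = t.make_template(t.TINNITUS_COMPONENTS)
        times = t.epoch_times(FS)
        peaks = t.detect_components(tpl, times, self.WINDOWS).peaks
        dt = 1000.0 / FS
        assert abs(peaks["N1"][1] - 150.0) <= dt
        assert abs(peaks["P3"][1] - 380.0) <= dt

    def test_tie_breaks_to_earliest(self):
        times = t.epoch_times(FS)
        flat = np.ones(256)
        peaks = t.detect_components(flat, times, {"P2": (100.0, 300.0)}).peaks
        in_window = times[(times >= 100.0) & (times <= 300.0)]
        assert peaks["P2"][1] == pytest.approx(in_window[0])

    def test_window_outside_epoch_rejected(self):
        times = t.epoch_times(FS)
        with pytest.raises(ValueError):
            t.detect_components(np.zeros(256), times, {"P9": (900.0, 1000.0)})
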