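import numpy as np
import pytest
from scipy import signal as sig

import ssvep_tuning as st

from conftest import make_epochs


def sinusoid_epochs(freq, n_trials=2, n_ch=4, fs=250.0, amp=1.0):
    t = np.arange(900) / fs
    wave = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(wave, (n_trials, n_ch, 1))
    return make_epochs(data, fs=fs)


def steady_amplitude(epochs, freq):
    """Amplitude of the driving frequency in the steady-state segment."""
    seg = epochs.data[0, 0, 200:825]  # integer cycles of 12/60 Hz at 250 Hz
    spec = np.abs(np.fft.rfft(seg)) * 2 / len(seg)
    freqs = np.fft.rfftfreq(len(seg), 1 / epochs.fs)
    return spec[int(np.argmin(np.abs(freqs - freq)))]


class TestLowpass:
    def test_dc_unchanged(self):
        epochs = make_epochs(np.full((2, 3, 900), 7.5))
        out = st.lowpass_filter(epochs)
        np.testing.assert_allclose(out.data, 7.5, atol=1e-9)

    def test_12hz_preserved(self):
        epochs = sinusoid_epochs(12.0)
        out = st.lowpass_filter(epochs, cutoff=40.0)
        assert steady_amplitude(out, 12.0) == pytest.approx(
            steady_amplitude(epochs, 12.0), rel=0.01)

    def test_60hz_attenuated(self):
        epochs = sinusoid_epochs(60.0)
        out = st.lowpass_filter(epochs, cutoff=40.0)
        assert steady_amplitude(out, 60.0) < 0.1 * steady_amplitude(epochs, 60.0)

    def test_magnitude_response_of_design(self):
        # the designed filter itself: |H(12)| > 0.99, |H(60)| < 0.1 after
        # forward-backward application
        sos = sig.butter(4, 40.0, btype="low", fs=250.0, output="sos")
        w, h = sig.sosfreqz(sos, worN=[12.0, 60.0], fs=250.0)
        assert np.abs(h[0]) ** 2 > 0.99
        assert np.abs(h[1]) ** 2 < 0.1

    def test_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            st.lowpass_filter(sinusoid_epochs(12.0), cutoff=130.0)


class TestDetectArtifacts:
    def make_noisy(self, rng, n_trials=30, n_ch=129):
        return make_epochs(rng.normal(0, 10, size=(n_trials, n_ch, 300)))

    def test_clean_data_no_rejections(self, rng):
        report = st.detect_artifacts(self.make_noisy(rng))
        assert report.n_rejected == 0

    def test_all_constant_no_flags(self):
        epochs = make_epochs(np.full((5, 10, 100), 3.0))
        report = st.detect_artifacts(epochs)
        assert not report.flags.any()
        assert report.n_rejected == 0

    def test_21_saturated_channels_rejects_trial(self, rng):
        epochs = self.make_noisy(rng)
        epochs.data[3, :21, :] = 500.0 * np.sign(np.sin(np.arange(300)))
        report = st.detect_artifacts(epochs, max_bad=20)
        assert report.rejected[3]
        assert report.rejected.sum() == 1

    def test_20_saturated_channels_kept_but_flagged(self, rng):
        epochs = self.make_noisy(rng)
        epochs.data[3, :20, :] = 500.0 * np.sign(np.sin(np.arange(300)))
        report = st.detect_artifacts(epochs, max_bad=20)
        assert not report.rejected[3]
        assert report.flags[3, :20].all()

    def test_decision_ignores_condition_labels(self, rng):
        epochs = self.make_noisy(rng)
        epochs.data[2, :25, :] = 400.0
        report1 = st.detect_artifacts(epochs)
        permuted = st.EpochSet(
            epochs.data, epochs.fs, epochs.t0_ms,
            epochs.trial_meta.assign(condition=np.random.default_rng(0).permutation(
                epochs.trial_meta["condition"].to_numpy())),
            list(epochs.channels))
        report2 = st.detect_artifacts(permuted)
        np.testing.assert_array_equal(report1.rejected, report2.rejected)
        np.testing.assert_array_equal(report1.flags, report2.flags)

    def test_single_trial_raises(self, rng):
        with pytest.raises(ValueError):
            st.detect_artifacts(make_epochs(rng.normal(size=(1, 4, 100))))


class TestInterpolation:
    def test_no_flags_identity(self, rng, small_montage):
        data = rng.normal(size=(3, small_montage.n_channels, 120))
        epochs = make_epochs(data)
        report = st.detect_artifacts(epochs)
        report.flags[:] = False  # no flags -> identity
        out = st.interpolate_channels(epochs, report, small_montage)
        np.testing.assert_array_equal(out.data, data)

    def test_constant_potential(self, small_montage):
        n_ch = small_montage.n_channels
        data = np.full((2, n_ch, 50), 4.2)
        epochs = make_epochs(data)
        report = st.detect_artifacts(epochs)
        report.flags[0, 5] = True  # force a flag
        out = st.interpolate_channels(epochs, report, small_montage)
        np.testing.assert_allclose(out.data[0, 5], 4.2, atol=1e-6)

    def test_degree1_harmonic_reconstruction(self, full_montage):
        """A linear (degree-1 spherical harmonic) field is recovered at a
        flagged sensor to high accuracy."""
        pos = full_montage.positions
        field = 3.0 * pos[:, 2] + 1.5 * pos[:, 0]  # combination of l=1 harmonics
        data = np.tile(field[None, :, None], (2, 1, 10))
        epochs = make_epochs(data)
        report = st.detect_artifacts(epochs)
        bad = 17
        report.flags[:] = False
        report.flags[0, bad] = True
        out = st.interpolate_channels(epochs, report, full_montage)
        rel_err = abs(out.data[0, bad, 0] - field[bad]) / np.abs(field).max()
        assert rel_err < 1e-3
        # unflagged channels bit-identical
        good = np.ones(129, bool)
        good[bad] = False
        np.testing.assert_array_equal(out.data[0, good], data[0, good])

    def test_linearity_on_fixed_flags(self, rng, small_montage):
        n_ch = small_montage.n_channels
        x = rng.normal(size=(2, n_ch, 30))
        y = rng.normal(size=(2, n_ch, 30))
        report = st.detect_artifacts(make_epochs(x))
        report.flags[:] = False
        report.flags[:, 3] = True
        def interp(d):
            return st.interpolate_channels(make_epochs(d), report, small_montage).data
        lhs = interp(2.0 * x + 0.5 * y)
        rhs = 2.0 * interp(x) + 0.5 * interp(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_too_few_good_channels(self, rng, small_montage):
        epochs = make_epochs(rng.normal(size=(2, small_montage.n_channels, 20)))
        report = st.detect_artifacts(epochs)
        report.flags[0, :] = True
        report.flags[0, :3] = False  # only 3 good
        report.rejected[:] = False
        with pytest.raises(ValueError, match="underdetermined"):
            st.interpolate_channels(epochs, report, small_montage)


class TestAveraging:
    def test_identical_trials(self, rng):
        trial = rng.normal(size=(1, 4, 50))
        data = np.tile(trial, (6, 1, 1))
        epochs = make_epochs(data, conditions=["CS+"] * 3 + ["CS-"] * 3)
        avg = st.average_conditions(epochs)
        np.testing.assert_allclose(avg.data, np.tile(trial, (2, 1, 1)))
        np.testing.assert_array_equal(avg.n_trials_averaged, [3, 3])

    def test_plus_minus_cancel(self, rng):
        v = rng.normal(size=(4, 50))
        data = np.stack([v, -v])
        epochs = make_epochs(data, conditions=["CS+", "CS+"])
        avg = st.average_conditions(epochs)
        np.testing.assert_allclose(avg.data[0], 0.0, atol=1e-12)

    def test_rejected_trials_excluded(self, rng):
        data = rng.normal(size=(4, 3, 20))
        data[0] = 1000.0
        epochs = make_epochs(data, conditions=["CS+"] * 4)
        report = st.detect_artifacts(epochs)
        report.rejected[:] = [True, False, False, False]
        avg = st.average_conditions(epochs, report)
        assert avg.n_trials_averaged[0] == 3
        np.testing.assert_allclose(avg.data[0], data[1:].mean(axis=0))

    def test_empty_cell_raises(self, rng):
        data = rng.normal(size=(2, 3, 20))
        epochs = make_epochs(data, conditions=["CS+", "CS-"])
        report = st.detect_artifacts(epochs)
        report.rejected[:] = [True, False]
        with pytest.raises(ValueError, match="CS\\+"):
            st.average_conditions(epochs, report)

    def test_exclude_reinforced(self, rng):
        data = rng.normal(size=(4, 3, 20))
        epochs = make_epochs(data, conditions=["CS+"] * 4)
        epochs.trial_meta["reinforced"] = [True, True, False, False]
        avg = st.average_conditions(epochs, exclude_reinforced=True)
        assert avg.n_trials_averaged[0] == 2
        np.testing.assert_allclose(avg.data[0], data[2:].mean(axis=0))

    def test_averaged_amplitude_within_3se(self, rng):
        """15 noisy repetitions of a fixed sinusoid: averaged 12 Hz amplitude
        lands within 3 standard errors of the truth."""
        fs, n, amp, sd = 250.0, 625, 2.0, 1.0
        t = np.arange(n) / fs
        wave = amp * np.sin(2 * np.pi * 12.0 * t)
        data = wave[None, None, :] + rng.normal(0, sd, size=(15, 1, n))
        epochs = make_epochs(data, t0_ms=0.0)
        avg = st.average_conditions(epochs)
        seg = avg.data[0, 0]
        spec = np.abs(np.fft.rfft(seg)) * 2 / n
        freqs = np.fft.rfftfreq(n, 1 / fs)
        est = spec[int(np.argmin(np.abs(freqs - 12.0)))]
        # SE of the complex bin amplitude ~ sd * sqrt(2/n) / sqrt(15)
        se = sd * np.sqrt(2.0 / n) / np.sqrt(15)
        assert abs(est - amp) < 3 * se


def test_filter_linearity(rng):
    x = rng.normal(size=(2, 3, 900))
    y = rng.normal(size=(2, 3, 900))
    fx = st.lowpass_filter(make_epochs(x)).data
    fy = st.lowpass_filter(make_epochs(y)).data
    fxy = st.lowpass_filter(make_epochs(3.0 * x - 0.7 * y)).data
    np.testing.assert_allclose(fxy, 3.0 * fx - 0.7 * fy, atol=1e-8)
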