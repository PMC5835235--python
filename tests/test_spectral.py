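"""Filtering and multitaper line-noise regression."""
import numpy as np
import pytest
from scipy import signal

from happe.core import Recording
from happe.spectral import (LineNoiseConfig, bandpass_if_high_rate,
                            highpass_filter, remove_line_noise)

from conftest import pink_noise


def fft_amplitude(x, fs, freq):
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    return 2.0 * np.abs(spec[np.argmin(np.abs(f - freq))]) / x.size


class TestHighpass:
    fs = 250.0
    n = 15000

    def test_dc_removed(self):
        rec = Recording(np.full((1, self.n), 10.0), self.fs, ["a"])
        out = highpass_filter(rec)
        assert np.abs(out.data).mean() < 0.01

    def test_passband_and_stopband(self):
        t = np.arange(self.n) / self.fs
        x = np.sin(2 * np.pi * 0.1 * t) + np.sin(2 * np.pi * 10 * t)
        out = highpass_filter(Recording(x[None, :], self.fs, ["a"]))
        a10 = fft_amplitude(out.data[0], self.fs, 10.0)
        a01 = fft_amplitude(out.data[0], self.fs, 0.1)
        assert a10 == pytest.approx(1.0, rel=0.05)
        assert 20 * np.log10(1.0 / max(a01, 1e-12)) > 20   # > 20 dB down

    def test_cutoff_gain_matches_design(self):
        # forward-backward application squares the filter's own response
        from happe.spectral import _fir_highpass
        taps = _fir_highpass(self.fs)
        w, h = signal.freqz(taps, worN=[1.0], fs=self.fs)
        designed = np.abs(h[0]) ** 2
        t = np.arange(self.n) / self.fs
        x = np.sin(2 * np.pi * 1.0 * t)
        out = highpass_filter(Recording(x[None, :], self.fs, ["a"]))
        measured = fft_amplitude(out.data[0], self.fs, 1.0)
        assert measured == pytest.approx(designed, rel=0.05)

    def test_too_short_recording(self):
        rec = Recording(np.zeros((1, 100)), self.fs, ["a"])
        with pytest.raises(ValueError, match="s at"):
            highpass_filter(rec)

    def test_zero_phase(self):
        rng = np.random.default_rng(3)
        x = 10 * pink_noise(rng, 1, self.n, self.fs)
        out = highpass_filter(Recording(x, self.fs, ["a"]))
        lags = signal.correlation_lags(self.n, self.n)
        xc = signal.correlate(out.data[0], x[0])
        assert lags[np.argmax(xc)] == 0


class TestBandpassBranch:
    def test_high_rate_attenuates_300hz(self):
        fs, n = 1000.0, 30000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 300 * t) + np.sin(2 * np.pi * 100 * t)
        out = bandpass_if_high_rate(Recording(x[None, :], fs, ["a"]))
        assert fft_amplitude(out.data[0], fs, 300.0) < 0.1   # > 20 dB
        assert fft_amplitude(out.data[0], fs, 100.0) == \
            pytest.approx(1.0, rel=0.05)

    def test_low_rate_equals_highpass(self):
        rng = np.random.default_rng(4)
        rec = Recording(10 * pink_noise(rng, 2, 15000, 250.0), 250.0,
                        ["a", "b"])
        assert np.allclose(bandpass_if_high_rate(rec).data,
                           highpass_filter(rec).data)


class TestLineNoise:
    fs = 250.0
    n = 15000

    def _psd(self, data):
        return signal.welch(data, self.fs, nperseg=int(4 * self.fs))

    def test_planted_tone_suppressed_neighbors_preserved(self):
        rng = np.random.default_rng(11)
        t = np.arange(self.n) / self.fs
        base = 10 * pink_noise(rng, 4, self.n, self.fs)
        tone = 20 * np.sin(2 * np.pi * 60 * t + rng.uniform(0, 2 * np.pi))
        rec = Recording(base + tone, self.fs, list("abcd"))
        out = remove_line_noise(rec, LineNoiseConfig(target_freq=60))
        f, p0 = self._psd(rec.data)
        _, p1 = self._psd(out.data)
        i60 = np.argmin(np.abs(f - 60))
        floor = p1[:, (np.abs(f - 55) < 1) | (np.abs(f - 65) < 1)].mean()
        assert 10 * np.log10(p1[:, i60].mean() / floor) < 3.0
        for center in (55.0, 65.0):
            band = np.abs(f - center) <= 1.0
            change = abs(p1[:, band].mean() / p0[:, band].mean() - 1.0)
            assert change < 0.10

    def test_null_case_untouched(self):
        rng = np.random.default_rng(12)
        lp = signal.firwin(501, 45, fs=self.fs)
        x = signal.filtfilt(lp, [1.0], 10 * pink_noise(rng, 3, self.n,
                                                       self.fs))
        rec = Recording(x, self.fs, list("abc"))
        out = remove_line_noise(rec, LineNoiseConfig(target_freq=60))
        assert np.abs(out.data - rec.data).max() < 1e-6 * x.std()

    def test_frequency_scan_locates_offset_tone(self):
        rng = np.random.default_rng(13)
        t = np.arange(self.n) / self.fs
        x = 10 * pink_noise(rng, 1, self.n, self.fs) \
            + 20 * np.sin(2 * np.pi * 60.4 * t)
        rec = Recording(x, self.fs, ["a"])
        out = remove_line_noise(rec, LineNoiseConfig(target_freq=60))
        f, p0 = self._psd(rec.data)
        _, p1 = self._psd(out.data)
        i = np.argmin(np.abs(f - 60.4))
        assert p1[:, i].mean() < 0.01 * p0[:, i].mean()   # > 20 dB removed

    def test_band_power_never_increased(self):
        rng = np.random.default_rng(14)
        t = np.arange(self.n) / self.fs
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = 10 * pink_noise(r, 2, self.n, self.fs) \
                + 15 * np.sin(2 * np.pi * 60 * t)
            rec = Recording(x, self.fs, ["a", "b"])
            out = remove_line_noise(rec, LineNoiseConfig(target_freq=60))
            f, p0 = self._psd(rec.data)
            _, p1 = self._psd(out.data)
            band = (f >= 1) & (f <= 45)
            assert p1[:, band].sum() <= 1.01 * p0[:, band].sum()

    def test_deterministic(self):
        rng = np.random.default_rng(15)
        t = np.arange(self.n) / self.fs
        x = 10 * pink_noise(rng, 2, self.n, self.fs) \
            + 10 * np.sin(2 * np.pi * 60 * t)
        rec = Recording(x, self.fs, ["a", "b"])
        cfg = LineNoiseConfig(target_freq=60)
        a = remove_line_noise(rec, cfg)
        b = remove_line_noise(rec, cfg)
        assert np.array_equal(a.data, b.data)

    def test_window_longer_than_recording(self):
        rec = Recording(np.zeros((1, 500)), self.fs, ["a"])
        with pytest.raises(ValueError, match="window"):
            remove_line_noise(rec, LineNoiseConfig(target_freq=60))

    def test_target_above_nyquist(self, pink_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            remove_line_noise(pink_recording,
                              LineNoiseConfig(target_freq=124.5))

    def test_harmonics_processed(self):
        rng = np.random.default_rng(16)
        t = np.arange(self.n) / self.fs
        x = 10 * pink_noise(rng, 1, self.n, self.fs) \
            + 15 * np.sin(2 * np.pi * 50 * t) \
            + 10 * np.sin(2 * np.pi * 100 * t)
        rec = Recording(x, self.fs, ["a"])
        out = remove_line_noise(rec, LineNoiseConfig(
            target_freq=50, harmonics=[100.0]))
        f, p0 = self._psd(rec.data)
        _, p1 = self._psd(out.data)
        for f0 in (50.0, 100.0):
            i = np.argmin(np.abs(f - f0))
            assert p1[:, i].mean() < 0.05 * p0[:, i].mean()
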