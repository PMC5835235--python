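"""Six component features, head model, classifier, variance accounting."""
import numpy as np
import pytest

from happe.components import (ClassifierWeights, HeadModel,
                              current_density_norm, extract_features,
                              fit_one_over_f, load_default_weights,
                              log_alpha_power, mean_local_skewness,
                              percent_variance_kept, range_within_pattern)
from happe.core import Recording

from conftest import pink_noise

FS = 250.0
N = 15000


@pytest.fixture(scope="module")
def head(montage19):
    return HeadModel.build(montage19)


class TestMeanLocalSkewness:
    def test_gaussian_near_zero(self):
        rng = np.random.default_rng(0)
        assert mean_local_skewness(rng.normal(0, 1, N), FS) < 0.1

    def test_spikes_raise_skewness(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, N)
        for s0 in range(1000, N, 3750):     # one spike per 15-s window
            x[s0:s0 + 5] += 200.0
        assert mean_local_skewness(x, FS) > 1.0

    def test_constant_series_zero(self):
        assert mean_local_skewness(np.ones(N), FS) == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, N)
        assert mean_local_skewness(x, FS) == pytest.approx(
            mean_local_skewness(-x, FS))


class TestLogAlphaPower:
    def test_alpha_tone_beats_beta_tone(self):
        t = np.arange(N) / FS
        a = log_alpha_power(np.sin(2 * np.pi * 10 * t), FS)
        b = log_alpha_power(np.sin(2 * np.pi * 30 * t), FS)
        assert a > b

    def test_tenfold_amplitude_adds_two(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, N)
        assert log_alpha_power(10 * x, FS) - log_alpha_power(x, FS) == \
            pytest.approx(2.0, abs=1e-9)

    def test_alpha_peak_dominates_beta_band(self):
        from scipy import signal as sps
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10 * t)
        freqs, psd = sps.welch(x, FS, nperseg=500)
        beta = np.log10(np.maximum(
            psd[(freqs >= 20) & (freqs <= 40)], 1e-300)).mean()
        assert log_alpha_power(x, FS) - beta > 2.0


class TestOneOverF:
    def test_exact_inverse_f_spectrum(self):
        rng = np.random.default_rng(4)
        f = np.fft.rfftfreq(N, 1 / FS)
        f[0] = f[1]
        spec = (f ** -0.5) * np.exp(1j * rng.uniform(0, 2 * np.pi, len(f)))
        x = np.fft.irfft(spec, N)
        lam, err = fit_one_over_f(x, FS)
        assert lam == pytest.approx(1.0, abs=0.05)
        assert err < 0.01

    def test_emg_like_spectrum_flat_or_rising(self):
        from scipy import signal as sps
        rng = np.random.default_rng(5)
        hp = sps.firwin(301, 25, fs=FS, pass_zero=False)
        emg = sps.filtfilt(hp, [1.0], rng.normal(0, 1, N))
        lam, _ = fit_one_over_f(emg, FS)
        assert lam < 0.3

    def test_white_noise_lambda_zero(self):
        rng = np.random.default_rng(6)
        lam, _ = fit_one_over_f(rng.normal(0, 1, N), FS)
        assert abs(lam) < 0.15


class TestScalpMapFeatures:
    def test_focal_map_larger_range_than_uniform(self):
        focal = np.zeros(19)
        focal[0] = 1.0
        uniform = np.ones(19)
        assert range_within_pattern(focal) > range_within_pattern(uniform)

    def test_uniform_map_hits_floor(self):
        assert range_within_pattern(np.ones(19)) == pytest.approx(
            np.log(1e-12))

    def test_spike_map_beats_deep_dipolar_map(self, head):
        d = np.array([0.0, 0.3, 0.8])
        v = head.forward(d / np.linalg.norm(d) * 0.5,
                         np.array([0.0, 0.0, 1.0]))
        spike = np.zeros(19)
        spike[4] = 1.0
        assert range_within_pattern(spike) > range_within_pattern(v)

    def test_cdn_dipolar_below_permuted(self, head):
        rng = np.random.default_rng(7)
        d = np.array([0.0, 0.5, 0.6])
        v = head.forward(d / np.linalg.norm(d) * 0.5,
                         np.array([0.0, 0.3, 1.0]))
        scrambled = v[rng.permutation(19)]
        assert current_density_norm(v, head) < \
            current_density_norm(scrambled, head)

    def test_cdn_scale_invariant(self, head):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 19)
        assert current_density_norm(10 * v, head) == pytest.approx(
            current_density_norm(v, head), abs=1e-9)

    def test_cdn_zero_map_rejected(self, head):
        with pytest.raises(ValueError):
            current_density_norm(np.zeros(19), head)


class TestClassifier:
    def test_zero_weights_probability_half_none_rejected(self):
        w = ClassifierWeights(np.zeros(6), 0.0, np.zeros(6), np.ones(6))
        p = w.probability(np.array([1.0, -2.0, 0.5, 3.0, 0.0, 1.0]))
        assert p == pytest.approx(0.5)
        assert not (p > 0.5)            # strict inequality: kept

    def test_blink_component_rejected(self, head):
        from happe.synth import SynthSpec, generate_labeled_components
        cw = load_default_weights()
        spec = SynthSpec(duration_s=60.0, seed=9100)
        comps = generate_labeled_components(spec, 3, classes=("blink",))
        for comp in comps:
            f = extract_features(comp.source, comp.scalp_map, FS, head)
            assert cw.probability(f) > 0.5

    def test_alpha_component_kept(self, head):
        from happe.synth import SynthSpec, generate_labeled_components
        cw = load_default_weights()
        spec = SynthSpec(duration_s=60.0, seed=9200)
        comps = generate_labeled_components(spec, 3,
                                            classes=("neural-alpha",))
        for comp in comps:
            f = extract_features(comp.source, comp.scalp_map, FS, head)
            assert cw.probability(f) < 0.5

    def test_classify_requires_ten_twenty_coverage(self, montage19):
        from happe.components import classify_components
        from happe.ica import run_extended_infomax
        rng = np.random.default_rng(10)
        labels = list(montage19.positions)[:10]   # 9 of 19 missing
        x = rng.normal(0, 1, (10, 4000))
        dec = run_extended_infomax(x, seed=0, channel_ids=labels, max_iter=3)
        with pytest.raises(ValueError, match="10-20"):
            classify_components(dec, montage19, FS)


class TestPercentVarianceKept:
    def test_identity_is_100(self, pink_recording):
        assert percent_variance_kept(pink_recording, pink_recording) == 100.0

    def test_zeros_is_about_zero(self, pink_recording):
        zeros = Recording(np.zeros_like(pink_recording.data),
                          pink_recording.sample_rate,
                          list(pink_recording.channel_ids))
        assert percent_variance_kept(pink_recording, zeros) == \
            pytest.approx(0.0, abs=1e-9)

    def test_constructed_thirty_percent_drop(self):
        # orthogonal mixing, unit-variance sources scaled so the dropped
        # component carries exactly 30% of the total variance
        rng = np.random.default_rng(11)
        n = 20000
        s = rng.standard_normal((4, n))
        s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        scales = np.array([np.sqrt(0.3), np.sqrt(0.25), np.sqrt(0.25),
                           np.sqrt(0.2)]) * 2
        a = q * scales
        pre = a @ s
        post = a[:, 1:] @ s[1:]
        assert percent_variance_kept(pre, post) == pytest.approx(70.0,
                                                                 abs=2.0)

    def test_monotone_in_dropped_set(self):
        rng = np.random.default_rng(12)
        s = rng.standard_normal((3, 10000))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        pre = q @ s
        kept2 = percent_variance_kept(pre, q[:, :2] @ s[:2])
        kept1 = percent_variance_kept(pre, q[:, :1] @ s[:1])
        assert kept1 <= kept2

    def test_shape_mismatch(self, pink_recording):
        with pytest.raises(ValueError):
            percent_variance_kept(pink_recording.data,
                                  pink_recording.data[:, :10])
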