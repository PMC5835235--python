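"""Bad-channel detection, spherical-spline interpolation, re-referencing."""
import numpy as np
import pytest
from scipy.special import sph_harm_y

from happe.channels import (avg_log_power, detect_bad_channels,
                            interpolate_bad_channels,
                            joint_probability_outliers, rereference,
                            spherical_spline_matrix)
from happe.core import Recording

from conftest import pink_noise


class TestAvgLogPower:
    fs = 250.0
    n = 15000

    def test_identical_channels_identical_values(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, self.n)
        rec = Recording(np.vstack([x, x]), self.fs, ["a", "b"])
        v = avg_log_power(rec)
        assert v[0] == pytest.approx(v[1], abs=1e-12)

    def test_tenfold_amplitude_adds_two_decades(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, self.n)
        rec = Recording(np.vstack([x, 10 * x]), self.fs, ["a", "b"])
        v = avg_log_power(rec)
        assert v[1] - v[0] == pytest.approx(2.0, abs=1e-9)

    def test_flat_channel_floored(self):
        rec = Recording(np.zeros((1, self.n)), self.fs, ["a"])
        assert np.isfinite(avg_log_power(rec)).all()

    def test_band_clipped_with_warning(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.normal(0, 5, (2, 2000)), 100.0, ["a", "b"])
        with pytest.warns(RuntimeWarning, match="clipped"):
            avg_log_power(rec)

    def test_too_short(self):
        rec = Recording(np.zeros((1, 100)), self.fs, ["a"])
        with pytest.raises(ValueError):
            avg_log_power(rec)


class TestJointProbabilityOutliers:
    def test_single_extreme_flagged_exactly(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = rng.normal(0, 1, 31)
            v[30] = 8.0
            flagged, _, _ = joint_probability_outliers(v)
            if flagged == [30]:
                hits += 1
        assert hits >= 99

    def test_symmetric_extremes_both_flagged(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            v = rng.normal(0, 1, 32)
            v[30], v[31] = 8.0, -8.0
            flagged, _, _ = joint_probability_outliers(v)
            if 30 in flagged and 31 in flagged:
                hits += 1
        assert hits >= 95

    def test_all_equal_no_flags(self):
        flagged, _, _ = joint_probability_outliers(np.ones(20))
        assert flagged == []

    def test_few_channels_falls_back(self):
        with pytest.warns(RuntimeWarning, match="fewer than 8"):
            flagged, _, _ = joint_probability_outliers(
                np.array([0.0, 0.1, -0.1, 0.05, 50.0]))
        assert 4 in flagged


class TestDetectBadChannels:
    @staticmethod
    def _clean_recording(seed):
        from happe.synth import SynthSpec, generate_recording
        rec, _ = generate_recording(
            SynthSpec(n_channels=39, duration_s=60.0, artifacts=[],
                      seed=seed))
        return rec

    @staticmethod
    def _planted_recording(seed):
        from happe.synth import ArtifactSpec, SynthSpec, generate_recording
        arts = [ArtifactSpec("flat_channel", channel="C3"),
                ArtifactSpec("noisy_channel", channel="T6")]
        rec, _ = generate_recording(
            SynthSpec(n_channels=39, duration_s=60.0, artifacts=arts,
                      seed=seed))
        return rec

    def test_flat_and_noisy_both_caught(self):
        for seed in range(5):
            res = detect_bad_channels(self._planted_recording(500 + seed))
            assert "C3" in res.bad_ids and "T6" in res.bad_ids

    def test_second_pass_catches_masked_outlier(self):
        # a gross outlier (flat) masks a milder one in pass 1
        rec = self._clean_recording(42)
        n = rec.n_samples
        rec.data[0] = 0.01 * np.random.default_rng(7).normal(0, 1, n)
        rec.data[1] *= 8.0                        # milder power outlier
        res = detect_bad_channels(rec)
        first, second = rec.channel_ids[0], rec.channel_ids[1]
        assert first in res.pass1_ids
        assert second in res.bad_ids
        assert set(res.bad_ids) == set(res.pass1_ids) | set(res.pass2_ids)

    def test_clean_false_positive_rate(self):
        fps = 0
        for seed in range(20):
            res = detect_bad_channels(self._clean_recording(300 + seed))
            fps += len(res.bad_ids)
        assert fps <= 1

    def test_deterministic(self):
        rec = self._planted_recording(3)
        a = detect_bad_channels(rec)
        b = detect_bad_channels(rec)
        assert a.bad_ids == b.bad_ids

    def test_majority_bad_reported(self):
        from happe.channels import BadChannelResult
        res = BadChannelResult(
            bad_ids=["a", "b", "c"], pass1_ids=["a", "b"], pass2_ids=["c"],
            stats={l: (0.0, 0.0, 0.0) for l in "abcde"})
        assert res.warn_majority


class TestSphericalSpline:
    def _harmonic_field(self, pos, rng, lmax=7):
        theta = np.arccos(np.clip(pos[:, 2], -1, 1))
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        f = np.zeros(len(pos))
        for l in range(1, lmax + 1):
            for m in range(0, l + 1):
                y = sph_harm_y(l, m, theta, phi)
                f += rng.normal() * y.real
                if m > 0:
                    f += rng.normal() * y.imag
        return f

    def test_reproduces_low_order_harmonics_exactly(self, montage128):
        pos = montage128.position_array(list(montage128.positions))
        rng = np.random.default_rng(0)
        f = self._harmonic_field(pos, rng)
        good, bad = np.arange(100), np.arange(100, 128)
        M = spherical_spline_matrix(pos[good], pos[bad], lam=0.0)
        err = np.abs(M @ f[good] - f[bad]).max() / np.abs(f[bad]).max()
        assert err < 1e-6

    def test_leave_one_out_dipolar_field(self, montage128):
        pos = montage128.position_array(list(montage128.positions))[:39]
        d = np.array([0.3, 0.2, 0.5])
        q = np.array([1.0, 0.5, 0.2])
        v = ((pos - d) @ q) / np.linalg.norm(pos - d, axis=1) ** 3
        errs = []
        for i in range(39):
            keep = [j for j in range(39) if j != i]
            M = spherical_spline_matrix(pos[keep], pos[[i]])
            errs.append(((M @ v[keep]).item() - v[i]) ** 2)
        rel_rmse = np.sqrt(np.mean(errs)) / (v.max() - v.min())
        assert rel_rmse < 0.10

    def test_constant_field_reproduced(self, montage128):
        pos = montage128.position_array(list(montage128.positions))
        M = spherical_spline_matrix(pos[:100], pos[100:])
        assert np.abs(M @ np.ones(100) - 1.0).max() < 1e-6

    def test_empty_bad_list_is_identity(self, pink_recording, montage19):
        out = interpolate_bad_channels(pink_recording, [], montage19)
        assert np.array_equal(out.data, pink_recording.data)

    def test_interpolation_restores_channel_order(self, montage19):
        rng = np.random.default_rng(1)
        labels = list(montage19.positions)
        rec = Recording(rng.normal(0, 10, (19, 1000)), 250.0, labels,
                        montage=montage19)
        out = interpolate_bad_channels(rec, ["Cz" if "Cz" in labels
                                             else labels[3]])
        assert out.channel_ids == labels

    def test_all_bad_errors(self, montage19):
        labels = list(montage19.positions)
        rec = Recording(np.zeros((19, 100)), 250.0, labels,
                        montage=montage19)
        with pytest.raises(ValueError):
            interpolate_bad_channels(rec, labels[:17])


class TestRereference:
    def test_average_zero_sum(self, pink_recording):
        out = rereference(pink_recording, "average")
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9

    def test_single_channel_reference_zeroes_it(self, pink_recording):
        out = rereference(pink_recording, "channels", ["c2"])
        assert np.abs(out.data[2]).max() < 1e-12

    def test_average_idempotent(self, pink_recording):
        once = rereference(pink_recording, "average")
        twice = rereference(once, "average")
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_common_offset_invariance(self, pink_recording):
        shifted = Recording(pink_recording.data + 42.0,
                            pink_recording.sample_rate,
                            list(pink_recording.channel_ids))
        a = rereference(pink_recording, "average")
        b = rereference(shifted, "average")
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_empty_reference_list(self, pink_recording):
        with pytest.raises(ValueError):
            rereference(pink_recording, "channels", [])

    def test_unknown_reference_channel(self, pink_recording):
        with pytest.raises(ValueError, match="zz"):
            rereference(pink_recording, "channels", ["zz"])
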