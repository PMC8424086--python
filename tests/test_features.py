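"""Feature extraction: PC1, kurtosis, jerk, and jerk cross-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from kcindex.errors import DegenerateSignalError
from kcindex.features import (
    extract_features,
    first_principal_component,
    jerk,
    kurtosis,
    pair_xcorr,
)
from kcindex.recording import LimbRecording, synchronize
from conftest import make_subject


def limb_from(accel, rate=150.0, limb_id="LW"):
    t = np.arange(len(accel)) / rate
    return LimbRecording(limb_id, t, np.asarray(accel, float), nominal_rate=rate)


class TestFirstPrincipalComponent:
    def test_axis_aligned_signal_recovered(self):
        x = np.sin(np.linspace(0, 20, 500))
        accel = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        scores = first_principal_component(limb_from(accel))
        np.testing.assert_allclose(scores, x - x.mean(), atol=1e-12)

    def test_rotation_leaves_score_variance_unchanged(self):
        rng = np.random.default_rng(3)
        accel = rng.normal(size=(800, 3)) @ np.diag([2.0, 1.0, 0.5])
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        var_a = first_principal_component(limb_from(accel)).var()
        var_b = first_principal_component(limb_from(accel @ rot.T)).var()
        assert var_b == pytest.approx(var_a, rel=1e-9)

    def test_variance_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        cov = np.diag([4.0, 1.0, 0.25])
        accel = rng.multivariate_normal(np.zeros(3), cov, size=1000)
        scores = first_principal_component(limb_from(accel))
        centered = accel - accel.mean(axis=0)
        top_eig = np.linalg.eigvalsh(centered.T @ centered / len(centered))[-1]
        assert scores.var() == pytest.approx(top_eig, rel=1e-12)
        assert scores.var() == pytest.approx(4.0, rel=0.25)  # sampling error

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            first_principal_component(limb_from(np.zeros((100, 3))))


class TestKurtosis:
    def test_gaussian_near_three(self):
        x = np.random.default_rng(7).normal(size=100_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_two_point_alternating_attains_lower_bound(self):
        assert kurtosis(np.array([-1.0, 1.0] * 4)) == 1.0

    def test_spike_series_matches_moment_oracle(self):
        x = np.array([0.0] * 7 + [10.0])
        centered = x - x.mean()
        oracle = np.mean(centered**4) / np.mean(centered**2) ** 2
        assert kurtosis(x) == pytest.approx(oracle, rel=1e-12)
        # brute-force value: mean 1.25, m2 = 7*1.25^2/8 + 8.75^2/8
        m2 = (7 * 1.25**2 + 8.75**2) / 8
        m4 = (7 * 1.25**4 + 8.75**4) / 8
        assert oracle == pytest.approx(m4 / m2**2)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_pearson_lower_bound(self, values):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            with pytest.raises(DegenerateSignalError):
                kurtosis(x)
        else:
            assert kurtosis(x) >= 1.0 - 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            kurtosis(np.ones(10))


class TestJerk:
    def test_constant_acceleration_zero_jerk(self):
        accel = np.tile([1.0, -2.0, 0.5], (100, 1))
        np.testing.assert_allclose(jerk(limb_from(accel)), 0.0, atol=1e-12)

    def test_linear_ramp_constant_jerk(self):
        rate, c = 150.0, 3.0
        t = np.arange(300) / rate
        accel = np.column_stack([c * t, np.zeros_like(t), np.zeros_like(t)])
        np.testing.assert_allclose(jerk(limb_from(accel)), c, rtol=1e-9)

    def test_sinusoid_matches_analytic_derivative(self):
        rate, f = 150.0, 2.0
        t = np.arange(1500) / rate
        accel = np.column_stack([np.sin(2 * np.pi * f * t), 0 * t, 0 * t])
        j = jerk(limb_from(accel, rate=rate))
        midpoints = (t[:-1] + t[1:]) / 2
        expected = np.abs(2 * np.pi * f * np.cos(2 * np.pi * f * midpoints))
        np.testing.assert_allclose(j, expected, atol=0.01 * 2 * np.pi * f)


class TestPairXcorr:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert pair_xcorr(x, x, fs=150.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("shift", [1, 8, 25])
    def test_shift_recovered_within_window(self, shift):
        # peak value loses ~shift/n to edge truncation, so keep shift << n
        rng = np.random.default_rng(1)
        x = rng.normal(size=40_000)
        y = np.roll(x, shift)
        assert pair_xcorr(x, y, fs=150.0, max_lag_s=2.0) == pytest.approx(1.0, abs=1e-3)

    def test_matches_bruteforce_lag_scan(self):
        rng = np.random.default_rng(5)
        fs, max_lag_s, n = 50.0, 2.0, 10_000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ac = a - a.mean()
        bc = b - b.mean()
        norm = np.linalg.norm(ac) * np.linalg.norm(bc)
        max_lag = int(round(max_lag_s * fs))
        best = -np.inf
        for lag in range(-max_lag, max_lag + 1):
            if lag >= 0:
                v = np.dot(ac[lag:], bc[: n - lag]) / norm
            else:
                v = np.dot(ac[: n + lag], bc[-lag:]) / norm
            best = max(best, v)
        result = pair_xcorr(a, b, fs=fs, max_lag_s=max_lag_s)
        assert result == pytest.approx(best, abs=1e-9)
        assert abs(result) < 0.1  # independent noise: small correlation

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert pair_xcorr(a, b, fs=150.0) == pytest.approx(
            pair_xcorr(b, a, fs=150.0), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pair_xcorr(np.ones(100), np.random.default_rng(0).normal(size=100), fs=150.0)


class TestExtractFeatures:
    def test_identical_limbs_fully_correlated_equal_kurtosis(self):
        rng = np.random.default_rng(2)
        burst = np.zeros(3001)
        for start in (300, 1200, 2200):
            burst[start : start + 150] += np.hanning(150) * np.sin(
                np.linspace(0, 12, 150)
            )
        base = np.column_stack([burst, 0.5 * burst, 0.1 * burst])
        base += 1e-6 * rng.normal(size=base.shape)  # break exact degeneracy

        rec = make_subject(duration=20.0, signal_fn=lambda lid, t: base)
        rec = synchronize(rec, min_duration_s=19.0)
        fv = extract_features(rec)
        assert fv.xcorr["upper"] == pytest.approx(1.0, abs=1e-6)
        assert fv.xcorr["lower"] == pytest.approx(1.0, abs=1e-6)
        kurs = list(fv.kur.values())
        assert max(kurs) - min(kurs) < 1e-6 * max(kurs)

    def test_independent_noise_limbs_near_gaussian_uncorrelated(self):
        rng = np.random.default_rng(12)

        def signal_fn(limb_id, t):
            return rng.normal(size=(len(t), 3))

        rec = synchronize(
            make_subject(duration=80.0, signal_fn=signal_fn), min_duration_s=75.0
        )
        fv = extract_features(rec)
        for value in fv.kur.values():
            assert value == pytest.approx(3.0, abs=0.3)
        for value in fv.xcorr.values():
            assert abs(value) < 0.1

    def test_dead_limb_named(self):
        def signal_fn(limb_id, t):
            if limb_id == "LA":
                return np.zeros((len(t), 3))
            return np.random.default_rng(4).normal(size=(len(t), 3))

        rec = synchronize(
            make_subject(duration=10.0, signal_fn=signal_fn), min_duration_s=9.0
        )
        with pytest.raises(DegenerateSignalError, match="LA"):
            extract_features(rec)


class TestInvariances:
    def test_scale_invariance_of_all_features(self, uniform_subject):
        rec = synchronize(uniform_subject, min_duration_s=19.0)
        base = extract_features(rec).as_dict()
        scaled = extract_features(synchronize(uniform_subject.scaled(137.0),
                                              min_duration_s=19.0)).as_dict()
        for name, value in base.items():
            assert scaled[name] == pytest.approx(value, rel=1e-9)

    def test_rotation_invariance_of_kurtosis(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=(3001, 3)) @ np.diag([2.0, 1.0, 0.4])
        rot = Rotation.from_rotvec([0.5, 0.2, -0.9]).as_matrix()
        k_base = kurtosis(first_principal_component(limb_from(base)))
        k_rot = kurtosis(first_principal_component(limb_from(base @ rot.T)))
        assert k_rot == pytest.approx(k_base, rel=1e-9)
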