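"""Windowing, time/frequency features and the chronological split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgdecode.features import (
    WindowConfig,
    extra_features,
    make_windows,
    mav,
    rms,
    split_half,
)
from emgdecode.io import SignalRecord


def brute_force_starts(t, w, stride):
    """Independent enumeration of every valid window start."""
    return [s for s in range(0, t, stride) if s + w <= t - 1]


def _record(t, c=3, fs=100.0, seed=0):
    rng = np.random.default_rng(seed)
    return SignalRecord(
        emg=rng.random((t, c)), angle=rng.random(t), fs=fs
    )


class TestMakeWindows:
    @pytest.mark.parametrize(
        "t,window_ms,overlap_ms",
        [(1000, 100, 10), (1000, 100, 0), (137, 50, 10), (212, 200, 50), (11, 100, 10)],
    )
    def test_window_count_matches_enumeration(self, t, window_ms, overlap_ms):
        rec = _record(t)
        cfg = WindowConfig(window_ms=window_ms, overlap_ms=overlap_ms)
        w, o = cfg.samples(rec.fs)
        expected = brute_force_starts(t, w, w - o)
        seq = make_windows(rec, cfg)
        np.testing.assert_array_equal(seq.window_starts, expected)
        assert len(seq) == (t - w - 1) // (w - o) + 1

    def test_default_config_on_1000_samples(self):
        seq = make_windows(_record(1000), WindowConfig())
        assert len(seq) == 110
        assert seq.window_starts[-1] == 981

    def test_minimal_record(self):
        rec = _record(11)
        seq = make_windows(rec, WindowConfig())
        assert len(seq) == 1
        assert seq.targets[0] == rec.angle[10]

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            make_windows(_record(10), WindowConfig())

    def test_fractional_window_raises(self):
        rec = _record(100, fs=128.0)
        with pytest.raises(ValueError, match="whole samples"):
            make_windows(rec, WindowConfig(window_ms=100, overlap_ms=10))

    def test_targets_are_next_samples(self):
        rec = _record(200)
        seq = make_windows(rec, WindowConfig())
        w, _ = seq.config.samples(rec.fs)
        np.testing.assert_array_equal(seq.targets, rec.angle[seq.window_starts + w])
        assert seq.window_starts[-1] + w <= rec.n_samples - 1  # no future leakage

    def test_channel_major_feature_order(self):
        rec = _record(50, c=2)
        seq = make_windows(rec, WindowConfig(feature_set=("MAV", "RMS")))
        s = seq.window_starts[0]
        w, _ = seq.config.samples(rec.fs)
        win = rec.emg[s : s + w]
        expected = [mav(win[:, 0]), rms(win[:, 0]), mav(win[:, 1]), rms(win[:, 1])]
        np.testing.assert_allclose(seq.features[0], expected)

    def test_features_finite(self, small_record):
        seq = make_windows(
            small_record,
            WindowConfig(feature_set=("MAV", "RMS", "VAR", "MNP", "MNF", "MDF")),
        )
        assert np.all(np.isfinite(seq.features))


class TestTimeDomainFeatures:
    def test_mav_closed_forms(self):
        assert mav([1, -1, 1, -1]) == 1.0
        assert mav([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_rms_closed_forms(self):
        assert rms([3, 4]) == pytest.approx(np.sqrt(12.5))
        assert rms([0, 0, 0]) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            rms([])

    def test_against_loop_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(1, 40))
            mav_ref = sum(abs(v) for v in x) / len(x)
            rms_ref = (sum(v * v for v in x) / len(x)) ** 0.5
            assert mav(x) == pytest.approx(mav_ref, abs=1e-12)
            assert rms(x) == pytest.approx(rms_ref, abs=1e-12)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(0, 10),
    )
    @settings(deadline=None, derandomize=True)
    def test_scale_equivariance_and_power_mean(self, values, a):
        x = np.array(values)
        assert rms(x) >= mav(x) - 1e-9  # power-mean inequality
        assert mav(a * x) == pytest.approx(a * mav(x), rel=1e-9, abs=1e-9)
        assert rms(a * x) == pytest.approx(a * rms(x), rel=1e-9, abs=1e-9)


class TestSpectralFeatures:
    def test_constant_window(self):
        var, mnp, mnf, mdf = extra_features(np.full(16, 2.0), fs=100.0)
        assert var == 0.0
        assert mnf == 0.0 and mdf == 0.0  # all power at DC

    def test_hand_computed_variance(self):
        var, *_ = extra_features(np.array([1.0, 2.0, 3.0, 4.0]), fs=100.0)
        assert var == pytest.approx(5.0 / 3.0)

    def test_sinusoid_frequency_recovery(self):
        fs, f0, w = 100.0, 20.0, 50  # whole number of periods in the window
        t = np.arange(w) / fs
        x = np.sin(2 * np.pi * f0 * t)
        _, _, mnf, mdf = extra_features(x, fs=fs)
        bin_width = fs / w
        assert abs(mnf - f0) <= bin_width
        assert abs(mdf - f0) <= bin_width

    def test_too_short_window(self):
        with pytest.raises(ValueError):
            extra_features(np.array([1.0]), fs=100.0)


class TestSplitHalf:
    @pytest.mark.parametrize("n,train_n,test_n", [(110, 55, 55), (11, 6, 5), (2, 1, 1)])
    def test_split_sizes(self, n, train_n, test_n):
        rec = _record(9 * (n - 1) + 11)
        seq = make_windows(rec, WindowConfig())
        assert len(seq) == n
        train, test = split_half(seq)
        assert (len(train), len(test)) == (train_n, test_n)

    def test_concatenation_recovers_sequence(self, small_sequence):
        train, test = split_half(small_sequence)
        np.testing.assert_array_equal(
            np.vstack([train.features, test.features]), small_sequence.features
        )
        np.testing.assert_array_equal(
            np.concatenate([train.targets, test.targets]), small_sequence.targets
        )

    def test_chronological_order(self, small_sequence):
        train, test = split_half(small_sequence)
        assert train.window_starts[-1] < test.window_starts[0]

    def test_too_small(self, small_sequence):
        from dataclasses import replace

        one = replace(
            small_sequence,
            features=small_sequence.features[:1],
            targets=small_sequence.targets[:1],
            window_starts=small_sequence.window_starts[:1],
        )
        with pytest.raises(ValueError):
            split_half(one)


class TestWindowConfigValidation:
    def test_rejects_overlap_not_less_than_window(self):
        with pytest.raises(ValueError):
            WindowConfig(window_ms=10, overlap_ms=10)

    def test_rejects_unknown_feature(self):
        with pytest.raises(ValueError, match="unknown"):
            WindowConfig(feature_set=("MAV", "ZCR"))
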