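"""Filter contracts, segment extraction, and sliding-window arithmetic."""

import numpy as np
import pytest

from hcsnet.preprocess import (
    ConfigError,
    PreprocessConfig,
    bandpass_filter,
    extract_movement_segment,
    notch_filter,
    select_channels,
    sliding_windows,
)
from hcsnet.signal_io import RawRecording


FS = 1500


def _rec(signal, **kw):
    defaults = dict(fs_hz=FS, subject_id="S1", label="standing", trial_index=0)
    defaults.update(kw)
    return RawRecording(signal=np.atleast_2d(signal), **defaults)


def _sine(freq, dur=2.0):
    t = np.arange(int(dur * FS)) / FS
    return np.sin(2 * np.pi * freq * t)


def _interior(x, margin_s=0.1):
    m = int(margin_s * FS)
    return x[m:-m]


def rms(x):
    return np.sqrt(np.mean(x**2))


class TestNotch:
    def test_50hz_attenuated_20db(self):
        x = _sine(50.0)
        y = notch_filter(_rec(x)).signal[0]
        assert rms(_interior(y)) <= 0.1 * rms(_interior(x))

    def test_100hz_passband_within_1db(self):
        x = _sine(100.0)
        y = notch_filter(_rec(x)).signal[0]
        assert rms(_interior(y)) >= 0.89 * rms(_interior(x))

    def test_zero_in_zero_out(self):
        y = notch_filter(_rec(np.zeros((5, 3000)))).signal
        assert np.allclose(y, 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ConfigError):
            notch_filter(_rec(np.zeros((1, 100)), fs_hz=80))


class TestBandpass:
    def test_dc_removed(self):
        y = bandpass_filter(_rec(np.full(2 * FS, 5.0))).signal[0]
        assert np.max(np.abs(_interior(y))) <= 0.05

    def test_2hz_attenuated_20db(self):
        x = _sine(2.0, dur=6.0)
        y = bandpass_filter(_rec(x)).signal[0]
        assert rms(_interior(y, 1.0)) <= 0.1 * rms(_interior(x, 1.0))

    def test_100hz_passed(self):
        x = _sine(100.0)
        y = bandpass_filter(_rec(x)).signal[0]
        assert rms(_interior(y)) >= 0.89 * rms(_interior(x))

    def test_linearity(self, rng):
        a, b = rng.standard_normal((2, 3000))
        fa = bandpass_filter(_rec(a)).signal[0]
        fb = bandpass_filter(_rec(b)).signal[0]
        fab = bandpass_filter(_rec(a + b)).signal[0]
        assert np.allclose(fab, fa + fb, atol=1e-9)


def test_zero_phase_peak_alignment():
    """A symmetric pulse keeps its peak position under both filters."""
    x = np.zeros(3000)
    t = np.arange(3000)
    x += np.exp(-0.5 * ((t - 1500) / 30.0) ** 2)
    for filt in (notch_filter, bandpass_filter):
        y = filt(_rec(x)).signal[0]
        assert abs(int(np.argmax(np.abs(y))) - 1500) <= 1


def test_filters_commute_with_channel_permutation(rng):
    x = rng.standard_normal((5, 3000))
    perm = [4, 2, 0, 3, 1]
    y1 = bandpass_filter(_rec(x)).signal[perm]
    y2 = bandpass_filter(_rec(x[perm])).signal
    assert np.allclose(y1, y2)


class TestSegment:
    def test_default_extraction(self, rng):
        rec = _rec(rng.standard_normal((5, 12 * FS)))
        seg = extract_movement_segment(rec)
        assert seg.signal.shape == (5, FS)
        assert np.array_equal(seg.signal, rec.signal[:, 6000:7500])
        assert seg.label == rec.label

    def test_too_short_trial_errors(self, rng):
        rec = _rec(rng.standard_normal((5, int(4.5 * FS))))
        with pytest.raises(ValueError):
            extract_movement_segment(rec)

    def test_identity_when_full_span(self, rng):
        rec = _rec(rng.standard_normal((5, 3000)))
        cfg = PreprocessConfig(onset_s=0.0, keep_duration_s=2.0)
        seg = extract_movement_segment(rec, cfg)
        assert np.array_equal(seg.signal, rec.signal)


class TestWindows:
    @pytest.mark.parametrize(
        "t,length,step,expected_n",
        [(1500, 300, 150, 9), (300, 300, 150, 1), (1500, 300, 75, 17)],
    )
    def test_window_counts(self, rng, t, length, step, expected_n):
        seg = _rec(rng.standard_normal((5, t)))
        cfg = PreprocessConfig(window_len=length, window_step=step)
        wins = sliding_windows(seg, cfg)
        assert len(wins) == expected_n
        assert [w.start_sample for w in wins] == [k * step for k in range(expected_n)]
        assert all(w.window.shape == (5, length) for w in wins)
        assert all(w.label == seg.label for w in wins)

    def test_short_segment_errors(self, rng):
        with pytest.raises(ValueError):
            sliding_windows(_rec(rng.standard_normal((5, 200))))

    def test_tiling_conserves_samples(self, rng):
        seg = _rec(rng.standard_normal((5, 1000)))
        cfg = PreprocessConfig(window_len=300, window_step=300)
        wins = sliding_windows(seg, cfg)
        rebuilt = np.concatenate([w.window for w in wins], axis=1)
        assert np.array_equal(rebuilt, seg.signal[:, :900])


class TestChannelSelect:
    def test_left_leg_five_of_ten(self, rng):
        rec = _rec(rng.standard_normal((10, 100)))
        cfg = PreprocessConfig(channels_used=[0, 1, 2, 3, 4])
        out = select_channels(rec, cfg)
        assert out.n_channels == 5
        assert np.array_equal(out.signal, rec.signal[:5])

    def test_select_all_identity(self, rng):
        rec = _rec(rng.standard_normal((5, 100)))
        out = select_channels(rec, PreprocessConfig(channels_used=list(range(5))))
        assert np.array_equal(out.signal, rec.signal)

    def test_out_of_range_errors(self, rng):
        rec = _rec(rng.standard_normal((10, 100)))
        with pytest.raises(IndexError):
            select_channels(rec, PreprocessConfig(channels_used=[11]))


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        PreprocessConfig(window_len=100, window_step=200)
    with pytest.raises(ConfigError):
        PreprocessConfig(band_hz=(450.0, 10.0))
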