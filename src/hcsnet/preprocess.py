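"""Filtering, movement-segment extraction, and sliding-window segmentation.

The chain applied to each raw trial is: 50 Hz notch (mains removal),
10-450 Hz bandpass, extraction of the first second of movement after the
cue, then overlapping sliding windows (default 300 samples, step 150).

Filters are a 2nd-order IIR notch (Q = 30) and a 4th-order Butterworth
bandpass, both run forward-backward (zero phase) so feature windows see no
group delay. Sample intervals are half-open and 0-based throughout; the
movement onset is the protocol cue time, not a detected EMG onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from hcsnet.signal_io import RawRecording


class ConfigError(ValueError):
    """A preprocessing configuration is inconsistent with the signal."""


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    band_hz: tuple[float, float] = (10.0, 450.0)
    filter_order: int = 4
    onset_s: float = 4.0
    keep_duration_s: float = 1.0
    window_len: int = 300
    window_step: int = 150
    channels_used: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.window_step > self.window_len:
            raise ConfigError("window_step must be <= window_len")
        if self.window_len < 1 or self.window_step < 1:
            raise ConfigError("window_len and window_step must be >= 1")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError("band_hz must satisfy 0 < low < high")

    def with_window(self, window_len: int, window_step: int) -> "PreprocessConfig":
        return replace(self, window_len=window_len, window_step=window_step)


@dataclass
class WindowSample:
    """One fixed-length analysis window, inheriting its trial's label."""

    window: np.ndarray  # C x W
    label: str
    subject_id: str
    source_trial: int
    start_sample: int


def notch_filter(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Zero-phase IIR notch at ``cfg.notch_hz`` applied per channel."""
    cfg = cfg or PreprocessConfig()
    if rec.fs_hz <= 2 * cfg.notch_hz:
        raise ConfigError(f"fs {rec.fs_hz} Hz too low for a {cfg.notch_hz} Hz notch")
    b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs_hz)
    filtered = sps.filtfilt(b, a, rec.signal, axis=1)
    return rec.copy_with(signal=filtered)


def bandpass_filter(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Zero-phase Butterworth bandpass applied per channel."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.band_hz
    if rec.fs_hz <= 2 * hi:
        raise ConfigError(f"fs {rec.fs_hz} Hz too low for a bandpass up to {hi} Hz")
    sos = sps.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=rec.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return rec.copy_with(signal=filtered)


def extract_movement_segment(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Keep samples in ``[round(onset*fs), round((onset+keep)*fs))``."""
    cfg = cfg or PreprocessConfig()
    start = int(round(cfg.onset_s * rec.fs_hz))
    stop = int(round((cfg.onset_s + cfg.keep_duration_s) * rec.fs_hz))
    if stop > rec.n_samples:
        raise ValueError(
            f"trial of {rec.n_samples} samples too short for segment [{start}, {stop}) "
            f"(onset {cfg.onset_s} s + keep {cfg.keep_duration_s} s at {rec.fs_hz} Hz)"
        )
    return rec.copy_with(signal=rec.signal[:, start:stop])


def sliding_windows(segment: RawRecording, cfg: PreprocessConfig | None = None) -> list[WindowSample]:
    """Cut a segment into overlapping windows; window k covers [k*step, k*step + len)."""
    cfg = cfg or PreprocessConfig()
    t = segment.n_samples
    if t < cfg.window_len:
        raise ValueError(f"segment of {t} samples shorter than window_len {cfg.window_len}")
    n_windows = (t - cfg.window_len) // cfg.window_step + 1
    out = []
    for k in range(n_windows):
        start = k * cfg.window_step
        out.append(
            WindowSample(
                window=segment.signal[:, start : start + cfg.window_len].copy(),
                label=segment.label,
                subject_id=segment.subject_id,
                source_trial=segment.trial_index,
                start_sample=start,
            )
        )
    return out


def select_channels(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Keep the configured channel subset, in configured order."""
    cfg = cfg or PreprocessConfig()
    if cfg.channels_used is None:
        return rec
    idx = list(cfg.channels_used)
    for i in idx:
        if not (0 <= i < rec.n_channels):
            raise IndexError(f"channel index {i} out of range for {rec.n_channels} channels")
    return rec.copy_with(
        signal=rec.signal[idx, :],
        channel_names=[rec.channel_names[i] for i in idx],
    )


def preprocess_trial(rec: RawRecording, cfg: PreprocessConfig | None = None) -> list[WindowSample]:
    """Full chain: channel selection, notch, bandpass, segment, windows."""
    cfg = cfg or PreprocessConfig()
    rec = select_channels(rec, cfg)
    rec = notch_filter(rec, cfg)
    rec = bandpass_filter(rec, cfg)
    seg = extract_movement_segment(rec, cfg)
    return sliding_windows(seg, cfg)


def preprocess_dataset(recordings, cfg: PreprocessConfig | None = None) -> list[WindowSample]:
    cfg = cfg or PreprocessConfig()
    windows: list[WindowSample] = []
    for rec in recordings:
        windows.extend(preprocess_trial(rec, cfg))
    return windows
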