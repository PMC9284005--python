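"""Surrogate multi-subject sEMG dataset generator.

Real surface EMG during a movement is well approximated, for the purposes of
amplitude- and spectrum-based decoding, by an interference pattern: a
bandlimited stochastic carrier whose instantaneous amplitude follows the
muscle's activation envelope. The generator builds each channel as

    s_c(t) = gain_c * env_c(t - jitter) * n_c(t) + noise_std * w_c(t)
             + mains_amplitude * sin(2*pi*50*t + phase_c)

where ``n_c`` is unit-RMS Gaussian noise bandpassed to the carrier band
(default 20-450 Hz), ``w_c`` is white baseline noise, and the 50 Hz term
emulates mains pickup so the notch filter downstream has something to remove.

Three movement classes are told apart by class-specific per-channel envelope
patterns (muscle synergies) on the five left-leg muscles:

* ``standing``  — ramp-up then hold, dominated by the knee extensors;
* ``sitting``   — reversed ramp (eccentric decay), dominated by the flexors;
* ``walking``   — ~1 Hz alternating bursts between shank antagonists.

Inter-subject variability is a single dial: channel gains are lognormal with
sigma = ``variability``, envelope onsets jitter by a zero-mean normal with
sd = 0.3 * ``variability`` seconds, and noise/mains levels scale lognormally
around their reference values. ``variability = 0`` yields identical subjects.

The trial paradigm mirrors a cued acquisition session: a rest period, an
auditory cue at 4 s, 3 s of movement, then rest until 12 s, sampled at
1500 Hz. A session holds 3 groups of 10 trials per subject (balanced
10/10/10 over classes); standing and walking are shuffled into the first 20
trials and the 10 sitting trials close the session, matching a protocol in
which subjects must be standing before stand/sit trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from hcsnet.signal_io import (
    CLASSES,
    DatasetManifest,
    RawRecording,
    write_manifest,
    write_recording,
)

#: Left-leg muscles, in channel order.
CHANNEL_NAMES = (
    "rectus_femoris",
    "vastus_lateralis",
    "tibialis_anterior",
    "biceps_femoris",
    "lateral_gastrocnemius",
)

#: Reference noise/mains levels for a variability-0 subject (signal units).
REFERENCE_NOISE_STD = 0.05
REFERENCE_MAINS_AMPLITUDE = 0.05

#: Envelope sampling rate (Hz); envelopes are slow relative to the carrier.
ENVELOPE_RATE_HZ = 50


@dataclass
class SubjectProfile:
    """Per-subject multiplicative gains, timing jitter, and noise levels."""

    subject_id: str
    channel_gains: np.ndarray
    onset_jitter_s: float
    noise_std: float
    mains_amplitude: float
    seed: int

    def __post_init__(self) -> None:
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel_gains must be strictly positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.mains_amplitude < 0:
            raise ValueError("mains_amplitude must be >= 0")


@dataclass
class MovementTemplate:
    """Class-specific activation envelopes (C x K, at ENVELOPE_RATE_HZ) and carrier band."""

    label: str
    envelope_matrix: np.ndarray
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        self.envelope_matrix = np.asarray(self.envelope_matrix, dtype=float)
        if np.any(self.envelope_matrix < 0):
            raise ValueError("envelope_matrix must be nonnegative")
        lo, hi = self.carrier_band_hz
        if not (0 < lo < hi):
            raise ValueError("carrier band must satisfy 0 < low < high")


@dataclass
class ParadigmSpec:
    """Timing of one cued trial and the session layout."""

    n_groups: int = 3
    moves_per_group: int = 10
    cue_onset_s: float = 4.0
    move_duration_s: float = 3.0
    trial_duration_s: float = 12.0
    fs_hz: int = 1500

    def __post_init__(self) -> None:
        if self.cue_onset_s + self.move_duration_s > self.trial_duration_s:
            raise ValueError("cue_onset_s + move_duration_s must fit within trial_duration_s")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.fs_hz))


def _ramp_hold(k: int, rise_frac: float = 0.15) -> np.ndarray:
    """Ramp to 1 over the first rise_frac of the movement, then hold."""
    n_rise = max(1, int(round(rise_frac * k)))
    env = np.ones(k)
    env[:n_rise] = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    return env

def _burst_train(k: int, duration_s: float, rate_hz: float, phase: float) -> np.ndarray:
    """Periodic raised-cosine bursts (half duty cycle) at rate_hz."""
    t = np.linspace(0.0, duration_s, k, endpoint=False)
    cyc = (t * rate_hz + phase) % 1.0
    env = np.where(cyc < 0.5, 0.5 * (1 - np.cos(2 * np.pi * cyc / 0.5)), 0.0)
    return env


def default_templates(paradigm: ParadigmSpec | None = None) -> dict[str, MovementTemplate]:
    """Build the three class templates over the movement period.

    Envelope rows follow :data:`CHANNEL_NAMES`; values are per-channel synergy
    weights times a common time course.
    """
    paradigm = paradigm or ParadigmSpec()
    k = int(round(paradigm.move_duration_s * ENVELOPE_RATE_HZ))
    # channel synergy weights:     RF    VL    TA    BF    GAS
    w_stand = np.array([1.00, 0.90, 0.35, 0.25, 0.30])
    w_sit = np.array([0.35, 0.30, 0.25, 1.00, 0.80])
    w_walk_a = np.array([0.55, 0.45, 1.00, 0.25, 0.10])  # swing-phase group (TA)
    w_walk_b = np.array([0.25, 0.30, 0.10, 0.45, 1.00])  # stance-phase group (GAS)

    stand = np.outer(w_stand, _ramp_hold(k))
    sit = np.outer(w_sit, _ramp_hold(k)[::-1])
    walk = np.outer(w_walk_a, _burst_train(k, paradigm.move_duration_s, 1.0, 0.0)) + np.outer(
        w_walk_b, _burst_train(k, paradigm.move_duration_s, 1.0, 0.5)
    )
    return {
        "standing": MovementTemplate("standing", stand),
        "sitting": MovementTemplate("sitting", sit),
        "walking": MovementTemplate("walking", walk),
    }


def make_subject_profile(subject_id: str, seed: int, variability: float = 0.1) -> SubjectProfile:
    """Draw one subject's gains/jitter/noise levels.

    ``variability`` is the lognormal sigma of channel gains; 0 gives unit
    gains, zero jitter, and the reference noise/mains levels.
    """
    if variability < 0:
        raise ValueError(f"variability must be >= 0, got {variability}")
    rng = np.random.default_rng(seed)
    n_ch = len(CHANNEL_NAMES)
    gains = np.exp(variability * rng.standard_normal(n_ch))
    jitter = float(0.3 * variability * rng.standard_normal())
    noise_std = REFERENCE_NOISE_STD * float(np.exp(variability * rng.standard_normal()))
    mains = REFERENCE_MAINS_AMPLITUDE * float(np.exp(variability * rng.standard_normal()))
    return SubjectProfile(
        subject_id=subject_id,
        channel_gains=gains,
        onset_jitter_s=jitter,
        noise_std=noise_std,
        mains_amplitude=mains,
        seed=seed,
    )


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: int, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise bandpassed to ``band`` (zero-phase)."""
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def simulate_trial(
    profile: SubjectProfile,
    template: MovementTemplate,
    paradigm: ParadigmSpec,
    trial_seed: int,
    trial_index: int = 0,
) -> RawRecording:
    """Simulate one cued trial as amplitude-modulated bandlimited noise."""
    lo, hi = template.carrier_band_hz
    if hi >= paradigm.fs_hz / 2:
        raise ValueError(
            f"carrier band upper edge {hi} Hz must be below Nyquist {paradigm.fs_hz / 2} Hz"
        )
    rng = np.random.default_rng(trial_seed)
    n = paradigm.n_samples
    fs = paradigm.fs_hz
    t = np.arange(n) / fs
    n_ch = template.envelope_matrix.shape[0]

    onset = paradigm.cue_onset_s + profile.onset_jitter_s
    onset = min(max(onset, 0.0), paradigm.trial_duration_s - paradigm.move_duration_s)
    k = template.envelope_matrix.shape[1]
    t_env = onset + np.arange(k) / ENVELOPE_RATE_HZ

    sig = np.empty((n_ch, n))
    for c in range(n_ch):
        env = np.interp(t, t_env, template.envelope_matrix[c], left=0.0, right=0.0)
        carrier = _bandlimited_noise(rng, n, fs, template.carrier_band_hz)
        chan = profile.channel_gains[c] * env * carrier
        if profile.noise_std > 0:
            chan = chan + profile.noise_std * rng.standard_normal(n)
        if profile.mains_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            chan = chan + profile.mains_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)
        sig[c] = chan
    return RawRecording(
        signal=sig,
        fs_hz=fs,
        subject_id=profile.subject_id,
        label=template.label,
        channel_names=list(CHANNEL_NAMES[:n_ch]),
        trial_index=trial_index,
    )


def session_label_order(rng: np.random.Generator, paradigm: ParadigmSpec) -> list[str]:
    """Trial labels for one session: standing/walking shuffled first, sitting last."""
    n_per_class = paradigm.n_groups * paradigm.moves_per_group // len(CLASSES)
    first = ["standing"] * n_per_class + ["walking"] * n_per_class
    perm = rng.permutation(len(first))
    first = [first[i] for i in perm]
    return first + ["sitting"] * n_per_class


def simulate_dataset(
    n_subjects: int,
    paradigm: ParadigmSpec | None = None,
    variability: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[RawRecording]]:
    """Simulate a full multi-subject dataset; optionally write it to disk.

    Each subject contributes ``n_groups * moves_per_group`` trials (default
    30, balanced over the three classes). Returns the manifest and the
    recordings in session order. Fully deterministic for a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    paradigm = paradigm or ParadigmSpec()
    templates = default_templates(paradigm)
    master = np.random.default_rng(seed)
    recordings: list[RawRecording] = []
    entries: list[dict] = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1}"
        subj_seed = int(master.integers(0, 2**31 - 1))
        profile = make_subject_profile(subject_id, seed=subj_seed, variability=variability)
        order_rng = np.random.default_rng(subj_seed + 1)
        labels = session_label_order(order_rng, paradigm)
        for trial_index, label in enumerate(labels):
            trial_seed = int(order_rng.integers(0, 2**31 - 1))
            rec = simulate_trial(profile, templates[label], paradigm, trial_seed, trial_index)
            recordings.append(rec)
            entries.append(
                {
                    "path": f"{subject_id}/trial{trial_index:03d}.csv",
                    "subject_id": subject_id,
                    "label": label,
                    "trial_index": trial_index,
                    "fs_hz": paradigm.fs_hz,
                }
            )
    manifest = DatasetManifest(entries=entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for e, rec in zip(manifest.entries, recordings):
            write_recording(rec, out_dir / e["path"])
        write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest, recordings
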