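"""Synthetic cue-locked motor-imagery EEG.

Generates multi-subject recordings with the statistical structure the decoding
pipeline assumes:

* 1/f^alpha background noise on every electrode;
* an ongoing mu rhythm (8-12 Hz narrowband process) whose power, during a
  trial, is attenuated by ``erd_factor`` on the hemisphere contralateral to
  the imagined hand (event-related desynchronization, ERD);
* occasional high-amplitude blink transients concentrated below 4 Hz;
* per-subject gain / mu-frequency / noise-level variability so that
  leave-one-subject-out generalization is a non-trivial task.

The convention for lateralization: the first half of the channel list plays
the role of the left hemisphere (contralateral to class +1, "right hand"),
the second half the role of the right hemisphere (contralateral to class -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SynthConfig", "RawRecording", "generate_recording", "generate_dataset"]

MU_BAND = (8.0, 12.0)

#: seconds of rest inserted between consecutive trials
REST_LEN = 2.0
#: seconds of signal before the first cue
LEAD_IN = 2.0
#: background 1/f noise standard deviation, microvolt
BG_SD_UV = 5.0
#: mu-rhythm standard deviation at baseline, microvolt
MU_SD_UV = 10.0
#: blink bump duration, seconds
BLINK_LEN = 0.4
#: blink amplitude as a multiple of the background SD
BLINK_GAIN = 10.0


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 8
    n_trials_per_subject: int = 200
    n_channels: int = 22
    fs: float = 250.0
    trial_len: float = 4.0
    erd_factor: float = 0.5
    noise_exponent: float = 1.0
    blink_rate: float = 2.0  # events per minute
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials_per_subject < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if self.fs < 2 * MU_BAND[1]:
            raise ValueError(
                f"fs={self.fs} cannot represent the mu band (need >= {2 * MU_BAND[1]} Hz)")
        if self.trial_len <= 0:
            raise ValueError("trial_len must be positive")
        if not (0.0 < self.erd_factor <= 1.0):
            raise ValueError("erd_factor must lie in (0, 1]")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")


@dataclass
class RawRecording:
    """Continuous multichannel signal (microvolt) with cue events."""

    data: np.ndarray  # (channels, samples)
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]]  # (onset_sample, label in {-1,+1})
    subject_id: int = 0

    def __post_init__(self):
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float,
                shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.normal(size=shape + (n,))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band."""
    white = rng.normal(size=shape + (n,))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(white, axis=-1) * mask
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _balanced_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    labels = np.concatenate([np.ones((n + 1) // 2, dtype=int),
                             -np.ones(n // 2, dtype=int)])
    rng.shuffle(labels)
    return labels


def generate_recording(cfg: SynthConfig, subject_id: int) -> RawRecording:
    """Simulate one subject's continuous recording.

    Deterministic given (cfg.seed, subject_id): the subject index seeds an
    independent random stream, so datasets are reproducible bit-for-bit and
    subjects are mutually independent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF,
                                                        int(subject_id)]))
    fs = cfg.fs
    trial_samples = int(round(cfg.trial_len * fs))
    step = int(round((cfg.trial_len + REST_LEN) * fs))
    lead = int(round(LEAD_IN * fs))
    n = lead + cfg.n_trials_per_subject * step
    C = cfg.n_channels

    # between-subject variability
    gain = float(rng.lognormal(mean=0.0, sigma=0.15))
    mu_center = float(rng.uniform(9.0, 11.0))
    mu_half = 1.5
    mu_band = (max(MU_BAND[0], mu_center - mu_half), min(MU_BAND[1], mu_center + mu_half))
    mu_sd = MU_SD_UV * float(rng.lognormal(0.0, 0.1))
    bg_sd = BG_SD_UV * float(rng.lognormal(0.0, 0.1))
    ch_gain = rng.lognormal(0.0, 0.05, size=(C, 1))

    background = bg_sd * _one_over_f(rng, n, fs, cfg.noise_exponent, (C,))
    mu = mu_sd * _narrowband(rng, n, fs, mu_band, (C,))

    labels = _balanced_labels(rng, cfg.n_trials_per_subject)
    onsets = lead + step * np.arange(cfg.n_trials_per_subject)

    # ERD: attenuate mu amplitude on the contralateral channel group per trial
    envelope = np.ones((C, n))
    half = C // 2
    amp = np.sqrt(cfg.erd_factor)
    for onset, lab in zip(onsets, labels):
        group = slice(0, half) if lab == +1 else slice(half, C)
        envelope[group, onset:onset + trial_samples] = amp
    signal = background + envelope * mu

    # blink transients: Poisson arrivals, raised-cosine bump below 4 Hz
    if cfg.blink_rate > 0:
        n_blinks = rng.poisson(cfg.blink_rate * (n / fs) / 60.0)
        blen = int(round(BLINK_LEN * fs))
        bump = BLINK_GAIN * bg_sd * 0.5 * (1 - np.cos(2 * np.pi * np.arange(blen) / blen))
        starts = rng.integers(0, max(n - blen, 1), size=n_blinks)
        for s in starts:
            signal[:, s:s + blen] += bump[: n - s]

    signal = gain * ch_gain * signal
    names = [f"C{i:02d}" for i in range(C)]
    events = [(int(o), int(l)) for o, l in zip(onsets, labels)]
    return RawRecording(data=signal, fs=fs, channel_names=names,
                        events=events, subject_id=int(subject_id))


def generate_dataset(cfg: SynthConfig) -> list[RawRecording]:
    """One recording per subject, each with its own independent stream."""
    return [generate_recording(cfg, s) for s in range(cfg.n_subjects)]
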