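"""Synthetic multi-channel EEG cohorts with controllable class separation.

Each channel is a sum of band-limited Gaussian noise processes — one per
classical EEG band (delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma
30-45 Hz) — plus a pink (1/f) background. Class structure enters through
the band amplitudes; subjects get multiplicative log-normal random effects
per band and channels a small gain jitter, so recordings within a class
are similar but not identical and subject identity is a real latent
variable (which is what makes image-level vs subject-level splitting
measurably different downstream).

Two presets define the study conditions used throughout the tests:

* ``separable``: the case class has reduced alpha (0.5 vs 1.0) and
  elevated theta (1.2 vs 0.8), all other bands equal — a deliberately
  detectable spectral signature. The direction of the difference is a
  generator convention, not a claim about real autism electrophysiology.
* ``null``: both classes share the control parameters; any downstream
  "signal" is overfitting by construction.

Defaults mirror a 16-channel, 256 Hz, 10-20-montage recording session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .recording import ClassLabel, EEGRecording, default_channel_labels

#: Band edges in Hz.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class BandAmplitudes:
    """RMS amplitude per band, arbitrary units, all >= 0."""

    delta: float = 1.0
    theta: float = 0.8
    alpha: float = 1.0
    beta: float = 0.6
    gamma: float = 0.3

    def __post_init__(self) -> None:
        if any(getattr(self, b) < 0 for b in BAND_EDGES):
            raise ValueError("band amplitudes must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {b: float(getattr(self, b)) for b in BAND_EDGES}


#: Control-like band profile (also the null-preset profile for both classes).
CONTROL_BANDS = BandAmplitudes(delta=1.0, theta=0.8, alpha=1.0, beta=0.6, gamma=0.3)
#: Case-class profile of the separable preset: reduced alpha, elevated theta.
CASE_BANDS = BandAmplitudes(delta=1.0, theta=1.2, alpha=0.5, beta=0.6, gamma=0.3)


@dataclass
class CohortSpec:
    subjects_per_class: int = 10
    channels: int = 16
    sampling_rate: float = 256.0
    duration: float = 60.0
    class_a: BandAmplitudes = field(default_factory=lambda: CASE_BANDS)  # ASD
    class_b: BandAmplitudes = field(default_factory=lambda: CONTROL_BANDS)  # CONTROL
    background: float = 0.5  # pink-noise RMS
    subject_sd: float = 0.1  # log-sd of per-subject band effects
    channel_jitter: float = 0.05  # sd of per-channel gain jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        if self.duration <= 0 or self.sampling_rate <= 0 or self.channels < 1:
            raise ValueError("invalid cohort geometry")
        for lo, hi in BAND_EDGES.values():
            if hi >= self.sampling_rate / 2:
                raise ValueError("band edges must lie below Nyquist")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to [lo, hi] Hz."""
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shape, n=n)
    return x / np.sqrt(np.mean(x**2))


def generate_subject(
    bands: BandAmplitudes,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S00",
    class_label: ClassLabel = ClassLabel.UNKNOWN,
) -> EEGRecording:
    """One subject's recording; bit-identical for a fixed seed."""
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    fs = spec.sampling_rate
    subject_gain = {
        b: amp * np.exp(rng.normal(0.0, spec.subject_sd))
        for b, amp in bands.as_dict().items()
    }
    signal = np.empty((spec.channels, n))
    for ch in range(spec.channels):
        acc = spec.background * _pink_noise(rng, n)
        for b, (lo, hi) in BAND_EDGES.items():
            gain = subject_gain[b] * max(0.0, 1.0 + rng.normal(0.0, spec.channel_jitter))
            if gain > 0:
                acc = acc + gain * _band_noise(rng, n, fs, lo, hi)
        signal[ch] = acc
    return EEGRecording(
        signal=signal,
        sampling_rate=fs,
        channel_labels=default_channel_labels(spec.channels),
        subject_id=subject_id,
        class_label=class_label,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Full labeled cohort: subjects_per_class recordings per class.

    Class A subjects (ids ``A01``..) carry the ASD label, class B
    (``B01``..) the CONTROL label. One master seed fixes everything.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(2 * spec.subjects_per_class)
    cohort: list[EEGRecording] = []
    for i in range(spec.subjects_per_class):
        cohort.append(
            generate_subject(spec.class_a, spec, streams[i], f"A{i + 1:02d}", ClassLabel.ASD)
        )
    for i in range(spec.subjects_per_class):
        cohort.append(
            generate_subject(
                spec.class_b, spec, streams[spec.subjects_per_class + i],
                f"B{i + 1:02d}", ClassLabel.CONTROL,
            )
        )
    return cohort


def separable_spec(subjects_per_class: int = 10, duration: float = 60.0, seed: int = 0,
                   **kwargs) -> CohortSpec:
    """The separable study preset (case: alpha 0.5/theta 1.2; control: 1.0/0.8)."""
    return CohortSpec(subjects_per_class=subjects_per_class, duration=duration, seed=seed,
                      class_a=replace(CASE_BANDS), class_b=replace(CONTROL_BANDS), **kwargs)


def null_spec(subjects_per_class: int = 10, duration: float = 60.0, seed: int = 0,
              **kwargs) -> CohortSpec:
    """The null preset: both classes drawn from identical parameters."""
    return CohortSpec(subjects_per_class=subjects_per_class, duration=duration, seed=seed,
                      class_a=replace(CONTROL_BANDS), class_b=replace(CONTROL_BANDS), **kwargs)


def band_power(rec: EEGRecording, band: str, nperseg: int = 512) -> float:
    """Mean Welch-periodogram power of ``rec`` inside a named band (diagnostic)."""
    lo, hi = BAND_EDGES[band]
    freqs, psd = sps.welch(rec.signal, fs=rec.sampling_rate, nperseg=nperseg, axis=1)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(psd[:, sel].mean())
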