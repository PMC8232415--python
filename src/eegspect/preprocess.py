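"""EEG cleaning chain: common average reference, IIR low-pass, per-channel
normalization to [-1, 1], and fixed-length single-channel segmentation.

The chain order is CAR -> low-pass -> normalize -> segment. The low-pass is
an order-4 Butterworth applied forward-backward (zero phase) by default so
that segment boundaries are not phase shifted; both choices are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import ClassLabel, EEGRecording

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain.

    cutoff_hz : low-pass cutoff (must be below Nyquist)
    filter_order : Butterworth order of the one-way design
    zero_phase : apply the filter forward-backward (squares the magnitude
        response, doubling the effective order and removing phase delay)
    window_seconds : segment length in seconds
    """

    cutoff_hz: float = 40.0
    filter_order: int = 4
    zero_phase: bool = True
    window_seconds: float = 3.5

    def __post_init__(self) -> None:
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")


@dataclass
class Segment:
    """A single-channel window of a preprocessed recording."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    channel_label: str = ""
    segment_index: int = 0
    class_label: ClassLabel = ClassLabel.UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be a 1-D vector")


def window_length_samples(cfg: PreprocessConfig, sampling_rate: float) -> int:
    """Segment length in samples: round(window_seconds * fs).

    Rounding is round-half-to-even (numpy convention); at the defaults
    (3.5 s, 256 Hz) the product is the exact integer 896.
    """
    return int(np.round(cfg.window_seconds * sampling_rate))


def apply_car(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average.

    At every time sample the across-channel mean is subtracted from every
    channel, so the output sums to zero across channels. Idempotent.
    """
    mean = rec.signal.mean(axis=0, keepdims=True)
    return rec.with_signal(rec.signal - mean)


def design_lowpass(cfg: PreprocessConfig, sampling_rate: float) -> np.ndarray:
    """Second-order sections of the Butterworth low-pass for ``sampling_rate``."""
    nyquist = sampling_rate / 2.0
    if cfg.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cfg.cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)"
        )
    return sps.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=sampling_rate, output="sos")


def lowpass_gain(cfg: PreprocessConfig, sampling_rate: float, freq_hz: float | np.ndarray) -> np.ndarray:
    """Analytic power gain |H(f)|^2 of the applied filter at ``freq_hz``.

    For zero-phase (forward-backward) application the one-way magnitude
    response is squared.
    """
    sos = design_lowpass(cfg, sampling_rate)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freq_hz, dtype=float)), fs=sampling_rate)
    gain = np.abs(h) ** 2
    if cfg.zero_phase:
        gain = gain**2
    return gain if np.ndim(freq_hz) else float(gain[0])


def apply_lowpass(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Low-pass every channel independently; output length equals input length."""
    cfg = cfg or PreprocessConfig()
    sos = design_lowpass(cfg, rec.sampling_rate)
    if cfg.zero_phase:
        # sosfiltfilt needs more samples than its edge-padding length
        padlen = 3 * (2 * sos.shape[0] + 1)
        if rec.n_samples <= padlen:
            raise ValueError(
                f"recording of {rec.n_samples} samples is shorter than the "
                f"zero-phase filter warm-up ({padlen} samples)"
            )
        filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    else:
        filtered = sps.sosfilt(sos, rec.signal, axis=1)
    return rec.with_signal(filtered)


def normalize_channels(rec: EEGRecording) -> EEGRecording:
    """Scale each channel by its maximum absolute value onto [-1, 1].

    An all-zero channel is passed through unchanged (no NaN/inf produced).
    """
    peak = np.abs(rec.signal).max(axis=1, keepdims=True)
    scale = np.where(peak > 0, peak, 1.0)
    return rec.with_signal(rec.signal / scale)


def segment_recording(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> list[Segment]:
    """Cut each channel into consecutive non-overlapping windows.

    The trailing partial window is dropped. A recording shorter than one
    window yields an empty list with a warning. Segments carry subject,
    channel and index provenance; ``segment_index`` counts within a channel.
    """
    cfg = cfg or PreprocessConfig()
    length = window_length_samples(cfg, rec.sampling_rate)
    n_windows = rec.n_samples // length
    if n_windows == 0:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{length}-sample window; no segments produced",
            stacklevel=2,
        )
        return []
    dropped = rec.n_samples - n_windows * length
    if dropped:
        log.info("dropping %d trailing samples (%.2f s)", dropped, dropped / rec.sampling_rate)
    segments: list[Segment] = []
    for ch, label in enumerate(rec.channel_labels):
        windows = rec.signal[ch, : n_windows * length].reshape(n_windows, length)
        for idx in range(n_windows):
            segments.append(
                Segment(
                    samples=windows[idx].copy(),
                    sampling_rate=rec.sampling_rate,
                    subject_id=rec.subject_id,
                    channel_label=label,
                    segment_index=idx,
                    class_label=rec.class_label,
                )
            )
    return segments


def preprocess_recording(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> list[Segment]:
    """Full chain: CAR -> low-pass -> normalize -> segment."""
    cfg = cfg or PreprocessConfig()
    return segment_recording(normalize_channels(apply_lowpass(apply_car(rec), cfg)), cfg)
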