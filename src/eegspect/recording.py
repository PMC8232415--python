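"""Core container for multi-channel EEG recordings.

Recordings are stored as a channels x samples matrix in microvolt-scale
arbitrary units, together with the sampling rate, 10-20 channel labels
(when known), a subject identifier and a binary class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class ClassLabel(str, Enum):
    """Binary screening label; ASD is the positive class."""

    ASD = "ASD"
    CONTROL = "CONTROL"
    UNKNOWN = "UNKNOWN"


#: Conventional 10-20 labels for a 16-channel montage.
TEN_TWENTY_16 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "P3", "P4", "T5", "T6", "O1", "O2",
]


def default_channel_labels(n_channels: int) -> list[str]:
    """10-20 names for the standard 16-channel montage, generic otherwise."""
    if n_channels == len(TEN_TWENTY_16):
        return list(TEN_TWENTY_16)
    return [f"CH{i + 1:02d}" for i in range(n_channels)]


@dataclass
class EEGRecording:
    """A multi-channel EEG recording.

    Attributes
    ----------
    signal : (n_channels, n_samples) float array
    sampling_rate : samples per second, > 0
    channel_labels : one label per channel
    subject_id : opaque subject identifier
    class_label : ASD / CONTROL / UNKNOWN
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    class_label: ClassLabel = ClassLabel.UNKNOWN

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.signal.shape[0] < 1:
            raise ValueError("recording must have at least one channel")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if isinstance(self.class_label, str) and not isinstance(self.class_label, ClassLabel):
            self.class_label = ClassLabel(self.class_label)
        if not self.channel_labels:
            self.channel_labels = default_channel_labels(self.signal.shape[0])
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one channel label required per channel")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_signal(self, signal: np.ndarray) -> "EEGRecording":
        """Copy of this recording with the signal matrix replaced."""
        return replace(self, signal=np.asarray(signal, dtype=float))
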