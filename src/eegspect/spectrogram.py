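"""STFT spectrogram images from EEG segments.

Each 3.5-s segment becomes one 8-bit grayscale image: magnitude STFT,
cropped to the 0-50 Hz display band, mapped to decibels relative to the
per-image peak over an 80 dB dynamic range, rescaled to 0-255 and resized
to a square raster. Row 0 is the highest displayed frequency.

Defaults: 64-sample Hann window with 75% overlap and a 128-point FFT — at
256 Hz that is a 0.25-s window, 2 Hz bin spacing and 52 frames per 3.5-s
segment. The short window is deliberate: it trades frequency resolution
(2 Hz still separates the classical EEG bands) for genuine texture along
the time axis, which census/LTP-style descriptors feed on; a 1-s window
leaves only 6 frames per segment and an almost featureless time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft
from scipy.signal import get_window
from skimage.transform import resize as _resize

from .preprocess import Segment
from .recording import ClassLabel

_DB_EPS = 1e-12


@dataclass
class STFTConfig:
    window_samples: int = 64
    hop_samples: int = 16
    fft_length: int = 128
    window_function: str = "hann"  # hann | hamming
    max_display_hz: float = 50.0
    dynamic_range_db: float = 80.0
    image_height: int = 128
    image_width: int = 128

    def __post_init__(self) -> None:
        if self.hop_samples > self.window_samples:
            raise ValueError("hop must not exceed window length")
        if self.fft_length < self.window_samples:
            raise ValueError("fft_length must be >= window length")
        if self.window_function not in ("hann", "hamming"):
            raise ValueError("window_function must be 'hann' or 'hamming'")

    def n_frames(self, n_samples: int) -> int:
        """Number of STFT frames for a segment of ``n_samples``."""
        if n_samples < self.window_samples:
            raise ValueError("segment shorter than one STFT window")
        return (n_samples - self.window_samples) // self.hop_samples + 1


@dataclass
class SpectrogramImage:
    """8-bit spectrogram raster plus axis metadata and provenance."""

    pixels: np.ndarray  # uint8, image_height x image_width
    freq_axis: np.ndarray  # Hz per row, descending from max_display_hz
    time_axis: np.ndarray  # seconds per column
    subject_id: str = ""
    channel_label: str = ""
    segment_index: int = 0
    class_label: ClassLabel = ClassLabel.UNKNOWN

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    @property
    def image_id(self) -> str:
        return f"{self.subject_id}_{self.channel_label}_{self.segment_index:04d}"


def compute_stft(seg: Segment | np.ndarray, cfg: STFTConfig | None = None,
                 sampling_rate: float | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude STFT of one segment.

    Frames are consecutive windows with the configured hop; no padding, so
    the frame count is floor((N - window)/hop) + 1. Returns
    (magnitude [n_freq_bins x n_frames], freqs_hz, frame_times_s), with
    fft_length//2 + 1 one-sided frequency rows.
    """
    cfg = cfg or STFTConfig()
    if isinstance(seg, Segment):
        x, fs = seg.samples, seg.sampling_rate
    else:
        x = np.asarray(seg, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare sample vector")
        fs = sampling_rate
    n_frames = cfg.n_frames(x.shape[0])
    frames = sliding_window_view(x, cfg.window_samples)[:: cfg.hop_samples][:n_frames]
    win = get_window(cfg.window_function, cfg.window_samples, fftbins=True)
    mag = np.abs(sfft.rfft(frames * win, n=cfg.fft_length, axis=1)).T
    freqs = sfft.rfftfreq(cfg.fft_length, d=1.0 / fs)
    times = (np.arange(n_frames) * cfg.hop_samples + cfg.window_samples / 2) / fs
    return mag, freqs, times


def render_image(
    mag: np.ndarray,
    cfg: STFTConfig | None = None,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    sampling_rate: float | None = None,
    provenance: dict | None = None,
) -> SpectrogramImage:
    """Render a magnitude matrix (freq rows ascending) to an 8-bit image.

    Rows above ``max_display_hz`` are discarded; magnitudes go to dB
    (20 log10(m + 1e-12)), are clipped to [peak - dynamic_range, peak],
    linearly rescaled to 0-255 and bilinearly resized. The vertical axis is
    flipped so row 0 carries the highest displayed frequency. An all-zero
    matrix renders as an all-zero image by policy. Because the dB clip is
    referenced to the per-image peak, scaling the input by a positive
    constant leaves the image unchanged.
    """
    cfg = cfg or STFTConfig()
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2:
        raise ValueError("magnitude must be 2-D (freq x time)")
    if (mag < 0).any():
        raise ValueError("magnitudes must be non-negative")
    if freqs is None:
        if sampling_rate is None:
            raise ValueError("either freqs or sampling_rate is required")
        freqs = sfft.rfftfreq(cfg.fft_length, d=1.0 / sampling_rate)
    freqs = np.asarray(freqs)
    if freqs.shape[0] != mag.shape[0]:
        raise ValueError(
            f"magnitude has {mag.shape[0]} frequency rows but {freqs.shape[0]} frequencies given"
        )
    keep = freqs <= cfg.max_display_hz + 1e-9
    band = mag[keep]
    band_freqs = np.asarray(freqs)[keep]

    if band.max() <= 0:
        scaled = np.zeros_like(band)
    else:
        db = 20.0 * np.log10(band + _DB_EPS)
        peak = db.max()
        db = np.clip(db, peak - cfg.dynamic_range_db, peak)
        scaled = (db - (peak - cfg.dynamic_range_db)) / cfg.dynamic_range_db * 255.0

    flipped = scaled[::-1]  # row 0 = highest displayed frequency
    out = _resize(flipped, (cfg.image_height, cfg.image_width), order=1,
                  mode="edge", anti_aliasing=False, preserve_range=True)
    pixels = np.clip(np.round(out), 0, 255).astype(np.uint8)

    row_freqs = np.linspace(band_freqs[-1], band_freqs[0], cfg.image_height)
    if times is None:
        times = np.arange(mag.shape[1], dtype=float)
    col_times = np.linspace(float(times[0]), float(times[-1]), cfg.image_width)
    prov = provenance or {}
    return SpectrogramImage(
        pixels=pixels,
        freq_axis=row_freqs,
        time_axis=col_times,
        subject_id=prov.get("subject_id", ""),
        channel_label=prov.get("channel_label", ""),
        segment_index=prov.get("segment_index", 0),
        class_label=ClassLabel(prov.get("class_label", ClassLabel.UNKNOWN)),
    )


def segment_to_image(seg: Segment, cfg: STFTConfig | None = None) -> SpectrogramImage:
    """Segment -> magnitude STFT -> rendered 8-bit image, with provenance."""
    cfg = cfg or STFTConfig()
    mag, freqs, times = compute_stft(seg, cfg)
    return render_image(
        mag,
        cfg,
        freqs=freqs,
        times=times,
        provenance={
            "subject_id": seg.subject_id,
            "channel_label": seg.channel_label,
            "segment_index": seg.segment_index,
            "class_label": seg.class_label,
        },
    )


def write_image(img: SpectrogramImage, path: str | Path) -> Path:
    """Write the raster as an 8-bit grayscale PNG (lossless)."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    return path


def read_image(path: str | Path, provenance: dict | None = None,
               cfg: STFTConfig | None = None) -> SpectrogramImage:
    """Read a PNG written by :func:`write_image`; axes are reconstructed
    from ``cfg`` when given, else left as pixel indices."""
    from PIL import Image

    cfg = cfg or STFTConfig()
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("L"), dtype=np.uint8)
    prov = provenance or {}
    return SpectrogramImage(
        pixels=pixels,
        freq_axis=np.linspace(cfg.max_display_hz, 0.0, pixels.shape[0]),
        time_axis=np.arange(pixels.shape[1], dtype=float),
        subject_id=prov.get("subject_id", ""),
        channel_label=prov.get("channel_label", ""),
        segment_index=int(prov.get("segment_index", 0)),
        class_label=ClassLabel(prov.get("class_label", ClassLabel.UNKNOWN)),
    )
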