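"""Reading and writing recordings, segments and manifests.

EDF (European Data Format) files are read through MNE. Writing uses a
minimal EDF+C-compatible writer implemented here: the format is an ASCII
header followed by 16-bit little-endian samples, which is all the cohort
simulator needs to emit files any EDF reader can open. Quantization to 16
bits means an EDF round trip is exact only up to the digitization step.

Delimited files are plain numeric matrices, rows = channels, whitespace or
comma separated; they carry no sampling rate, so one must be supplied.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import ClassLabel, EEGRecording, default_channel_labels

__all__ = [
    "read_recording",
    "write_edf",
    "write_delimited",
    "write_segments",
    "read_manifest",
]


def read_recording(
    path: str | Path,
    format: str = "edf",
    sampling_rate: float | None = None,
    subject_id: str | None = None,
    class_label: ClassLabel | str = ClassLabel.UNKNOWN,
) -> EEGRecording:
    """Load a recording from an EDF or delimited numeric file.

    Parameters
    ----------
    format : "edf" or "delimited"
    sampling_rate : required for delimited input (EDF stores its own)
    subject_id : defaults to the file stem
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subject = subject_id if subject_id is not None else path.stem
    if format == "edf":
        return _read_edf(path, subject, ClassLabel(class_label))
    if format == "delimited":
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for delimited input")
        return _read_delimited(path, sampling_rate, subject, ClassLabel(class_label))
    raise ValueError(f"unknown format {format!r} (expected 'edf' or 'delimited')")


def _read_edf(path: Path, subject_id: str, class_label: ClassLabel) -> EEGRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return EEGRecording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        class_label=class_label,
    )


def _read_delimited(
    path: Path, sampling_rate: float, subject_id: str, class_label: ClassLabel
) -> EEGRecording:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        data = np.loadtxt(_io.StringIO(text), delimiter=delimiter, ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed delimited matrix in {path}: {err}") from err
    return EEGRecording(
        signal=data,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        class_label=class_label,
    )


def _ascii_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file.

    Samples are quantized onto a symmetric physical range covering the data
    peak; records are one second long, so a trailing sub-second remainder is
    zero-padded in the file (readers see it as signal).
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = int(np.ceil(rec.n_samples / fs))
    peak = float(np.abs(rec.signal).max())
    phys_max = max(1.0, float(np.format_float_positional(peak * 1.001, precision=4, unique=False, fractional=False)))
    dig_max, dig_min = 32767, -32767
    scale = phys_max / dig_max

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(f"X X X {rec.subject_id or 'X'}"[:80], 80),
            _ascii_field("Startdate 01-JAN-2000 X X X"[:80], 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + rec.n_channels), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(rec.n_channels, 4),
        ]
    )
    labels = [lab[:16] for lab in rec.channel_labels]
    per_signal = b"".join(
        [
            b"".join(_ascii_field(lab, 16) for lab in labels),
            b"".join(_ascii_field("AgAgCl electrode"[:80], 80) for _ in labels),
            b"".join(_ascii_field("uV", 8) for _ in labels),
            b"".join(_ascii_field(f"{-phys_max:.8g}"[:8], 8) for _ in labels),
            b"".join(_ascii_field(f"{phys_max:.8g}"[:8], 8) for _ in labels),
            b"".join(_ascii_field(dig_min, 8) for _ in labels),
            b"".join(_ascii_field(dig_max, 8) for _ in labels),
            b"".join(_ascii_field("", 80) for _ in labels),
            b"".join(_ascii_field(fs, 8) for _ in labels),
            b"".join(_ascii_field("", 32) for _ in labels),
        ]
    )

    padded = np.zeros((rec.n_channels, n_records * fs))
    padded[:, : rec.n_samples] = rec.signal
    digital = np.clip(np.round(padded / scale), dig_min, dig_max).astype("<i2")
    # records are interleaved: for each second, each channel's block in turn
    blocks = digital.reshape(rec.n_channels, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(blocks.tobytes())
    return path


def write_delimited(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a whitespace-delimited channels x samples matrix."""
    path = Path(path)
    np.savetxt(path, rec.signal, fmt="%.9g")
    return path


def write_segments(segments, out_dir: str | Path, manifest_name: str = "manifest.tsv") -> Path:
    """Write one delimited vector file per segment plus a TSV manifest.

    Manifest columns: segment_id, subject, channel, index, label, file.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        seg_id = f"{seg.subject_id}_{seg.channel_label}_{seg.segment_index:04d}"
        fname = f"{seg_id}.txt"
        np.savetxt(out_dir / fname, seg.samples, fmt="%.9g")
        rows.append(
            {
                "segment_id": seg_id,
                "subject": seg.subject_id,
                "channel": seg.channel_label,
                "index": seg.segment_index,
                "label": seg.class_label.value,
                "file": fname,
            }
        )
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a segment/image manifest TSV."""
    return pd.read_csv(path, sep="\t")
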