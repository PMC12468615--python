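"""Dataset readers and writers, and signal segmentation.

Two on-disk signal formats are supported:

* plain ASCII, one numeric sample per line (the distribution format of
  the classic 4097-sample / 173.61 Hz single-channel benchmark segments);
* EDF (European Data Format) recordings with named channels, read via
  :mod:`mne`.  A minimal 16-bit EDF *writer* is included for generating
  test fixtures, since no installed library writes EDF.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .signal import Signal
from .synthetic import SyntheticDataset

__all__ = [
    "BONN_FS",
    "BONN_SAMPLES",
    "read_bonn_file",
    "write_bonn_file",
    "read_edf_channel",
    "write_edf",
    "segment",
    "write_ascii_dataset",
    "read_ascii_dataset",
]

BONN_FS = 173.61
BONN_SAMPLES = 4097


def read_bonn_file(path, fs: float = BONN_FS, expected_samples: int | None = BONN_SAMPLES) -> Signal:
    """Read a single-column ASCII sample file.

    Tolerates CR/LF line endings and blank lines; a non-numeric line
    raises with its line number.  Warns (does not error) if the sample
    count differs from ``expected_samples`` (the conventional 4097;
    pass None to disable the check).
    """
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    if expected_samples is not None and len(values) != expected_samples:
        warnings.warn(
            f"{path}: expected {expected_samples} samples, found {len(values)}",
            stacklevel=2,
        )
    return Signal(samples=np.asarray(values), fs=fs, meta={"path": str(path)})


def write_bonn_file(path, signal: Signal | np.ndarray) -> None:
    """Write one sample per line with round-trip-lossless precision."""
    samples = signal.samples if isinstance(signal, Signal) else np.asarray(signal)
    with open(path, "w") as fh:
        for v in samples:
            fh.write(f"{float(v)!r}\n")


def read_edf_channel(path, channel: str) -> Signal:
    """Extract one named channel from an EDF recording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not found in {path}; available: {raw.ch_names}"
        )
    raw = raw.pick([channel]).load_data(verbose="error")
    data = raw.get_data()[0]
    return Signal(
        samples=data,
        fs=float(raw.info["sfreq"]),
        meta={"path": str(path), "channel": channel},
    )


def write_edf(path, channels: dict[str, np.ndarray], fs: float) -> None:
    """Minimal EDF writer (16-bit, one data record) for test fixtures.

    All channels must share the sampling rate and length.  Physical
    scaling spans each channel's data range, so a write→read round trip
    agrees within 16-bit quantization of that range.
    """
    names = list(channels)
    arrays = [np.asarray(channels[n], dtype=np.float64) for n in names]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all channels must have equal length")
    ns = len(names)
    duration = n / fs

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad("1", 8),  # number of data records
            pad(f"{duration:.6f}"[:8], 8),
            pad(str(ns), 4),
        ]
    )
    phys_min, phys_max, dig = [], [], []
    for a in arrays:
        lo, hi = float(a.min()), float(a.max())
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (a - lo) / (hi - lo) * 65535.0 - 32768.0
        dig.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    def fmt(x: float) -> str:
        s = f"{x:.6g}"
        return s[:8]

    sig_header = b"".join(
        [
            b"".join(pad(nm, 16) for nm in names),
            b"".join(pad("", 80) for _ in names),  # transducer
            b"".join(pad("uV", 8) for _ in names),
            b"".join(pad(fmt(v), 8) for v in phys_min),
            b"".join(pad(fmt(v), 8) for v in phys_max),
            b"".join(pad("-32768", 8) for _ in names),
            b"".join(pad("32767", 8) for _ in names),
            b"".join(pad("", 80) for _ in names),  # prefiltering
            b"".join(pad(str(n), 8) for _ in names),
            b"".join(pad("", 32) for _ in names),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for d in dig:
            fh.write(d.tobytes())


def segment(signal: Signal, window_s: float, step_s: float | None = None) -> list[Signal]:
    """Split into fixed-length windows; non-overlapping by default.

    The trailing partial window is dropped.  ``step_s`` < ``window_s``
    yields overlapping windows.
    """
    if signal.fs is None:
        raise ValueError("segmentation requires a sampling rate")
    n_win = int(round(window_s * signal.fs))
    if n_win > len(signal):
        raise ValueError(
            f"window of {n_win} samples exceeds signal length {len(signal)}"
        )
    step = n_win if step_s is None else int(round(step_s * signal.fs))
    if step < 1:
        raise ValueError("step must be positive")
    out = []
    for i, start in enumerate(range(0, len(signal) - n_win + 1, step)):
        out.append(
            Signal(
                samples=signal.samples[start : start + n_win],
                fs=signal.fs,
                label=signal.label,
                meta={**signal.meta, "segment": i, "start_sample": start},
            )
        )
    return out


# ---------------------------------------------------------------------------
# on-disk synthetic datasets (ASCII files + JSON manifest)


def write_ascii_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write each signal as an ASCII file plus a manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads(json.dumps(dataset.manifest))  # deep copy
    for rec, sig in zip(manifest["signals"], dataset.signals):
        fname = f"sig_{rec['index']:04d}_{rec['class']}.txt"
        write_bonn_file(out_dir / fname, sig)
        rec["file"] = fname
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return out_dir / "manifest.json"


def read_ascii_dataset(data_dir) -> tuple[list[Signal], np.ndarray, dict]:
    """Load signals and labels from a directory written by
    :func:`write_ascii_dataset`."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    fs = manifest["config"]["fs"]
    signals, labels = [], []
    for rec in manifest["signals"]:
        sig = read_bonn_file(data_dir / rec["file"], fs=fs, expected_samples=None)
        sig.label = rec["class"]
        signals.append(sig)
        labels.append(rec["class_index"])
    return signals, np.asarray(labels), manifest
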