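"""File adapters: CSV and EDF readers sharing the ingest chunk contract.

CSV layout: an optional leading metadata comment ``# sampling_rate=<Hz>``,
then a header row of channel labels, then one row per sample.  If the
metadata row is absent, a JSON sidecar ``<file>.json`` with a
``sampling_rate`` key is consulted.

EDF is read through MNE's reader.  A minimal 16-bit EDF writer is included
so synthetic fixtures can exercise the EDF path end-to-end; amplitudes are
stored as microvolts and quantized to the int16 grid, so round-trips are
exact only to quantization precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .buffers import ConfigurationError, StreamInfo


def write_csv_stream(path: str | Path, data: np.ndarray, sampling_rate: float,
                     channel_labels: list[str] | None = None) -> None:
    """Write samples x channels to the CSV stream format."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    labels = channel_labels or [f"ch{i}" for i in range(data.shape[1])]
    if len(labels) != data.shape[1]:
        raise ConfigurationError(
            f"{len(labels)} labels for {data.shape[1]} channels"
        )
    with open(path, "w", newline="") as fh:
        fh.write(f"# sampling_rate={sampling_rate!r}\n")
        writer = csv.writer(fh)
        writer.writerow(labels)
        for row in data:
            writer.writerow([repr(float(v)) for v in row])


def read_csv_stream(path: str | Path) -> tuple[StreamInfo, np.ndarray]:
    """Read a CSV stream file into (StreamInfo, samples x channels)."""
    path = Path(path)
    sampling_rate = None
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first.lstrip("# ").strip().split(";") if "=" in kv
            )
            if "sampling_rate" in meta:
                sampling_rate = float(meta["sampling_rate"])
            header_line = fh.readline()
        else:
            header_line = first
        labels = next(csv.reader([header_line]))
        rows = [row for row in csv.reader(fh) if row]
    if sampling_rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ConfigurationError(
                f"{path}: no '# sampling_rate=' metadata row and no sidecar {sidecar.name}"
            )
        sampling_rate = float(json.loads(sidecar.read_text())["sampling_rate"])
    if not rows:
        raise ConfigurationError(f"{path}: no samples")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(labels):
        raise ConfigurationError(
            f"{path}: {data.shape[1]} columns vs {len(labels)} header labels"
        )
    info = StreamInfo(
        stream_id=path.stem,
        channel_count=len(labels),
        sampling_rate=sampling_rate,
        channel_labels=tuple(labels),
    )
    return info, data


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {value!r} (> {width})")
    return b.ljust(width)


def write_edf(path: str | Path, data: np.ndarray, sampling_rate: float,
              channel_labels: list[str] | None = None) -> None:
    """Write samples x channels to a minimal EDF file (16-bit, uV units).

    One data record per second; the tail shorter than a full record is
    dropped, and sampling_rate must be an integer for this writer.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    fs = int(round(sampling_rate))
    if fs != sampling_rate:
        raise ConfigurationError("the EDF writer requires an integer sampling rate")
    n_samples, n_sig = data.shape
    n_records = n_samples // fs
    if n_records < 1:
        raise ConfigurationError("need at least 1 s of data to write EDF")
    labels = channel_labels or [f"ch{i}" for i in range(n_sig)]

    phys_min = np.floor(data.min(axis=0) * 1000) / 1000
    phys_max = np.ceil(data.max(axis=0) * 1000) / 1000
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_sig)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_sig), 4),
    ])
    sig_fields = [
        [_edf_field(lbl, 16) for lbl in labels],
        [_edf_field("", 80)] * n_sig,
        [_edf_field("uV", 8)] * n_sig,
        [_edf_field(f"{v:.3f}"[:8], 8) for v in phys_min],
        [_edf_field(f"{v:.3f}"[:8], 8) for v in phys_max],
        [_edf_field(str(dig_min), 8)] * n_sig,
        [_edf_field(str(dig_max), 8)] * n_sig,
        [_edf_field("", 80)] * n_sig,
        [_edf_field(str(fs), 8)] * n_sig,
        [_edf_field("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(group) for group in sig_fields)

    # re-parse the headers we wrote so digitization uses the stored precision
    pmin = np.array([float(f"{v:.3f}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.3f}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.clip(
        np.round((data - pmin) / gain + dig_min), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[rec * fs:(rec + 1) * fs]
            fh.write(block.T.tobytes())  # per-signal contiguous within record


def read_edf_stream(path: str | Path) -> tuple[StreamInfo, np.ndarray]:
    """Read an EDF file into (StreamInfo, samples x channels), in uV."""
    from mne.io import read_raw_edf

    path = Path(path)
    raw = read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # MNE returns volts for uV-dimensioned EDF
    info = StreamInfo(
        stream_id=path.stem,
        channel_count=data.shape[1],
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )
    return info, data


def read_stream_file(path: str | Path) -> tuple[StreamInfo, np.ndarray]:
    """Dispatch on extension: .csv or .edf."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return read_csv_stream(path)
    if suffix == ".edf":
        return read_edf_stream(path)
    raise ConfigurationError(f"{path}: unsupported stream file type {suffix!r}")
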