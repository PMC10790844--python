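"""Packing connectivity frames into flat vectors and delivering them to sinks.

The packed vector is pair-major (subject pairs in lexicographic stream
order), band-minor (configuration order): for 3 subjects x 2 bands the order
is (1-2, b1), (1-2, b2), (1-3, b1), (1-3, b2), (2-3, b1), (2-3, b2), length
C(n_subjects, 2) * n_bands — 24 values for 4 subjects and 4 bands.  The
ordering is embedded in each sink's metadata so consumers need not guess.

Sinks: in-memory (tests), CSV recorder (long format, losslessly
round-trippable), an OSC/UDP sender, and an optional LSL Marker outlet named
"Rvalues" when pylsl is available.  Sink failures are logged per sink and
never halt the analysis loop.
"""

from __future__ import annotations

import csv
import logging
import socket
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import ConnectivityFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PackedFrame:
    """Flat pair-major/band-minor vector of connectivity values + timestamp."""

    vector: np.ndarray
    timestamp: float
    pair_order: tuple[tuple[str, str], ...]
    band_order: tuple[str, ...]

    def __len__(self) -> int:
        return self.vector.shape[0]

    @property
    def labels(self) -> list[tuple[tuple[str, str], str]]:
        """(pair, band) key for every vector position, in packing order."""
        return [(p, b) for p in self.pair_order for b in self.band_order]


def pack_frame(frame: ConnectivityFrame) -> PackedFrame:
    """Flatten a ConnectivityFrame; raises if any (pair, band) entry is missing."""
    vec = []
    for pair in frame.pair_order:
        for band in frame.band_order:
            key = (pair, band)
            if key not in frame.values:
                raise KeyError(f"frame is missing entry for {key}")
            vec.append(frame.values[key])
    return PackedFrame(
        vector=np.asarray(vec, dtype=float),
        timestamp=frame.window_time,
        pair_order=frame.pair_order,
        band_order=frame.band_order,
    )


def unpack_frame(packed: PackedFrame) -> dict[tuple[tuple[str, str], str], float]:
    """Inverse of pack_frame's flattening (labels -> values)."""
    return dict(zip(packed.labels, packed.vector.tolist()))


# ---------------------------------------------------------------------------
# Sinks
# ---------------------------------------------------------------------------


class MemorySink:
    """Keeps every delivered frame; used in tests and for baseline capture."""

    name = "memory"

    def __init__(self) -> None:
        self.frames: list[PackedFrame] = []

    def send(self, packed: PackedFrame) -> None:
        self.frames.append(packed)

    def close(self) -> None:
        pass


class CSVRecorder:
    """Long-format CSV recorder: timestamp, pair, band, value per row.

    The format round-trips losslessly through :func:`read_recording` (floats
    are written with repr precision).  Append mode concatenates sessions
    chronologically.
    """

    name = "csv"
    HEADER = ["timestamp", "pair", "band", "value"]

    def __init__(self, path: str | Path, append: bool = False) -> None:
        self.path = Path(path)
        mode = "a" if append and self.path.exists() else "w"
        self._fh = open(self.path, mode, newline="")
        self._writer = csv.writer(self._fh)
        if mode == "w":
            self._writer.writerow(self.HEADER)

    def send(self, packed: PackedFrame) -> None:
        for (pair, band), value in zip(packed.labels, packed.vector):
            self._writer.writerow(
                [repr(float(packed.timestamp)), f"{pair[0]}|{pair[1]}", band, repr(float(value))]
            )
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def read_recording(path: str | Path) -> list[PackedFrame]:
    """Read a CSVRecorder file back into PackedFrames (grouped by timestamp)."""
    rows: list[tuple[float, tuple[str, str], str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSVRecorder.HEADER:
            raise ValueError(f"{path}: not a hypersync recording (header {header})")
        for ts, pair, band, value in reader:
            a, b = pair.split("|")
            rows.append((float(ts), (a, b), band, float(value)))
    frames: list[PackedFrame] = []
    i = 0
    while i < len(rows):
        ts = rows[i][0]
        group = []
        while i < len(rows) and rows[i][0] == ts and not _starts_new_frame(rows, i, group):
            group.append(rows[i])
            i += 1
        pair_order = tuple(dict.fromkeys(r[1] for r in group))
        band_order = tuple(dict.fromkeys(r[2] for r in group))
        vec = np.asarray([r[3] for r in group], dtype=float)
        frames.append(PackedFrame(vec, ts, pair_order, band_order))
    return frames


def _starts_new_frame(rows, i, group) -> bool:
    # same timestamp may legitimately repeat across frames; a frame restarts
    # when the (pair, band) key of its first row reappears
    return bool(group) and (rows[i][1], rows[i][2]) == (group[0][1], group[0][2])


def _osc_string(s: str) -> bytes:
    b = s.encode("ascii") + b"\x00"
    return b + b"\x00" * (-len(b) % 4)


def encode_osc_message(address: str, floats: list[float]) -> bytes:
    """Encode an OSC 1.0 message with a flat float32 argument list."""
    type_tags = "," + "f" * len(floats)
    payload = b"".join(struct.pack(">f", f) for f in floats)
    return _osc_string(address) + _osc_string(type_tags) + payload


class OSCSink:
    """Sends each packed vector as one UDP OSC message (default /rvalues)."""

    name = "osc"

    def __init__(self, ip: str = "127.0.0.1", port: int = 9000,
                 address: str = "/rvalues") -> None:
        self.ip = ip
        self.port = port
        self.address = address
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)

    def send(self, packed: PackedFrame) -> None:
        msg = encode_osc_message(self.address, [float(v) for v in packed.vector])
        self._sock.sendto(msg, (self.ip, self.port))

    def close(self) -> None:
        self._sock.close()


class LSLSink:
    """LSL Marker-type outlet named "Rvalues" (requires the pylsl package)."""

    name = "lsl"

    def __init__(self, stream_name: str = "Rvalues", n_values: int = 1) -> None:
        try:
            import pylsl
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError("the LSL sink requires the 'pylsl' package") from exc
        info = pylsl.StreamInfo(
            stream_name, "Marker", n_values, pylsl.IRREGULAR_RATE, "float32"
        )
        self._outlet = pylsl.StreamOutlet(info)

    def send(self, packed: PackedFrame) -> None:  # pragma: no cover - needs LSL
        self._outlet.push_sample([float(v) for v in packed.vector], packed.timestamp)

    def close(self) -> None:  # pragma: no cover - needs LSL
        del self._outlet


@dataclass
class DeliveryReport:
    delivered: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed


def emit(packed: PackedFrame, sinks: list) -> DeliveryReport:
    """Deliver to every sink; per-sink failures are logged, never raised."""
    report = DeliveryReport()
    for sink in sinks:
        name = getattr(sink, "name", type(sink).__name__)
        try:
            sink.send(packed)
            report.delivered.append(name)
        except Exception as exc:
            logger.warning("sink %s failed: %s", name, exc)
            report.failed[name] = str(exc)
    return report
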