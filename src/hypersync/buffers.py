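"""Rolling per-stream sample buffers and analysis-window extraction.

Each EEG stream (one per subject) feeds a :class:`RingBuffer` that keeps the
most recent ``capacity_seconds`` of samples (30 s by default) and serves the
latest analysis window on demand.  Windows are aligned per stream by the
most-recent-sample rule; no cross-stream clock correction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BUFFER_SECONDS = 30.0
DEFAULT_WINDOW_SECONDS = 3.0
DEFAULT_PAD_SECONDS = 1.0


class ConfigurationError(ValueError):
    """Raised when stream/session configuration is inconsistent."""


class WarmingUp(Exception):
    """The buffer does not yet hold a full analysis window; no frame emitted."""


@dataclass(frozen=True)
class StreamInfo:
    """Metadata describing one incoming multichannel stream."""

    stream_id: str
    channel_count: int
    sampling_rate: float
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.channel_count < 1:
            raise ConfigurationError(
                f"stream {self.stream_id!r}: channel_count must be >= 1, "
                f"got {self.channel_count}"
            )
        if not self.sampling_rate > 0:
            raise ConfigurationError(
                f"stream {self.stream_id!r}: sampling_rate must be > 0, "
                f"got {self.sampling_rate}"
            )
        if self.channel_labels is not None and len(self.channel_labels) != self.channel_count:
            raise ConfigurationError(
                f"stream {self.stream_id!r}: {len(self.channel_labels)} labels "
                f"for {self.channel_count} channels"
            )


@dataclass(frozen=True)
class SampleWindow:
    """A contiguous block of real-valued samples: n_samples x n_channels."""

    data: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"window data must be 2-D (time x channels), got ndim={arr.ndim}")
        object.__setattr__(self, "data", arr)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class RingBuffer:
    """Chronological rolling buffer of at most ``capacity_seconds`` of samples.

    Samples arrive in chunks via :meth:`push`; the oldest are evicted first
    once the capacity is reached.  NaNs in a chunk are repaired by carrying
    the previous sample value forward (with a logged warning), so windows
    served downstream never contain missing values.
    """

    info: StreamInfo
    capacity_seconds: float = DEFAULT_BUFFER_SECONDS
    _data: np.ndarray = field(init=False, repr=False)
    _count: int = field(init=False, default=0)
    newest_timestamp: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.capacity_samples = int(round(self.capacity_seconds * self.info.sampling_rate))
        self._data = np.zeros((0, self.info.channel_count))

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.info.sampling_rate

    def push(self, chunk: np.ndarray, timestamp: float | None = None) -> None:
        """Append ``chunk`` (n x channels); evict oldest beyond capacity."""
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size == 0:
            return
        if chunk.ndim == 1:
            chunk = chunk[:, None]
        if chunk.shape[1] != self.info.channel_count:
            raise ConfigurationError(
                f"stream {self.info.stream_id!r}: chunk has {chunk.shape[1]} "
                f"channels, expected {self.info.channel_count}"
            )
        if np.isnan(chunk).any():
            chunk = self._repair_nans(chunk)
        self._data = np.concatenate([self._data, chunk], axis=0)
        if self._data.shape[0] > self.capacity_samples:
            self._data = self._data[-self.capacity_samples:]
        n = chunk.shape[0]
        if timestamp is None:
            timestamp = self.newest_timestamp + n / self.info.sampling_rate
        self.newest_timestamp = timestamp

    def _repair_nans(self, chunk: np.ndarray) -> np.ndarray:
        n_bad = int(np.isnan(chunk).sum())
        logger.warning(
            "stream %s: %d NaN sample(s) repaired by previous-value hold",
            self.info.stream_id, n_bad,
        )
        chunk = chunk.copy()
        # seed first row from the last buffered sample when available
        prev = self._data[-1] if self.n_samples else np.zeros(chunk.shape[1])
        for t in range(chunk.shape[0]):
            bad = np.isnan(chunk[t])
            chunk[t, bad] = prev[bad]
            prev = chunk[t]
        return chunk

    def latest_window(
        self,
        window_size: float = DEFAULT_WINDOW_SECONDS,
        pad: float = DEFAULT_PAD_SECONDS,
    ) -> SampleWindow:
        """Most recent ``window_size + pad`` seconds as a :class:`SampleWindow`.

        The leading ``pad`` seconds absorb filter/Hilbert edge transients and
        are discarded downstream after the analytic transform.  Raises
        :class:`WarmingUp` until enough data has been buffered.
        """
        fs = self.info.sampling_rate
        need = int(round((window_size + pad) * fs))
        if self.n_samples < need:
            raise WarmingUp(
                f"stream {self.info.stream_id!r}: buffered {self.duration:.2f} s "
                f"< window+pad {window_size + pad:.2f} s"
            )
        data = self._data[-need:].copy()
        start = self.newest_timestamp - need / fs
        return SampleWindow(data=data, sampling_rate=fs, start_time=start)


# ---------------------------------------------------------------------------
# Transport adapters.  All adapters present the same contract: `streams()`
# returns StreamInfo metadata and `pull(stream_id)` returns the next chunk
# (array, timestamp) or None when exhausted, so the engine is transport-
# agnostic.
# ---------------------------------------------------------------------------


class MockAdapter:
    """In-memory adapter used in tests and by the synthetic generator."""

    def __init__(self) -> None:
        self._adverts: dict[str, tuple[int, float]] = {}
        self._queues: dict[str, list[tuple[np.ndarray, float]]] = {}

    def register(self, info: StreamInfo) -> None:
        self.advertise(info.stream_id, info.channel_count, info.sampling_rate)

    def advertise(self, stream_id: str, channel_count: int, sampling_rate: float) -> None:
        """Advertise a stream by raw metadata (validated lazily in streams())."""
        self._adverts[stream_id] = (channel_count, sampling_rate)
        self._queues.setdefault(stream_id, [])

    def feed(self, stream_id: str, chunk: np.ndarray, timestamp: float) -> None:
        self._queues[stream_id].append((np.asarray(chunk, dtype=float), timestamp))

    def streams(self) -> list[StreamInfo]:
        infos = []
        for sid in sorted(self._adverts):
            n_ch, fs = self._adverts[sid]
            try:
                infos.append(StreamInfo(sid, n_ch, fs))
            except ConfigurationError as exc:
                logger.warning("rejecting advertised stream: %s", exc)
        return infos

    def pull(self, stream_id: str):
        q = self._queues[stream_id]
        return q.pop(0) if q else None


class LSLAdapter:
    """LabStreamingLayer inlet adapter (requires the optional pylsl package)."""

    def __init__(self) -> None:
        try:
            import pylsl  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "live LSL streaming requires the 'pylsl' package; "
                "install it or use a file adapter"
            ) from exc
        self._pylsl = __import__("pylsl")
        self._inlets: dict[str, object] = {}

    def streams(self) -> list[StreamInfo]:  # pragma: no cover - needs live LSL
        infos = []
        for s in self._pylsl.resolve_streams(wait_time=1.0):
            if s.channel_count() < 1:
                logger.warning("ignoring stream %r with 0 channels", s.name())
                continue
            infos.append(
                StreamInfo(s.name(), s.channel_count(), s.nominal_srate())
            )
        return sorted(infos, key=lambda i: i.stream_id)

    def pull(self, stream_id: str):  # pragma: no cover - needs live LSL
        inlet = self._inlets.get(stream_id)
        if inlet is None:
            matches = self._pylsl.resolve_byprop("name", stream_id, timeout=1.0)
            if not matches:
                return None
            inlet = self._pylsl.StreamInlet(matches[0])
            self._inlets[stream_id] = inlet
        samples, ts = inlet.pull_chunk(timeout=0.0)
        if not samples:
            return None
        return np.asarray(samples, dtype=float), float(ts[-1])


def discover_streams(adapter) -> list[StreamInfo]:
    """All visible streams on ``adapter``, deterministically sorted by id.

    Streams advertising zero channels are rejected with a warning at
    StreamInfo construction inside the adapter; an empty result is not an
    error (the caller may retry).
    """
    infos = adapter.streams()
    return sorted(infos, key=lambda i: i.stream_id)
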