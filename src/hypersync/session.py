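"""Session orchestration: config, validation, the analysis loop, offline batch.

The loop is: ingest -> window -> band-pass -> analytic signal -> pair metric
-> band weight -> normalize -> pack -> emit/record, at a fixed hop cadence.
Frame k is computed the moment a stream has received exactly
``n_warm + k * n_hop`` samples (``n_warm`` = window + pad); nothing is
emitted while a buffer is still warming up.  Because the hop grid is defined
in sample counts, streaming a file chunk-by-chunk through the ring buffers
(:func:`run_files`) and slicing the same file directly (:func:`run_offline`)
produce bit-identical frame sequences — the module's central contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .buffers import (
    DEFAULT_BUFFER_SECONDS,
    DEFAULT_PAD_SECONDS,
    DEFAULT_WINDOW_SECONDS,
    ConfigurationError,
    RingBuffer,
    SampleWindow,
    StreamInfo,
    WarmingUp,
)
from .io import read_stream_file
from .metrics import CONNECTIVITY_TYPES, METRICS, ConnectivityFrame, pair_matrix
from .normalize import NormalizationSpec, minmax
from .preprocess import DEFAULT_BANDS, BandSpec, band_analytic, band_power, select_channels
from .transport import PackedFrame, emit, pack_frame

logger = logging.getLogger(__name__)

DEFAULT_HOP_SECONDS = 0.25


def default_bands() -> list[BandSpec]:
    return [BandSpec(name, lo, hi) for name, lo, hi in DEFAULT_BANDS]


@dataclass(frozen=True)
class SessionConfig:
    """Everything a session needs; mirrors the tool's parameter panels."""

    streams: tuple[str, ...] = ()
    bands: tuple[BandSpec, ...] = field(default_factory=lambda: tuple(default_bands()))
    metric: str = "envelope_correlation"
    connectivity_type: str = "one-to-one"
    window_size: float = DEFAULT_WINDOW_SECONDS
    pad: float = DEFAULT_PAD_SECONDS
    buffer_seconds: float = DEFAULT_BUFFER_SECONDS
    hop_seconds: float = DEFAULT_HOP_SECONDS
    normalization: NormalizationSpec | None = None
    send_power: bool = False
    allow_resample: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        violations = validate_dict(d)
        if violations:
            raise ConfigurationError(
                "invalid session config:\n  " + "\n  ".join(violations)
            )
        bands = tuple(_band_from_dict(b) for b in d.get("bands", [])) or tuple(default_bands())
        norm = d.get("normalization")
        norm_spec = (
            NormalizationSpec(
                manual_min=float(norm.get("manual_min", 0.0)),
                manual_max=float(norm.get("manual_max", 1.0)),
                blend_weight=float(norm.get("blend_weight", 1.0)),
            )
            if norm
            else None
        )
        return cls(
            streams=tuple(str(s) for s in d.get("streams", [])),
            bands=bands,
            metric=d.get("metric", "envelope_correlation"),
            connectivity_type=d.get("connectivity_type", "one-to-one"),
            window_size=float(d.get("window_size", DEFAULT_WINDOW_SECONDS)),
            pad=float(d.get("pad", DEFAULT_PAD_SECONDS)),
            buffer_seconds=float(d.get("buffer_seconds", DEFAULT_BUFFER_SECONDS)),
            hop_seconds=float(d.get("hop_seconds", DEFAULT_HOP_SECONDS)),
            normalization=norm_spec,
            send_power=bool(d.get("send_power", False)),
            allow_resample=bool(d.get("allow_resample", False)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _band_from_dict(b: dict) -> BandSpec:
    channels = {
        str(k): tuple(int(i) for i in v)
        for k, v in (b.get("channels") or {}).items()
    }
    return BandSpec(
        name=str(b["name"]),
        f_lo=float(b["f_lo"]),
        f_hi=float(b["f_hi"]),
        weight=float(b.get("weight", 1.0)),
        channels_per_stream=channels,
    )


def validate_dict(d: dict) -> list[str]:
    """Check every config invariant on a raw dict; return all violations."""
    out: list[str] = []
    window = float(d.get("window_size", DEFAULT_WINDOW_SECONDS))
    buffer_s = float(d.get("buffer_seconds", DEFAULT_BUFFER_SECONDS))
    hop = float(d.get("hop_seconds", DEFAULT_HOP_SECONDS))
    pad = float(d.get("pad", DEFAULT_PAD_SECONDS))
    if window <= 0:
        out.append(f"window_size: must be > 0, got {window}")
    if not window <= buffer_s:
        out.append(f"window_size ({window}) must be <= buffer_seconds ({buffer_s})")
    if not hop > 0:
        out.append(f"hop_seconds: must be > 0, got {hop}")
    if pad < 0:
        out.append(f"pad: must be >= 0, got {pad}")
    metric = d.get("metric", "envelope_correlation")
    if metric not in METRICS:
        out.append(f"metric: unknown {metric!r}; allowed: {sorted(METRICS)}")
    ctype = d.get("connectivity_type", "one-to-one")
    if ctype not in CONNECTIVITY_TYPES:
        out.append(
            f"connectivity_type: unknown {ctype!r}; allowed: {list(CONNECTIVITY_TYPES)}"
        )
    for i, b in enumerate(d.get("bands", [])):
        try:
            _band_from_dict(b)
        except (ConfigurationError, KeyError, TypeError, ValueError) as exc:
            out.append(f"bands[{i}]: {exc}")
    norm = d.get("normalization")
    if norm:
        try:
            NormalizationSpec(
                manual_min=float(norm.get("manual_min", 0.0)),
                manual_max=float(norm.get("manual_max", 1.0)),
                blend_weight=float(norm.get("blend_weight", 1.0)),
            )
        except ConfigurationError as exc:
            out.append(f"normalization: {exc}")
    return out


def validate_config(
    config: SessionConfig, stream_infos: list[StreamInfo] | None = None
) -> list[str]:
    """Rate- and stream-dependent checks; empty list = valid."""
    out: list[str] = []
    if stream_infos:
        for info in stream_infos:
            for band in config.bands:
                if band.f_hi >= info.sampling_rate / 2:
                    out.append(
                        f"band {band.name!r}: f_hi={band.f_hi} >= Nyquist of "
                        f"stream {info.stream_id!r} ({info.sampling_rate / 2} Hz)"
                    )
                try:
                    sel = band.channels_for(info.stream_id, info.channel_count)
                    if len(sel) == 0 or any(
                        not 0 <= i < info.channel_count for i in sel
                    ):
                        out.append(
                            f"band {band.name!r}, stream {info.stream_id!r}: "
                            f"invalid channel selection {sel}"
                        )
                except ConfigurationError as exc:
                    out.append(str(exc))
        rates = {info.sampling_rate for info in stream_infos}
        if len(rates) > 1 and not config.allow_resample:
            out.append(
                f"streams have unequal sampling rates {sorted(rates)}; "
                "set allow_resample to resample to the minimum rate"
            )
    return out


# ---------------------------------------------------------------------------
# Frame computation shared by the online and offline paths
# ---------------------------------------------------------------------------


def compute_frame(
    windows: dict[str, SampleWindow],
    config: SessionConfig,
    window_time: float,
) -> tuple[ConnectivityFrame, dict[str, dict[str, np.ndarray]] | None]:
    """One (window+pad) block per stream -> one normalized ConnectivityFrame.

    Returns the frame and, when ``send_power`` is set, per-stream per-band
    channel band powers.
    """
    analytic: dict[str, dict[str, object]] = {}
    powers: dict[str, dict[str, np.ndarray]] | None = {} if config.send_power else None
    for sid, window in windows.items():
        per_band = {}
        for band in config.bands:
            subset = select_channels(window, band, sid)
            aw = band_analytic(subset, band, pad=config.pad)
            per_band[band.name] = aw
            if powers is not None:
                powers.setdefault(sid, {})[band.name] = band_power(aw)
        analytic[sid] = per_band
    frame = pair_matrix(
        analytic,
        metric=config.metric,
        connectivity_type=config.connectivity_type,
        bands=list(config.bands),
        window_time=window_time,
    )
    if config.normalization is not None:
        frame = minmax(frame, config.normalization)
    return frame, powers


def _load_streams(
    paths: list[str | Path], config: SessionConfig
) -> tuple[list[StreamInfo], list[np.ndarray], float]:
    infos, arrays = [], []
    for p in paths:
        info, data = read_stream_file(p)
        if data.shape[0] == 0:
            raise ConfigurationError(f"{p}: empty stream file")
        infos.append(info)
        arrays.append(data)
    problems = validate_config(config, infos)
    rates = {i.sampling_rate for i in infos}
    if len(rates) > 1 and config.allow_resample:
        from scipy.signal import resample_poly

        target = min(rates)
        resampled = []
        for info, arr in zip(infos, arrays):
            if info.sampling_rate != target:
                up, down = int(target), int(info.sampling_rate)
                arr = resample_poly(arr, up, down, axis=0)
                info = StreamInfo(info.stream_id, info.channel_count, target,
                                  info.channel_labels)
            resampled.append((info, arr))
        infos = [i for i, _ in resampled]
        arrays = [a for _, a in resampled]
        problems = validate_config(config, infos)
    if problems:
        raise ConfigurationError("invalid session:\n  " + "\n  ".join(problems))
    fs = infos[0].sampling_rate
    return infos, arrays, fs


def _hop_grid(config: SessionConfig, fs: float, n_total: int) -> tuple[int, int, list[int]]:
    """Frame-boundary sample counts: n_warm + round(k * hop * fs).

    The cumulative rounding keeps the grid drift-free when hop * fs is not
    an integer, so frame counts follow (duration - window - pad)/hop + 1.
    """
    n_warm = int(round((config.window_size + config.pad) * fs))
    hop_samples = config.hop_seconds * fs
    if hop_samples < 1:
        raise ConfigurationError("hop_seconds shorter than one sample")
    targets = []
    k = 0
    while True:
        t = n_warm + int(round(k * hop_samples))
        if t > n_total:
            break
        if not targets or t > targets[-1]:
            targets.append(t)
        k += 1
    return n_warm, max(1, int(round(hop_samples))), targets


def run_offline(
    paths: list[str | Path],
    config: SessionConfig,
    sinks: list | None = None,
) -> list[PackedFrame]:
    """Batch analysis: slice the files at the hop grid and compute each frame."""
    infos, arrays, fs = _load_streams(list(paths), config)
    n_total = min(a.shape[0] for a in arrays)
    n_warm, _, targets = _hop_grid(config, fs, n_total)
    if not targets:
        logger.warning(
            "window+pad (%g s) longer than the recording (%g s): no frames",
            config.window_size + config.pad, n_total / fs,
        )
    frames = []
    for end in targets:
        windows = {
            info.stream_id: SampleWindow(
                arr[end - n_warm:end], fs, (end - n_warm) / fs
            )
            for info, arr in zip(infos, arrays)
        }
        frame, _ = compute_frame(windows, config, window_time=end / fs)
        packed = pack_frame(frame)
        if sinks:
            emit(packed, sinks)
        frames.append(packed)
    return frames


def run_files(
    paths: list[str | Path],
    config: SessionConfig,
    sinks: list | None = None,
    chunk_seconds: float = 0.1,
):
    """Online loop over recorded files: feed ring buffers chunk-by-chunk.

    Yields each PackedFrame as it is produced.  Chunks are split internally
    at hop boundaries so frames are computed at the exact sample counts of
    the offline hop grid; the result is bit-identical to :func:`run_offline`.
    """
    infos, arrays, fs = _load_streams(list(paths), config)
    n_total = min(a.shape[0] for a in arrays)
    n_warm, n_hop, targets = _hop_grid(config, fs, n_total)
    buffers = {
        info.stream_id: RingBuffer(info, capacity_seconds=config.buffer_seconds)
        for info in infos
    }
    order = [info.stream_id for info in infos]
    arrays_by_id = dict(zip(order, arrays))
    chunk_n = max(1, int(round(chunk_seconds * fs)))
    pushed = 0
    target_idx = 0
    while pushed < n_total:
        next_target = targets[target_idx] if target_idx < len(targets) else n_total
        step = min(chunk_n, n_total - pushed, max(1, next_target - pushed))
        for sid in order:
            buffers[sid].push(arrays_by_id[sid][pushed:pushed + step])
        pushed += step
        if target_idx < len(targets) and pushed == targets[target_idx]:
            windows = {}
            try:
                for sid in order:
                    windows[sid] = buffers[sid].latest_window(
                        config.window_size, config.pad
                    )
            except WarmingUp as exc:  # pragma: no cover - grid starts at n_warm
                logger.debug("still warming up: %s", exc)
            else:
                frame, _ = compute_frame(windows, config, window_time=pushed / fs)
                packed = pack_frame(frame)
                if sinks:
                    emit(packed, sinks)
                yield packed
            target_idx += 1


def run_live(
    config: SessionConfig,
    adapter,
    sinks: list | None = None,
    max_frames: int | None = None,
):
    """Live loop over a transport adapter (LSL or mock).

    Windows are aligned per stream by most-recent-sample; a frame is emitted
    whenever every stream has accumulated ``hop_seconds`` of new data since
    the previous frame.  Streams that stop delivering stall the loop (frame
    skip with a warning) rather than crashing it.
    """
    infos = adapter.streams()
    if len(infos) < 2:
        raise ConfigurationError("need at least 2 streams")
    problems = validate_config(config, infos)
    if problems:
        raise ConfigurationError("invalid session:\n  " + "\n  ".join(problems))
    fs = infos[0].sampling_rate
    n_hop = int(round(config.hop_seconds * fs))
    buffers = {i.stream_id: RingBuffer(i, config.buffer_seconds) for i in infos}
    since_hop = {i.stream_id: 0 for i in infos}
    emitted = 0
    idle = 0
    while max_frames is None or emitted < max_frames:
        got_data = False
        for info in infos:
            item = adapter.pull(info.stream_id)
            if item is None:
                continue
            chunk, ts = item
            buffers[info.stream_id].push(chunk, ts)
            since_hop[info.stream_id] += np.atleast_2d(chunk).shape[0]
            got_data = True
        if not got_data:
            idle += 1
            if idle > 2:  # adapter exhausted (file-backed) or stalled
                return
            continue
        idle = 0
        if all(v >= n_hop for v in since_hop.values()):
            try:
                windows = {
                    sid: buf.latest_window(config.window_size, config.pad)
                    for sid, buf in buffers.items()
                }
            except WarmingUp as exc:
                logger.debug("warming up: %s", exc)
            else:
                t = max(buf.newest_timestamp for buf in buffers.values())
                frame, _ = compute_frame(windows, config, window_time=t)
                packed = pack_frame(frame)
                if sinks:
                    emit(packed, sinks)
                yield packed
                emitted += 1
            for sid in since_hop:
                since_hop[sid] = 0


def baseline_normalization(
    paths: list[str | Path],
    config: SessionConfig,
    percentiles: tuple[float, float] | None = None,
) -> NormalizationSpec:
    """Run a recording offline and derive per-(pair, band) baseline limits."""
    from .normalize import limits_from_baseline
    from .transport import unpack_frame

    raw_config = replace(config, normalization=None)
    frames = run_offline(paths, raw_config)
    conn_frames = []
    for p in frames:
        values = unpack_frame(p)
        conn_frames.append(
            ConnectivityFrame(
                values=values,
                metric_name=config.metric,
                connectivity_type=config.connectivity_type,
                window_time=p.timestamp,
                pair_order=p.pair_order,
                band_order=p.band_order,
            )
        )
    limits = limits_from_baseline(conn_frames, percentiles=percentiles)
    base_spec = config.normalization or NormalizationSpec()
    return base_spec.with_baseline(limits)
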