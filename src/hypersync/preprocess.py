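"""Band-pass filtering and the instantaneous analytic signal.

Each analysis window is filtered per channel with a causal 4th-order
Butterworth band-pass (second-order sections) into the configured frequency
band, then Hilbert-transformed into the complex analytic signal X(t).  The
leading pad region — included in the window precisely to soak up the filter's
settling transient and the Hilbert transform's circular edge effects — is
discarded after the transform.

Derived per-sample quantities follow the standard analytic-signal reading:
envelope ``|X|``, band power ``|X|^2``, unit phasor ``X/|X|`` and phase angle
``angle(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfilt

from .buffers import ConfigurationError, SampleWindow

#: default band table (name, f_lo, f_hi in Hz), the standard EEG division
#: used by the validation setup
DEFAULT_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 20.0),
)

FILTER_ORDER = 4


@dataclass(frozen=True)
class BandSpec:
    """One row of the frequency-band table.

    ``weight`` multiplies the band's connectivity values before output;
    ``channels_per_stream`` maps stream id -> channel indices used for this
    band (empty map = all channels of every stream).
    """

    name: str
    f_lo: float
    f_hi: float
    weight: float = 1.0
    channels_per_stream: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )
        if self.weight < 0:
            raise ConfigurationError(f"band {self.name!r}: weight must be >= 0")

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.f_hi >= sampling_rate / 2:
            raise ConfigurationError(
                f"band {self.name!r}: f_hi={self.f_hi} Hz >= Nyquist "
                f"({sampling_rate / 2} Hz)"
            )

    def channels_for(self, stream_id: str, n_channels: int) -> tuple[int, ...]:
        sel = self.channels_per_stream.get(stream_id)
        if sel is None:
            return tuple(range(n_channels))
        return tuple(sel)


@dataclass(frozen=True)
class AnalyticWindow:
    """Complex analytic signal per channel for one band.

    ``values[t, c]`` is X(c, t); real part equals the band-limited input.
    """

    values: np.ndarray
    band: BandSpec
    sampling_rate: float
    start_time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def envelope(self) -> np.ndarray:
        """Instantaneous envelope |X|, >= 0."""
        return np.abs(self.values)

    @property
    def power(self) -> np.ndarray:
        """Instantaneous band power |X|^2."""
        return np.abs(self.values) ** 2

    @property
    def phasor(self) -> np.ndarray:
        """Unit phasor X/|X|; 0 where the envelope vanishes (flagged degenerate)."""
        env = np.abs(self.values)
        out = np.zeros_like(self.values)
        np.divide(self.values, env, out=out, where=env > 0)
        return out

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase angle in (-pi, pi]."""
        return np.angle(self.values)

    @property
    def degenerate_mask(self) -> np.ndarray:
        """True where the phase is undefined (zero envelope)."""
        return np.abs(self.values) == 0


def design_bandpass(band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Second-order sections of the causal Butterworth band-pass for ``band``."""
    band.validate_for_rate(sampling_rate)
    return butter(
        FILTER_ORDER,
        (band.f_lo, band.f_hi),
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass(window: SampleWindow, band: BandSpec) -> SampleWindow:
    """Causal band-pass of every channel; output has the input's shape.

    Filtering is stateless per window (initial conditions zero); the window's
    leading pad absorbs the settling transient.
    """
    sos = design_bandpass(band, window.sampling_rate)
    filtered = sosfilt(sos, window.data, axis=0)
    return SampleWindow(
        data=filtered,
        sampling_rate=window.sampling_rate,
        start_time=window.start_time,
    )


def analytic_signal(band_limited: SampleWindow, pad: float = 0.0) -> AnalyticWindow:
    """Hilbert transform to the complex analytic signal, discarding the pad.

    The transform runs over the full padded window (its circular boundary
    assumption corrupts edges); the first ``pad`` seconds are then dropped so
    the retained region is transient-free.
    """
    n_pad = int(round(pad * band_limited.sampling_rate))
    if n_pad >= band_limited.n_samples:
        raise ValueError(
            f"pad ({n_pad} samples) must be shorter than the window "
            f"({band_limited.n_samples} samples)"
        )
    analytic = hilbert(band_limited.data, axis=0)[n_pad:]
    band = BandSpec("broadband", 1e-6, band_limited.sampling_rate / 2 * 0.999)
    return AnalyticWindow(
        values=analytic,
        band=band,
        sampling_rate=band_limited.sampling_rate,
        start_time=band_limited.start_time + n_pad / band_limited.sampling_rate,
    )


def band_analytic(window: SampleWindow, band: BandSpec, pad: float = 0.0) -> AnalyticWindow:
    """bandpass + analytic_signal in one step, tagging the band."""
    filtered = bandpass(window, band)
    n_pad = int(round(pad * window.sampling_rate))
    if n_pad >= filtered.n_samples:
        raise ValueError("pad must be shorter than the window")
    analytic = hilbert(filtered.data, axis=0)[n_pad:]
    return AnalyticWindow(
        values=analytic,
        band=band,
        sampling_rate=window.sampling_rate,
        start_time=window.start_time + n_pad / window.sampling_rate,
    )


def band_power(aw: AnalyticWindow) -> np.ndarray:
    """Per-channel band power: mean square of the band-limited real signal.

    Computed as mean(|X|^2)/2 — the analytic envelope carries twice the real
    signal's power, so the halving makes a unit in-band sinusoid read 0.5,
    the physical mean-square convention.
    """
    return aw.power.mean(axis=0) / 2.0


def select_channels(window: SampleWindow, band: BandSpec, stream_id: str) -> SampleWindow:
    """Restrict ``window`` to the channels configured for ``band``/``stream_id``."""
    sel = band.channels_for(stream_id, window.n_channels)
    if len(sel) == 0:
        raise ConfigurationError(
            f"stream {stream_id!r}, band {band.name!r}: empty channel selection"
        )
    bad = [i for i in sel if not (0 <= i < window.n_channels)]
    if bad:
        raise ConfigurationError(
            f"stream {stream_id!r}, band {band.name!r}: channel indices {bad} "
            f"out of range for {window.n_channels} channels"
        )
    return SampleWindow(
        data=window.data[:, list(sel)],
        sampling_rate=window.sampling_rate,
        start_time=window.start_time,
    )
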