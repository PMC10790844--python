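"""The six inter-brain connectivity metrics and per-pair averaging.

All metrics operate on two equal-length complex analytic signals X(t), Y(t)
(one channel each).  Following the cross-spectrum-as-dot-product formulation,
the coherence family uses the within-window summed cross-spectrum

    S_xy = sum_t X(t) * conj(Y(t))

so that coherence = |S_xy| / sqrt(sum|X|^2 * sum|Y|^2) and imaginary
coherence replaces |S_xy| with |Im(S_xy)|.  Envelope/power correlation are
Pearson correlations of |X|,|Y| and |X|^2,|Y|^2; PLV is the magnitude of the
mean relative unit phasor; CCorr is the circular correlation coefficient of
the instantaneous phases (deviations taken from the circular mean).

Degenerate inputs (zero power, zero envelope variance, zero circular
variance) return 0 together with a quality flag instead of NaN: a live
feedback loop must keep emitting frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import AnalyticWindow, BandSpec

logger = logging.getLogger(__name__)

#: metric name -> closed interval of attainable values (before band weighting)
METRIC_RANGES = {
    "coherence": (0.0, 1.0),
    "imaginary_coherence": (0.0, 1.0),
    "plv": (0.0, 1.0),
    "envelope_correlation": (-1.0, 1.0),
    "power_correlation": (-1.0, 1.0),
    "ccorr": (-1.0, 1.0),
}

CONNECTIVITY_TYPES = ("one-to-one", "all-to-all")


@dataclass
class MetricResult:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def _as_complex(x) -> np.ndarray:
    return np.asarray(x, dtype=complex).ravel()


def _check_lengths(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"sample counts differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] == 0:
        raise ValueError("empty input")


def coherence(x, y) -> MetricResult:
    """|sum X conj(Y)| / sqrt(sum|X|^2 sum|Y|^2); 1 iff Y is a scalar multiple of X."""
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    px = float(np.sum(np.abs(x) ** 2))
    py = float(np.sum(np.abs(y) ** 2))
    if px == 0.0 or py == 0.0:
        return MetricResult(0.0, degenerate=True)
    s_xy = np.sum(x * np.conj(y))
    return MetricResult(float(np.abs(s_xy) / np.sqrt(px * py)))


def imaginary_coherence(x, y) -> MetricResult:
    """|Im(sum X conj(Y))| / sqrt(sum|X|^2 sum|Y|^2); kills zero-lag synchrony."""
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    px = float(np.sum(np.abs(x) ** 2))
    py = float(np.sum(np.abs(y) ** 2))
    if px == 0.0 or py == 0.0:
        return MetricResult(0.0, degenerate=True)
    s_xy = np.sum(x * np.conj(y))
    return MetricResult(float(np.abs(np.imag(s_xy)) / np.sqrt(px * py)))


def _pearson(a: np.ndarray, b: np.ndarray) -> MetricResult:
    # variance below (1e-10 x data scale)^2 counts as constant: |exp(i.)| style
    # envelopes carry O(1e-16) float jitter that must not masquerade as signal
    scale_a = float(np.max(np.abs(a))) or 1.0
    scale_b = float(np.max(np.abs(b))) or 1.0
    a = a - a.mean()
    b = b - b.mean()
    va = float(np.sum(a * a))
    vb = float(np.sum(b * b))
    n = a.shape[0]
    if va <= n * (1e-10 * scale_a) ** 2 or vb <= n * (1e-10 * scale_b) ** 2:
        return MetricResult(0.0, degenerate=True)
    r = float(np.sum(a * b) / np.sqrt(va * vb))
    return MetricResult(min(1.0, max(-1.0, r)))


def envelope_correlation(x, y) -> MetricResult:
    """Pearson correlation of the instantaneous envelopes |X|, |Y|."""
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    return _pearson(np.abs(x), np.abs(y))


def power_correlation(x, y) -> MetricResult:
    """Pearson correlation of the instantaneous band powers |X|^2, |Y|^2."""
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    return _pearson(np.abs(x) ** 2, np.abs(y) ** 2)


def plv(x, y) -> MetricResult:
    """Phase-locking value: |mean of phi_x * conj(phi_y)| over valid samples.

    Samples where either envelope vanishes carry no phase and are excluded.
    """
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    ex, ey = np.abs(x), np.abs(y)
    valid = (ex > 0) & (ey > 0)
    n = int(valid.sum())
    if n == 0:
        return MetricResult(0.0, degenerate=True)
    px = x[valid] / ex[valid]
    py = y[valid] / ey[valid]
    return MetricResult(float(np.abs(np.sum(px * np.conj(py))) / n))


def _circular_mean(theta: np.ndarray) -> float:
    return float(np.angle(np.sum(np.exp(1j * theta))))


def ccorr(x, y) -> MetricResult:
    """Circular correlation coefficient of instantaneous phases.

    sum sin(tx - tx_bar) sin(ty - ty_bar) /
    sqrt(sum sin^2(tx - tx_bar) * sum sin^2(ty - ty_bar)),
    with the bars denoting circular means.  More robust than PLV to
    coincidental synchrony because it tracks covariation of phase
    deviations, not mere phase alignment.
    """
    x, y = _as_complex(x), _as_complex(y)
    _check_lengths(x, y)
    ex, ey = np.abs(x), np.abs(y)
    valid = (ex > 0) & (ey > 0)
    if not valid.any():
        return MetricResult(0.0, degenerate=True)
    tx = np.angle(x[valid])
    ty = np.angle(y[valid])
    sx = np.sin(tx - _circular_mean(tx))
    sy = np.sin(ty - _circular_mean(ty))
    vx = float(np.sum(sx * sx))
    vy = float(np.sum(sy * sy))
    n = sx.shape[0]
    if vx <= n * 1e-20 or vy <= n * 1e-20:  # zero circular variance
        return MetricResult(0.0, degenerate=True)
    r = float(np.sum(sx * sy) / np.sqrt(vx * vy))
    return MetricResult(min(1.0, max(-1.0, r)))


METRICS = {
    "coherence": coherence,
    "imaginary_coherence": imaginary_coherence,
    "envelope_correlation": envelope_correlation,
    "power_correlation": power_correlation,
    "plv": plv,
    "ccorr": ccorr,
}


@dataclass
class ConnectivityFrame:
    """One connectivity value per (subject pair, band) for one window.

    Keys are ``((stream_a, stream_b), band_name)`` with pairs ordered
    lexicographically by stream position; values are the electrode-pair
    averages, already multiplied by the band weight.
    """

    values: dict[tuple[tuple[str, str], str], float]
    metric_name: str
    connectivity_type: str
    window_time: float
    pair_order: tuple[tuple[str, str], ...]
    band_order: tuple[str, ...]
    degenerate: dict[tuple[tuple[str, str], str], bool] = field(default_factory=dict)

    def __getitem__(self, key) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)


def subject_pairs(stream_ids: list[str]) -> list[tuple[str, str]]:
    """Unordered subject pairs in lexicographic stream-position order."""
    return [
        (stream_ids[i], stream_ids[j])
        for i in range(len(stream_ids))
        for j in range(i + 1, len(stream_ids))
    ]


def _electrode_pairs(n_a: int, n_b: int, connectivity_type: str):
    if connectivity_type == "one-to-one":
        n = min(n_a, n_b)
        if n_a != n_b:
            logger.warning(
                "one-to-one with mismatched channel counts (%d vs %d): "
                "pairing first %d channels", n_a, n_b, n,
            )
        return [(i, i) for i in range(n)]
    if connectivity_type == "all-to-all":
        return [(i, j) for i in range(n_a) for j in range(n_b)]
    raise ValueError(
        f"unknown connectivity type {connectivity_type!r}; "
        f"choose from {CONNECTIVITY_TYPES}"
    )


def pair_matrix(
    analytic: dict[str, dict[str, AnalyticWindow]],
    metric: str,
    connectivity_type: str,
    bands: list[BandSpec],
    window_time: float = 0.0,
) -> ConnectivityFrame:
    """Average the metric over electrode pairs: one r per (subject pair, band).

    ``analytic`` maps stream_id -> band name -> AnalyticWindow (channels
    already restricted to the band's selection).  The metric is computed for
    every configured electrode pair, arithmetically averaged, then multiplied
    by the band's weight.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    stream_ids = list(analytic)
    if len(stream_ids) < 2:
        raise ValueError("need at least 2 streams for connectivity")
    pairs = subject_pairs(stream_ids)
    values: dict[tuple[tuple[str, str], str], float] = {}
    degen: dict[tuple[tuple[str, str], str], bool] = {}
    for pair in pairs:
        sid_a, sid_b = pair
        for band in bands:
            aw_a = analytic[sid_a][band.name]
            aw_b = analytic[sid_b][band.name]
            epairs = _electrode_pairs(aw_a.n_channels, aw_b.n_channels, connectivity_type)
            results = [fn(aw_a.values[:, i], aw_b.values[:, j]) for i, j in epairs]
            mean_r = float(np.mean([r.value for r in results]))
            key = (pair, band.name)
            values[key] = mean_r * band.weight
            degen[key] = any(r.degenerate for r in results)
    return ConnectivityFrame(
        values=values,
        metric_name=metric,
        connectivity_type=connectivity_type,
        window_time=window_time,
        pair_order=tuple(pairs),
        band_order=tuple(b.name for b in bands),
        degenerate=degen,
    )
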