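"""Min-max normalization of connectivity values into the [0, 1] feedback range.

Limits come from manual settings, from a pre-recorded baseline session, or a
weighted blend of the two: eff = w * manual + (1 - w) * baseline, applied to
the minimum and maximum limits (not to the normalized outputs).  Baseline
limits are kept per (subject pair, band) — pairs differ systematically in
raw synchrony — with a global fallback when a key is missing.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field, replace

import numpy as np

from .buffers import ConfigurationError
from .metrics import ConnectivityFrame

logger = logging.getLogger(__name__)

#: smallest allowed limit span; degenerate spans are inflated to this
MIN_SPAN = 1e-9

Key = tuple[tuple[str, str], str]


@dataclass(frozen=True)
class NormalizationSpec:
    """Manual limits, optional baseline limits, and the blending weight.

    ``blend_weight`` = 1 uses the manual limits only; 0 uses the baseline
    only (mirroring a manual-vs-from-file slider).
    """

    manual_min: float = 0.0
    manual_max: float = 1.0
    blend_weight: float = 1.0
    baseline: dict[Key, tuple[float, float]] = field(default_factory=dict)
    baseline_global: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.manual_min < self.manual_max:
            raise ConfigurationError(
                f"manual_min ({self.manual_min}) must be < manual_max ({self.manual_max})"
            )
        if not 0.0 <= self.blend_weight <= 1.0:
            raise ConfigurationError(
                f"blend_weight must lie in [0, 1], got {self.blend_weight}"
            )

    def with_baseline(
        self, limits: dict[Key, tuple[float, float]]
    ) -> "NormalizationSpec":
        lo = min(v[0] for v in limits.values())
        hi = max(v[1] for v in limits.values())
        return replace(self, baseline=dict(limits), baseline_global=(lo, hi))


def limits_from_baseline(
    recorded_frames: Iterable[ConnectivityFrame],
    percentiles: tuple[float, float] | None = None,
) -> dict[Key, tuple[float, float]]:
    """Per-(pair, band) (min, max) over a recorded baseline session.

    With ``percentiles=(5, 95)`` the limits are those percentiles instead of
    the extremes, giving robustness to transient artifacts.  A constant
    recording yields a degenerate span, inflated to ``MIN_SPAN`` with a
    warning.
    """
    series: dict[Key, list[float]] = {}
    for frame in recorded_frames:
        for key, value in frame.values.items():
            series.setdefault(key, []).append(value)
    if not series:
        raise ConfigurationError("baseline recording is empty")
    limits: dict[Key, tuple[float, float]] = {}
    for key, vals in series.items():
        if len(vals) < 2:
            raise ConfigurationError(
                f"baseline for {key} has {len(vals)} frame(s); need >= 2"
            )
        arr = np.asarray(vals, dtype=float)
        if percentiles is None:
            lo, hi = float(arr.min()), float(arr.max())
        else:
            lo, hi = (float(p) for p in np.percentile(arr, percentiles))
        lo, hi = _guard_span(lo, hi, context=str(key))
        limits[key] = (lo, hi)
    return limits


def _guard_span(lo: float, hi: float, context: str = "") -> tuple[float, float]:
    if hi <= lo:
        logger.warning(
            "degenerate normalization limits%s: (%g, %g); inflating span",
            f" for {context}" if context else "", lo, hi,
        )
        hi = lo + MIN_SPAN
    return lo, hi


def blend_limits(spec: NormalizationSpec, key: Key | None = None) -> tuple[float, float]:
    """Effective (min, max): w * manual + (1 - w) * baseline, per limit.

    Falls back to the global baseline range when ``key`` has no dedicated
    baseline entry; with no baseline at all (or w = 1) the manual limits
    apply unchanged.
    """
    w = spec.blend_weight
    base = None
    if key is not None and key in spec.baseline:
        base = spec.baseline[key]
    elif spec.baseline_global is not None:
        base = spec.baseline_global
    if base is None:
        if w < 1.0:
            raise ConfigurationError(
                "blend_weight < 1 requires baseline limits, none configured"
            )
        return spec.manual_min, spec.manual_max
    eff_min = w * spec.manual_min + (1.0 - w) * base[0]
    eff_max = w * spec.manual_max + (1.0 - w) * base[1]
    return _guard_span(eff_min, eff_max)


def minmax(frame: ConnectivityFrame, spec: NormalizationSpec) -> ConnectivityFrame:
    """clip((r - min) / (max - min), 0, 1) per value, with per-key limits."""
    out = {}
    for key, r in frame.values.items():
        lo, hi = blend_limits(spec, key)
        out[key] = float(np.clip((r - lo) / (hi - lo), 0.0, 1.0))
    return ConnectivityFrame(
        values=out,
        metric_name=frame.metric_name,
        connectivity_type=frame.connectivity_type,
        window_time=frame.window_time,
        pair_order=frame.pair_order,
        band_order=frame.band_order,
        degenerate=dict(frame.degenerate),
    )
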