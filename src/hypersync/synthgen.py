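"""Synthetic multi-subject EEG with known ground-truth coupling.

Each subject's signal is a slowly amplitude-modulated oscillation at a base
frequency buried in 1/f (pink) background noise.  Coupling between two
subjects has two independent knobs:

* **phase coupling** — subject B's oscillation carries per-sample phase
  offsets drawn from a von Mises(0, kappa) distribution relative to A's
  phase.  For sample-wise independent offsets the expected phase-locking
  value is the von Mises mean resultant length I1(kappa)/I0(kappa), which is
  what makes the generator a calibration instrument: kappa=0 gives
  independent phases (chance-level PLV), kappa -> infinity gives perfect
  lock.  Offsets may optionally be low-pass smoothed (Gaussian copula, so
  the marginal stays exactly von Mises) to keep B narrowband at the cost of
  raising finite-window PLV above the Bessel ratio.
* **envelope coupling** — the two log-normal envelopes are built on a
  Gaussian copula whose correlation is chosen so the envelopes' Pearson
  correlation hits the target rho exactly in expectation (the Gaussian pair
  is constructed with its *sample* correlation equal to the required value).

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import i0, i1, ndtr
from scipy.stats import vonmises

from .buffers import ConfigurationError, SampleWindow

#: default modulation bandwidth of the log-normal envelopes (Hz); slow
#: relative to any analysis band of interest
ENVELOPE_BANDWIDTH_HZ = 0.8

#: log-amplitude standard deviation of the log-normal envelopes
ENVELOPE_LOG_SIGMA = 0.4

#: slow phase wander (radians RMS and its bandwidth) given to each
#: *uncoupled* session subject, so unrelated oscillators at the same base
#: frequency decohere instead of being trivially phase-locked
PHASE_DRIFT_SIGMA = 1.5
PHASE_DRIFT_CUTOFF_HZ = 1.5


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling parameters for one synthetic dyad.

    snr is the ratio of oscillation power to pink-noise power; use
    ``np.inf`` for noiseless signals.  ``jitter_bandwidth_hz=None`` draws the
    phase offsets independently per sample (the regime where expected PLV
    equals I1(kappa)/I0(kappa)); a finite bandwidth low-pass smooths them.
    """

    base_freq: float = 10.0
    kappa: float = 0.0
    env_corr: float = 0.0
    snr: float = 4.0
    duration: float = 60.0
    fs: float = 250.0
    seed: int = 0
    jitter_bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ConfigurationError(f"kappa must be >= 0, got {self.kappa}")
        if not -1.0 <= self.env_corr <= 1.0:
            raise ConfigurationError(f"env_corr must lie in [-1, 1], got {self.env_corr}")
        if not self.snr > 0:
            raise ConfigurationError(f"snr must be > 0, got {self.snr}")
        if not self.fs > 2 * self.base_freq:
            raise ConfigurationError(
                f"fs ({self.fs}) must exceed 2 x base_freq ({self.base_freq})"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")


def expected_plv(kappa: float) -> float:
    """Mean resultant length of von Mises(0, kappa): I1(kappa)/I0(kappa).

    This is the population PLV of two signals whose relative phase is von
    Mises distributed with concentration kappa; 0 at kappa=0 (uniform
    phases), monotonically approaching 1 as kappa grows.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    if kappa > 700:  # avoid Bessel overflow; asymptotic 1 - 1/(2k)
        return 1.0 - 1.0 / (2.0 * kappa)
    return float(i1(kappa) / i0(kappa))


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def _slow_gaussian(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited standard-normal series via spectral shaping.

    White Gaussian noise is low-passed in the frequency domain (half-cosine
    roll-off from cutoff to 1.5x cutoff); being a linear map of Gaussian
    noise, the marginal stays exactly Gaussian, and the circular construction
    has no filter edge transients.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    taper = np.zeros_like(freqs)
    taper[freqs <= cutoff_hz] = 1.0
    roll = (freqs > cutoff_hz) & (freqs < 1.5 * cutoff_hz)
    taper[roll] = 0.5 * (1.0 + np.cos(np.pi * (freqs[roll] - cutoff_hz) / (0.5 * cutoff_hz)))
    g = np.fft.irfft(spec * taper, n)
    g = g - g.mean()
    return g / g.std()


def _correlated_pair(n: int, fs: float, cutoff_hz: float, rho: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two slow standard Gaussians whose sample correlation is exactly rho."""
    g1 = _slow_gaussian(n, fs, cutoff_hz, rng)
    raw = _slow_gaussian(n, fs, cutoff_hz, rng)
    # orthogonalize so the mix has exactly the requested sample correlation
    resid = raw - (g1 @ raw) / (g1 @ g1) * g1
    resid = resid - resid.mean()
    resid = resid / resid.std()
    g2 = rho * g1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * resid
    g2 = g2 / g2.std()
    return g1, g2


def _gaussian_rho_for_lognormal(rho_target: float, sigma: float) -> float:
    """Gaussian-copula correlation giving Pearson rho_target between
    exp(sigma*g) marginals: invert rho_LN = (e^{rho_G s^2}-1)/(e^{s^2}-1)."""
    s2 = sigma * sigma
    arg = 1.0 + rho_target * (np.expm1(s2))
    if arg <= 0:
        raise ConfigurationError(
            f"envelope correlation {rho_target} unattainable for log-normal "
            f"envelopes with log-sigma {sigma}"
        )
    rho_g = float(np.log(arg) / s2)
    if not -1.0 <= rho_g <= 1.0:
        raise ConfigurationError(
            f"envelope correlation {rho_target} unattainable (needs Gaussian "
            f"correlation {rho_g:.3f})"
        )
    return rho_g


def _phase_offsets(spec: CouplingSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Relative phase offsets, marginally von Mises(0, kappa)."""
    if spec.jitter_bandwidth_hz is None:
        if spec.kappa == 0:
            return rng.uniform(-np.pi, np.pi, n)
        return rng.vonmises(0.0, spec.kappa, n)
    # Gaussian copula: smooth driver, exact von Mises marginal
    z = _slow_gaussian(n, spec.fs, spec.jitter_bandwidth_hz, rng)
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    if spec.kappa == 0:
        return 2.0 * np.pi * (u - 0.5)
    return vonmises.ppf(u, spec.kappa)


@dataclass(frozen=True)
class DyadGroundTruth:
    """The generator's exact complex oscillations plus the target quantities."""

    analytic_a: np.ndarray
    analytic_b: np.ndarray
    phase_offsets: np.ndarray
    envelope_a: np.ndarray
    envelope_b: np.ndarray
    expected_plv: float
    env_corr: float


def generate_dyad(
    spec: CouplingSpec, with_ground_truth: bool = False
) -> tuple[SampleWindow, SampleWindow] | tuple[SampleWindow, SampleWindow, DyadGroundTruth]:
    """Two coupled single-channel subject signals (see module docstring).

    With ``with_ground_truth=True`` also returns the noise-free complex
    oscillations and the population coupling targets, for calibration tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    rho_g = _gaussian_rho_for_lognormal(spec.env_corr, ENVELOPE_LOG_SIGMA)
    g_a, g_b = _correlated_pair(n, spec.fs, ENVELOPE_BANDWIDTH_HZ, rho_g, rng)
    env_a = np.exp(ENVELOPE_LOG_SIGMA * g_a)
    env_b = np.exp(ENVELOPE_LOG_SIGMA * g_b)

    phi0 = rng.uniform(-np.pi, np.pi)
    delta = _phase_offsets(spec, n, rng)
    # no shared phase wander inside a dyad: a common drift would modulate both
    # band-filtered envelopes identically and confound envelope-correlation
    # ground truth; uncoupled session subjects get independent drift instead
    carrier = 2.0 * np.pi * spec.base_freq * t + phi0
    osc_a = env_a * np.exp(1j * carrier)
    osc_b = env_b * np.exp(1j * (carrier + delta))

    sig_a = osc_a.real.copy()
    sig_b = osc_b.real.copy()
    if np.isfinite(spec.snr):
        power_a = float(np.mean(sig_a**2))
        power_b = float(np.mean(sig_b**2))
        sig_a += np.sqrt(power_a / spec.snr) * pink_noise(n, rng)
        sig_b += np.sqrt(power_b / spec.snr) * pink_noise(n, rng)

    win_a = SampleWindow(sig_a[:, None], spec.fs, 0.0)
    win_b = SampleWindow(sig_b[:, None], spec.fs, 0.0)
    if not with_ground_truth:
        return win_a, win_b
    gt = DyadGroundTruth(
        analytic_a=osc_a,
        analytic_b=osc_b,
        phase_offsets=delta,
        envelope_a=env_a,
        envelope_b=env_b,
        expected_plv=expected_plv(spec.kappa),
        env_corr=spec.env_corr,
    )
    return win_a, win_b, gt


def generate_session(
    n_subjects: int,
    pair_specs: dict[tuple[int, int], CouplingSpec],
    duration: float,
    fs: float,
    seed: int,
    n_channels: int = 1,
) -> tuple[list[SampleWindow], list[dict]]:
    """Streams for ``n_subjects`` with heterogeneous pairwise coupling.

    ``pair_specs`` maps (i, j) subject-index pairs (i < j) to coupling specs.
    Coupled pairs must be disjoint (a subject belongs to at most one coupled
    pair); subjects in no pair get independent oscillation + noise.
    Multi-channel subjects share their oscillation across channels with
    independent pink noise per channel.

    Returns the per-subject SampleWindows and a ground-truth table (one dict
    per pair with kappa, env_corr and expected PLV; uncoupled pairs have
    kappa 0 / env_corr 0).
    """
    members: list[int] = []
    for (i, j), ps in pair_specs.items():
        if not (0 <= i < j < n_subjects):
            raise ConfigurationError(f"invalid subject pair ({i}, {j})")
        if ps.fs != fs or ps.duration != duration:
            raise ConfigurationError(
                f"pair ({i}, {j}): spec fs/duration must match the session's"
            )
        members.extend((i, j))
    if len(members) != len(set(members)):
        raise ConfigurationError("coupled pairs must be disjoint")

    master = np.random.default_rng(seed)
    sub_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(n_subjects)]
    n = int(round(duration * fs))
    base_freq = next(iter(pair_specs.values())).base_freq if pair_specs else 10.0
    default_snr = next(iter(pair_specs.values())).snr if pair_specs else 4.0

    oscillations: dict[int, np.ndarray] = {}
    snr_of: dict[int, float] = {}
    for (i, j), ps in pair_specs.items():
        dyad_spec = replace(ps, seed=sub_seeds[i])
        _, _, gt = generate_dyad(dyad_spec, with_ground_truth=True)
        oscillations[i], oscillations[j] = gt.analytic_a, gt.analytic_b
        snr_of[i] = snr_of[j] = ps.snr
    for s in range(n_subjects):
        if s in oscillations:
            continue
        rng_s = np.random.default_rng(sub_seeds[s])
        t = np.arange(n) / fs
        g = _slow_gaussian(n, fs, ENVELOPE_BANDWIDTH_HZ, rng_s)
        env = np.exp(ENVELOPE_LOG_SIGMA * g)
        phi0 = rng_s.uniform(-np.pi, np.pi)
        drift = PHASE_DRIFT_SIGMA * _slow_gaussian(n, fs, PHASE_DRIFT_CUTOFF_HZ, rng_s)
        oscillations[s] = env * np.exp(
            1j * (2 * np.pi * base_freq * t + phi0 + drift)
        )
        snr_of[s] = default_snr

    signals: list[np.ndarray] = []
    for s in range(n_subjects):
        osc = oscillations[s].real
        rng_noise = np.random.default_rng(sub_seeds[s] + 1)
        chans = np.empty((n, n_channels))
        for c in range(n_channels):
            sig = osc.copy()
            if np.isfinite(snr_of[s]):
                sig = sig + np.sqrt(float(np.mean(osc**2)) / snr_of[s]) * pink_noise(n, rng_noise)
            chans[:, c] = sig
        signals.append(chans)

    windows = [SampleWindow(sig, fs, 0.0) for sig in signals]
    truth = []
    for i in range(n_subjects):
        for j in range(i + 1, n_subjects):
            ps = pair_specs.get((i, j))
            truth.append(
                {
                    "pair": (i, j),
                    "kappa": ps.kappa if ps else 0.0,
                    "env_corr": ps.env_corr if ps else 0.0,
                    "expected_plv": expected_plv(ps.kappa) if ps else 0.0,
                }
            )
    return windows, truth
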