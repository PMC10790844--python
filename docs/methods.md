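# Methods

## Processing model

The engine treats each subject's EEG as an independent multichannel stream
at a common sampling rate. Analysis is windowed and stateless: at every hop
the most recent `window_size + pad` seconds are taken from a rolling buffer,
filtered, transformed, and reduced to one connectivity value per subject
pair per band. Nothing is carried between windows, which makes the online
(chunk-fed ring buffer) and offline (direct file slicing) paths exactly
equivalent — a property the test suite asserts bit-for-bit. Frame boundaries
live on a cumulative sample grid, `n_warm + round(k · hop · fs)`, so
non-integer hop-in-samples (e.g. 0.25 s at 250 Hz) cannot drift.

Windows from different subjects are aligned by most-recent-sample. No
cross-stream clock correction or jitter compensation is attempted; with
drifting acquisition clocks the pairing of samples across subjects is only
as good as the transport's own synchronization. This is a documented
limitation, not a configuration option.

### Filtering and the analytic signal

Each band is isolated with a causal Butterworth band-pass of order 4 in
second-order sections (`scipy.signal.butter`/`sosfilt`). The choice is a
default, not a claim: any stable IIR band-pass with a flat passband would
do; Butterworth at order 4 settles within roughly one second for EEG-typical
bands, which motivates the default `pad = 1 s`. Because filtering is
per-window with zero initial conditions, the settling transient occupies the
pad region, which is discarded after the Hilbert transform
(`scipy.signal.hilbert`) — the transform's circular boundary assumption
corrupts edges, so the pad does double duty. Zero-phase (acausal) filtering
is deliberately excluded: it would be non-causal and unavailable in a live
loop, and the offline path must match the live path.

Band power is reported as `mean(|X|²)/2` per channel — the mean square of
the band-limited real signal (the analytic envelope carries twice the real
signal's power). A unit-amplitude in-band sinusoid therefore reads 0.5.

### Metrics

All six metrics consume the complex analytic signal. The coherence family
uses the within-window summed cross-spectrum `Σₜ X·Y*`; summing inside the
window (rather than averaging spectra across windows) is what makes a single
window produce a value, and gives the Cauchy–Schwarz bound that pins
coherence(X, cX) = 1. CCorr uses deviations from the circular (angular)
mean, the standard definition of the circular correlation coefficient.

Degenerate inputs return 0 with a per-value quality flag rather than NaN,
because a feedback loop must keep emitting frames. "Degenerate" is decided
with relative thresholds (variance below (1e-10 × data scale)²), since an
analytically constant envelope such as |exp(iθ)| still carries ~1e-16 float
jitter that must not be mistaken for signal. One numerical caveat is
inherent to CCorr: when the phase distribution is exactly uniform (e.g. a
pure carrier whose phases sweep the circle), the circular-mean resultant
cancels to machine zero and the mean — hence the coefficient — is
ill-conditioned; tests of its shift invariance use concentrated phase sets.

Electrode-pair averaging is the unweighted arithmetic mean. Band weights
multiply the averaged value per band; bands are never summed into one
scalar. Subject pairs are ordered lexicographically by stream position and
bands in configuration order, giving the packed vector a deterministic
pair-major/band-minor layout of length C(n_subjects, 2) × n_bands that is
embedded in sink metadata.

### Normalization

Min-max normalization `clip((r − min)/(max − min), 0, 1)` with limits from
manual settings, a recorded baseline, or the blend
`w·manual + (1−w)·baseline` applied to the limits (not to the outputs).
Baseline limits are per (pair, band) with a global fallback, because pairs
differ systematically in raw synchrony; an optional percentile mode (e.g.
5th/95th) robustifies against transient artifacts. Degenerate spans are
inflated by ε with a warning. Clipping rather than rescaling keeps the
feedback channel bounded under out-of-range values.

## Synthetic ground truth

The generator emulates the features of hyperscanning EEG that the metrics
measure, and nothing more:

* each subject = log-normal slowly modulated oscillation (base 10 Hz) in
  1/f noise; `snr` is oscillation power over noise power (default 4, a
  strong posterior alpha regime; `inf` = noiseless);
* **phase coupling**: subject B carries per-sample phase offsets drawn von
  Mises(0, κ) against A. With sample-wise independent offsets (the default)
  the population PLV is exactly the resultant length I₁(κ)/I₀(κ), which is
  what makes the generator a calibration instrument. An optional
  Gaussian-copula smoothing (`jitter_bandwidth_hz`) keeps B narrowband while
  preserving the von Mises marginal — but correlated offsets within a window
  raise finite-window PLV above the Bessel ratio (for a 1 Hz bandwidth and
  3 s windows, by ~0.1 at κ = 1), so calibration against I₁/I₀ is only valid
  in the independent-offset regime. This trade-off is intrinsic, not a tuning
  choice: a smooth phase process has few effective samples per window.
* **envelope coupling**: envelopes are `exp(0.4·g)` of band-limited (0.8 Hz)
  Gaussian processes generated in the frequency domain (spectral shaping
  keeps the marginal exactly Gaussian; time-domain IIR filtering at such low
  cutoffs produces edge transients that destroy it). The Gaussian pair is
  constructed with its sample correlation exactly at the copula value that
  maps to the requested Pearson correlation of the log-normal envelopes.
* **uncoupled subjects** in multi-subject sessions get independent slow
  phase wander (1.5 rad RMS, ≤ 1.5 Hz), so same-frequency oscillators
  decohere rather than being trivially phase-locked. The wander is *not*
  shared within a coupled dyad: a common drift would modulate both subjects'
  band-filtered envelopes identically and contaminate the envelope
  correlation ground truth.

What the generator does **not** emulate: volume conduction and source
mixing, non-stationary band structure, ocular/muscle artifacts, electrode
drift, inter-subject differences in spectra. Passing recovery tests on this
generator therefore validates the estimator chain (filtering, analytic
transform, metric, averaging, normalization), not robustness to real-world
artifacts — online artifact handling is out of scope.

## Measurement protocols used in validation

* PLV calibration (κ ∈ {1, 2, 4}) and null calibration (κ = 0) are measured
  on the generator's exact analytic signals with the package's metric, over
  ≥ 200 sliding 3 s windows of 120 s noiseless dyads. The filter+Hilbert
  route is validated separately (filter-response oracle, analytic-signal
  identities, strong-lock and monotonicity checks) because a narrow
  band-pass necessarily smooths sample-wise jitter and shifts windowed PLV
  above the Bessel ratio — the identification of I₁/I₀ is only exact on the
  unfiltered analytic pair.
* Envelope-correlation recovery averages windowed estimates over four
  replicate 60 s dyads: a 3 s window spans only ~5 effective samples of a
  0.8 Hz envelope process, so single-realization windowed means carry
  sd ≈ 0.04 and replication is needed for a stable estimate.
* The Monte-Carlo null oracle simulates 1000 windows of 750 independent
  uniform relative phases (E[PLV] = √π/2·N^(−1/2) ≈ 0.032).
* Problem sizes throughout (120 s calibration records, 1000 oracle windows,
  6–20 s end-to-end sessions) were chosen as the smallest sizes at which
  Monte-Carlo error is clearly below the tolerances being checked.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| window_size | 3 s | standard online synchrony window |
| buffer | 30 s | rolling history for warm-up and re-reads |
| pad | 1 s | Butterworth settling + Hilbert edge region |
| hop | 0.25 s | fixed cadence; reproducible, unlike CPU-bound rates |
| bands | δ 1–4, θ 4–8, α 8–12, β 12–20 Hz | the validation band table |
| filter | Butterworth order 4, causal SOS | flat passband, real-time capable |
| metric | envelope_correlation | the validated neurofeedback signal |
| snr (generator) | 4 | strong-alpha regime |

Unequal sampling rates across streams are rejected unless
`allow_resample` is set, in which case streams are polyphase-resampled to
the minimum rate before analysis. NaN samples are repaired by
previous-value hold with a logged warning. One-to-one pairing with
mismatched channel counts pairs up to the smaller count with a warning;
an empty channel selection for a band is a configuration error.

## Known limitations

* No cross-stream clock alignment (see above).
* CCorr is ill-conditioned for exactly uniform phase distributions.
* The LSL adapter and sink require `pylsl`, which is optional; without it
  the live loop runs over file-backed streams only.
* EDF output is 16-bit quantized; round-trips are exact only to the
  quantization grid. XDF files are not read.
* One engine instance computes one metric; run several instances (or
  several offline passes) for multi-metric output.
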