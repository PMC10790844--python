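import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hypersync import (
    METRICS,
    BandSpec,
    ccorr,
    coherence,
    envelope_correlation,
    imaginary_coherence,
    pair_matrix,
    plv,
    power_correlation,
)
from hypersync.metrics import METRIC_RANGES, subject_pairs
from hypersync.preprocess import AnalyticWindow

from _oracles import DIRECT


def random_analytic(rng, n=100):
    return rng.standard_normal(n) + 1j * rng.standard_normal(n)


def modulated(rng, n=750, fs=250.0):
    """Amplitude-modulated narrowband analytic signal (non-constant envelope)."""
    t = np.arange(n) / fs
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
    return env * np.exp(1j * (2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", sorted(METRICS))
    def test_matches_direct_summation(self, name, rng):
        """Each metric equals an independently coded brute-force sum on 1000
        random 100-sample complex windows to 1e-10 relative tolerance."""
        fn, direct = METRICS[name], DIRECT[name]
        for _ in range(1000):
            x = random_analytic(rng)
            y = random_analytic(rng)
            got = fn(x, y).value
            want = direct(list(map(complex, x)), list(map(complex, y)))
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


class TestAnalyticLimits:
    def test_coherence_of_signal_with_itself_is_one(self, rng):
        x = random_analytic(rng)
        assert coherence(x, x).value == pytest.approx(1.0)

    def test_coherence_amplitude_scale_invariant(self, rng):
        x = random_analytic(rng)
        assert coherence(x, 3.0 * x).value == pytest.approx(1.0)

    def test_imaginary_coherence_of_self_is_zero(self, rng):
        x = random_analytic(rng)
        assert imaginary_coherence(x, x).value == pytest.approx(0.0, abs=1e-12)

    def test_imaginary_coherence_quarter_turn_equals_coherence(self, rng):
        x = random_analytic(rng)
        y = 1j * x  # fully imaginary cross-spectrum
        assert imaginary_coherence(x, y).value == pytest.approx(
            coherence(x, y).value
        )

    def test_plv_constant_phase_offset_is_one(self, rng):
        x = modulated(rng)
        assert plv(x, x * np.exp(1j * 1.1)).value == pytest.approx(1.0)

    def test_plv_amplitude_rescaling_invariant(self, rng):
        x, y = modulated(rng), modulated(rng)
        a = rng.uniform(0.5, 2.0, x.shape[0])
        b = rng.uniform(0.5, 2.0, y.shape[0])
        assert plv(a * x, b * y).value == pytest.approx(plv(x, y).value, rel=1e-12)

    def test_envelope_correlation_of_self_is_one(self, rng):
        x = modulated(rng)
        assert envelope_correlation(x, x).value == pytest.approx(1.0)

    def test_envelope_anticorrelation_is_minus_one(self, rng):
        x = modulated(rng)
        env = np.abs(x)
        y = (2.5 - env) * np.exp(1j * np.angle(x))  # env_y = c - env_x
        assert envelope_correlation(x, y).value == pytest.approx(-1.0)

    def test_power_correlation_of_self_is_one(self, rng):
        x = modulated(rng)
        assert power_correlation(x, x).value == pytest.approx(1.0)

    def test_ccorr_constant_phase_shift_is_one(self, rng):
        # use concentrated phases so the circular mean is well-conditioned
        x = np.exp(1j * rng.vonmises(0.0, 2.0, 750)) * rng.uniform(0.5, 2.0, 750)
        r = ccorr(x, x * np.exp(1j * 0.9))
        assert r.value == pytest.approx(1.0)


class TestDegenerateInputs:
    def test_zero_power_channel_flagged(self, rng):
        x = random_analytic(rng)
        zero = np.zeros_like(x)
        for fn in (coherence, imaginary_coherence, plv, ccorr):
            r = fn(x, zero)
            assert r.value == 0.0 and r.degenerate

    def test_constant_envelope_power_correlation_degenerate(self):
        t = np.arange(750) / 250.0
        x = np.exp(2j * np.pi * 10 * t)
        y = np.exp(2j * np.pi * 10 * t + 0.4j)
        r = power_correlation(x, y)
        assert r.value == 0.0 and r.degenerate

    def test_zero_circular_variance_ccorr_degenerate(self):
        x = np.full(100, 1.0 + 0.0j) * np.linspace(1, 2, 100)  # constant phase
        y = np.exp(1j * np.linspace(0, 3, 100))
        r = ccorr(x, y)
        assert r.value == 0.0 and r.degenerate

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            plv(random_analytic(rng, 10), random_analytic(rng, 11))


class TestNullDistributions:
    def test_independent_noise_coherence_small(self, rng):
        """Coherence of independent white noise, N=750: below 0.3 with high
        probability (null 95th percentile is ~2.5/sqrt(N) ~ 0.09)."""
        vals = [
            coherence(random_analytic(rng, 750), random_analytic(rng, 750)).value
            for _ in range(50)
        ]
        assert np.max(vals) < 0.3

    def test_plv_uniform_phase_chance_level(self, rng):
        """Mean PLV of independent uniform phases matches the Rayleigh
        expectation sqrt(pi)/(2 sqrt(N))."""
        n, reps = 1000, 300
        vals = []
        for _ in range(reps):
            x = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
            y = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
            vals.append(plv(x, y).value)
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))  # ~0.028
        se = np.std(vals) / np.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 4 * se + 1e-3

    def test_ccorr_uniform_phase_centred_on_zero(self, rng):
        n, reps = 1000, 300
        vals = []
        for _ in range(reps):
            x = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
            y = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
            vals.append(ccorr(x, y).value)
        se = np.std(vals) / np.sqrt(reps)
        assert abs(np.mean(vals)) < 4 * se


class TestCrossLibrary:
    def test_ccorr_against_pingouin(self, rng):
        """Circular correlation agrees with pingouin's independent
        implementation on random phase series."""
        pingouin = pytest.importorskip("pingouin")
        for _ in range(10):
            base = rng.uniform(-np.pi, np.pi, 200)
            tx = np.angle(np.exp(1j * (base + rng.normal(0, 0.5, 200))))
            ty = np.angle(np.exp(1j * (0.8 * base + rng.normal(0, 0.7, 200))))
            got = ccorr(np.exp(1j * tx), np.exp(1j * ty)).value
            want = pingouin.circ_corrcc(tx, ty)[0]
            assert got == pytest.approx(want, abs=1e-8)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=hnp.arrays(
        np.complex128,
        st.integers(8, 60).map(lambda n: (2, n)),
        elements=st.complex_numbers(
            min_magnitude=1e-3, max_magnitude=1e3, allow_nan=False, allow_infinity=False
        ),
    ),
    name=st.sampled_from(sorted(METRICS)),
)
def test_symmetry_and_range_properties(data, name):
    """Every metric is symmetric in its arguments and respects its range."""
    x, y = data[0], data[1]
    fn = METRICS[name]
    r_xy, r_yx = fn(x, y), fn(y, x)
    assert r_xy.value == pytest.approx(r_yx.value, rel=1e-9, abs=1e-9)
    lo, hi = METRIC_RANGES[name]
    assert lo - 1e-9 <= r_xy.value <= hi + 1e-9


class TestPairMatrix:
    def make_analytic(self, rng, stream_ids, bands, n_ch=2, n=200):
        out = {}
        for sid in stream_ids:
            per_band = {}
            for band in bands:
                values = rng.standard_normal((n, n_ch)) + 1j * rng.standard_normal((n, n_ch))
                per_band[band.name] = AnalyticWindow(values, band, 250.0)
            out[sid] = per_band
        return out

    def four_bands(self, weight=1.0):
        return [
            BandSpec("delta", 1, 4, weight),
            BandSpec("theta", 4, 8, weight),
            BandSpec("alpha", 8, 12, weight),
            BandSpec("beta", 12, 20, weight),
        ]

    def test_four_streams_four_bands_gives_24_values(self, rng):
        bands = self.four_bands()
        analytic = self.make_analytic(rng, ["s1", "s2", "s3", "s4"], bands)
        frame = pair_matrix(analytic, "plv", "all-to-all", bands)
        assert len(frame) == 24  # 6 pairs x 4 bands

    def test_single_channel_one_to_one_equals_all_to_all(self, rng):
        bands = self.four_bands()[:2]
        analytic = self.make_analytic(rng, ["a", "b"], bands, n_ch=1)
        f1 = pair_matrix(analytic, "coherence", "one-to-one", bands)
        f2 = pair_matrix(analytic, "coherence", "all-to-all", bands)
        assert f1.values == f2.values

    def test_zero_weight_band_zeroes_values(self, rng):
        bands = [BandSpec("alpha", 8, 12, weight=0.0)]
        analytic = self.make_analytic(rng, ["a", "b"], bands)
        frame = pair_matrix(analytic, "plv", "all-to-all", bands)
        assert all(v == 0.0 for v in frame.values.values())

    def test_band_weight_multiplies_values(self, rng):
        b1 = [BandSpec("alpha", 8, 12, weight=1.0)]
        b2 = [BandSpec("alpha", 8, 12, weight=0.5)]
        analytic = self.make_analytic(rng, ["a", "b"], b1)
        f1 = pair_matrix(analytic, "plv", "all-to-all", b1)
        analytic2 = {
            sid: {"alpha": per["alpha"]} for sid, per in analytic.items()
        }
        f2 = pair_matrix(analytic2, "plv", "all-to-all", b2)
        for key in f1.values:
            assert f2.values[key] == pytest.approx(0.5 * f1.values[key])

    def test_one_to_one_mismatched_counts_pairs_up_to_smaller(self, rng, caplog):
        import logging

        band = BandSpec("alpha", 8, 12)
        analytic = {
            "a": {"alpha": AnalyticWindow(random_analytic(rng, 300).reshape(100, 3), band, 250.0)},
            "b": {"alpha": AnalyticWindow(random_analytic(rng, 200).reshape(100, 2), band, 250.0)},
        }
        with caplog.at_level(logging.WARNING):
            frame = pair_matrix(analytic, "plv", "one-to-one", [band])
        assert "mismatched" in caplog.text
        assert len(frame) == 1

    def test_lexicographic_pair_order(self):
        assert subject_pairs(["s1", "s2", "s3"]) == [
            ("s1", "s2"), ("s1", "s3"), ("s2", "s3"),
        ]

    def test_unknown_metric_rejected(self, rng):
        bands = self.four_bands()[:1]
        analytic = self.make_analytic(rng, ["a", "b"], bands)
        with pytest.raises(ValueError, match="unknown metric"):
            pair_matrix(analytic, "granger", "all-to-all", bands)


class TestCouplingMonotonicity:
    def test_mean_plv_nondecreasing_in_kappa(self, mean_plv_by_kappa):
        """Stronger phase coupling never lowers measured mean PLV
        (kappa in {0, 0.5, 1, 2, 4}, >= 200 windows each)."""
        kappas = sorted(mean_plv_by_kappa)
        means = [mean_plv_by_kappa[k] for k in kappas]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_mean_ccorr_nondecreasing_in_kappa(self, noiseless_dyads):
        from conftest import sliding_metric

        means = [
            float(np.abs(sliding_metric(noiseless_dyads[k], ccorr)).mean())
            for k in (0.0, 1.0, 4.0)
        ]
        assert means[0] < means[1] < means[2]

    def test_plv_calibration_bessel_ratio(self, mean_plv_by_kappa):
        """Mean windowed PLV matches I1(kappa)/I0(kappa) within 0.03."""
        from hypersync import expected_plv

        for kappa in (1.0, 2.0, 4.0):
            assert abs(mean_plv_by_kappa[kappa] - expected_plv(kappa)) < 0.03
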