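"""HRV indices: hand-oracle values, spectral oracle equivalence,
shift/scale invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lombscargle as scipy_lombscargle

from cardiohrv import (
    BandDefinition,
    IBISeries,
    SpectralEstimate,
    ValidationError,
    band_powers,
    compute_all,
    lomb_periodogram,
    poincare,
    time_domain,
)
from cardiohrv.metrics import INDEX_NAMES
from cardiohrv.synthetic import SyntheticConfig, generate_rr_series


def _series(intervals_ms, start_s=0.0):
    iv = np.asarray(intervals_ms, dtype=float)
    return IBISeries(intervals=iv, beat_times=start_s + np.cumsum(iv) / 1000.0)


def _brute_force_oracle(nn):
    """Loop-based recomputation of all time-domain/Poincaré indices."""
    n = len(nn)
    avnn = sum(nn) / n
    sdnn = math.sqrt(sum((x - avnn) ** 2 for x in nn) / (n - 1))
    diffs = [nn[i + 1] - nn[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d ** 2 for d in diffs) / len(diffs))
    pnn50 = sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    d_proj = [d / math.sqrt(2) for d in diffs]
    s_proj = [(nn[i] + nn[i + 1]) / math.sqrt(2) for i in range(n - 1)]

    def sd(v):
        m = sum(v) / len(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))

    return avnn, sdnn, rmssd, pnn50, sd(d_proj), sd(s_proj)


class TestTimeDomainAndPoincare:
    def test_toy_series_against_brute_force(self, toy_series):
        avnn, sdnn, rmssd, pnn50, sd1, sd2 = _brute_force_oracle(
            list(toy_series.intervals))
        td = time_domain(toy_series)
        pc = poincare(toy_series)
        assert td.avnn == pytest.approx(avnn) == 835.0
        assert td.sdnn == pytest.approx(sdnn)
        assert td.rmssd == pytest.approx(rmssd) == pytest.approx(77.89, abs=0.01)
        assert td.pnn50 == pytest.approx(pnn50) == pytest.approx(2.0 / 3.0)
        assert pc.sd1 == pytest.approx(sd1) == pytest.approx(60.96, abs=0.01)
        assert pc.sd2 == pytest.approx(sd2) == pytest.approx(18.71, abs=0.01)

    def test_constant_series_degenerate(self):
        s = _series([800.0] * 10)
        td = time_domain(s)
        assert (td.avnn, td.sdnn, td.rmssd, td.pnn50) == (800.0, 0.0, 0.0, 0.0)
        pc = poincare(s)
        assert pc.sd1 == 0.0
        assert math.isnan(pc.sd1_sd2)

    def test_pnn50_threshold_is_strict(self):
        s = _series([800.0, 850.0, 800.0])  # |diffs| exactly 50 ms
        assert time_domain(s).pnn50 == 0.0

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValidationError):
            time_domain(_series([800.0, 810.0]))
        with pytest.raises(ValidationError):
            poincare(_series([800.0, 810.0]))

    def test_sd1_approximates_rmssd_over_sqrt2(self):
        cfg = SyntheticConfig(n_beats=200, mean_rr=900.0, rr_noise_sd=40.0,
                              lf_amp=30.0, hf_amp=30.0, seed=5)
        rr = generate_rr_series(cfg)
        sd1 = poincare(rr).sd1
        rmssd = time_domain(rr).rmssd
        assert sd1 == pytest.approx(rmssd / math.sqrt(2.0), rel=0.05)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        nn=st.lists(st.floats(500.0, 1400.0), min_size=5, max_size=40),
        shift=st.floats(-100.0, 300.0),
    )
    def test_shift_invariance(self, nn, shift):
        a = _series(nn)
        b = _series([x + shift for x in nn])
        ta, tb = time_domain(a), time_domain(b)
        assert tb.avnn == pytest.approx(ta.avnn + shift)
        assert tb.sdnn == pytest.approx(ta.sdnn, abs=1e-9)
        assert tb.rmssd == pytest.approx(ta.rmssd, abs=1e-9)
        assert tb.pnn50 == ta.pnn50
        pa, pb = poincare(a), poincare(b)
        assert pb.sd1 == pytest.approx(pa.sd1, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        nn=st.lists(st.floats(500.0, 1400.0), min_size=5, max_size=40),
        c=st.floats(0.5, 2.0),
    )
    def test_scale_equivariance_of_ms_indices(self, nn, c):
        a = _series(nn)
        b = IBISeries(intervals=a.intervals * c, beat_times=a.beat_times * c)
        ta, tb = time_domain(a), time_domain(b)
        assert tb.avnn == pytest.approx(c * ta.avnn)
        assert tb.sdnn == pytest.approx(c * ta.sdnn)
        assert tb.rmssd == pytest.approx(c * ta.rmssd)
        pa, pb = poincare(a), poincare(b)
        assert pb.sd1 == pytest.approx(c * pa.sd1)
        assert pb.sd2 == pytest.approx(c * pa.sd2)
        if pa.sd2 > 0:
            assert pb.sd1_sd2 == pytest.approx(pa.sd1_sd2)

    def test_pnn50_breaks_scale_equivariance(self):
        """The fixed 50 ms threshold makes pNN50 the one non-equivariant
        index: scaling a series across the threshold changes it."""
        nn = [800.0, 840.0, 800.0, 840.0, 800.0]  # |diffs| = 40 ms
        assert time_domain(_series(nn)).pnn50 == 0.0
        scaled = [2.0 * x for x in nn]            # |diffs| = 80 ms
        assert time_domain(_series(scaled)).pnn50 == 1.0


class TestLombPeriodogram:
    def test_single_tone_peak_location(self):
        n = 1000
        t = np.arange(1, n + 1) * 1.0
        iv = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.1 * t)
        spec = lomb_periodogram(IBISeries(intervals=iv, beat_times=t))
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(0.1, abs=spec.df)

    def test_uniform_sampling_equals_classical_periodogram(self):
        """On a uniform grid whose evaluation frequencies are Fourier
        frequencies, the Lomb estimate reduces to the classical
        periodogram to near machine precision."""
        n = 2560  # 0.4k/1024 = k/2560 are Fourier frequencies at dt = 1 s
        t = np.arange(1, n + 1) * 1.0
        rng = np.random.default_rng(0)
        iv = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.1 * t) \
            + 10.0 * rng.standard_normal(n)
        spec = lomb_periodogram(IBISeries(intervals=iv, beat_times=t))
        x = iv - iv.mean()
        dft = np.exp(-1j * np.outer(2 * np.pi * spec.freqs, t)) @ x
        classical = np.abs(dft) ** 2 / n
        classical *= np.var(x, ddof=1) / (classical.sum() * spec.df)
        assert np.max(np.abs(spec.power - classical)) / np.max(classical) < 1e-6

    def test_agrees_with_scipy_lombscargle_on_uneven_times(self):
        rng = np.random.default_rng(7)
        t = np.cumsum(rng.uniform(0.7, 1.3, size=400))
        iv = 900.0 + 60.0 * np.sin(2 * np.pi * 0.1 * t) \
            + 20.0 * rng.standard_normal(t.size)
        spec = lomb_periodogram(IBISeries(intervals=iv, beat_times=t))
        x = iv - iv.mean()
        ref = scipy_lombscargle(t, x, 2 * np.pi * spec.freqs)
        ref *= np.var(x, ddof=1) / (ref.sum() * spec.df)
        np.testing.assert_allclose(spec.power, ref, rtol=1e-8, atol=1e-10)

    def test_mean_subtraction_invariance(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.uniform(0.8, 1.2, size=400))
        iv = 900.0 + 30.0 * rng.standard_normal(t.size)
        a = lomb_periodogram(IBISeries(intervals=iv, beat_times=t))
        b = lomb_periodogram(IBISeries(intervals=iv + 200.0, beat_times=t))
        np.testing.assert_allclose(a.power, b.power, rtol=1e-9)

    def test_riemann_sum_matches_variance(self):
        rng = np.random.default_rng(2)
        t = np.cumsum(rng.uniform(0.8, 1.2, size=500))
        iv = 900.0 + 40.0 * rng.standard_normal(t.size)
        spec = lomb_periodogram(IBISeries(intervals=iv, beat_times=t))
        assert spec.power.sum() * spec.df == pytest.approx(
            np.var(iv, ddof=1), rel=1e-9)

    def test_short_duration_rejected_with_minimum(self):
        s = _series([800.0] * 20)
        with pytest.raises(ValidationError, match="303"):
            lomb_periodogram(s)


class TestBandPowers:
    def test_all_mass_in_hf(self):
        freqs = 0.4 * np.arange(1, 1025) / 1024
        power = np.zeros(1024)
        power[np.argmin(np.abs(freqs - 0.25))] = 5.0
        bp = band_powers(SpectralEstimate(freqs=freqs, power=power))
        assert bp.vlf == 0.0 and bp.lf == 0.0
        assert bp.hf == pytest.approx(power.sum() * (0.4 / 1024))
        assert bp.lf_hf == 0.0

    def test_partition_subadditivity(self):
        rng = np.random.default_rng(4)
        freqs = 0.4 * np.arange(1, 1025) / 1024
        power = rng.uniform(0, 1, size=1024)
        bp = band_powers(SpectralEstimate(freqs=freqs, power=power))
        total = power.sum() * (0.4 / 1024)
        assert bp.vlf + bp.lf + bp.hf <= total + 1e-12

    def test_zero_hf_gives_nan_ratio_not_exception(self):
        freqs = 0.4 * np.arange(1, 1025) / 1024
        power = np.zeros(1024)
        power[100] = 1.0  # ~0.039 Hz, inside VLF
        bp = band_powers(SpectralEstimate(freqs=freqs, power=power))
        assert math.isnan(bp.lf_hf)

    def test_spectrum_must_cover_bands(self):
        freqs = np.linspace(0.05, 0.3, 100)
        with pytest.raises(ValidationError):
            band_powers(SpectralEstimate(freqs=freqs, power=np.ones(100)))

    def test_equal_amplitude_tones_give_unit_ratio(self):
        cfg = SyntheticConfig(n_beats=1000, mean_rr=900.0, rr_noise_sd=0.0,
                              lf_amp=50.0, hf_amp=50.0, seed=3)
        rr = generate_rr_series(cfg)
        bp = band_powers(lomb_periodogram(rr))
        assert 0.8 <= bp.lf_hf <= 1.25


class TestComputeAll:
    def test_composition_matches_parts(self):
        cfg = SyntheticConfig(n_beats=400, seed=11)
        rr = generate_rr_series(cfg)
        idx = compute_all(rr)
        td = time_domain(rr)
        pc = poincare(rr)
        bp = band_powers(lomb_periodogram(rr))
        assert idx.avnn == td.avnn and idx.rmssd == td.rmssd
        assert idx.sd1 == pc.sd1 and idx.sd2 == pc.sd2
        assert idx.lf == bp.lf and idx.hf == bp.hf

    def test_parameter_recovery_healthy_like(self):
        cfg = SyntheticConfig(n_beats=400, mean_rr=950.0, rr_noise_sd=55.0,
                              lf_amp=75.0, hf_amp=65.0, seed=29)
        rr = generate_rr_series(cfg)
        idx = compute_all(rr)
        assert idx.avnn == pytest.approx(950.0, rel=0.10)
        expected_sdnn = math.sqrt((75.0 ** 2 + 65.0 ** 2) / 2 + 55.0 ** 2)
        assert idx.sdnn == pytest.approx(expected_sdnn, rel=0.15)

    def test_index_table_order(self):
        cfg = SyntheticConfig(n_beats=400, seed=1)
        series = compute_all(generate_rr_series(cfg)).as_series()
        assert list(series.index) == list(INDEX_NAMES)
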