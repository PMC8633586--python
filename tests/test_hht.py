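"""Empirical mode decomposition and Hilbert spectral analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vmibci.hht import (
    InextricableError,
    count_zero_crossings,
    emd,
    envelope_mean,
    find_extrema,
    hilbert_envelope,
    instantaneous_energy,
    is_imf,
    sift,
)
from vmibci.synth import generate_tone

FS = 250.0


def tone(freq, amp=1.0, n=750, phase=0.0):
    return generate_tone(freq, amp, FS, n, phase)


class TestFindExtrema:
    @pytest.mark.parametrize(
        "x, exp_max, exp_min",
        [
            ([0, 1, 0, -1, 0], [1], [3]),
            ([0, 1, 2, 3, 4], [], []),  # monotone ramp
            ([0, 1, 1, 0], [1], []),  # plateau -> lower-middle index
            ([0, 1, 1, 1, 0], [2], []),  # odd plateau -> midpoint
            ([0, -2, -2, 0, 5], [], [1]),
            ([3, 3, 3, 3], [], []),
        ],
    )
    def test_known_cases(self, x, exp_max, exp_min):
        mx, mn = find_extrema(np.asarray(x, dtype=float))
        assert list(mx) == exp_max
        assert list(mn) == exp_min

    def test_tone_extrema_count(self):
        # 10 Hz over 1 s: 10 maxima and 10 minima, all strict
        x = tone(10.0, n=250)
        mx, mn = find_extrema(x)
        assert 9 <= len(mx) <= 10 and 9 <= len(mn) <= 10

    @given(
        st.lists(
            st.integers(min_value=-5, max_value=5), min_size=3, max_size=40
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_extrema_are_strict_and_interleaved(self, vals):
        x = np.asarray(vals, dtype=float)
        mx, mn = find_extrema(x)
        for i in mx:
            assert 0 < i < len(x) - 1
        # maxima and minima alternate when merged in index order
        merged = sorted([(i, "M") for i in mx] + [(i, "m") for i in mn])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestEnvelopeMean:
    def test_pure_tone_interior_mean_near_zero(self):
        x = tone(10.0)
        mx, mn = find_extrema(x)
        m = envelope_mean(x, mx, mn)
        interior = slice(75, 675)
        assert np.abs(m[interior]).max() < 0.02

    def test_shift_equivariance(self):
        x = tone(10.0)
        mx, mn = find_extrema(x)
        m0 = envelope_mean(x, mx, mn)
        m5 = envelope_mean(x + 5.0, mx, mn)
        assert np.allclose(m5 - m0, 5.0, atol=1e-9)
        assert np.abs(m5[75:675] - 5.0).max() < 0.02

    def test_minimum_extrema_boundary(self):
        # exactly 2 maxima / 2 minima is valid input
        x = tone(2.0, n=260)  # ~2 cycles
        mx, mn = find_extrema(x)
        assert len(mx) == 2 and len(mn) == 2
        out = envelope_mean(x, mx, mn)
        assert out.shape == x.shape and np.all(np.isfinite(out))

    def test_too_few_extrema_raises(self):
        x = np.linspace(0, 1, 50) ** 2
        mx, mn = find_extrema(x)
        with pytest.raises(InextricableError):
            envelope_mean(x, mx, mn)


class TestSift:
    def test_pure_tone_is_near_fixed_point(self):
        x = tone(10.0)
        imf, iters = sift(x)
        interior = slice(75, 675)
        rel = np.abs(imf[interior] - x[interior]).max() / np.abs(x).max()
        assert rel < 0.01
        assert iters <= 5
        assert is_imf(imf)

    def test_resift_converges_immediately(self):
        imf, _ = sift(tone(10.0))
        again, iters = sift(imf)
        assert iters == 1
        assert np.allclose(again[75:675], imf[75:675], atol=0.01)

    def test_inextricable_input_raises(self):
        with pytest.raises(InextricableError):
            sift(np.linspace(0.0, 1.0, 100))


class TestEmd:
    def test_constant_input_yields_no_imfs(self):
        x = np.full(100, 3.7)
        dec = emd(x, fs=FS)
        assert dec.n_imfs == 0
        assert np.array_equal(dec.residual, x)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            emd(np.zeros(5), fs=FS)

    def test_two_tone_mixture_separates(self):
        hi, lo = tone(10.0), tone(2.0)
        dec = emd(hi + lo, fs=FS)
        assert dec.n_imfs >= 2
        interior = slice(37, 713)
        assert np.corrcoef(dec.imfs[0][interior], hi[interior])[0, 1] > 0.95
        assert np.corrcoef(dec.imfs[1][interior], lo[interior])[0, 1] > 0.95

    def test_reconstruction_exact(self, rng):
        x = rng.standard_normal(750)
        dec = emd(x, fs=FS)
        err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
        assert err < 1e-9

    def test_every_imf_satisfies_counting_condition(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            dec = emd(x, fs=FS)
            for c in dec.imfs:
                mx, mn = find_extrema(c)
                assert abs(mx.size + mn.size - count_zero_crossings(c)) <= 1

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(400)
        d1 = emd(x, fs=FS)
        d2 = emd(7.5 * x, fs=FS)
        assert d1.n_imfs == d2.n_imfs
        for a, b in zip(d1.imfs, d2.imfs):
            assert np.allclose(7.5 * a, b, rtol=1e-6, atol=1e-9)

    def test_residual_is_monotone_or_single_pole(self, rng):
        x = rng.standard_normal(600) + np.linspace(0, 4, 600)
        dec = emd(x, fs=FS)
        mx, mn = find_extrema(dec.residual)
        assert mx.size + mn.size <= 1 or mx.size < 2 or mn.size < 2


class TestHilbertEnvelope:
    def test_cosine_amplitude_and_phase_slope(self):
        t = np.arange(0, 2, 1 / FS)
        env = hilbert_envelope(np.cos(2 * np.pi * 10 * t), FS)
        edge = int(0.05 * t.size)
        core = slice(edge, -edge)
        assert np.abs(env.amplitude[core] - 1.0).max() < 0.02
        slope = np.polyfit(t[core], env.unwrapped_phase()[core], 1)[0]
        assert abs(slope - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.02

    def test_zero_signal_zero_amplitude(self):
        env = hilbert_envelope(np.zeros(100), FS)
        assert np.all(env.amplitude == 0)

    def test_amplitude_homogeneity(self):
        t = np.arange(0, 2, 1 / FS)
        env = hilbert_envelope(3.0 * np.cos(2 * np.pi * 10 * t), FS)
        edge = int(0.05 * t.size)
        assert np.abs(env.amplitude[edge:-edge] - 3.0).max() < 0.06

    def test_amplitude_is_modulus_of_analytic(self, rng):
        x = rng.standard_normal(300)
        env = hilbert_envelope(x, FS)
        assert np.allclose(
            env.amplitude,
            np.hypot(env.real_part, env.quad_part),
            atol=1e-12,
        )
        assert np.all(env.phase > -np.pi) and np.all(env.phase <= np.pi)


class TestInstantaneousEnergy:
    def test_constant_signal(self):
        es = instantaneous_energy(np.full(50, 2.0), fs=100.0)
        assert np.allclose(es.values, 4.0)

    def test_hand_evaluated_prefix(self):
        es = instantaneous_energy(np.array([1.0, 2.0]), fs=1e6)
        assert np.allclose(es.values, [1.0, 2.5])

    def test_zeros(self):
        es = instantaneous_energy(np.zeros(20), fs=10.0)
        assert np.all(es.values == 0)

    def test_trailing_window_global_vs_window_norm(self):
        c = np.ones(10)
        global_n = instantaneous_energy(c, fs=4.0, norm="global_n")
        windowed = instantaneous_energy(c, fs=4.0, norm="window_length")
        # N <= Fs: both are the running mean square = 1
        assert np.allclose(global_n.values[:4], 1.0)
        assert np.allclose(windowed.values[:4], 1.0)
        # N > Fs: the default keeps the 1/N prefactor on a 4-sample sum
        n = np.arange(5, 11)
        assert np.allclose(global_n.values[4:], 4.0 / n)
        assert np.allclose(windowed.values[4:], 1.0)

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10), min_size=1, max_size=30
        ),
        st.integers(min_value=1, max_value=12),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_direct_double_loop(self, vals, fs):
        c = np.asarray(vals)
        es = instantaneous_energy(c, fs=float(fs))
        for i in range(len(c)):
            n = i + 1
            lo = max(n - fs, 0)
            expected = np.sum(c[lo:n] ** 2) / n
            assert es.values[i] == pytest.approx(expected, abs=1e-12)
        assert np.all(es.values >= 0)
        assert es.values.max() <= (c**2).max() + 1e-12
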