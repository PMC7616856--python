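import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammalink.spectral import (
    PhaseSpectrum,
    SpectralCoeffs,
    align_to_gamma_peak,
    find_gamma_peak,
    lfp_lfp_ppc,
    multitaper_coeffs,
    pairwise_consistency,
    power_spectrum,
    tf_lfp_ppc,
)
from gammalink.synthdata import one_over_f_noise

FS = 1000.0


def brute_force_ppc(phases):
    n = len(phases)
    tot = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            tot += np.cos(phases[j] - phases[k])
    return tot / (n * (n - 1) / 2)


@settings(deadline=None, max_examples=30)
@given(
    st.lists(st.floats(min_value=-np.pi, max_value=np.pi), min_size=2, max_size=40)
)
def test_pairwise_identity_matches_brute_force(phases):
    """The O(n) algebraic identity equals the all-pairs mean cosine."""
    u = np.exp(1j * np.array(phases))
    assert pairwise_consistency(u) == pytest.approx(brute_force_ppc(phases), abs=1e-10)


class TestMultitaper:
    def test_frequency_resolution(self):
        c = multitaper_coeffs(np.zeros((1, 500)), FS)
        assert np.allclose(np.diff(c.freqs)[0], 2.0)
        assert c.coeffs.shape == (1, 7, 251)

    def test_tone_at_grid_frequency_peaks(self):
        t = np.arange(500) / FS
        tone = np.cos(2 * np.pi * 60 * t)
        c = multitaper_coeffs(tone[None, :], FS)
        # taper-averaged power peaks at the tone; per-taper peaks stay
        # inside the 2NW/T = 16 Hz concentration band
        p = (np.abs(c.coeffs[0]) ** 2).mean(axis=0)
        assert c.freqs[np.argmax(p)] == pytest.approx(60, abs=2)
        for k in range(7):
            assert c.freqs[np.argmax(np.abs(c.coeffs[0, k]))] == pytest.approx(60, abs=8)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            multitaper_coeffs(np.zeros((1, 400)), FS)


class TestPower:
    def test_zero_signal(self):
        c = multitaper_coeffs(np.zeros((3, 500)), FS)
        assert np.allclose(power_spectrum(c), 0)

    def test_quadratic_scaling(self, rng):
        x = rng.standard_normal((4, 500))
        p1 = power_spectrum(multitaper_coeffs(x, FS))
        p2 = power_spectrum(multitaper_coeffs(2 * x, FS))
        assert np.allclose(p2, 4 * p1)

    def test_f2_scale_flattens_brown_noise(self, rng):
        # power ~ 1/f^2 background becomes approximately flat after f^2 scaling
        x = np.stack(
            [one_over_f_noise(500, FS, exponent=2.0, rng=rng) for _ in range(300)]
        )
        p = power_spectrum(multitaper_coeffs(x, FS), f2_scale=True)
        sel = (np.fft.rfftfreq(500, 1 / FS) > 20) & (np.fft.rfftfreq(500, 1 / FS) < 400)
        lo = np.mean(p[sel][: sel.sum() // 2])
        hi = np.mean(p[sel][sel.sum() // 2 :])
        assert 0.5 < lo / hi < 2.0


def coeffs_from_phases(phases_a, phases_b):
    """Single-frequency coefficient pair with given per-epoch phases."""
    ca = np.exp(1j * np.asarray(phases_a))[:, None, None]
    cb = np.exp(1j * np.asarray(phases_b))[:, None, None]
    f = np.array([60.0])
    return (
        SpectralCoeffs(ca, f, 0.5, 1),
        SpectralCoeffs(cb, f, 0.5, 1),
    )


class TestLfpLfpPPC:
    def test_constant_offset_gives_one(self):
        a, b = coeffs_from_phases([0.3, 1.1, 2.0], [0.3 - np.pi / 2, 1.1 - np.pi / 2, 2.0 - np.pi / 2])
        sp = lfp_lfp_ppc(a, b)
        assert sp.values[0] == pytest.approx(1.0)
        assert sp.rel_phase[0] == pytest.approx(np.pi / 2)

    def test_antipodal_pair(self):
        a, b = coeffs_from_phases([0.0, np.pi], [0.0, 0.0])
        assert lfp_lfp_ppc(a, b).values[0] == pytest.approx(-1.0)

    def test_two_by_two_antipodal(self):
        a, b = coeffs_from_phases([0, 0, np.pi, np.pi], [0, 0, 0, 0])
        assert lfp_lfp_ppc(a, b).values[0] == pytest.approx(-1 / 3)

    def test_fewer_than_two_epochs_rejected(self):
        a, b = coeffs_from_phases([0.0], [0.0])
        with pytest.raises(ValueError):
            lfp_lfp_ppc(a, b)

    def test_phase_shifted_copy_full_consistency(self, rng):
        x = rng.standard_normal((20, 500))
        ca = multitaper_coeffs(x, FS)
        cb = multitaper_coeffs(x, FS)
        cb.coeffs = cb.coeffs * np.exp(1j * 0.7)
        sp = lfp_lfp_ppc(ca, cb)
        assert np.allclose(sp.values, 1.0, atol=1e-10)

    def test_null_mean_near_zero(self, rng):
        # E[PPC] ~ 0 under independent phases
        vals = []
        for _ in range(200):
            a, b = coeffs_from_phases(
                rng.uniform(-np.pi, np.pi, 20), rng.uniform(-np.pi, np.pi, 20)
            )
            vals.append(lfp_lfp_ppc(a, b).values[0])
        assert abs(np.mean(vals)) < 0.01

    def test_no_sample_size_bias(self, rng):
        # fixed coupling: expectation invariant to epoch count, unlike
        # the naive squared resultant which inflates at small n
        kappa = 1.0

        def sample(n):
            rel = rng.vonmises(0.0, kappa, n)
            a, b = coeffs_from_phases(rel, np.zeros(n))
            u = np.exp(1j * rel)
            naive = np.abs(u.mean()) ** 2
            return lfp_lfp_ppc(a, b).values[0], naive

        small = np.array([sample(5) for _ in range(2000)])
        large = np.array([sample(80) for _ in range(300)])
        # PPC unbiased across n; naive estimator biased upward at small n
        assert abs(small[:, 0].mean() - large[:, 0].mean()) < 0.03
        assert small[:, 1].mean() - large[:, 1].mean() > 0.1


class TestAlignment:
    @staticmethod
    def peaked(freqs, f0):
        return PhaseSpectrum(freqs=freqs, values=np.exp(-((freqs - f0) ** 2) / 20.0), n=10)

    def test_single_session_peak_at_zero_offset(self):
        f = np.arange(20, 101, 2.0)
        off, mean, peaks = align_to_gamma_peak([self.peaked(f, 60)])
        assert peaks == [60.0]
        assert off[np.argmax(mean)] == pytest.approx(0.0)

    def test_two_sessions_superimpose(self):
        f = np.arange(20, 101, 2.0)
        off, mean, peaks = align_to_gamma_peak([self.peaked(f, 44), self.peaked(f, 60)])
        assert peaks == [44.0, 60.0]
        assert off[np.argmax(mean)] == pytest.approx(0.0)

    def test_flat_spectrum_excluded(self):
        f = np.arange(20, 101, 2.0)
        flat = PhaseSpectrum(freqs=f, values=np.ones_like(f), n=5)
        off, mean, peaks = align_to_gamma_peak([flat, self.peaked(f, 50)])
        assert peaks[0] is None and peaks[1] == 50.0

    def test_all_flat_rejected(self):
        f = np.arange(20, 101, 2.0)
        flat = PhaseSpectrum(freqs=f, values=np.ones_like(f), n=5)
        with pytest.raises(ValueError):
            align_to_gamma_peak([flat])

    def test_find_peak_monotone_rejected(self):
        f = np.arange(20, 101, 2.0)
        with pytest.raises(ValueError):
            find_gamma_peak(f, f.astype(float))


class TestTimeFrequencyPPC:
    def test_window_arithmetic_masks_edges(self, rng):
        x = rng.standard_normal((6, 1000))
        times, ppc, valid = tf_lfp_ppc(x, x, FS, np.array([50.0]), step=0.01)
        # +-2.5 cycles at 50 Hz -> half window 50 ms: first/last 50 ms invalid
        assert not valid[0, times < 0.05].any()
        assert valid[0, (times > 0.06) & (times < 0.93)].all()

    def test_stationary_coupling_flat_in_time(self, rng):
        t = np.arange(1000) / FS
        ph = rng.uniform(-np.pi, np.pi, (30, 1))
        a = np.cos(2 * np.pi * 60 * t + ph) + 0.2 * rng.standard_normal((30, 1000))
        b = np.cos(2 * np.pi * 60 * t + ph + 1.0) + 0.2 * rng.standard_normal((30, 1000))
        _, ppc, valid = tf_lfp_ppc(a, b, FS, np.array([60.0]), step=0.02)
        vals = ppc[0, valid[0]]
        assert vals.min() > 0.6
        assert vals.std() < 0.1

    def test_coupling_onset_detected_within_window(self, rng):
        t = np.arange(1000) / FS
        onset = 0.5
        ph = rng.uniform(-np.pi, np.pi, (40, 1))
        jitter = rng.uniform(-np.pi, np.pi, (40, 1))
        carrier = np.cos(2 * np.pi * 60 * t + ph)
        a = carrier + 0.1 * rng.standard_normal((40, 1000))
        b = np.where(
            t >= onset,
            np.cos(2 * np.pi * 60 * t + ph + 0.8),
            np.cos(2 * np.pi * 60 * t + jitter),
        ) + 0.1 * rng.standard_normal((40, 1000))
        times, ppc, valid = tf_lfp_ppc(a, b, FS, np.array([60.0]), step=0.01)
        pre = ppc[0, valid[0] & (times < onset - 0.06)]
        post = ppc[0, valid[0] & (times > onset + 0.06)]
        assert pre.mean() < 0.2
        assert post.mean() > 0.7
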