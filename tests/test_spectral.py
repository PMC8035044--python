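import numpy as np
import pytest

from lgnbinoc import spectral, synthetic_data as sd
from lgnbinoc.phase_response import autocorr_matrix
from lgnbinoc.spectral import (F1Response, f1_from_binaries, f1_response,
                               irasa, power_at_frequency, psd,
                               responsiveness_test)


def pink_noise(rng, n_signals, n=1100, n_full=4096):
    w = rng.normal(size=(n_signals, n_full))
    W = np.fft.rfft(w, axis=1)
    f = np.fft.rfftfreq(n_full, 1e-3)
    f[0] = f[1]
    return np.fft.irfft(W / np.sqrt(f), axis=1)[:, :n]


class TestPsd:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(1100) / 1000.0
        f, P = psd(np.cos(2 * np.pi * 4 * t))
        assert f[np.argmax(P)] == pytest.approx(4.0, abs=0.25)

    def test_dc_goes_to_zero_after_detrending(self):
        f, P = psd(np.full(1100, 3.0))
        assert P.max() < 1e-20

    def test_dc_input_without_detrend_stays_below_resolution(self):
        f, P = psd(np.full(1100, 3.0), detrend="none")
        # all power inside the window mainlobe around 0 Hz
        assert f[np.argmax(P)] < 1.0
        assert P[f > 2.0].max() < 1e-3 * P.max()  # only Hann sidelobes remain

    def test_two_tone_amplitude_ratio_preserved_in_power(self):
        t = np.arange(4000) / 1000.0
        x = 2 * np.cos(2 * np.pi * 4 * t) + 1 * np.cos(2 * np.pi * 8 * t)
        f, P = psd(x)
        p4 = P[np.argmin(np.abs(f - 4))]
        p8 = P[np.argmin(np.abs(f - 8))]
        assert p4 / p8 == pytest.approx(4.0, rel=0.05)

    def test_grid_spacing_meets_target_resolution(self):
        f, P = psd(np.zeros(1100), target_resolution=0.25)
        assert np.diff(f)[0] == pytest.approx(0.25)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="length"):
            psd(np.zeros(64))


class TestIrasa:
    def test_decomposition_identity_is_exact(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 1100))
        trip = irasa(X)
        np.testing.assert_allclose(trip.oscillatory + trip.fractal,
                                   trip.total, rtol=1e-12)

    def test_pink_noise_band_oscillatory_residual_small(self):
        # on pure fractal input the rhythmic component should carry < 10%
        # of the band's fractal power; per-bin residuals sit at the chi2
        # noise floor of a 100-window average (~10%/bin SD)
        rng = np.random.default_rng(0)
        m = irasa(pink_noise(rng, 100), mode="average")
        band = (m.freqs >= 1) & (m.freqs <= 20)
        integrated = np.abs(m.oscillatory[band]).sum() / m.fractal[band].sum()
        assert integrated < 0.10
        per_bin = np.abs(m.oscillatory[band]) / m.fractal[band]
        assert per_bin.max() < 0.35

    def test_tone_in_pink_noise_recovered_fractal_preserved(self):
        rng = np.random.default_rng(1)
        X = pink_noise(rng, 100)
        tone = 0.5 * np.cos(2 * np.pi * 4 * np.arange(1100) / 1000.0)
        m0 = irasa(X, mode="average")
        m1 = irasa(X + tone, mode="average")
        band = (m1.freqs >= 1) & (m1.freqs <= 20)
        sel = m1.freqs > 1
        assert m1.freqs[sel][np.argmax(m1.oscillatory[sel])] == pytest.approx(4.0)
        i4 = np.argmin(np.abs(m1.freqs - 4.0))
        assert m1.oscillatory[i4] > 5 * np.median(np.abs(m1.oscillatory[band]))
        # fractal estimate barely perturbed by the added tone
        keep = band & (np.abs(m1.freqs - 4.0) > 1.0)
        rel = np.abs(m1.fractal[keep] - m0.fractal[keep]) / m0.fractal[keep]
        assert np.median(rel) < 0.2

    def test_white_noise_fractal_is_flat(self):
        rng = np.random.default_rng(3)
        m = irasa(rng.normal(size=(100, 1100)), mode="average")
        band = (m.freqs >= 2) & (m.freqs <= 100)
        slope = np.polyfit(np.log(m.freqs[band]), np.log(m.fractal[band]), 1)[0]
        assert abs(slope) < 0.1

    def test_single_bin_fast_path_matches_full_grid(self):
        rng = np.random.default_rng(7)
        X = (rng.uniform(size=(8, 1000)) < 0.02).astype(float)
        from lgnbinoc.phase_response import autocorr_matrix
        V, _ = autocorr_matrix(X)
        V = V[~np.isnan(V).any(axis=1)]
        trip = irasa(V)
        fast = spectral.irasa_at_frequencies(V, [4.0, 8.0])
        for f in (4.0, 8.0):
            osc_full, frac_full = power_at_frequency(trip, f)
            osc_fast, frac_fast = fast[f]
            np.testing.assert_allclose(osc_fast, osc_full, rtol=1e-9)
            np.testing.assert_allclose(frac_fast, frac_full, rtol=1e-9)

    def test_degenerate_h_rejected(self):
        with pytest.raises(ValueError):
            irasa(np.zeros((2, 1100)), hset=(1.0, 1.5))

    def test_too_short_after_compression_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            irasa(np.zeros((2, 150)))


class TestPowerAtFrequency:
    def test_exact_bin_and_nearest_bin_lookup(self):
        t = np.arange(1100) / 1000.0
        trip = irasa(np.cos(2 * np.pi * 4 * t)[None, :] + 0.01)
        o1, f1_ = power_at_frequency(trip, 4.0)
        o2, f2_ = power_at_frequency(trip, 4.1)  # nearest bin is 4.0
        assert o1 == o2 and f1_ == f2_

    def test_tie_breaks_toward_lower_frequency(self):
        trip = spectral.PsdTriple(freqs=np.array([3.875, 4.0, 4.125]),
                                  total=np.array([1.0, 2.0, 3.0]),
                                  fractal=np.array([0.1, 0.2, 0.3]))
        osc, frac = power_at_frequency(trip, 3.9375)  # equidistant
        assert osc == pytest.approx(0.9)

    def test_outside_grid_raises(self):
        t = np.arange(1100) / 1000.0
        trip = irasa(np.cos(2 * np.pi * 4 * t)[None, :])
        with pytest.raises(ValueError):
            power_at_frequency(trip, 1e6)


class TestF1Response:
    def test_driven_unit_f1_exceeds_blank_f1(self):
        rng = np.random.default_rng(4)
        cfg = sd.archetype_config("P")
        cond = sd.Condition(0.9, 0.0, 4.0, 1.0, "achromatic", 1000.0)
        blank = sd.Condition(0.0, 0.0, 4.0, 1.0, "none", 1000.0, is_blank=True)
        driven = f1_from_binaries(sd.simulate_binaries(cfg, cond, 30, rng), 4.0)
        rest = f1_from_binaries(sd.simulate_binaries(cfg, blank, 30, rng), 4.0)
        assert driven.mean > 5 * abs(rest.mean)

    def test_doubling_unit_has_more_power_at_8_than_4(self):
        rng = np.random.default_rng(5)
        cfg = sd.archetype_config("M")
        cond = sd.Condition(0.9, 0.0, 4.0, 1.0, "L-M", 1000.0)
        B = sd.simulate_binaries(cfg, cond, 30, rng)
        V, _ = autocorr_matrix(B)
        trip = irasa(V)
        o4, _ = power_at_frequency(trip, 4.0)
        o8, _ = power_at_frequency(trip, 8.0)
        assert np.mean(o8) > np.mean(o4)

    def test_zero_spike_trials_counted_not_crashed(self):
        A = np.vstack([np.full(1100, np.nan),
                       trial_vec()])
        resp = f1_response(A, 4.0)
        assert resp.n_excluded == 1
        assert resp.n_trials == 1


def trial_vec():
    x = np.zeros(1100)
    x[[10, 260, 510, 760]] = 1
    V, _ = autocorr_matrix(x[None, :])
    return V[0]


class TestResponsiveness:
    def _f1(self, cfg, cond, n, rng, f=4.0):
        return f1_from_binaries(sd.simulate_binaries(cfg, cond, n, rng), f)

    def test_strongly_driven_unit_is_responsive(self):
        rng = np.random.default_rng(6)
        cfg = sd.archetype_config("P")  # drive >> baseline at high contrast
        cond = sd.Condition(0.9, 0.0, 4.0, 1.0, "achromatic", 1000.0)
        blankc = sd.Condition(0.0, 0.0, 4.0, 1.0, "none", 1000.0, is_blank=True)
        stim = self._f1(cfg, cond, 30, rng)
        blank = self._f1(cfg, blankc, 30, rng)
        res = responsiveness_test(stim, blank)
        assert res.responsive
        assert res.p_versus_blank < 0.05 and res.p_osc_versus_fractal < 0.05

    def test_single_trial_sample_is_untestable(self):
        stim = F1Response(np.array([1.0]), np.array([0.5]), 4.0)
        res = responsiveness_test(stim, None)
        assert res.status == "untestable" and not res.responsive

    def test_missing_blanks_never_silently_pass(self):
        stim = F1Response(np.array([1.0, 2.0, 1.5]), np.array([0.1, 0.2, 0.1]), 4.0)
        res = responsiveness_test(stim, None)
        assert res.status == "untestable"
        assert not res.responsive
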